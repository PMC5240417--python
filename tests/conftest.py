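"""Shared fixtures: small simulated datasets and count-matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import triodiff as td
from triodiff.containers import CountMatrix, NormalizedCounts
from triodiff.simulate import TRIO_MODES


def make_count_matrix(
    counts: np.ndarray,
    group_sizes: dict[str, int],
    tissue: str = "leaf",
    gene_prefix: str = "g",
) -> CountMatrix:
    """Wrap a genes x samples array with generated metadata.

    ``group_sizes`` maps species label -> number of replicate columns, in
    order left to right.
    """
    names, meta = [], []
    for sp, n in group_sizes.items():
        for rep in range(1, n + 1):
            names.append(f"{sp}_{tissue}_rep{rep}")
            meta.append({"sample": names[-1], "species": sp, "tissue": tissue, "replicate": rep})
    frame = pd.DataFrame(
        np.asarray(counts), columns=names,
        index=[f"{gene_prefix}{i}" for i in range(np.asarray(counts).shape[0])],
    )
    return CountMatrix(frame, pd.DataFrame(meta))


def unit_normalized(cm: CountMatrix) -> NormalizedCounts:
    return NormalizedCounts(cm, pd.Series(1.0, index=cm.counts.columns))


def equal_mode_proportions() -> dict[str, float]:
    """The six inheritance modes in equal shares, no conserved genes."""
    props = {m: 1.0 / 6.0 for m in TRIO_MODES if m != "conserved"}
    props["conserved"] = 0.0
    props["F1d_under"] = 1.0 - sum(v for k, v in props.items() if k != "F1d_under")
    return props


def recovery_config(seed: int, n_genes: int = 2000, replicates: int = 6) -> td.SimulationConfig:
    """Well-powered design for classification-recovery checks: six
    replicates per tissue, 4-fold minimum parental divergence, one log2 of
    transgressive margin, moderate dispersion."""
    return td.SimulationConfig(
        n_genes=n_genes,
        replicates_per_tissue=replicates,
        mode_proportions=equal_mode_proportions(),
        singleton_fraction_per_species=0.0,
        parental_log2fc_min=2.0,
        transgressive_margin_log2=1.0,
        dispersion=0.05,
        seed=seed,
    )


def integrate_trio(matrices, truth):
    """Group-level count matrix built from the simulated ortholog links."""
    from triodiff import orthologs, simulate

    sets = {sp: set(matrices[sp].counts.index) for sp in matrices}
    pairs = orthologs.pairs_from_frame(simulate.simulate_ortholog_pairs(truth))
    groups = orthologs.build_groups(pairs, sets)
    return groups, orthologs.counts_to_groups(groups, matrices)


@pytest.fixture(scope="session")
def small_trio():
    """A small but complete simulated trio shared across tests."""
    cfg = td.SimulationConfig(n_genes=400, replicates_per_tissue=3, seed=11)
    matrices, truth = td.simulate_trio(cfg)
    return cfg, matrices, truth
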