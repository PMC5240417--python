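"""Synthetic trio generator: negative-binomial counts for two parents and
their F1 hybrid, with per-gene inheritance modes and ground-truth labels.

The generator emulates the statistical structure the downstream analysis
assumes: per-gene group means for parent1 / parent2 / hybrid placed according
to a true inheritance mode, gene-wise NB dispersion (Var = mu + alpha*mu^2),
per-sample library-size factors, several tissues with replicated libraries,
and species-specific ("singleton") genes that exist in only one assembly.

Modes
-----
``conserved``
    all three means equal (not a DEG between the parents).
``F1a``
    additive: hybrid mean is exactly the mid-parent value (MPV) on the
    linear expected-count scale, (mu1 + mu2) / 2.
``F1b_P1`` / ``F1b_P2``
    complete dominance: hybrid mean equals one parent's mean.
``F1c``
    incomplete dominance: hybrid mean strictly between the parents but at
    least ``transgressive_margin_log2`` away from the MPV in log2.
``F1d_over`` / ``F1d_under``
    transgressive: hybrid mean beyond the higher (lower) parent by more
    than the margin.

Singleton genes are present in exactly one species' count matrix; the other
two species carry structural zeros for them once counts are integrated into
ortholog groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import ConfigurationError

SPECIES = ("parent1", "parent2", "hybrid")

TRIO_MODES = ("conserved", "F1a", "F1b_P1", "F1b_P2", "F1c", "F1d_over", "F1d_under")

#: default mode mix: mostly conserved genes, the rest split roughly like the
#: inheritance spectrum observed in interspecific F1 crosses (complete
#: dominance dominating, additivity and transgression rare).
DEFAULT_MODE_PROPORTIONS: dict[str, float] = {
    "conserved": 0.70,
    "F1a": 0.0105,
    "F1b_P1": 0.1302,
    "F1b_P2": 0.1122,
    "F1c": 0.0205,
    "F1d_over": 0.0203,
    "F1d_under": 0.0063,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trio.

    Defaults mirror the design of a two-tissue, two-replicate bulk RNA-seq
    comparison of an F1 hybrid and its parents: parental fold changes are
    kept at or above the 2-fold DEG threshold so non-conserved genes are
    detectable in principle, and about a fifth of each species' genes are
    species-specific singletons.
    """

    n_genes: int = 5000
    replicates_per_tissue: int = 2
    tissues: Sequence[str] = ("leaf", "corolla")
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    singleton_fraction_per_species: float = 0.2
    base_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    parental_log2fc_min: float = 2.0
    parental_log2fc_spread: float = 2.0
    dispersion: float | Sequence[float] = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    transgressive_margin_log2: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.replicates_per_tissue <= 0:
            raise ConfigurationError("replicates_per_tissue must be positive")
        if not self.tissues:
            raise ConfigurationError("at least one tissue required")
        unknown = set(self.mode_proportions) - set(TRIO_MODES)
        if unknown:
            raise ConfigurationError(f"unknown modes in mode_proportions: {sorted(unknown)}")
        props = np.array([self.mode_proportions.get(m, 0.0) for m in TRIO_MODES])
        if (props < 0).any():
            raise ConfigurationError("mode proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"mode_proportions must sum to 1, got {props.sum()!r}")
        if self.n_genes < int((props > 0).sum()):
            raise ConfigurationError("n_genes smaller than the number of active modes")
        if not 0 <= self.singleton_fraction_per_species < 1:
            raise ConfigurationError("singleton_fraction_per_species must lie in [0, 1)")
        if 3 * self.singleton_fraction_per_species >= 1:
            raise ConfigurationError("singleton fractions of the three species must sum below 1")
        if self.parental_log2fc_min < 1:
            raise ConfigurationError("parental_log2fc_min must be >= 1 (the DEG threshold)")
        if self.transgressive_margin_log2 <= 0:
            raise ConfigurationError("transgressive_margin_log2 must be positive")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp < 0).any():
            raise ConfigurationError("dispersion must be non-negative")
        if self.mode_proportions.get("F1c", 0.0) > 0:
            # an F1c mean a full margin away from the MPV must still fit
            # strictly between the parents
            needed = np.log2(2 ** (self.transgressive_margin_log2 + 1) - 1)
            if self.parental_log2fc_min <= needed:
                raise ConfigurationError(
                    "F1c genes need parental_log2fc_min > "
                    f"log2(2^(margin+1)-1) = {needed:.3f}"
                )
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ConfigurationError("size_factor_range must be positive and ordered")


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per logical task."""
    streams = {"structure": 1, "means": 2, "counts": 3, "transcripts": 4}
    return np.random.default_rng([streams[stream], config.seed % (2**31)])


def _per_gene_dispersion(config: SimulationConfig) -> np.ndarray:
    disp = np.asarray(config.dispersion, dtype=float)
    if disp.ndim == 0:
        return np.full(config.n_genes, float(disp))
    if disp.shape[0] != config.n_genes:
        raise ConfigurationError("per-gene dispersion length must equal n_genes")
    return disp


def _assign_structure(config: SimulationConfig) -> pd.DataFrame:
    """Assign singleton status and true inheritance mode to each gene.

    Uses its own seeded substream so that count simulation and transcript
    table simulation agree on the assignments.
    """
    rng = _rng_for(config, "structure")
    n = config.n_genes
    gene_ids = np.array([f"g{i:06d}" for i in range(n)])
    singleton = np.array([""] * n, dtype=object)
    n_single = int(round(config.singleton_fraction_per_species * n))
    order = rng.permutation(n)
    for k, sp in enumerate(SPECIES):
        singleton[order[k * n_single : (k + 1) * n_single]] = sp
    modes = np.array(["singleton"] * n, dtype=object)
    trio = singleton == ""
    props = np.array([config.mode_proportions.get(m, 0.0) for m in TRIO_MODES])
    props = props / props.sum()
    modes[trio] = rng.choice(TRIO_MODES, size=int(trio.sum()), p=props)
    return pd.DataFrame({"gene_id": gene_ids, "true_mode": modes, "singleton_species": singleton})


def _tissue_means(
    config: SimulationConfig, structure: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-gene expected counts for each tissue and species.

    Tissue means are independent draws: the analysis treats tissues as
    separate experiments, so no shared tissue effect is modelled.
    """
    lo, hi = config.base_log2_mean_range
    margin = config.transgressive_margin_log2
    rows = []
    for tissue in config.tissues:
        base = 2.0 ** rng.uniform(lo, hi, size=len(structure))
        delta = rng.uniform(
            config.parental_log2fc_min,
            config.parental_log2fc_min + config.parental_log2fc_spread,
            size=len(structure),
        )
        # which parent carries the higher mean, per gene
        p2_higher = rng.random(len(structure)) < 0.5
        extra = rng.uniform(0.0, 1.0, size=len(structure))
        for i, rec in enumerate(structure.itertuples(index=False)):
            mode = rec.true_mode
            if rec.singleton_species:
                mu = {sp: 0.0 for sp in SPECIES}
                mu[rec.singleton_species] = base[i]
            elif mode == "conserved":
                mu = {sp: base[i] for sp in SPECIES}
            else:
                ratio = 2.0 ** (delta[i] / 2.0)
                lo_mu, hi_mu = base[i] / ratio, base[i] * ratio
                mu1, mu2 = (lo_mu, hi_mu) if p2_higher[i] else (hi_mu, lo_mu)
                mpv = 0.5 * (mu1 + mu2)
                if mode == "F1a":
                    mh = mpv
                elif mode == "F1b_P1":
                    mh = mu1
                elif mode == "F1b_P2":
                    mh = mu2
                elif mode == "F1c":
                    # a full margin below the MPV, still strictly inside the
                    # parental range (guaranteed by config validation)
                    mh = mpv / 2.0**margin
                elif mode == "F1d_over":
                    mh = max(mu1, mu2) * 2.0 ** (margin + extra[i])
                else:  # F1d_under
                    mh = min(mu1, mu2) / 2.0 ** (margin + extra[i])
                mu = {"parent1": mu1, "parent2": mu2, "hybrid": mh}
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "tissue": tissue,
                    "true_mode": mode,
                    "singleton_species": rec.singleton_species,
                    "parent1_mean": mu["parent1"],
                    "parent2_mean": mu["parent2"],
                    "hybrid_mean": mu["hybrid"],
                }
            )
    return pd.DataFrame(rows)


def species_gene_id(species: str, gene_id: str) -> str:
    """Species-local identifier for a simulated gene (its assembly id)."""
    return f"{species}_{gene_id}"


def simulate_trio(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame]:
    """Simulate count matrices for the trio plus a ground-truth table.

    Returns
    -------
    matrices
        ``{"parent1": CountMatrix, "parent2": ..., "hybrid": ...}``; each
        matrix holds only the genes present in that species, under
        species-local gene ids (``species_gXXXXXX``).
    truth
        one row per (gene, tissue): true mode, the three expected means,
        dispersion, singleton species ('' for trio genes), and the
        per-sample size factors encoded in the sample metadata.
    """
    config.validate()
    structure = _assign_structure(config)
    alpha = _per_gene_dispersion(config)
    mean_rng = _rng_for(config, "means")
    truth = _tissue_means(config, structure, mean_rng)
    truth["dispersion"] = np.tile(alpha, len(config.tissues))

    count_rng = _rng_for(config, "counts")
    lo_sf, hi_sf = config.size_factor_range
    matrices: dict[str, CountMatrix] = {}
    for sp_idx, sp in enumerate(SPECIES):
        present = structure["singleton_species"].isin(["", sp]).to_numpy()
        genes = structure.loc[present, "gene_id"].to_numpy()
        local_ids = [species_gene_id(sp, g) for g in genes]
        disp = alpha[present]
        cols, meta = {}, []
        for tissue in config.tissues:
            tmeans = truth[(truth["tissue"] == tissue)].set_index("gene_id")
            mu = tmeans.loc[genes, f"{sp}_mean"].to_numpy()
            for rep in range(1, config.replicates_per_tissue + 1):
                sf = count_rng.uniform(lo_sf, hi_sf)
                name = f"{sp}_{tissue}_rep{rep}"
                cols[name] = _nb_draw(count_rng, mu * sf, disp)
                meta.append(
                    {"sample": name, "species": sp, "tissue": tissue,
                     "replicate": rep, "true_size_factor": sf}
                )
        counts = pd.DataFrame(cols, index=pd.Index(local_ids, name="gene_id"))
        matrices[sp] = CountMatrix(counts, pd.DataFrame(meta))
    return matrices, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) draws with Var = mu + alpha mu^2; alpha=0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    poisson = pos & (alpha == 0)
    nb = pos & (alpha > 0)
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_ortholog_pairs(truth: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ortholog links implied by the simulated structure.

    Every non-singleton gene is present in all three assemblies, so it
    contributes the three pairwise edges; singletons contribute none.
    Output columns: species_a, gene_a, species_b, gene_b.
    """
    genes = truth.drop_duplicates("gene_id")
    trio = genes.loc[genes["singleton_species"] == "", "gene_id"]
    rows = []
    for g in trio:
        for a, b in (("parent1", "parent2"), ("parent1", "hybrid"), ("parent2", "hybrid")):
            rows.append(
                {"species_a": a, "gene_a": species_gene_id(a, g),
                 "species_b": b, "gene_b": species_gene_id(b, g)}
            )
    return pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b"])


def simulate_transcript_tables(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-species transcript tables for exercising unigene selection.

    Each gene becomes a cluster of 1-4 isoforms with lognormal lengths.
    One isoform per non-singleton cluster carries the ortholog flag (the
    cross-assembly evidence); FPKM values straddle the retention threshold
    of 2 and include exact 2.0 boundary records for threshold testing.
    """
    config.validate()
    structure = _assign_structure(config)
    rng = _rng_for(config, "transcripts")
    tables: dict[str, pd.DataFrame] = {}
    for sp in SPECIES:
        present = structure[structure["singleton_species"].isin(["", sp])]
        rows = []
        for j, rec in enumerate(present.itertuples(index=False)):
            cluster = species_gene_id(sp, rec.gene_id)
            n_iso = int(rng.integers(1, 5))
            lengths = np.maximum(200, rng.lognormal(7.0, 0.6, size=n_iso)).astype(int)
            fpkm = rng.uniform(0.0, 20.0, size=n_iso)
            if j == 0:
                fpkm[0] = 2.0  # exact-threshold boundary fixture
            has_orth = np.zeros(n_iso, dtype=bool)
            if rec.singleton_species == "":
                has_orth[int(rng.integers(0, n_iso))] = True
            for k in range(n_iso):
                rows.append(
                    {
                        "cluster_id": cluster,
                        "transcript_id": f"{cluster}_i{k + 1}",
                        "length_bp": int(lengths[k]),
                        "fpkm": float(fpkm[k]),
                        "has_ortholog": bool(has_orth[k]),
                    }
                )
        tables[sp] = pd.DataFrame(rows)
    return tables
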