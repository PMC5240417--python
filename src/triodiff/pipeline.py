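"""End-to-end orchestration: simulate/load -> unigenes -> groups ->
normalization -> differential expression -> inheritance -> reports.

Tissues are analysed separately throughout (separate dispersion estimates
and tests per tissue), mirroring a tissue-specific experimental design; the
overall summaries deduplicate groups across tissues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dge, inheritance, io, orthologs, reporting, simulate, unigenes
from .containers import CountMatrix, NormalizedCounts
from .errors import ConfigurationError
from .simulate import SimulationConfig

logger = logging.getLogger("triodiff")

COMPARISONS = ("parent2_vs_parent1", "hybrid_vs_parent1", "hybrid_vs_parent2", "hybrid_vs_mpv")


@dataclass
class PipelineConfig:
    """Run-level configuration; either file paths or a simulation block."""

    output_dir: str = "triodiff_out"
    seed: int = 0
    parent1: str = "parent1"
    parent2: str = "parent2"
    hybrid: str = "hybrid"
    fpkm_cutoff: float = 2.0
    padj_cutoff: float = 0.001
    log2fc_cutoff: float = 1.0
    preferred_tissue: str = "corolla"
    simulation: SimulationConfig | None = None
    counts: dict[str, str] | None = None  # species -> counts TSV
    metadata: dict[str, str] | None = None  # species -> metadata TSV
    transcripts: dict[str, str] | None = None  # species -> transcript TSV
    ortholog_pairs: str | None = None

    def validate(self) -> None:
        labels = {self.parent1, self.parent2, self.hybrid}
        if len(labels) != 3:
            raise ConfigurationError("parent1/parent2/hybrid labels must be distinct")
        for name in ("fpkm_cutoff", "padj_cutoff", "log2fc_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.simulation is None and not (self.counts and self.transcripts and self.ortholog_pairs):
            raise ConfigurationError(
                "either a simulation block or counts + transcripts + ortholog_pairs paths"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "output_dir", "seed", "parent1", "parent2", "hybrid", "fpkm_cutoff",
                "padj_cutoff", "log2fc_cutoff", "preferred_tissue", "counts",
                "metadata", "transcripts", "ortholog_pairs",
            )
        }
        if self.simulation is not None:
            sim = dict(vars(self.simulation))
            sim["tissues"] = list(sim["tissues"])
            sim["mode_proportions"] = dict(sim["mode_proportions"])
            for key in ("base_log2_mean_range", "size_factor_range"):
                sim[key] = list(sim[key])
            out["simulation"] = sim
        return out


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def analyze_groups(
    group_counts: CountMatrix,
    parent1: str,
    parent2: str,
    hybrid: str,
    padj_cutoff: float = dge.PADJ_CUTOFF,
    log2fc_cutoff: float = dge.LOG2FC_CUTOFF,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-tissue DE testing of the four comparisons on group-level counts.

    Size factors come from the full matrix (median of ratios); dispersions
    are estimated per tissue with species as the design groups.  The MPV
    comparison tests the hybrid mean against the fixed value
    (m_P1 + m_P2) / 2 with delta-method variance from both parents.
    """
    size_factors = dge.estimate_size_factors(group_counts)
    norm_all = NormalizedCounts(group_counts, size_factors)
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for tissue in sorted(group_counts.samples["tissue"].unique()):
        t0 = time.perf_counter()
        samples = group_counts.samples_for(tissue=tissue)
        norm = norm_all.subset_samples(samples)
        design = norm.counts.samples.set_index("sample")["species"]
        alpha = dge.estimate_dispersion(norm, design)
        s_p1 = norm.counts.samples_for(species=parent1)
        s_p2 = norm.counts.samples_for(species=parent2)
        s_hyb = norm.counts.samples_for(species=hybrid)

        parents = dge.test_de(norm, alpha, s_p1, s_p2, comparison="parent2_vs_parent1")
        hv_p1 = dge.test_de(norm, alpha, s_p1, s_hyb, comparison="hybrid_vs_parent1")
        hv_p2 = dge.test_de(norm, alpha, s_p2, s_hyb, comparison="hybrid_vs_parent2")

        m1, v1 = dge.group_mean_and_variance(norm, alpha, s_p1)
        m2, v2 = dge.group_mean_and_variance(norm, alpha, s_p2)
        mpv = 0.5 * (m1 + m2)
        mpv_var = 0.25 * (v1 + v2)
        hv_mpv = dge.test_de(
            norm, alpha, s_p1 + s_p2, s_hyb, comparison="hybrid_vs_mpv",
            null_mean=mpv, null_mean_var=mpv_var,
        )
        results[tissue] = {
            "parents": dge.finalize_de(parents, padj_cutoff, log2fc_cutoff),
            "hv_p1": dge.finalize_de(hv_p1, padj_cutoff, log2fc_cutoff),
            "hv_p2": dge.finalize_de(hv_p2, padj_cutoff, log2fc_cutoff),
            "hv_mpv": dge.finalize_de(hv_mpv, padj_cutoff, log2fc_cutoff),
        }
        logger.info("tissue %s: DE testing took %.1fs", tissue, time.perf_counter() - t0)
    return results


def universal_gene_of_group(groups: pd.DataFrame, species: list[str]) -> pd.Series:
    """Map each group id to the simulation's universal gene id.

    Simulated species-local ids are ``<species>_<gene>``; the first present
    member determines the universal id.
    """
    def strip(row):
        for sp in species:
            val = row.get(sp)
            if pd.notna(val) and str(val).startswith(f"{sp}_"):
                return str(val)[len(sp) + 1 :]
        return None

    return pd.Series(
        [strip(row) for _, row in groups.iterrows()], index=groups["group_id"]
    )


def evaluate_recovery(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    group_to_gene: pd.Series,
) -> dict:
    """Compare per-tissue classifications against simulation ground truth.

    Recall per class counts a truth gene as recovered only when it entered
    the DEG set and was classified correctly, so missed entry genes count
    against recall.  Returns per-class recall/precision, macro recall, and
    the transgressive (F1d) pooled precision.
    """
    modes = list(reporting.INHERITANCE_ORDER)
    truth_modes = truth.drop_duplicates("gene_id").set_index("gene_id")["true_mode"]
    gene_of = group_to_gene.to_dict()
    tissues = sorted(calls["tissue"].unique()) if not calls.empty else []
    predicted: dict[tuple[str, str], str] = {}
    for row in calls.itertuples(index=False):
        gene = gene_of.get(row.group_id)
        if gene is not None:
            predicted[(gene, row.tissue)] = row.category
    per_class: dict[str, dict] = {}
    for mode in modes:
        truth_genes = truth_modes.index[truth_modes == mode]
        n_truth = len(truth_genes) * max(len(tissues), 1)
        n_correct = sum(
            1 for g in truth_genes for t in tissues if predicted.get((g, t)) == mode
        )
        n_pred = sum(1 for c in predicted.values() if c == mode)
        per_class[mode] = {
            "n_truth": n_truth,
            "recall": n_correct / n_truth if n_truth else None,
            "precision": n_correct / n_pred if n_pred else None,
        }
    recalls = [v["recall"] for v in per_class.values() if v["recall"] is not None]
    f1d_truth = truth_modes.index[truth_modes.isin(["F1d_over", "F1d_under"])]
    f1d_pred = [(g, t) for (g, t), c in predicted.items() if c in ("F1d_over", "F1d_under")]
    f1d_correct = sum(
        1 for g, t in f1d_pred
        if g in set(f1d_truth) and predicted[(g, t)] == truth_modes.get(g)
    )
    return {
        "per_class": per_class,
        "macro_recall": float(np.mean(recalls)) if recalls else None,
        "f1d_precision": f1d_correct / len(f1d_pred) if f1d_pred else None,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    def timed(name):
        t0 = time.perf_counter()

        def done():
            stage_times[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s finished in %.2fs", name, stage_times[name])

        return done

    species_labels = [config.parent1, config.parent2, config.hybrid]

    # --- inputs ---
    done = timed("inputs")
    truth = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        matrices_sim, truth = simulate.simulate_trio(sim_cfg)
        transcripts = simulate.simulate_transcript_tables(sim_cfg)
        pairs_table = simulate.simulate_ortholog_pairs(truth)
        # map internal species slots onto configured labels
        slot_of = dict(zip(simulate.SPECIES, species_labels))
        matrices = {slot_of[s]: m for s, m in matrices_sim.items()}
        transcripts = {slot_of[s]: t for s, t in transcripts.items()}
        pairs_table = pairs_table.assign(
            species_a=[slot_of[s] for s in pairs_table["species_a"]],
            species_b=[slot_of[s] for s in pairs_table["species_b"]],
        )
        for sp in matrices:
            io.write_counts(matrices[sp], outdir / f"counts_{sp}.tsv", outdir / f"samples_{sp}.tsv")
            io.write_table(transcripts[sp], outdir / f"transcripts_{sp}.tsv")
        io.write_table(truth, outdir / "truth.tsv")
        io.write_table(pairs_table, outdir / "ortholog_pairs.tsv")
    else:
        matrices = {
            sp: io.read_counts(config.counts[sp], config.metadata[sp])
            for sp in species_labels
        }
        transcripts = {sp: io.read_table(config.transcripts[sp]) for sp in species_labels}
        pairs_table = io.read_table(config.ortholog_pairs)
    done()

    # --- unigene selection ---
    done = timed("select")
    unigene_sets = {}
    summaries = []
    for sp in species_labels:
        records = unigenes.records_from_frame(transcripts[sp])
        uset = unigenes.select_unigenes(records, species=sp, fpkm_cutoff=config.fpkm_cutoff)
        unigene_sets[sp] = uset
        summaries.append(unigenes.assembly_summary(records, uset))
    io.write_table(pd.DataFrame(summaries), outdir / "assembly_summary.tsv")
    done()

    # --- ortholog groups ---
    done = timed("groups")
    cluster_sets = {sp: u.cluster_ids for sp, u in unigene_sets.items()}
    pairs = [
        p for p in orthologs.pairs_from_frame(pairs_table)
        if p.gene_a in cluster_sets[p.species_a] and p.gene_b in cluster_sets[p.species_b]
    ]
    groups = orthologs.build_groups(pairs, cluster_sets)
    io.write_group_table(groups, outdir / "ortholog_groups.tsv")
    venn = orthologs.venn_counts(groups)
    venn["hybrid_specific_pct"] = reporting.hybrid_specific_fraction(venn, config.hybrid)
    (outdir / "venn_counts.json").write_text(json.dumps(venn, indent=2))

    # genes in count matrices but filtered out of the unigene sets are
    # dropped before integration
    matrices = {
        sp: CountMatrix(
            m.counts.loc[m.counts.index.intersection(sorted(cluster_sets[sp]))], m.samples
        )
        for sp, m in matrices.items()
    }
    group_counts = orthologs.counts_to_groups(groups, matrices)
    done()

    # --- differential expression ---
    done = timed("dge")
    results = analyze_groups(
        group_counts, config.parent1, config.parent2, config.hybrid,
        config.padj_cutoff, config.log2fc_cutoff,
    )
    summary_input = {}
    for tissue, tables in results.items():
        for key, comp in (("parents", "parent2_vs_parent1"),
                          ("hv_p1", "hybrid_vs_parent1"), ("hv_p2", "hybrid_vs_parent2")):
            io.write_table(
                tables[key].rename_axis("group_id").reset_index(),
                outdir / f"de_{comp}_{tissue}.tsv",
            )
            summary_input[(tissue, comp)] = tables[key]
        io.write_table(
            tables["hv_mpv"].rename_axis("group_id").reset_index(),
            outdir / f"de_hybrid_vs_mpv_{tissue}.tsv",
        )
    io.write_table(dge.deg_summary(summary_input), outdir / "deg_summary.tsv")
    done()

    # --- inheritance classification ---
    done = timed("classify")
    calls, overall = inheritance.classify_all(results, preferred_tissue=config.preferred_tissue)
    io.write_table(calls, outdir / "inheritance_calls.tsv")
    io.write_table(overall, outdir / "inheritance_overall.tsv")
    table3 = reporting.inheritance_table(calls, overall)
    io.write_table(table3, outdir / "inheritance_table.tsv")
    done()

    # --- truth-based recovery (simulation runs only) ---
    recovery = None
    if truth is not None:
        done = timed("recovery")
        g2g = universal_gene_of_group(groups, species_labels)
        recovery = evaluate_recovery(calls, truth, g2g)
        (outdir / "recovery.json").write_text(json.dumps(recovery, indent=2))
        done()

    manifest = _write_manifest(config, outdir, stage_times, recovery)
    return manifest


def _write_manifest(
    config: PipelineConfig, outdir: Path, stage_times: dict, recovery: dict | None
) -> dict:
    from . import __version__

    cfg_dict = config.to_dict()
    cfg_yaml = json.dumps(cfg_dict, sort_keys=True)
    file_hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stage_seconds": stage_times,
        "files": file_hashes,
    }
    if recovery is not None:
        manifest["recovery"] = {
            "macro_recall": recovery["macro_recall"],
            "f1d_precision": recovery["f1d_precision"],
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
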