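"""Inheritance-mode classification of parent-vs-parent DEGs.

Entry condition: a gene must be a DEG between the two parents.  Its hybrid
expression is then compared against each parent and against the mid-parent
value (MPV, the linear-scale average of the parental means), and the three
outcomes feed a fixed-order decision tree:

1. hybrid significantly above BOTH parents -> ``F1d_over`` (over-dominant);
   significantly below both -> ``F1d_under``.  Transgression is checked
   first so a gene outside the parental range is never mislabeled dominant.
2. not significant against exactly one parent, significant against the
   other -> complete dominance toward the indistinguishable parent
   (``F1b_P1`` / ``F1b_P2``).
3. significant against both parents in opposite directions (hybrid strictly
   between them) -> ``F1a`` (additive) if the MPV test does not reject,
   otherwise ``F1c`` (incomplete dominance).
4. not significant against either parent -> ``ambiguous`` (the data cannot
   resolve a mode even though the parents differ); excluded from summary
   denominators.

Significance of the companion comparisons uses the dual-test adjusted-p
rule without the fold-change gate: a fold-change gate would mask genuinely
intermediate hybrid states.  Equality with a parent or with the MPV is read
as non-rejection, a deliberately lenient criterion.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

CATEGORIES = ("F1a", "F1b_P1", "F1b_P2", "F1c", "F1d_over", "F1d_under", "ambiguous")

_OUTCOMES = ("sig_up", "sig_down", "ns")


def test_outcome(row: pd.Series) -> str:
    """Collapse one finalized DE row to sig_up / sig_down / ns."""
    if not bool(row["significant"]):
        return "ns"
    return "sig_up" if row["log2fc"] > 0 else "sig_down"


def classify(hv_p1: str, hv_p2: str, hv_mpv: str) -> str:
    """Decision tree over the three test outcomes (see module docstring).

    ``hv_p1`` etc. are outcomes of hybrid-vs-parent1, hybrid-vs-parent2 and
    hybrid-vs-MPV, each in {sig_up, sig_down, ns}.
    """
    for name, value in (("hv_p1", hv_p1), ("hv_p2", hv_p2), ("hv_mpv", hv_mpv)):
        if value not in _OUTCOMES:
            raise InputError(f"{name} must be one of {_OUTCOMES}, got {value!r}")
    if hv_p1 == "sig_up" and hv_p2 == "sig_up":
        return "F1d_over"
    if hv_p1 == "sig_down" and hv_p2 == "sig_down":
        return "F1d_under"
    if hv_p1 == "ns" and hv_p2 != "ns":
        return "F1b_P1"
    if hv_p2 == "ns" and hv_p1 != "ns":
        return "F1b_P2"
    if hv_p1 != "ns" and hv_p2 != "ns":  # opposite directions: strictly between
        return "F1a" if hv_mpv == "ns" else "F1c"
    return "ambiguous"


def classify_tissue(
    parents: pd.DataFrame,
    hv_p1: pd.DataFrame,
    hv_p2: pd.DataFrame,
    hv_mpv: pd.DataFrame,
    tissue: str,
) -> pd.DataFrame:
    """Classify every parent-vs-parent DEG of one tissue.

    All four inputs are finalized DE tables indexed by group id; the three
    hybrid comparisons must cover every DEG of the parental comparison.
    """
    degs = parents.index[parents["is_deg"]]
    for name, table in (("hybrid-vs-parent1", hv_p1), ("hybrid-vs-parent2", hv_p2),
                        ("hybrid-vs-MPV", hv_mpv)):
        missing = degs.difference(table.index)
        if len(missing):
            raise InputError(f"{name} results missing for {len(missing)} DEGs")
    rows = []
    for gid in degs:
        o1 = test_outcome(hv_p1.loc[gid])
        o2 = test_outcome(hv_p2.loc[gid])
        om = test_outcome(hv_mpv.loc[gid])
        rows.append(
            {
                "group_id": gid,
                "tissue": tissue,
                "category": classify(o1, o2, om),
                "hybrid_vs_p1": o1,
                "hybrid_vs_p2": o2,
                "hybrid_vs_mpv": om,
                "hybrid_mean": float(hv_p1.loc[gid, "base_mean_b"]),
                "parent1_mean": float(hv_p1.loc[gid, "base_mean_a"]),
                "parent2_mean": float(hv_p2.loc[gid, "base_mean_a"]),
                "mpv": float(hv_mpv.loc[gid, "base_mean_a"]),
            }
        )
    columns = ["group_id", "tissue", "category", "hybrid_vs_p1", "hybrid_vs_p2",
               "hybrid_vs_mpv", "hybrid_mean", "parent1_mean", "parent2_mean", "mpv"]
    return pd.DataFrame(rows, columns=columns)


def classify_all(
    per_tissue: dict[str, dict[str, pd.DataFrame]],
    preferred_tissue: str = "corolla",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify all tissues and derive a deduplicated overall set.

    ``per_tissue`` maps tissue -> {"parents": ..., "hv_p1": ..., "hv_p2":
    ..., "hv_mpv": ...} finalized DE tables.  The overall set counts each
    group once; when tissues disagree on the category the call from
    ``preferred_tissue`` wins (the floral tissue, the phenotype of
    interest), and the conflict is flagged.

    Returns (per-tissue calls, overall calls with a ``conflict`` column).
    """
    frames = []
    for tissue, tables in per_tissue.items():
        frames.append(
            classify_tissue(
                tables["parents"], tables["hv_p1"], tables["hv_p2"],
                tables["hv_mpv"], tissue,
            )
        )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["group_id", "tissue", "category"])
    )
    if calls.empty:
        overall = calls.assign(conflict=pd.Series(dtype=bool))
        return calls, overall

    tissue_rank = {preferred_tissue: 0}
    order = calls.assign(
        _rank=[tissue_rank.get(t, 1) for t in calls["tissue"]]
    ).sort_values(["group_id", "_rank", "tissue"], kind="mergesort")
    n_cat = order.groupby("group_id")["category"].nunique()
    first = order.drop_duplicates("group_id").drop(columns="_rank")
    overall = first.assign(conflict=first["group_id"].map(n_cat > 1).to_numpy())
    return calls, overall.reset_index(drop=True)
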