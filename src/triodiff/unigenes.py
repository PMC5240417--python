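"""Unigene selection from de novo transcript clusters.

De novo assemblers group alternative isoforms of one gene into a cluster.
To obtain a non-redundant gene set ("unigenes"), each cluster is reduced to
a single representative transcript after an abundance/orthology retention
filter: a transcript survives if its FPKM exceeds 2 or if an ortholog for it
exists in one of the other assemblies.  Clusters with ortholog evidence are
represented by the ortholog-linked transcript; clusters without it fall back
to the longest retained transcript (accounting for alternative splicing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

TRANSCRIPT_COLUMNS = ("cluster_id", "transcript_id", "length_bp", "fpkm", "has_ortholog")


@dataclass(frozen=True)
class TranscriptRecord:
    cluster_id: str
    transcript_id: str
    length_bp: int
    fpkm: float
    has_ortholog: bool = False

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise InputError(f"{self.transcript_id}: length_bp must be >= 1")
        if self.fpkm < 0:
            raise InputError(f"{self.transcript_id}: fpkm must be non-negative")


@dataclass
class UnigeneSet:
    """Representative transcripts, at most one per cluster."""

    species: str
    representatives: dict[str, str]  # cluster_id -> transcript_id

    @property
    def transcript_ids(self) -> set[str]:
        return set(self.representatives.values())

    @property
    def cluster_ids(self) -> set[str]:
        return set(self.representatives)

    def __len__(self) -> int:
        return len(self.representatives)


def records_from_frame(table: pd.DataFrame) -> list[TranscriptRecord]:
    """Build transcript records from a table with the standard columns."""
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"transcript table lacks columns: {missing}")
    return [
        TranscriptRecord(
            str(r.cluster_id), str(r.transcript_id), int(r.length_bp),
            float(r.fpkm), bool(r.has_ortholog),
        )
        for r in table.itertuples(index=False)
    ]


def select_unigenes(
    records: list[TranscriptRecord],
    species: str = "",
    fpkm_cutoff: float = 2.0,
) -> UnigeneSet:
    """Apply the retention filter and pick one representative per cluster.

    A transcript is retained iff ``fpkm > fpkm_cutoff`` (strict) or it has
    ortholog evidence.  Within a cluster, ortholog-linked transcripts take
    priority as representative; ties on length break to the
    lexicographically smallest transcript id for determinism.  Clusters
    whose every transcript fails the filter are dropped.
    """
    if not records:
        raise InputError("no transcript records supplied")
    seen: set[str] = set()
    clusters: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        if rec.transcript_id in seen:
            raise InputError(f"duplicate transcript id: {rec.transcript_id}")
        seen.add(rec.transcript_id)
        if rec.fpkm > fpkm_cutoff or rec.has_ortholog:
            clusters.setdefault(rec.cluster_id, []).append(rec)
    reps: dict[str, str] = {}
    for cluster_id, members in clusters.items():
        linked = [m for m in members if m.has_ortholog]
        pool = linked if linked else members
        best = min(pool, key=lambda m: (-m.length_bp, m.transcript_id))
        reps[cluster_id] = best.transcript_id
    return UnigeneSet(species=species, representatives=reps)


def compute_n50(lengths: list[int] | np.ndarray) -> int:
    """Standard N50: smallest length L such that contigs >= L cover half
    the total assembly length."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise InputError("N50 of an empty length list is undefined")
    if (arr <= 0).any():
        raise InputError("lengths must be positive")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    if not seq:
        raise InputError("empty sequence")
    gc = sum(seq.count(b) for b in "GC")
    return 100.0 * gc / len(seq)


def assembly_summary(
    records: list[TranscriptRecord],
    unigenes: UnigeneSet,
    sequences: dict[str, str] | None = None,
) -> dict:
    """Summary statistics over the selected unigene set.

    Returns count, total/mean length, N50, and GC% when sequences of the
    representatives are supplied.
    """
    if len(unigenes) == 0:
        raise InputError("empty unigene set")
    by_id = {r.transcript_id: r for r in records}
    try:
        lengths = [by_id[t].length_bp for t in unigenes.transcript_ids]
    except KeyError as exc:
        raise InputError(f"unigene not found among records: {exc}") from exc
    summary = {
        "species": unigenes.species,
        "n_unigenes": len(unigenes),
        "total_length_bp": int(np.sum(lengths)),
        "mean_length_bp": float(np.mean(lengths)),
        "n50_bp": compute_n50(lengths),
    }
    if sequences is not None:
        concat = "".join(sequences[t] for t in sorted(unigenes.transcript_ids) if t in sequences)
        summary["gc_percent"] = gc_percent(concat)
    return summary
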