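"""TSV / FASTA / YAML input and output.

All tabular artifacts are tab-separated text; FASTA is read through
Biopython.  Writers are the single place that touches the filesystem so the
pipeline stays easy to audit.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .containers import CountMatrix
from .errors import InputError


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample metadata TSV."""
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    for p in (counts_path, metadata_path):
        if not p.exists():
            raise InputError(f"missing input file: {p}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(metadata_path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing input file: {path}")
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Group table TSV with 'NA' marking absent species members."""
    table = read_table(path)
    if "group_id" not in table.columns:
        raise InputError("group table must have a group_id column")
    return table


def write_group_table(groups: pd.DataFrame, path: str | Path) -> None:
    groups.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_transcripts_fasta(
    fasta_path: str | Path,
    fpkm_path: str | Path,
    ortholog_ids: set[str] | None = None,
    cluster_of=None,
) -> pd.DataFrame:
    """Build a transcript table from FASTA sequences plus an FPKM TSV.

    ``fpkm_path`` is a two-column TSV (transcript_id, fpkm).  Cluster ids
    default to the transcript id up to the last ``_i``-style suffix unless
    ``cluster_of`` (a callable) is given; ``ortholog_ids`` marks transcripts
    with cross-species evidence.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"missing FASTA: {fasta_path}")
    fpkm = pd.read_csv(fpkm_path, sep="\t", header=None, names=["transcript_id", "fpkm"])
    fpkm_map = dict(zip(fpkm["transcript_id"].astype(str), fpkm["fpkm"].astype(float)))
    cluster_of = cluster_of or (lambda tid: tid.rsplit("_i", 1)[0])
    ortholog_ids = ortholog_ids or set()
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid = rec.id
        if tid not in fpkm_map:
            raise InputError(f"no FPKM value for transcript {tid}")
        rows.append(
            {
                "cluster_id": cluster_of(tid),
                "transcript_id": tid,
                "length_bp": len(rec.seq),
                "fpkm": fpkm_map[tid],
                "has_ortholog": tid in ortholog_ids,
            }
        )
    if not rows:
        raise InputError(f"no sequences in {fasta_path}")
    return pd.DataFrame(rows)


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError("config must be a mapping")
    return data


def write_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
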