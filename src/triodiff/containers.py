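"""In-memory containers for count data and sample annotation.

A :class:`CountMatrix` couples an integer genes x samples table with the
per-sample metadata (species, tissue, replicate) the downstream stages need
to slice on.  Both parts are plain pandas DataFrames so they round-trip
through TSV without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

SAMPLE_COLUMNS = ("sample", "species", "tissue", "replicate")


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with attached sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene/group id, one column per sample.
    samples
        DataFrame with columns ``sample``, ``species``, ``tissue``,
        ``replicate``; ``sample`` must match the count columns exactly.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample metadata lacks columns: {missing}")
        meta_samples = list(self.samples["sample"])
        if list(self.counts.columns) != meta_samples:
            raise InputError(
                "count columns and sample metadata disagree: "
                f"{list(self.counts.columns)} vs {meta_samples}"
            )
        if (np.asarray(self.counts) < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, *, species: str | None = None, tissue: str | None = None) -> list[str]:
        """Sample names matching the given species and/or tissue."""
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        return list(self.samples.loc[mask, "sample"])

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        meta = self.samples[self.samples["sample"].isin(samples)].reset_index(drop=True)
        return CountMatrix(self.counts[list(meta["sample"])], meta)


@dataclass
class NormalizedCounts:
    """Counts together with per-sample size factors (geometric mean ~ 1)."""

    counts: CountMatrix
    size_factors: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        sf = self.size_factors.reindex(self.counts.counts.columns)
        if sf.isna().any():
            raise InputError("size factors missing for some samples")
        if (sf <= 0).any():
            raise InputError("size factors must be strictly positive")
        self.size_factors = sf.astype(float)

    @property
    def normalized(self) -> pd.DataFrame:
        """Counts divided by their sample size factor."""
        return self.counts.counts / self.size_factors

    def subset_samples(self, samples: list[str]) -> "NormalizedCounts":
        return NormalizedCounts(
            self.counts.subset_samples(samples), self.size_factors.loc[samples]
        )
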