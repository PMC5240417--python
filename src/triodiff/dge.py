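"""Negative-binomial two-group differential expression.

Counts are modelled as NB with Var = mu + alpha * mu^2 (alpha = 0 is the
Poisson limit).  Two tests are computed per gene and a gene is a DEG only
when BOTH reject — the both-methods-agree consensus rule:

``p_exact``
    an exact conditional test.  Under the null of equal means the group
    sums are NB with size parameters proportional to the group sizes, and
    the distribution of one group's sum conditioned on the grand total is
    negative hypergeometric (free of the unknown mean).  The two-sided
    p-value sums the probabilities of all splits of the total whose
    conditional probability does not exceed that of the observed split.
    At alpha = 0 this reduces to the binomial conditional (Poisson) test.

``p_wald``
    a Wald test of the difference of log means with delta-method variances
    from the NB moment relation.

A fixed-null variant (``null_mean`` given) tests the group-B mean against a
known value such as the mid-parent value; only the Wald form applies there.

Significance thresholds follow the analysis design: BH-adjusted p < 0.001
for both tests plus |log2 fold change| > 1.  Fold changes use a 0.5
pseudo-count on normalized means so structural-zero singletons stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .containers import CountMatrix, NormalizedCounts
from .errors import InputError

PADJ_CUTOFF = 0.001
LOG2FC_CUTOFF = 1.0
PSEUDOCOUNT = 0.5

#: grand totals above this switch the exact test to its normal approximation
EXACT_TOTAL_CUTOFF = 10_000

#: dispersions below this are treated as Poisson in the exact test
_POISSON_ALPHA = 1e-6


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every gene expressed in all samples, each sample's ratio to the
    gene's geometric mean is formed; the sample's factor is the median of
    those ratios.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise InputError(
            "no gene has nonzero counts in every sample; supply size factors "
            "from a pseudo-reference instead"
        )
    expressed = mat[all_pos]
    geo = np.exp(np.log(expressed).mean(axis=1, keepdims=True))
    factors = np.median(expressed / geo, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def estimate_dispersion(norm: NormalizedCounts, design: pd.Series | dict) -> pd.Series:
    """Per-gene NB dispersion by pooled method of moments with shrinkage.

    Within each design group with >= 2 replicates the moment estimate
    ``(s^2 - m) / m^2`` is formed and pooled across groups weighted by
    degrees of freedom, clipped at 0.  Estimates are then shrunk toward the
    20%-trimmed mean of all gene estimates with weight 1 / (mean replicates
    per group), so sparse designs borrow strength across genes while
    well-replicated ones mostly keep their own estimate.
    """
    design = pd.Series(design)
    data = norm.normalized
    groups = [list(design.index[design == g]) for g in design.unique()]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise InputError("dispersion estimation needs >= 2 replicates in some group")
    num = np.zeros(len(data))
    den = np.zeros(len(data))
    df_total = 0
    for cols in groups:
        sub = data[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        df_total += df
        ok = m > 0
        num[ok] += df * (v[ok] - m[ok])
        den[ok] += df * m[ok] ** 2
    raw = np.zeros(len(data))
    pos = den > 0
    raw[pos] = np.maximum(0.0, num[pos] / den[pos])
    informative = raw[pos]
    if informative.size:
        lo, hi = np.quantile(informative, [0.2, 0.8])
        trimmed = informative[(informative >= lo) & (informative <= hi)]
        center = float(trimmed.mean()) if trimmed.size else float(informative.mean())
    else:
        center = 0.0
    n_bar = np.mean([len(g) for g in groups])
    w = min(1.0, 1.0 / n_bar)
    shrunk = (1 - w) * raw + w * center
    return pd.Series(shrunk, index=data.index, name="dispersion")


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def _conditional_log_pmf(total: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(S_B = k | S_A + S_B = total) for k = 0..total.

    S_A ~ NB(r_a, p), S_B ~ NB(r_b, p) independent with a shared success
    probability; p cancels in the conditional, leaving the negative
    hypergeometric form C(k+r_b-1, k) C(T-k+r_a-1, T-k) / C(T+r_a+r_b-1, T).
    """
    k = np.arange(total + 1, dtype=float)
    logs = (
        gammaln(k + r_b) - gammaln(k + 1.0)
        + gammaln(total - k + r_a) - gammaln(total - k + 1.0)
    )
    return logs - logsumexp(logs)


def _binomial_log_pmf(total: int, q_b: float) -> np.ndarray:
    k = np.arange(total + 1, dtype=float)
    return (
        gammaln(total + 1.0) - gammaln(k + 1.0) - gammaln(total - k + 1.0)
        + k * np.log(q_b) + (total - k) * np.log1p(-q_b)
    )


def exact_conditional_pvalue(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    alpha: float,
    total_cutoff: int = EXACT_TOTAL_CUTOFF,
) -> float:
    """Two-sided exact conditional p-value for equal group means.

    Sums the conditional probabilities of every split of the grand total at
    most as probable as the observed one (within a 1e-8 relative tie
    tolerance, so exactly symmetric outcomes land in both tails).  Totals
    above ``total_cutoff`` use a continuity-corrected normal approximation
    to the conditional distribution.
    """
    if sum_a < 0 or sum_b < 0:
        raise InputError("negative counts")
    if alpha < 0:
        raise InputError("dispersion must be non-negative")
    total = int(sum_a + sum_b)
    if total == 0:
        return 1.0
    q_b = n_b / (n_a + n_b)
    if total > total_cutoff:
        return _normal_tail_pvalue(total, sum_b, n_a, n_b, alpha, q_b)
    if alpha < _POISSON_ALPHA:
        log_pmf = _binomial_log_pmf(total, q_b)
    else:
        r = 1.0 / alpha
        log_pmf = _conditional_log_pmf(total, n_a * r, n_b * r)
    observed = log_pmf[int(sum_b)]
    p = float(np.exp(logsumexp(log_pmf[log_pmf <= observed + 1e-8])))
    return min(1.0, p)


def _normal_tail_pvalue(
    total: int, sum_b: int, n_a: int, n_b: int, alpha: float, q_b: float
) -> float:
    mean = total * q_b
    if alpha < _POISSON_ALPHA:
        var = total * q_b * (1 - q_b)
    else:
        r_a, r_b = n_a / alpha, n_b / alpha
        var = (
            total * (r_a * r_b) / (r_a + r_b) ** 2
            * (r_a + r_b + total) / (r_a + r_b + 1.0)
        )
    z = (abs(sum_b - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------

def _group_mean_var(
    norm_block: np.ndarray, sf: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized group means and the NB moment variance of those means.

    A raw count K_ij ~ NB(mu_i * s_j, alpha_i); the normalized value
    K_ij / s_j then has variance (mu_i s_j + alpha_i mu_i^2 s_j^2) / s_j^2,
    and the group mean of n such values has 1/n^2 times their sum.
    """
    n = norm_block.shape[1]
    mean = norm_block.mean(axis=1)
    var = (mean[:, None] / sf[None, :] + alpha[:, None] * mean[:, None] ** 2).sum(axis=1) / n**2
    return mean, var


def group_mean_and_variance(
    norm: NormalizedCounts,
    dispersion: pd.Series,
    samples: list[str],
) -> tuple[pd.Series, pd.Series]:
    """Normalized mean of a sample group and the NB variance of that mean."""
    if not samples:
        raise InputError("empty sample group")
    data = norm.normalized
    alpha = dispersion.reindex(data.index).to_numpy(dtype=float)
    sf = norm.size_factors.loc[samples].to_numpy()
    mean, var = _group_mean_var(data[samples].to_numpy(dtype=float), sf, alpha)
    return pd.Series(mean, index=data.index), pd.Series(var, index=data.index)


def test_de(
    norm: NormalizedCounts,
    dispersion: pd.Series,
    samples_a: list[str],
    samples_b: list[str],
    comparison: str = "B_vs_A",
    null_mean: pd.Series | None = None,
    null_mean_var: pd.Series | None = None,
    total_cutoff: int = EXACT_TOTAL_CUTOFF,
) -> pd.DataFrame:
    """Per-gene two-group NB tests of group B against group A.

    Returns a DataFrame indexed by gene with base means, ``log2fc`` (B over
    A, 0.5 pseudo-count), ``p_exact`` and ``p_wald``.  When ``null_mean``
    is given, group B is tested against that fixed per-gene mean (with
    ``null_mean_var`` carrying its estimation variance) and ``p_exact`` is
    NaN — only the Wald form applies to a fixed-value null.
    """
    if not samples_a or not samples_b:
        raise InputError("both sample groups must be non-empty")
    data = norm.normalized
    alpha = dispersion.reindex(data.index).to_numpy(dtype=float)
    if np.isnan(alpha).any():
        raise InputError("dispersion missing for some genes")
    if (alpha < 0).any():
        raise InputError("dispersion must be non-negative")
    sf_a = norm.size_factors.loc[samples_a].to_numpy()
    sf_b = norm.size_factors.loc[samples_b].to_numpy()
    block_a = data[samples_a].to_numpy(dtype=float)
    block_b = data[samples_b].to_numpy(dtype=float)
    mean_a, var_a = _group_mean_var(block_a, sf_a, alpha)
    mean_b, var_b = _group_mean_var(block_b, sf_b, alpha)

    if null_mean is not None:
        m0 = null_mean.reindex(data.index).to_numpy(dtype=float)
        v0 = (
            null_mean_var.reindex(data.index).to_numpy(dtype=float)
            if null_mean_var is not None
            else np.zeros_like(m0)
        )
        z = (mean_b - m0) / np.sqrt(np.maximum(var_b + v0, 1e-300))
        z[(mean_b == m0)] = 0.0
        p_wald = 2.0 * _norm_sf_abs(z)
        log2fc = np.log2((mean_b + PSEUDOCOUNT) / (m0 + PSEUDOCOUNT))
        return pd.DataFrame(
            {
                "comparison": comparison,
                "base_mean_a": m0,
                "base_mean_b": mean_b,
                "log2fc": log2fc,
                "p_exact": np.nan,
                "p_wald": np.clip(p_wald, 0.0, 1.0),
            },
            index=data.index,
        )

    # Wald on the log-mean difference
    la = np.log(mean_a + PSEUDOCOUNT)
    lb = np.log(mean_b + PSEUDOCOUNT)
    var_log = var_a / (mean_a + PSEUDOCOUNT) ** 2 + var_b / (mean_b + PSEUDOCOUNT) ** 2
    z = (lb - la) / np.sqrt(np.maximum(var_log, 1e-300))
    z[mean_a + mean_b == 0] = 0.0
    p_wald = np.clip(2.0 * _norm_sf_abs(z), 0.0, 1.0)

    # exact conditional test on rounded normalized counts
    pseudo_a = np.rint(block_a).astype(np.int64)
    pseudo_b = np.rint(block_b).astype(np.int64)
    sums_a = pseudo_a.sum(axis=1)
    sums_b = pseudo_b.sum(axis=1)
    p_exact = np.ones(len(data))
    for i in range(len(data)):
        p_exact[i] = exact_conditional_pvalue(
            int(sums_a[i]), int(sums_b[i]), len(samples_a), len(samples_b),
            float(alpha[i]), total_cutoff=total_cutoff,
        )
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    return pd.DataFrame(
        {
            "comparison": comparison,
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": log2fc,
            "p_exact": p_exact,
            "p_wald": p_wald,
        },
        index=data.index,
    )


test_de.__test__ = False  # not a pytest case


def _norm_sf_abs(z: np.ndarray) -> np.ndarray:
    return norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# multiple testing and DEG calling
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def finalize_de(
    results: pd.DataFrame,
    padj_cutoff: float = PADJ_CUTOFF,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
) -> pd.DataFrame:
    """Attach BH-adjusted p-values, consensus significance and DEG calls.

    ``significant`` is the dual-test consensus on adjusted p-values alone
    (used for the equals-parent / equals-MPV judgments); ``is_deg``
    additionally requires |log2fc| above the fold-change cutoff.  Fixed-null
    results (NaN ``p_exact``) rest on the Wald test only.
    """
    out = results.copy()
    if out["p_exact"].notna().any():
        out["padj_exact"] = adjust_bh(out["p_exact"].to_numpy())
    else:
        out["padj_exact"] = np.nan
    out["padj_wald"] = adjust_bh(out["p_wald"].to_numpy())
    wald_sig = out["padj_wald"] < padj_cutoff
    if out["p_exact"].notna().any():
        sig = (out["padj_exact"] < padj_cutoff) & wald_sig
    else:
        sig = wald_sig
    out["significant"] = sig
    out["is_deg"] = sig & (out["log2fc"].abs() > log2fc_cutoff)
    out["direction"] = np.where(
        out["is_deg"], np.where(out["log2fc"] > 0, "higher", "lower"), "none"
    )
    return out


def deg_summary(
    results: dict[tuple[str, str], pd.DataFrame],
    percent_fn=None,
) -> pd.DataFrame:
    """Direction summary of DEG calls per tissue and comparison.

    ``results`` maps (tissue, comparison) to finalized DE tables.  For each
    comparison an ``Overall`` row pools the per-tissue DEG sets, counting
    each group once; a group called in both tissues with opposing
    directions keeps the call of the first tissue in sorted order (corolla
    before leaf), matching the classification module's conflict rule.
    Percentages are of the comparison's DEG total.
    """
    from .reporting import percent as _percent

    pct = percent_fn or _percent
    comparisons = sorted({comp for (_, comp) in results})
    rows = []
    for comp in comparisons:
        tissues = sorted(t for (t, c) in results if c == comp)
        pooled: dict[str, str] = {}
        for tissue in tissues:
            table = results[(tissue, comp)]
            degs = table[table["is_deg"]]
            n_hi = int((degs["direction"] == "higher").sum())
            n_lo = int((degs["direction"] == "lower").sum())
            rows.append(_summary_row(tissue, comp, n_hi, n_lo, pct))
            for gid, direction in degs["direction"].items():
                # first tissue in sorted order wins on conflict
                # (corolla before leaf, matching the classification rule)
                pooled.setdefault(gid, direction)
        n_hi = sum(1 for d in pooled.values() if d == "higher")
        n_lo = sum(1 for d in pooled.values() if d == "lower")
        rows.append(_summary_row("Overall", comp, n_hi, n_lo, pct))
    return pd.DataFrame(rows)


def _summary_row(tissue: str, comp: str, n_hi: int, n_lo: int, pct) -> dict:
    total = n_hi + n_lo
    return {
        "tissue": tissue,
        "comparison": comp,
        "n_higher": n_hi,
        "n_lower": n_lo,
        "pct_higher": pct(n_hi, total) if total else None,
        "pct_lower": pct(n_lo, total) if total else None,
    }
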