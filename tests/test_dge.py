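"""Normalization, dispersion estimation, NB tests, BH, DEG summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import triodiff as td
from triodiff import dge
from triodiff.errors import InputError

from conftest import make_count_matrix, unit_normalized


def conditional_pvalue_oracle(sum_a, sum_b, n_a, n_b, alpha, mu=7.3):
    """Brute-force conditional test: convolve per-group NB (or Poisson) sum
    distributions with scipy, condition on the total, and sum the
    probabilities of splits at most as likely as the observed one."""
    total = sum_a + sum_b
    ks = np.arange(total + 1)
    if alpha == 0:
        pmf_a = stats.poisson.pmf(ks, n_a * mu)
        pmf_b = stats.poisson.pmf(ks, n_b * mu)
    else:
        r = 1.0 / alpha
        pmf_a = stats.nbinom.pmf(ks, n_a * r, r / (r + mu))
        pmf_b = stats.nbinom.pmf(ks, n_b * r, r / (r + mu))
    joint = pmf_b * pmf_a[::-1]
    cond = joint / joint.sum()
    return float(cond[cond <= cond[sum_b] * (1 + 1e-8)].sum())


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[10], [40], [7]], (1, 4)), {"A": 4})
        np.testing.assert_allclose(td.estimate_size_factors(cm), 1.0)

    def test_doubled_column_ratio_preserved(self):
        base = np.array([[10, 10], [40, 40], [7, 7]])
        base[:, 1] *= 2
        cm = make_count_matrix(base, {"A": 2})
        sf = td.estimate_size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_median_of_ratios_definition(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 200, size=(50, 6))
        cm = make_count_matrix(counts, {"A": 6})
        sf = td.estimate_size_factors(cm).to_numpy()
        geo = np.exp(np.log(counts).mean(axis=1))
        raw = np.median(counts / geo[:, None], axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(sf, expected, rtol=1e-12)

    def test_no_universally_expressed_gene_errors(self):
        cm = make_count_matrix([[0, 5], [5, 0]], {"A": 2})
        with pytest.raises(InputError):
            td.estimate_size_factors(cm)


class TestDispersion:
    def _estimate(self, counts, n_per_group):
        cm = make_count_matrix(counts, {"A": n_per_group, "B": n_per_group})
        norm = unit_normalized(cm)
        design = cm.samples.set_index("sample")["species"]
        return td.estimate_dispersion(norm, design)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(20, 200, size=10000)
        counts = rng.poisson(mu[:, None], size=(10000, 10))
        est = self._estimate(counts, 5)
        assert np.median(est) < 0.02

    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(2)
        alpha = 0.2
        r = 1 / alpha
        mu = rng.uniform(30, 300, size=4000)
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(4000, 10))
        est = self._estimate(counts, 5)
        assert 0.1 <= np.median(est) <= 0.3

    def test_constant_gene_shrinks_toward_prior_only(self):
        counts = np.full((5, 4), 20)
        est = self._estimate(counts, 2)
        # raw estimate is 0 for every gene, so the trimmed-mean center is 0
        np.testing.assert_allclose(est, 0.0)

    def test_single_sample_errors(self):
        cm = make_count_matrix([[3], [4]], {"A": 1})
        with pytest.raises(InputError):
            td.estimate_dispersion(unit_normalized(cm), cm.samples.set_index("sample")["species"])


class TestExactConditional:
    def test_identical_groups_no_evidence(self):
        cm = make_count_matrix([[10, 10, 10, 10]], {"A": 2, "B": 2})
        res = dge.test_de(unit_normalized(cm), pd.Series(0.1, index=cm.counts.index),
                          ["A_leaf_rep1", "A_leaf_rep2"], ["B_leaf_rep1", "B_leaf_rep2"])
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p_exact"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, alpha):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n_a, n_b = (int(x) for x in rng.integers(1, 5, 2))
            total = int(rng.integers(1, 51))
            sum_b = int(rng.integers(0, total + 1))
            got = td.exact_conditional_pvalue(total - sum_b, sum_b, n_a, n_b, alpha)
            want = conditional_pvalue_oracle(total - sum_b, sum_b, n_a, n_b, alpha)
            assert got == pytest.approx(want, abs=1e-10)

    def test_poisson_limit_equals_binomial_conditional(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            n_a, n_b = (int(x) for x in rng.integers(1, 7, 2))
            total = int(rng.integers(1, 300))
            sum_b = int(rng.integers(0, total + 1))
            got = td.exact_conditional_pvalue(total - sum_b, sum_b, n_a, n_b, 1e-8)
            pmf = stats.binom.pmf(np.arange(total + 1), total, n_b / (n_a + n_b))
            want = float(pmf[pmf <= pmf[sum_b] * (1 + 1e-8)].sum())
            assert got == pytest.approx(want, abs=1e-6)

    def test_normal_fallback_close_to_exact_near_cutoff(self):
        # just under vs. forced-approximation p-values agree to a few percent
        for sum_b in (4800, 5200, 5600):
            exact = td.exact_conditional_pvalue(10000 - sum_b, sum_b, 3, 3, 0.0)
            approx = td.exact_conditional_pvalue(10000 - sum_b, sum_b, 3, 3, 0.0, total_cutoff=10)
            if exact > 1e-12:
                assert np.log(approx) == pytest.approx(np.log(exact), abs=0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            td.exact_conditional_pvalue(-1, 3, 2, 2, 0.1)
        with pytest.raises(InputError):
            td.exact_conditional_pvalue(1, 3, 2, 2, -0.1)


class TestWaldAndSymmetry:
    def _trio(self, rng, n=5):
        counts = rng.negative_binomial(10, 10 / (10 + 60), size=(200, 2 * n))
        cm = make_count_matrix(counts, {"A": n, "B": n})
        norm = unit_normalized(cm)
        a = [f"A_leaf_rep{i}" for i in range(1, n + 1)]
        b = [f"B_leaf_rep{i}" for i in range(1, n + 1)]
        return norm, pd.Series(0.1, index=cm.counts.index), a, b

    def test_group_swap_negates_log2fc_and_keeps_pvalues(self):
        norm, alpha, a, b = self._trio(np.random.default_rng(41))
        fwd = dge.test_de(norm, alpha, a, b)
        rev = dge.test_de(norm, alpha, b, a)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p_exact"], rev["p_exact"], rtol=1e-9)
        np.testing.assert_allclose(fwd["p_wald"], rev["p_wald"], rtol=1e-9)

    def test_wald_null_uniformity_at_high_means(self):
        """Raw Wald p-values on 5000 null NB genes (mu >= 50, alpha=0.1,
        n=4 per group) are KS-indistinguishable from uniform."""
        rng = np.random.default_rng(42)
        mu = rng.uniform(50, 500, 5000)
        r = 10.0
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(5000, 8))
        cm = make_count_matrix(counts, {"A": 4, "B": 4})
        res = dge.test_de(
            unit_normalized(cm), pd.Series(0.1, index=cm.counts.index),
            [f"A_leaf_rep{i}" for i in range(1, 5)], [f"B_leaf_rep{i}" for i in range(1, 5)],
        )
        assert stats.kstest(res["p_wald"], "uniform").pvalue > 0.01

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(43)
        rates = []
        for fc in (1.0, 1.5, 2.0, 4.0):
            mu_a, mu_b = 60.0, 60.0 * fc
            r = 20.0
            counts = np.hstack(
                [
                    rng.negative_binomial(r, r / (r + mu_a), size=(300, 4)),
                    rng.negative_binomial(r, r / (r + mu_b), size=(300, 4)),
                ]
            )
            cm = make_count_matrix(counts, {"A": 4, "B": 4})
            res = dge.finalize_de(
                dge.test_de(
                    unit_normalized(cm), pd.Series(0.05, index=cm.counts.index),
                    [f"A_leaf_rep{i}" for i in range(1, 5)],
                    [f"B_leaf_rep{i}" for i in range(1, 5)],
                )
            )
            rates.append(res["is_deg"].mean())
        assert rates == sorted(rates)

    def test_fixed_null_detects_departure_from_mpv(self):
        rng = np.random.default_rng(44)
        counts = rng.poisson(100, size=(50, 4))
        cm = make_count_matrix(counts, {"H": 4})
        norm = unit_normalized(cm)
        alpha = pd.Series(0.0, index=cm.counts.index)
        samples = list(cm.counts.columns)
        at_null = dge.test_de(norm, alpha, samples, samples, null_mean=pd.Series(100.0, index=cm.counts.index))
        away = dge.test_de(norm, alpha, samples, samples, null_mean=pd.Series(30.0, index=cm.counts.index))
        assert at_null["p_exact"].isna().all()
        assert np.median(at_null["p_wald"]) > 0.01
        assert (away["p_wald"] < 1e-6).all()


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(td.adjust_bh([0.01]), [0.01])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(td.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(
            # sorted: .005->.015, .03->.045, .04->.04; step-up min gives .04
            td.adjust_bh([0.005, 0.04, 0.03]), [0.015, 0.04, 0.04]
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_dominates_raw_p_and_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        got = td.adjust_bh(pvals)
        assert (got >= np.asarray(pvals) - 1e-15).all()
        assert (got <= 1.0).all()
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            td.adjust_bh([0.5, 1.5])


class TestDegSummary:
    @staticmethod
    def _table(n_hi, n_lo, n_none=5):
        n = n_hi + n_lo + n_none
        return pd.DataFrame(
            {
                "comparison": "x",
                "log2fc": [2.0] * n_hi + [-2.0] * n_lo + [0.0] * n_none,
                "is_deg": [True] * (n_hi + n_lo) + [False] * n_none,
                "direction": ["higher"] * n_hi + ["lower"] * n_lo + ["none"] * n_none,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_direction_percentages(self):
        out = td.deg_summary({("leaf", "p2_vs_p1"): self._table(672, 314)})
        leaf = out[out["tissue"] == "leaf"].iloc[0]
        assert (leaf["n_higher"], leaf["n_lower"]) == (672, 314)
        assert (leaf["pct_higher"], leaf["pct_lower"]) == (68.15, 31.85)

    def test_empty_row_reports_no_percentages(self):
        out = td.deg_summary({("leaf", "x"): self._table(0, 0)})
        leaf = out[out["tissue"] == "leaf"].iloc[0]
        assert leaf["n_higher"] == 0 and leaf["pct_higher"] is None

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_hi, n_lo = (int(x) for x in rng.integers(1, 500, 2))
            out = td.deg_summary({("leaf", "x"): self._table(n_hi, n_lo)})
            leaf = out[out["tissue"] == "leaf"].iloc[0]
            assert leaf["pct_higher"] + leaf["pct_lower"] == pytest.approx(100.0, abs=0.011)

    def test_overall_deduplicates_by_group(self):
        t1 = self._table(3, 2, 0)
        t2 = self._table(3, 2, 0)  # same gene ids -> same groups in both tissues
        out = td.deg_summary({("corolla", "x"): t1, ("leaf", "x"): t2})
        overall = out[out["tissue"] == "Overall"].iloc[0]
        assert overall["n_higher"] == 3 and overall["n_lower"] == 2
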