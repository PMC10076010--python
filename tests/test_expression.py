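import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from exopba.expression import (SampleExpressionTable, aggregate_counts,
                               bh_adjust, diff_expression, normalize,
                               tmm_factors)
from exopba.readproc import build_matrix


def tmm_oracle(counts: np.ndarray, logratio_trim=0.30, sum_trim=0.05):
    """Independent direct-definition TMM: explicit loops over proteins.

    Follows the published definition literally — M and A values over proteins
    positive in both sample and reference, double trim by average ranks,
    inverse-asymptotic-variance weights, geometric-mean-1 rescaling.
    """
    counts = np.asarray(counts, dtype=float)
    n_samples, n_proteins = counts.shape
    totals = counts.sum(axis=1)
    uq = np.array([np.quantile(counts[i], 0.75) / totals[i]
                   for i in range(n_samples)])
    ref = int(np.argmin([abs(u - uq.mean()) for u in uq]))
    factors = []
    for s in range(n_samples):
        if s == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, weights = [], [], []
        for g in range(n_proteins):
            o, r = counts[s, g], counts[ref, g]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / totals[s], r / totals[ref]
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * (np.log2(po) + np.log2(pr)))
            weights.append((totals[s] - o) / (totals[s] * o)
                           + (totals[ref] - r) / (totals[ref] * r))
        m_vals, a_vals, weights = map(np.array, (m_vals, a_vals, weights))
        if m_vals.size == 0 or np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = m_vals.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = st.rankdata(m_vals)
        rank_a = st.rankdata(a_vals)
        keep = [(lo_m <= rank_m[i] <= hi_m) and (lo_a <= rank_a[i] <= hi_a)
                for i in range(n)]
        keep = np.array(keep)
        if not keep.any():
            factors.append(1.0)
            continue
        f = (m_vals[keep] / weights[keep]).sum() / (1.0 / weights[keep]).sum()
        factors.append(2.0 ** f)
    factors = np.array(factors)
    return factors / np.exp(np.log(factors).mean()), ref


def make_table(counts, groups=None):
    counts = np.asarray(counts)
    samples = [f"S{i+1}" for i in range(counts.shape[0])]
    proteins = [f"P{j+1}" for j in range(counts.shape[1])]
    if groups is None:
        groups = ["A"] * counts.shape[0]
    return SampleExpressionTable(
        pd.DataFrame(counts, index=samples, columns=proteins),
        pd.Series(groups, index=samples),
    )


class TestAggregateCounts:
    def test_column_sums(self, small_panel):
        m = build_matrix({("e1", 0): 1, ("e1", 1): 1, ("e2", 0): 1}, small_panel)
        assert aggregate_counts(m).tolist() == [2, 1, 0, 0]

    def test_row_permutation_invariant(self, small_panel):
        a = build_matrix({("e1", 0): 2, ("e2", 1): 3}, small_panel)
        b = build_matrix({("e2", 1): 3, ("e1", 0): 2}, small_panel)
        assert aggregate_counts(a).tolist() == aggregate_counts(b).tolist()


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = np.tile([10, 20, 30, 40, 5], (3, 1))
        factors = tmm_factors(make_table(counts)).factors
        assert np.allclose(factors, 1.0)

    def test_pure_scaling_cancels(self):
        """Sample B = 2 x sample A: library-size scaling absorbs the factor
        and normalized expression is identical."""
        rng = np.random.default_rng(1)
        a = rng.integers(1, 200, size=30)
        counts = np.vstack([a, 2 * a])
        table = make_table(counts)
        factors = tmm_factors(table)
        normed = normalize(table, factors)
        np.testing.assert_allclose(normed.iloc[0], normed.iloc[1], rtol=1e-12)

    def test_matches_direct_definition_oracle(self):
        """Random toy tables agree with the brute-force oracle to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_s = rng.integers(2, 6)
            n_p = rng.integers(10, 25)
            counts = rng.integers(0, 300, size=(n_s, n_p))
            counts[:, 0] += 1  # keep totals positive
            factors = tmm_factors(make_table(counts)).factors.to_numpy()
            expected, _ = tmm_oracle(counts)
            np.testing.assert_allclose(factors, expected, atol=1e-10)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against edgeR::calcNormFactors on a fixed table."""
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.05, size=(4, 40))
        counts[:, 0] += 1
        ours = tmm_factors(make_table(counts)).factors.to_numpy()
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts.T).to_csv(csv, index=False)  # edgeR: genes x samples
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv(commandArgs(TRUE)[1]))
            f <- calcNormFactors(DGEList(counts = x), method = "TMM")
            cat(sprintf("%.12f", f$samples$norm.factors), sep = "\\n")
        """))
        res = subprocess.run(["Rscript", str(script), str(csv)],
                             capture_output=True, text=True, check=True)
        reference = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours, reference, atol=1e-8)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(5, 40))
        factors = tmm_factors(make_table(counts)).factors
        assert np.log(factors).mean() == pytest.approx(0.0, abs=1e-12)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 500, size=(4, 30))
        perm = [2, 0, 3, 1]
        f = tmm_factors(make_table(counts)).factors.to_numpy()
        fp = tmm_factors(make_table(counts[perm])).factors.to_numpy()
        np.testing.assert_allclose(fp, f[perm], rtol=1e-12)

    def test_zero_total_sample_raises(self):
        counts = np.array([[0, 0, 0], [1, 2, 3]])
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(make_table(counts))

    def test_disjoint_support_warns_factor_one(self):
        counts = np.array([[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 7, 9]])
        with pytest.warns(UserWarning, match="no positive protein"):
            factors = tmm_factors(make_table(counts)).factors
        assert (factors > 0).all()


class TestNormalize:
    def test_unit_factors_equal_cpm(self):
        counts = np.array([[10, 30, 60], [20, 60, 120]])
        table = make_table(counts)
        factors = tmm_factors(table)
        normed = normalize(table, factors)
        np.testing.assert_allclose(
            normed.iloc[0], np.array([10, 30, 60]) / 100 * 1e6, rtol=1e-9
        )

    def test_zero_count_zero_value(self):
        counts = np.array([[0, 10], [5, 5]])
        table = make_table(counts)
        normed = normalize(table, tmm_factors(table))
        assert normed.iloc[0, 0] == 0.0


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        """(0.01, 0.02, 0.03, 0.04) all adjust to 0.04."""
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_matches_step_up_oracle(self):
        """Agreement with a literal step-up computed from its definition."""
        def oracle(p):
            p = np.asarray(p, float)
            m = p.size
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                q[i] = running
            return q

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)

    def test_sorted_q_monotone_and_nan_passthrough(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        p[5] = np.nan
        q = bh_adjust(p)
        assert np.isnan(q[5])
        finite = ~np.isnan(p)
        order = np.argsort(p[finite])
        assert (np.diff(q[finite][order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_flags_subset_of_unadjusted(self):
        rng = np.random.default_rng(9)
        p = rng.random(100) ** 2
        q = bh_adjust(p)
        assert set(np.flatnonzero(q < 0.05)) <= set(np.flatnonzero(p < 0.05))


class TestDiffExpression:
    def _frame(self, a, b):
        data = np.vstack([a, b])
        samples = [f"A{i}" for i in range(a.shape[0])] + \
                  [f"B{i}" for i in range(b.shape[0])]
        groups = pd.Series(["A"] * a.shape[0] + ["B"] * b.shape[0], index=samples)
        return pd.DataFrame(data, index=samples), groups

    def test_planted_shift_detected(self):
        """A 4-fold planted shift at n=10 vs 10, CV 0.3, is flagged among
        200 null proteins."""
        rng = np.random.default_rng(12)
        a = rng.normal(100, 30, size=(10, 200)).clip(min=1)
        b = rng.normal(100, 30, size=(10, 200)).clip(min=1)
        b[:, 0] = rng.normal(400, 120, size=10).clip(min=1)
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert res["significant"].iloc[0]
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.5)

    def test_null_data_rarely_flagged(self):
        rng = np.random.default_rng(13)
        a = rng.normal(50, 10, size=(8, 150))
        b = rng.normal(50, 10, size=(8, 150))
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert res["significant"].sum() <= 1

    def test_constant_protein_reports_missing_p(self):
        rng = np.random.default_rng(14)
        a = rng.normal(10, 2, size=(5, 3))
        b = rng.normal(10, 2, size=(5, 3))
        a[:, 2] = b[:, 2] = 7.0
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert np.isnan(res["p"].iloc[2])
        assert not res["significant"].iloc[2]
        assert res["test"].iloc[2] == "none"

    def test_routing_normal_vs_nonnormal(self):
        rng = np.random.default_rng(15)
        heavy = st.cauchy.rvs(size=60, random_state=rng)  # non-normal on any scale
        a = np.column_stack([
            rng.normal(20, 3, size=30),
            np.exp(heavy[:30].clip(-20, 20)),
        ])
        b = np.column_stack([
            rng.normal(20, 3, size=30),
            np.exp(heavy[30:].clip(-20, 20)),
        ])
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert res["test"].iloc[0] in ("t", "welch")
        assert res["test"].iloc[1] == "wilcoxon"

    def test_type_one_error_near_nominal(self):
        """Raw p-values of the routed test hold their nominal 5% level under
        a Gaussian null (1000 protein-replicates)."""
        rng = np.random.default_rng(19)
        a = rng.normal(100, 30, size=(10, 1000)).clip(min=1)
        b = rng.normal(100, 30, size=(10, 1000)).clip(min=1)
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_welch_routed_for_unequal_variance(self):
        # both groups Gaussian on the log scale, with very different spread
        rng = np.random.default_rng(16)
        a = np.exp(rng.normal(np.log(50), 0.05, size=(25, 1)))
        b = np.exp(rng.normal(np.log(50), 0.6, size=(25, 1)))
        normed, groups = self._frame(a, b)
        res = diff_expression(normed, groups)
        assert res["test"].iloc[0] == "welch"

    def test_group_swap_flips_log2fc(self):
        rng = np.random.default_rng(17)
        a = rng.normal(30, 5, size=(6, 10))
        b = rng.normal(60, 5, size=(6, 10))
        normed, groups = self._frame(a, b)
        fwd = diff_expression(normed, groups, group_a="A", group_b="B")
        rev = diff_expression(normed, groups, group_a="B", group_b="A")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-9)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-9)

    def test_small_groups_rejected(self):
        rng = np.random.default_rng(18)
        a = rng.normal(size=(2, 4))
        b = rng.normal(size=(5, 4))
        normed, groups = self._frame(a, b)
        with pytest.raises(ValueError, match="at least 3"):
            diff_expression(normed, groups)
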