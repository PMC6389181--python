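"""G-test, BH-FDR, fold change and replicate QC against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisnat.diffexpr import (
    bh_fdr,
    call_responsive,
    fold_change,
    g_test,
    replicate_qc,
    summarize_calls,
)


def scipy_g_oracle(c1, n1, c2, n2):
    """Independent log-likelihood-ratio computation via scipy's power-divergence."""
    table = np.array([[c1, c2], [n1 - c1, n2 - c2]])
    res = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
    return res.statistic, res.pvalue


class TestGTest:
    def test_equal_proportions_give_zero(self):
        assert g_test(10, 100, 20, 200) == (0.0, 1.0)

    def test_matches_oracle_on_worked_example(self):
        g, p = g_test(10, 10**6, 100, 10**6)
        g_ref, p_ref = scipy_g_oracle(10, 10**6, 100, 10**6)
        assert g == pytest.approx(g_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_zero_count_cell_is_finite_and_significant(self):
        g, p = g_test(0, 1000, 10, 1000)
        g_ref, p_ref = scipy_g_oracle(0, 1000, 10, 1000)
        assert np.isfinite(g) and p < 0.05
        assert g == pytest.approx(g_ref, rel=1e-9)

    def test_zero_margin_is_uninformative(self):
        assert g_test(0, 1000, 0, 1000) == (0.0, 1.0)
        assert g_test(1000, 1000, 500, 500) == (0.0, 1.0)  # second row all zero

    def test_symmetry_under_sample_swap(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(10, 10_000, size=2)
            c1, c2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            assert g_test(c1, n1, c2, n2) == pytest.approx(g_test(c2, n2, c1, n1), rel=1e-12)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            n1, n2 = rng.integers(50, 100_000, size=2)
            c1 = int(rng.integers(0, n1))
            c2 = int(rng.integers(1, n2))  # keep the c-column margin positive
            g, p = g_test(c1, int(n1), c2, int(n2))
            g_ref, p_ref = scipy_g_oracle(c1, int(n1), c2, int(n2))
            assert g == pytest.approx(g_ref, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            g_test(10, 5, 0, 100)
        with pytest.raises(ValueError):
            g_test(0, 0, 0, 0)


def hand_bh(p):
    """Step-up rule applied literally: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = [min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)]
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_hand_stepup_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_fdr(p) == pytest.approx(hand_bh(p), rel=1e-12)

    def test_monotone_along_sorted_pvalues(self, rng):
        p = np.sort(rng.random(100))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_permutation_invariance(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        assert bh_fdr(p[perm]) == pytest.approx(bh_fdr(p)[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFoldChange:
    def test_equal_inputs_give_one(self):
        assert fold_change(5.0, 5.0) == pytest.approx(1.0)

    def test_zero_baseline_convention(self):
        assert fold_change(37.5, 0.0) == pytest.approx(38.5)

    def test_monotonicity(self):
        assert fold_change(10.0, 2.0) > fold_change(9.0, 2.0)
        assert fold_change(10.0, 2.0) > fold_change(10.0, 3.0)

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 1.0, pseudocount=-0.5)


class TestReplicateQc:
    @staticmethod
    def expr_frame(vectors):
        rows = []
        for sample, vec in vectors.items():
            for i, v in enumerate(vec):
                rows.append({"transcript_id": f"t{i}", "strand_class": "sense",
                             "sample_id": sample, "rpkm": v})
        return pd.DataFrame(rows)

    @staticmethod
    def design_frame(samples, tissue="root", condition="c", time=0):
        return pd.DataFrame([
            {"sample_id": s, "tissue": tissue, "condition": condition,
             "time": time, "replicate": i + 1}
            for i, s in enumerate(samples)
        ])

    def test_identical_replicates_pass(self):
        expr = self.expr_frame({"r1": [1, 5, 9, 2], "r2": [1, 5, 9, 2]})
        qc = replicate_qc(expr, self.design_frame(["r1", "r2"]))
        assert qc["r"].iloc[0] == pytest.approx(1.0) and qc["pass"].iloc[0]

    def test_reversed_ranks_fail(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        expr = self.expr_frame({"r1": x, "r2": x[::-1]})
        qc = replicate_qc(expr, self.design_frame(["r1", "r2"]))
        r_expected = stats.pearsonr(x, x[::-1]).statistic
        assert qc["r"].iloc[0] == pytest.approx(r_expected)
        assert not qc["pass"].iloc[0]

    def test_zero_variance_replicate_flagged_undefined(self):
        expr = self.expr_frame({"r1": [2, 2, 2], "r2": [1, 5, 9]})
        qc = replicate_qc(expr, self.design_frame(["r1", "r2"]))
        assert np.isnan(qc["r"].iloc[0]) and not qc["pass"].iloc[0]

    def test_nb_replicates_usually_correlate(self, rng):
        # dispersion 0.05, per-transcript means >= 10 spanning a realistic
        # log-uniform dynamic range: r > 0.9 in >= 95% of 200 groups
        n_groups, n_tx = 200, 150
        passed = 0
        means = 10 ** rng.uniform(1, 4, size=n_tx)
        n = 1 / 0.05
        for _ in range(n_groups):
            x = rng.negative_binomial(n, n / (n + means))
            y = rng.negative_binomial(n, n / (n + means))
            if stats.pearsonr(x, y).statistic > 0.9:
                passed += 1
        assert passed / n_groups >= 0.95


class TestCallResponsive:
    def base_frame(self, q, fc):
        return pd.DataFrame({
            "tissue": "root", "condition": "c", "time": 24,
            "transcript_id": [f"t{i}" for i in range(len(q))],
            "strand_class": "sense", "G": 1.0, "p": q, "q": q, "fc": fc,
        })

    def test_nonsignificant_is_ns(self):
        calls = call_responsive(self.base_frame([0.5], [10.0]))
        assert calls["call"].iloc[0] == "ns"

    def test_direction_follows_fold_change(self):
        calls = call_responsive(self.base_frame([1e-5, 1e-5, 1e-5], [2.0, 0.5, 1.0]))
        assert list(calls["call"]) == ["up", "down", "ns"]

    def test_fc_floor_filters_weak_changes(self):
        calls = call_responsive(self.base_frame([1e-5, 1e-5], [3.0, 6.0]), fc_floor=5.0)
        assert list(calls["call"]) == ["ns", "up"]

    def test_summary_counts(self):
        calls = call_responsive(self.base_frame([1e-5, 1e-5, 0.9], [2.0, 0.5, 1.0]))
        summary = summarize_calls(calls)
        up = summary[summary["call"] == "up"]["n_transcripts"].iloc[0]
        down = summary[summary["call"] == "down"]["n_transcripts"].iloc[0]
        assert (up, down) == (1, 1)
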