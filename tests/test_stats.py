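"""Statistical-machinery tests against independent brute-force oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plasticore as pc
from plasticore.normalize import NormalizedMatrix
from plasticore.stats import (
    bh_adjust,
    differential_features,
    nb_wald_differential,
    ols_condition_test,
    rank_sum_auc,
    spearman_corr,
)
import scipy.sparse as sp


def auc_oracle(a, b):
    """Pairwise enumeration: P(A > B) + 0.5 P(A = B)."""
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (len(a) * len(b))


def exact_p_oracle(a, b, alternative):
    """Full enumeration of label assignments of the pooled sample."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    obs = auc_oracle(a, b)
    hits = 0
    for idx in combinations(range(n), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(n) if i not in idx]
        val = auc_oracle(grp_a, grp_b)
        if alternative == "greater":
            hits += val >= obs - 1e-12
        elif alternative == "less":
            hits += val <= obs + 1e-12
        else:
            hits += abs(val - 0.5) >= abs(obs - 0.5) - 1e-12
    return hits / comb(n, n_a)


def bh_oracle(pvals):
    """Step-up formula evaluated directly: padj_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestRankSumAuc:
    def test_complete_separation(self):
        u, auc, p = rank_sum_auc([4, 5, 6], [1, 2, 3])
        assert (u, auc) == (9.0, 1.0)

    def test_symmetry_with_ties(self):
        _, auc, _ = rank_sum_auc([1, 2], [1, 2])
        assert auc == 0.5

    def test_interleaved_hand_case(self):
        u, auc, _ = rank_sum_auc([2, 4, 6], [1, 3, 5])
        assert u == 6.0
        assert auc == pytest.approx(6 / 9)

    def test_auc_matches_pairwise_oracle_random(self, rng):
        for _ in range(50):
            n_a, n_b = rng.integers(2, 30, size=2)
            a = rng.integers(0, 6, size=n_a).astype(float)  # heavy ties
            b = rng.integers(0, 6, size=n_b).astype(float)
            _, auc, _ = rank_sum_auc(a, b)
            assert auc == pytest.approx(auc_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_enumeration(self, rng, alternative):
        for _ in range(10):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 13 - n_a))
            a = rng.integers(0, 5, size=n_a).astype(float)
            b = rng.integers(0, 5, size=n_b).astype(float)
            _, _, p = rank_sum_auc(a, b, alternative)
            assert p == pytest.approx(exact_p_oracle(a, b, alternative), abs=1e-12)

    def test_complement_identity(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=40)
        _, auc_ab, _ = rank_sum_auc(a, b)
        _, auc_ba, _ = rank_sum_auc(b, a)
        assert auc_ab + auc_ba == pytest.approx(1.0, abs=1e-12)

    def test_large_sample_p_close_to_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(0.3, 1, size=60)
        b = rng.normal(0.0, 1, size=50)
        _, _, p = rank_sum_auc(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_auc([], [1.0])


class TestBhAdjust:
    def test_hand_cases(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_adjust([0.05, 1.0]), [0.10, 1.0])
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.random(size=rng.integers(1, 60))
            p = np.clip(p, 1e-12, 1.0)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(np.clip(rng.random(30), 1e-9, 1))
        assert np.all(np.diff(bh_adjust(p)) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestDifferentialFeatures:
    def _norm(self, dense):
        nf, nc = dense.shape
        return NormalizedMatrix(
            sp.csr_matrix(dense), [f"f{i}" for i in range(nf)], [f"c{j}" for j in range(nc)], "none"
        )

    def test_identical_feature_is_null(self):
        dense = np.vstack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        labels = ["A"] * 4 + ["B"] * 4
        out = differential_features(self._norm(dense), labels, "B")
        row = out.set_index("feature_id").loc["f0"]
        assert row["auc"] == 0.5 and row["avg_log2fc"] == pytest.approx(0.0)

    def test_planted_signature_recovered(self, multiome):
        norm = pc.lognorm_rna(multiome["rna"])
        truth = multiome["truth"]
        out = differential_features(norm, truth.labels.to_numpy(), "ILC2")
        hits = out.set_index("feature_id").loc[truth.signature_genes["ILC2"]]
        assert ((hits["padj"] < 0.05) & (hits["avg_log2fc"] > 0)).mean() >= 0.98
        assert (hits["auc"] > 0.5).all()

    def test_permuted_labels_near_null(self, multiome):
        norm = pc.lognorm_rna(multiome["rna"])
        rng = np.random.default_rng(77)
        labels = rng.permutation(multiome["truth"].labels.to_numpy())
        out = differential_features(norm, labels, "ILC2")
        assert (out["padj"] < 0.05).sum() <= 2

    def test_small_group_rejected(self):
        dense = np.ones((2, 4))
        with pytest.raises(ValueError):
            differential_features(self._norm(dense), ["A", "B", "B", "B"], "A")


class TestNbWald:
    def test_constant_region_is_null(self):
        counts = pd.DataFrame(
            np.vstack([np.full(6, 50), np.full(6, 20), np.full(6, 80)]),
            index=["flat", "low", "high"],
            columns=list("abcdef"),
        )
        out = nb_wald_differential(counts, ["A"] * 3 + ["B"] * 3)
        row = out.set_index("feature_id").loc["flat"]
        assert abs(row["log2fc"]) < 1e-6
        assert row["p"] > 0.9

    def test_all_zero_region_skipped(self):
        counts = pd.DataFrame(
            np.vstack([np.zeros(4), np.full(4, 20)]), index=["z", "nz"], columns=list("abcd")
        )
        out = nb_wald_differential(counts, ["A", "A", "B", "B"]).set_index("feature_id")
        assert np.isnan(out.loc["z", "p"]) and not np.isnan(out.loc["nz", "p"])

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(np.ones((2, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_differential(counts, ["A", "A", "B"])

    def test_planted_recovery_single_seed(self):
        tab, truth = pc.generate_bulk_counts(
            n_regions=500, n_differential=50, planted_log2fc=2.0, seed=3
        )
        out = nb_wald_differential(tab, tab.attrs["conditions"]).set_index("feature_id")
        hit = out.loc[truth.differential_regions]
        assert ((hit["padj"] < 0.05) & (hit["log2fc"] > 0)).mean() >= 0.9
        assert hit["log2fc"].mean() == pytest.approx(2.0, abs=0.3)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert spearman_corr([1, 2, 3, 4], [8, 6, 4, 2]) == -1.0

    def test_hand_case(self):
        assert spearman_corr([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_matches_rank_then_pearson(self, rng):
        from scipy.stats import rankdata

        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            manual = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert spearman_corr(x, y) == pytest.approx(manual, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert spearman_corr(np.exp(x), y) == pytest.approx(spearman_corr(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestOlsConditionTest:
    def test_identical_groups_null(self):
        res = ols_condition_test([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert res.coef("B")["coef"] == pytest.approx(0.0)
        assert res.coef("B")["p"] == pytest.approx(1.0)

    def test_exact_fit_two_groups(self):
        res = ols_condition_test([0, 0, 0, 1, 1, 1], ["A"] * 3 + ["B"] * 3)
        assert res.coef("B")["coef"] == pytest.approx(1.0)
        assert res.coef("B")["p"] < 1e-10

    def test_matches_pooled_t(self, rng):
        from scipy.stats import ttest_ind

        x = rng.normal(0, 1, size=12)
        y = rng.normal(0.8, 1, size=9)
        res = ols_condition_test(
            np.r_[x, y], ["A"] * 12 + ["B"] * 9, reference="A"
        )
        t_ref, p_ref = ttest_ind(y, x, equal_var=True)
        assert res.coef("B")["t"] == pytest.approx(t_ref, abs=1e-10)
        assert res.coef("B")["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_thin_level_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            ols_condition_test([1, 2, 3], ["A", "A", "B"])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(st.integers(0, 8), min_size=2, max_size=20),
    st.lists(st.integers(0, 8), min_size=2, max_size=20),
)
def test_auc_complement_property(a, b):
    """auc(a,b) + auc(b,a) == 1 for arbitrary integer samples with ties."""
    _, auc_ab, _ = rank_sum_auc(a, b)
    _, auc_ba, _ = rank_sum_auc(b, a)
    assert auc_ab + auc_ba == pytest.approx(1.0, abs=1e-12)
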