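"""Statistical engine against independent oracles.

Welch's t is checked against a direct evaluation of the Welch-Satterthwaite
formula, the Mann-Whitney exact p against full enumeration of group
assignments, BH/Bonferroni against hand-computed step-up values, Spearman
against an explicit rank-then-product-moment computation, and Dunn's
z-statistics against direct mean-rank arithmetic.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aldlipid.stats import (
    adjust_p,
    compare_groups,
    correlate,
    fold_change,
    kruskal_dunn,
    mann_whitney,
    pca_scores,
    plsda_scores,
    route_test,
    volcano,
    welch_t,
)

# ---------------------------------------------------------------------------
# oracles


def _welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * sps.t.sf(abs(t), df)


def _mwu_exact_oracle(a, b):
    """Two-sided exact p by enumerating all group assignments."""
    pooled = np.asarray(list(a) + list(b), float)
    na = len(a)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - na * (na + 1) / 2

    observed = u_of(range(na))
    n_extreme = 0
    total = 0
    mean_u = na * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_of(idx) - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / total


def _spearman_oracle(x, y):
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + j + 1) / 2  # average rank, 1-based
            i = j
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


# ---------------------------------------------------------------------------
# test routing


def test_route_test_normal_vs_lognormal(rng):
    normal_a = rng.normal(0, 1, 50)
    normal_b = rng.normal(0, 1, 50)
    skewed = rng.lognormal(0, 1.5, 50)
    assert route_test(normal_a, normal_b) == "welch"
    assert route_test(normal_a, skewed) == "mannwhitney"


def test_route_test_small_group_forced(caplog):
    with caplog.at_level("WARNING"):
        assert route_test([1.0, 2.0], [1.0, 2.0, 3.0]) == "mannwhitney"
    assert "n < 3" in caplog.text


def test_welch_matches_formula_oracle(rng):
    a = rng.normal(0.0, 1.0, 14)
    b = rng.normal(0.7, 2.0, 9)
    t, p = welch_t(a, b)
    t0, p0 = _welch_oracle(a, b)
    assert t == pytest.approx(t0, abs=1e-10)
    assert p == pytest.approx(p0, abs=1e-10)


def test_degenerate_equal_constant_groups():
    assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    _, p = mann_whitney([2.0, 2.0], [2.0, 2.0])
    assert p == 1.0


def test_mwu_exact_small_sample():
    """{1,2,3} vs {4,5,6}: the 20 assignments give two-sided p = 0.1."""
    _, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1, abs=1e-12)
    assert _mwu_exact_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_mwu_identical_groups_p_one():
    _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=1e-12)


def test_mwu_normal_approximation_near_exact(rng):
    """At n = 8 per group without ties the tie-corrected normal
    approximation should sit within 0.01 of the enumeration p."""
    for _ in range(5):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = _mwu_exact_oracle(a, b)
        approx = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(exact - approx) < 0.01


class TestKruskalDunn:
    def test_identical_groups(self):
        h, p, pairwise = kruskal_dunn([[1, 2, 3]] * 3)
        assert p == pytest.approx(1.0)
        assert len(pairwise) == 3

    def test_disjoint_supports(self, rng):
        groups = [rng.uniform(i * 10, i * 10 + 1, 10) for i in range(3)]
        _, p, pairwise = kruskal_dunn(groups)
        assert p < 0.01
        assert (pairwise["p_adj"] < 0.05).all()

    def test_pairwise_count(self, rng):
        groups = [rng.normal(0, 1, 5) for _ in range(5)]
        _, _, pairwise = kruskal_dunn(groups)
        assert len(pairwise) == 5 * 4 // 2

    def test_dunn_z_matches_rank_arithmetic(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 8.0], [9.0, 10.0, 11.0]]
        _, _, pairwise = kruskal_dunn(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        mean_ranks = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
        n = len(pooled)
        var = n * (n + 1) / 12 * (1 / 3 + 1 / 3)  # no ties
        z01 = (mean_ranks[0] - mean_ranks[1]) / np.sqrt(var)
        row = pairwise[(pairwise.group_i == 0) & (pairwise.group_j == 1)].iloc[0]
        assert row["z"] == pytest.approx(z01, abs=1e-12)

    def test_too_few_groups(self):
        with pytest.raises(ValueError, match="two-group"):
            kruskal_dunn([[1, 2], [3, 4]])


class TestAdjustment:
    def test_bh_hand_step_up(self):
        out = adjust_p([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_p([0.3], "BH")[0] == pytest.approx(0.3)

    def test_bonferroni_and_holm(self):
        assert np.allclose(adjust_p([0.01, 0.4], "Bonferroni"), [0.02, 0.8])
        # Holm: sorted p * (m - rank + 1), cummax
        assert np.allclose(adjust_p([0.01, 0.04, 0.03], "Holm"), [0.03, 0.06, 0.06])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.2], "BH")
        with pytest.raises(ValueError):
            adjust_p([0.5], "FDR")

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_bh_monotone_and_permutation_invariant(self, pvals, rand):
        adj = adjust_p(pvals, "BH")
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = list(range(len(pvals)))
        rand.shuffle(perm)
        assert np.allclose(adj[perm], adjust_p(np.asarray(pvals)[perm], "BH"))


class TestFoldChange:
    def test_printed_group_means_ratio(self):
        fc, _ = fold_change([601.0] * 3, [269.0] * 3)
        assert 2.23 <= fc <= 2.24

    def test_identity_and_antisymmetry(self, rng):
        a = rng.lognormal(1, 0.3, 10)
        fc, log2fc = fold_change(a, a)
        assert fc == pytest.approx(1.0) and log2fc == pytest.approx(0.0)
        _, fwd = fold_change(a, 2 * a)
        _, rev = fold_change(2 * a, a)
        assert fwd == pytest.approx(-rev)

    def test_nonpositive_reference_flagged(self):
        fc, log2fc = fold_change([1.0, 2.0], [0.0, 0.0])
        assert np.isnan(fc) and np.isnan(log2fc)


class TestVolcano:
    def _planted_table(self, rng):
        fcs = {"L1": 3.0, "L2": 2.0, "L3": 1.2, "L4": 0.4, "L5": 1.0}
        n = 20
        data = {}
        for lipid, fc in fcs.items():
            base = rng.lognormal(3.0, 0.05, 2 * n)
            base[:n] *= fc
            data[lipid] = base
        table = pd.DataFrame(data).T
        table.columns = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        return table

    def test_planted_fold_changes_classified(self, rng):
        table = self._planted_table(rng)
        groups_a = [c for c in table.columns if c.startswith("A")]
        groups_b = [c for c in table.columns if c.startswith("B")]
        results = compare_groups(table, groups_a, groups_b)
        _, n_elev, n_lower = volcano(results, fc_thresh=1.5, p_thresh=0.05)
        assert (n_elev, n_lower) == (2, 1)

    def test_identical_strata_all_ns(self, rng):
        table = self._planted_table(rng)
        cols = list(table.columns[:10])
        results = compare_groups(table, cols, cols)
        _, n_elev, n_lower = volcano(results)
        assert (n_elev, n_lower) == (0, 0)

    def test_degenerate_thresholds(self, rng):
        table = self._planted_table(rng)
        groups_a = [c for c in table.columns if c.startswith("A")]
        groups_b = [c for c in table.columns if c.startswith("B")]
        results = compare_groups(table, groups_a, groups_b)
        labels, n_elev, n_lower = volcano(results, fc_thresh=1.0, p_thresh=1.0)
        separable = results.index[results["fold_change"] != 1.0]
        assert (labels.loc[separable, "label"] != "ns").all()


def test_compare_groups_invariant_to_row_and_column_order(rng):
    table = pd.DataFrame(
        rng.lognormal(3, 0.3, (6, 16)),
        index=[f"L{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(16)],
    )
    a, b = [f"S{i}" for i in range(8)], [f"S{i}" for i in range(8, 16)]
    base = compare_groups(table, a, b)
    perm = table.sample(frac=1.0, axis=0, random_state=3).sample(
        frac=1.0, axis=1, random_state=4
    )
    shuffled = compare_groups(perm, list(rng.permutation(a)), b)
    pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())


def test_missing_values_excluded_not_zeroed(caplog, rng):
    table = pd.DataFrame(
        rng.lognormal(3, 0.3, (2, 10)),
        index=["L0", "L1"],
        columns=[f"S{i}" for i in range(10)],
    )
    table.loc["L1", ["S0", "S1", "S2", "S3"]] = np.nan
    with caplog.at_level("WARNING"):
        results = compare_groups(table, [f"S{i}" for i in range(5)], [f"S{i}" for i in range(5, 10)])
    assert "L1" not in results.index  # only one value left in group A
    assert "excluded" in caplog.text


class TestCorrelate:
    def test_monotone_gives_spearman_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert correlate(x, np.exp(x), "spearman")[0] == pytest.approx(1.0)

    def test_antithetic_pearson(self, rng):
        x = rng.normal(0, 1, 20)
        assert correlate(x, -x, "pearson")[0] == pytest.approx(-1.0)

    def test_spearman_matches_rank_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        x[3] = x[7]  # inject a tie
        coef, _ = correlate(x, y, "spearman")
        assert coef == pytest.approx(_spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_flagged(self):
        coef, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")
        assert np.isnan(coef) and np.isnan(p)


class TestProjections:
    def test_duplicated_samples_get_identical_scores(self, toy_table):
        table = pd.concat([toy_table, toy_table.iloc[:, :1]], axis=1)
        table.columns = list(toy_table.columns) + ["dup"]
        scores, _, _ = pca_scores(table)
        assert np.allclose(scores.loc["S0"], scores.loc["dup"])

    def test_explained_variance_conservation(self, toy_table):
        _, _, ratio = pca_scores(toy_table, n_components=5)
        assert ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(0, 1, 8)
        v = rng.normal(0, 1, 20)
        table = pd.DataFrame(
            np.exp2(np.outer(v, u) + 5),
            index=[f"L{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(8)],
        )
        _, _, ratio = pca_scores(table, n_components=3)
        assert ratio[0] >= 0.999

    def test_constant_rows_dropped_with_warning(self, toy_table, caplog):
        table = toy_table.copy()
        table.loc["FLAT(1:0)"] = 7.0
        with caplog.at_level("WARNING"):
            scores, loadings, _ = pca_scores(table)
        assert "FLAT(1:0)" not in loadings.index

    def test_plsda_separates_separable_groups(self, rng):
        n = 10
        table = pd.DataFrame(
            rng.lognormal(3, 0.1, (12, 2 * n)),
            index=[f"L{i}" for i in range(12)],
            columns=[f"S{i}" for i in range(2 * n)],
        )
        table.iloc[:4, :n] *= 4.0
        labels = {f"S{i}": ("case" if i < n else "ctrl") for i in range(2 * n)}
        scores = plsda_scores(table, labels)
        case = scores.iloc[:n, 0]
        ctrl = scores.iloc[n:, 0]
        assert min(case) > max(ctrl) or max(case) < min(ctrl)
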