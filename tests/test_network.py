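"""Profile correlations, pair classes, curves, clustering and set utilities."""

import itertools

import numpy as np
import pytest

from emapkit import (
    InteractionMatrix,
    Thresholds,
    classify_pairs,
    class_crosstab,
    hierarchical_cluster,
    high_correlation_pairs,
    hyper_interactors,
    pos_neg_ratio_curve,
    profile_correlations,
    s_vs_correlation_curve,
    set_overlap,
)
from emapkit.core_io import GeneLocus, ValidationError
from emapkit.network import CorrelationMatrix
from tests.conftest import make_matrix


def oracle_profile_corr(m, i, j):
    """Pairwise-complete Pearson over partners excluding i, j and flags."""
    S = np.where(m.usable, m.S, np.nan)
    x, y = S[i].copy(), S[j].copy()
    x[[i, j]] = np.nan
    y[[i, j]] = np.nan
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    return np.corrcoef(x[ok], y[ok])[0, 1]


class TestProfileCorrelations:
    def test_scaled_profile_correlates_perfectly(self):
        m = make_matrix(12, seed=1, p_from_null=False)
        m.S[1, :] = 2 * m.S[0, :]
        m.S[:, 1] = 2 * m.S[:, 0]
        m.S[0, 1] = m.S[1, 0] = 0.5  # mutual entry excluded, cannot spoil r
        np.fill_diagonal(m.S, np.nan)
        c = profile_correlations(m)
        assert c.r[0, 1] == pytest.approx(1.0)

    def test_matches_oracle_on_random_matrix(self):
        m = make_matrix(20, seed=2, p_from_null=False)
        m.S[m.S > 1.8] = np.nan  # sprinkle missing values
        m.flags["MISSING"] |= ~np.isfinite(m.S)
        c = profile_correlations(m)
        for i, j in itertools.combinations(range(20), 2):
            want = oracle_profile_corr(m, i, j)
            if np.isnan(want):
                assert np.isnan(c.r[i, j])
            else:
                assert c.r[i, j] == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_all_missing_profile_yields_missing(self):
        m = make_matrix(8, seed=3, p_from_null=False)
        m.S[4, :] = np.nan
        m.S[:, 4] = np.nan
        m.flags["MISSING"] |= ~np.isfinite(m.S)
        c = profile_correlations(m)
        assert np.isnan(c.r[4, :]).all()

    def test_invariant_to_the_pair_own_entry(self):
        m = make_matrix(15, seed=4, p_from_null=False)
        c1 = profile_correlations(m)
        m.S[2, 9] = m.S[9, 2] = 99.0  # perturb only the mutual entry
        c2 = profile_correlations(m)
        assert c1.r[2, 9] == pytest.approx(c2.r[2, 9], rel=1e-12)

    def test_symmetry(self, default_results):
        _, res = default_results
        c = res.correlations("control")
        np.testing.assert_allclose(
            np.nan_to_num(c.r, nan=0.0), np.nan_to_num(c.r.T, nan=0.0), rtol=1e-12
        )


def _mats_with_p(ps, pc, n=4):
    genes = [f"g{i}" for i in range(n)]
    S = np.ones((n, n))
    m = InteractionMatrix(genes, S)
    m.P = np.where(np.isfinite(m.S), ps, np.nan)
    r = np.full((n, n), 0.1)
    P = np.full((n, n), pc)
    c = CorrelationMatrix(genes, r, P, np.full((n, n), 10))
    return m, c


class TestClassifyPairs:
    @pytest.mark.parametrize(
        "ps,pc,want",
        [
            (0.004, 0.2, "S_ONLY"),
            (0.5, 0.5, "NEITHER"),
            (0.005, 0.05, "BOTH"),  # boundary values count as significant
            (0.9, 0.01, "CORR_ONLY"),
        ],
    )
    def test_two_by_two_rule(self, ps, pc, want):
        m, c = _mats_with_p(ps, pc)
        cats = {p.category for p in classify_pairs(m, c, Thresholds())}
        assert cats == {want}

    def test_categories_partition_scored_pairs(self, default_results):
        _, res = default_results
        m = res.interactions("control")
        classes = classify_pairs(m, res.correlations("control"), res.thresholds)
        iu = np.triu_indices(m.n, 1)
        assert len(classes) == int(m.usable[iu].sum())
        assert all(p.category in ("S_ONLY", "CORR_ONLY", "BOTH", "NEITHER") for p in classes)


class TestHighCorrelationPairs:
    def test_strict_inequality_at_cut(self):
        genes = list("abc")
        r = np.array([[np.nan, 0.51, 0.5], [0.51, np.nan, -0.2], [0.5, -0.2, np.nan]])
        c = CorrelationMatrix(genes, r, np.full((3, 3), 0.5), np.full((3, 3), 10))
        pairs = high_correlation_pairs(c, 0.5)
        assert [p for p, _ in pairs] == [("a", "b")]

    def test_empty_matrix_empty_list(self):
        c = CorrelationMatrix(["a", "b"], np.full((2, 2), np.nan), np.full((2, 2), np.nan), np.zeros((2, 2)))
        assert high_correlation_pairs(c, 0.5) == []


def _curve_inputs(n_pairs, seed=0, n=40):
    """Matrix + correlations with exactly n_pairs significant S pairs."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    S = rng.normal(size=(n, n))
    S = (S + S.T) / 2
    m = InteractionMatrix(genes, S)
    m.P = np.full((n, n), 1.0)
    iu = list(zip(*np.triu_indices(n, 1)))
    chosen = [iu[k] for k in rng.choice(len(iu), size=n_pairs, replace=False)]
    for i, j in chosen:
        m.P[i, j] = m.P[j, i] = 0.001
    r = np.clip(rng.normal(scale=0.3, size=(n, n)), -1, 1)
    r = (r + r.T) / 2
    c = CorrelationMatrix(genes, r, np.full((n, n), 0.5), np.full((n, n), n - 2))
    return m, c


class TestCurves:
    def test_window_counting_35_pairs(self):
        m, c = _curve_inputs(35, seed=1)
        pts = s_vs_correlation_curve(m, c, Thresholds())
        assert len(pts) == 4
        assert [p.n for p in pts] == [10, 10, 10, 5]
        assert [p.partial for p in pts] == [False, False, False, True]

    def test_flat_when_all_scores_equal(self):
        m, c = _curve_inputs(30, seed=2)
        m.S[np.isfinite(m.S)] = -3.0
        pts = s_vs_correlation_curve(m, c, Thresholds())
        assert all(p.value == pytest.approx(-3.0) for p in pts)

    def test_matches_sort_and_chunk_oracle(self):
        m, c = _curve_inputs(47, seed=3)
        th = Thresholds()
        iu = np.triu_indices(m.n, 1)
        ok = m.usable[iu] & (m.P[iu] <= th.p_s) & np.isfinite(c.r[iu])
        r, s = c.r[iu][ok], m.S[iu][ok]
        order = np.argsort(r, kind="stable")
        r, s = r[order], s[order]
        want = [
            (r[k : k + 10].mean(), s[k : k + 10].mean()) for k in range(0, len(r), 10)
        ]
        got = [(p.mean_r, p.value) for p in s_vs_correlation_curve(m, c, th)]
        assert got == pytest.approx(want)

    def test_ratio_and_degenerate_window(self):
        m, c = _curve_inputs(10, seed=4)
        vals = np.array([1.0] * 6 + [-1.0] * 3 + [2.0])
        iu = np.triu_indices(m.n, 1)
        sig = np.where(m.usable[iu] & (m.P[iu] <= 0.005))[0]
        S = m.S
        for k, idx in enumerate(sig):
            i, j = iu[0][idx], iu[1][idx]
            S[i, j] = S[j, i] = vals[k]
        pts = pos_neg_ratio_curve(m, c, Thresholds())
        assert pts[0].value == pytest.approx(7 / 3)
        # all-positive window -> missing, not infinity
        S[np.isfinite(S)] = 1.0
        pts = pos_neg_ratio_curve(m, c, Thresholds())
        assert np.isnan(pts[0].value)

    def test_permutation_invariance(self):
        m, c = _curve_inputs(30, seed=5)
        perm = np.random.default_rng(0).permutation(m.n)
        m2 = m.reordered(perm)
        c2 = CorrelationMatrix(
            [c.genes[i] for i in perm],
            c.r[np.ix_(perm, perm)],
            c.P[np.ix_(perm, perm)],
            c.n_used[np.ix_(perm, perm)],
        )
        a = [(p.mean_r, p.value) for p in s_vs_correlation_curve(m, c, Thresholds())]
        b = [(p.mean_r, p.value) for p in s_vs_correlation_curve(m2, c2, Thresholds())]
        assert a == pytest.approx(b)


class TestClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        m = make_matrix(10, seed=6, p_from_null=False)
        m.S[1, :] = m.S[0, :]
        m.S[:, 1] = m.S[:, 0]
        m.S[0, 1] = m.S[1, 0] = 0.0
        np.fill_diagonal(m.S, np.nan)
        c = profile_correlations(m)
        leaves, Z = hierarchical_cluster(c)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)
        i1, i2 = int(Z[0, 0]), int(Z[0, 1])
        genes_sorted = sorted(c.genes)
        assert {genes_sorted[i1], genes_sorted[i2]} == {m.genes[0], m.genes[1]}

    def test_two_block_structure_separates(self):
        # two planted blocks with correlated profiles: the leaf order keeps
        # each block contiguous (adjusted-Rand 1 at the 2-cluster cut)
        rng = np.random.default_rng(7)
        n = 16
        base1, base2 = rng.normal(size=n), rng.normal(size=n)
        S = np.empty((n, n))
        for i in range(n):
            src = base1 if i < 8 else base2
            S[i] = src + rng.normal(scale=0.05, size=n)
        S = (S + S.T) / 2
        m = InteractionMatrix([f"g{i:02d}" for i in range(n)], S)
        c = profile_correlations(m)
        leaves, Z = hierarchical_cluster(c)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=2, criterion="maxclust")
        genes_sorted = sorted(c.genes)
        block = {g: (0 if int(g[1:]) < 8 else 1) for g in genes_sorted}
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score([block[g] for g in genes_sorted], labels) == 1.0

    def test_deterministic_rerun(self, default_results):
        _, res = default_results
        l1, Z1 = hierarchical_cluster(res.correlations("control"))
        l2, Z2 = hierarchical_cluster(res.correlations("control"))
        assert l1 == l2
        np.testing.assert_array_equal(Z1, Z2)

    def test_degenerate_matrix_rejected(self):
        c = CorrelationMatrix(["a", "b"], np.full((2, 2), np.nan), np.full((2, 2), np.nan), np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            hierarchical_cluster(c)


class TestHyperInteractors:
    def test_planted_hub_flagged(self):
        n = 40
        m = make_matrix(n, seed=8, p_from_null=False)
        m.P = np.full((n, n), 1.0)
        hub = 5
        for j in range(n):  # hub interacts with ~30% of partners
            if j != hub and j % 3 == 0:
                m.P[hub, j] = m.P[j, hub] = 0.001
        flagged, counts = hyper_interactors(m, Thresholds())
        assert flagged == {m.genes[hub]}
        assert counts[m.genes[hub]] >= 12

    def test_uniform_screen_flags_nothing(self, default_results):
        _, res = default_results
        flagged, _ = hyper_interactors(res.interactions("control"), res.thresholds)
        assert flagged == set()

    def test_empty_matrix_empty_set(self):
        m = InteractionMatrix(["a", "b", "c"], np.full((3, 3), np.nan))
        flagged, _ = hyper_interactors(m, Thresholds())
        assert flagged == set()


class TestClassCrosstab:
    def _loci(self, m, classes):
        return [
            GeneLocus(g, "chr1", 1_000_000 * i, 1_000_000 * i + 100, classes[i])
            for i, g in enumerate(m.genes)
        ]

    def test_single_class_overall_rate(self):
        m = make_matrix(12, seed=9)
        loci = self._loci(m, ["transporter"] * 12)
        tab = class_crosstab(m, loci, Thresholds())
        assert len(tab) == 1
        iu = np.triu_indices(12, 1)
        sig = int((m.usable[iu] & (m.P[iu] <= 0.005)).sum())
        assert tab.iloc[0]["freq_s"] == pytest.approx(sig / m.usable[iu].sum())

    def test_no_cross_class_interactions(self):
        n = 10
        genes = [f"g{i}" for i in range(n)]
        S = np.zeros((n, n))
        m = InteractionMatrix(genes, S)
        m.P = np.full((n, n), 1.0)
        for i, j in [(0, 1), (2, 3)]:  # within class A only
            m.P[i, j] = m.P[j, i] = 0.001
        classes = ["A"] * 5 + ["B"] * 5
        tab = class_crosstab(m, self._loci(m, classes), Thresholds())
        off = tab[(tab.class_a == "A") & (tab.class_b == "B")]
        assert off.iloc[0]["freq_s"] == 0.0
        within = tab[(tab.class_a == "A") & (tab.class_b == "A")]
        assert within.iloc[0]["n_sig_s"] == 2

    def test_unlabeled_grouped_as_unannotated(self):
        m = make_matrix(6, seed=10, p_from_null=False)
        m.P = np.full((6, 6), 1.0)
        loci = self._loci(m, ["A", "A", "A", None, None, None])
        tab = class_crosstab(m, loci, Thresholds())
        assert "unannotated" in set(tab.class_a) | set(tab.class_b)


class TestSetOverlap:
    def test_disjoint_and_identical(self):
        a = {("g1", "g2"), ("g1", "g3")}
        b = {("g4", "g5")}
        counts = set_overlap(a, {"other": b})
        assert counts[frozenset({"tested", "other"})] == 0
        counts = set_overlap(a, {"other": set(a)})
        assert counts[frozenset({"tested", "other"})] == len(a)

    def test_matches_bruteforce_regions(self):
        rng = np.random.default_rng(11)
        universe = [(f"g{i}", f"g{j}") for i in range(20) for j in range(i + 1, 20)]
        sets = {
            name: {universe[k] for k in rng.choice(len(universe), 40, replace=False)}
            for name in ("tested", "krogan", "boone")
        }
        counts = set_overlap(sets["tested"], {k: v for k, v in sets.items() if k != "tested"})
        # brute force every element of the union
        regions = {}
        for el in set().union(*sets.values()):
            key = frozenset(n for n, s in sets.items() if el in s)
            regions[key] = regions.get(key, 0) + 1
        for key, n in regions.items():
            assert counts[key] == n
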