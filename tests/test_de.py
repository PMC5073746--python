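import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vinestress import de
from vinestress.core import AnnotationTable, SampleDesign
from vinestress.simulate import SimulationConfig, simulate_experiment

from conftest import full_design, make_matrix


def design_1g(n_timepoints=3, n_replicates=3):
    return full_design(n_timepoints, n_replicates, genotypes=("MP",))


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

class TestSam:
    def test_constant_gene_scores_zero(self, design36):
        rng = np.random.default_rng(0)
        X = rng.normal(8, 0.3, (20, 36))
        X[0] = 7.0
        em = make_matrix(X, design36)
        labels = em.group_labels()
        res = de.sam_multiclass(em, labels, n_perm=50, seed=0)
        assert res.d.iloc[0] == 0.0
        assert not res.significant.iloc[0]

    def test_d_matches_brute_force_oracle(self, design36):
        rng = np.random.default_rng(1)
        em = make_matrix(rng.normal(8, 0.5, (15, 36)), design36)
        labels = em.group_labels()
        res = de.sam_multiclass(em, labels, n_perm=20, s0=0.2, seed=0)
        X = em.values.to_numpy()
        lab = np.array(labels)
        for i in range(15):
            grand = X[i].mean()
            ssb = ssw = 0.0
            inv = 0.0
            for c in sorted(set(labels)):
                xk = X[i][lab == c]
                ssb += len(xk) * (xk.mean() - grand) ** 2
                ssw += ((xk - xk.mean()) ** 2).sum()
                inv += 1.0 / len(xk)
            r = math.sqrt(ssb)
            s = math.sqrt(inv * ssw / (36 - 12))
            assert res.d.iloc[i] == pytest.approx(r / (s + 0.2), abs=1e-10)

    def test_planted_shift_recovered_with_no_false_calls(self, design36):
        """5-sigma one-class shifts dominate the permutation null at FDR 0.1%."""
        rng = np.random.default_rng(42)
        X = rng.normal(8, 0.25, (1000, 36))
        labels = ["{0}:{1}:{2}".format(s.genotype, s.treatment, s.timepoint)
                  for s in design36]
        target = np.array(labels) == "MP:WS:0"
        X[:50, target] += 5 * 0.25
        em = make_matrix(X, design36)
        res = de.sam_multiclass(em, labels, n_perm=300, fdr_percent=0.1, seed=0)
        planted = set(em.gene_ids[:50])
        assert len(res.selected & planted) >= 45
        assert len(res.selected - planted) <= 1

    def test_selection_shrinks_as_fdr_tightens(self, design36):
        rng = np.random.default_rng(3)
        X = rng.normal(8, 0.25, (300, 36))
        X[:30, ::2] += 0.8
        em = make_matrix(X, design36)
        labels = em.group_labels()
        loose = de.sam_multiclass(em, labels, n_perm=100, fdr_percent=5.0, seed=1)
        tight = de.sam_multiclass(em, labels, n_perm=100, fdr_percent=0.1, seed=1)
        assert tight.selected <= loose.selected

    def test_small_class_rejected(self, design36):
        em = make_matrix(np.ones((3, 36)), design36)
        labels = ["a"] + ["b"] * 35
        with pytest.raises(ValueError, match="'a'"):
            de.sam_multiclass(em, labels, n_perm=10)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_groups_give_f_zero(self):
        design = design_1g(n_timepoints=2)
        em = make_matrix([[1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3]], design)
        res = de.anova_bonferroni(em, em.group_labels(("treatment", "timepoint")), alpha=0.01)
        assert res.F.iloc[0] == 0.0
        assert not res.selected

    def test_matches_scipy_f_oneway(self, design36):
        rng = np.random.default_rng(5)
        em = make_matrix(rng.normal(8, 1, (25, 36)), design36)
        labels = em.group_labels()
        res = de.anova_bonferroni(em, labels, alpha=0.01)
        lab = np.array(labels)
        X = em.values.to_numpy()
        for i in range(25):
            groups = [X[i][lab == c] for c in sorted(set(labels))]
            F, p = stats.f_oneway(*groups)
            assert res.F.iloc[i] == pytest.approx(F, abs=1e-10)
            assert res.p.iloc[i] == pytest.approx(p, abs=1e-10)

    def test_bonferroni_family_is_tested_genes(self, design36):
        rng = np.random.default_rng(6)
        em = make_matrix(rng.normal(8, 0.5, (100, 36)), design36)
        res = de.anova_bonferroni(em, em.group_labels(), alpha=0.01)
        # selected iff p * 100 <= 0.01, i.e. per-gene cutoff 1e-4
        expect = set(res.p.index[res.p <= 1e-4])
        assert res.selected == expect

    def test_degenerate_rows(self, design36):
        X = np.tile(np.ones(36), (2, 1))
        X[0, :3] = 5.0  # zero within-group variance, unequal means
        em = make_matrix(X, design36)
        res = de.anova_bonferroni(em, em.group_labels(), alpha=0.01)
        assert res.p.iloc[0] == 0.0 and res.selected_mask.iloc[0]
        assert res.p.iloc[1] == 1.0 and not res.selected_mask.iloc[1]

    def test_selection_shrinks_as_alpha_tightens(self, design36):
        rng = np.random.default_rng(8)
        X = rng.normal(8, 0.25, (200, 36))
        X[:20, ::3] += 1.0
        em = make_matrix(X, design36)
        labels = em.group_labels()
        loose = de.anova_bonferroni(em, labels, alpha=0.05)
        tight = de.anova_bonferroni(em, labels, alpha=0.001)
        assert tight.selected <= loose.selected


# ---------------------------------------------------------------------------
# fold change & Welch t
# ---------------------------------------------------------------------------

class TestFoldChangeAndT:
    def test_arithmetic(self):
        design = design_1g(n_timepoints=1, n_replicates=3)
        em = make_matrix([[8, 8, 8, 10, 10, 10], [10, 10, 10, 9.2, 9.2, 9.2],
                          [7, 7, 7, 7, 7, 7]], design)
        ww = em.samples_where(treatment="WW")
        ws = em.samples_where(treatment="WS")
        fc = de.fold_change(em, ww, ws)
        assert fc.iloc[0] == pytest.approx(2.0)
        assert fc.iloc[1] == pytest.approx(-0.8)
        assert fc.iloc[2] == 0.0
        assert de.fc_select(fc, 2.0) == {"g0000"}
        assert de.fc_select(fc, 3.0) == {"g0000"}

    def test_empty_group_rejected(self):
        design = design_1g(1, 2)
        em = make_matrix(np.ones((1, 4)), design)
        with pytest.raises(ValueError):
            de.fold_change(em, [], em.samples_where(treatment="WS"))

    def test_welch_matches_closed_form(self):
        design = design_1g(n_timepoints=1, n_replicates=3)
        a = np.array([8.0, 8.1, 7.9])
        b = np.array([11.0, 11.2, 10.8])
        em = make_matrix([np.concatenate([a, b])], design)
        _, p = de.welch_t(em, em.samples_where(treatment="WW"),
                          em.samples_where(treatment="WS"))
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert p.iloc[0] == pytest.approx(p_oracle, abs=1e-10)
        sel = de.ttest_fc_select(em, p_threshold=0.01, fc_threshold=2.0)[("MP", 0)]
        assert sel.selected == {"g0000"}

    def test_identical_replicates_select_nothing(self):
        design = design_1g(n_timepoints=1, n_replicates=3)
        rng = np.random.default_rng(0)
        row = rng.normal(8, 0.2, 3)
        em = make_matrix([np.concatenate([row, row])], design)
        sel = de.ttest_fc_select(em)[("MP", 0)]
        assert sel.selected == set()

    def test_lagged_genotype_has_fewer_early_selections(self):
        """The delayed genotype responds later, so its first-occasion set is smaller."""
        em, _ = simulate_experiment(
            SimulationConfig(n_genes=400, de_fraction=0.25, genotype_lag=True, seed=9)
        )
        sel = de.ttest_fc_select(em, p_threshold=0.01, fc_threshold=2.0)
        assert len(sel[("MP", 0)].selected) > len(sel[("SG", 0)].selected)

    def test_fold_change_antisymmetry(self, design36):
        rng = np.random.default_rng(11)
        em = make_matrix(rng.normal(8, 1, (10, 36)), design36)
        ww = em.samples_where(treatment="WW", timepoint=0)
        ws = em.samples_where(treatment="WS", timepoint=0)
        fwd = de.fold_change(em, ww, ws)
        rev = de.fold_change(em, ws, ww)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# ledger, direction split, ranking
# ---------------------------------------------------------------------------

class TestSetAlgebra:
    def test_union_worked_example(self):
        a = {f"a{i}" for i in range(888)} | {f"s{i}" for i in range(300)}
        b = {f"b{i}" for i in range(137)} | {f"s{i}" for i in range(300)}
        ledger = de.ws_union_ledger(a, b)
        s = ledger.summary()
        assert (s["n_genotype_specific"], s["n_treatment_only"]) == (1188, 437)
        assert s["n_shared"] == 300
        assert s["n_union"] == 1325

    def test_disjoint_and_nested_unions(self):
        assert de.ws_union_ledger({"a", "b", "c"}, {"d", "e"}).summary()["n_union"] == 5
        assert de.ws_union_ledger({"a", "b", "c"}, {"a"}).summary()["n_union"] == 3

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_inclusion_exclusion_property(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        s = de.ws_union_ledger(a, b).summary()
        assert s["n_union"] == len(a) + len(b) - len(a & b)

    def test_annotated_union_subset(self):
        ann = AnnotationTable({"a": "kinase", "b": ""})
        ledger = de.ws_union_ledger({"a", "b"}, {"c"}, annotation=ann)
        assert ledger.annotated_union == {"a"}

    def test_direction_split_worked_example(self):
        fc = pd.Series(np.concatenate([np.ones(765), -np.ones(471), np.zeros(10)]),
                       index=[f"g{i}" for i in range(1246)])
        split = de.direction_split(fc, [f"g{i}" for i in range(1236)])
        assert (split.n_up, split.n_down, split.total) == (765, 471, 1236)

    def test_direction_split_sign_flip_swaps_counts(self):
        rng = np.random.default_rng(1)
        fc = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
        sel = list(fc.index[np.abs(fc) > 0.5])
        fwd = de.direction_split(fc, sel)
        rev = de.direction_split(-fc, sel)
        assert (fwd.n_up, fwd.n_down) == (rev.n_down, rev.n_up)

    def test_overlap_percent(self):
        study = {f"g{i}" for i in range(269)}
        ref = {f"g{i}" for i in range(48)} | {f"x{i}" for i in range(100)}
        shared, pct = de.overlap_percent(study, ref)
        assert shared == 48
        assert round(pct) == 18


class TestRankByFc:
    def test_returns_all_when_short(self):
        fc = pd.Series([1.0, 2.0, -1.0, 0.5, 3.0], index=list("abcde"))
        ann = AnnotationTable({g: "x" for g in "abcde"})
        top, bottom = de.rank_by_fc(fc, top_n=20, bottom_n=20, annotation=ann,
                                    annotated_only=True)
        assert len(top) == 5 and len(bottom) == 5

    def test_ties_break_by_gene_id(self):
        fc = pd.Series([1.5, 1.5, 0.0], index=["zz", "aa", "mm"])
        top, _ = de.rank_by_fc(fc, top_n=2, bottom_n=0)
        assert top == ["aa", "zz"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(13)
        fc = pd.Series(rng.normal(0, 2, 50), index=[f"g{i:02d}" for i in range(50)])
        top, bottom = de.rank_by_fc(fc, top_n=10, bottom_n=10)
        order = sorted(fc.index, key=lambda g: (-fc[g], g))
        assert top == order[:10]
        assert bottom == order[::-1][:10]


# ---------------------------------------------------------------------------
# normalization, PCA, clustering order
# ---------------------------------------------------------------------------

class TestMatrixOps:
    def test_row_median_normalize(self):
        design = design_1g(1, 2)
        em = make_matrix([[7.3, 7.3, 7.3, 7.3], [1, 2, 3, 4]], design)
        out = de.row_median_normalize(em)
        np.testing.assert_allclose(out.values.iloc[0], 0.0)
        assert (np.abs(out.values.median(axis=1)) < 1e-12).all()

    def test_pca_rank_one_explains_everything(self):
        design = design_1g(1, 2)
        base = np.array([1.0, 2.0, 3.0, 4.0])
        em = make_matrix(np.outer([1.0, -0.5, 2.0], base), design)
        _, _, evf = de.pca_loading_extremes(em, component=1, percentile=10)
        assert evf == pytest.approx(1.0)
        with pytest.raises(ValueError, match="rank"):
            de.pca_loading_extremes(em, component=2)

    def test_pca_one_gene_per_tail(self, design36):
        rng = np.random.default_rng(17)
        latent = rng.normal(0, 1, 36)
        loadings = np.linspace(-1, 1, 100)
        em = make_matrix(np.outer(loadings, latent) + rng.normal(0, 1e-6, (100, 36)),
                         design36)
        low, high, _ = de.pca_loading_extremes(em, component=1, percentile=1)
        assert len(low) == 1 and len(high) == 1

    def test_pca_sign_invariance(self, design36):
        rng = np.random.default_rng(19)
        X = rng.normal(8, 1, (60, 36))
        em = make_matrix(X, design36)
        em_flipped = make_matrix(-X, design36)
        low1, high1, _ = de.pca_loading_extremes(em, percentile=5)
        low2, high2, _ = de.pca_loading_extremes(em_flipped, percentile=5)
        assert {frozenset(low1), frozenset(high1)} == {frozenset(low2), frozenset(high2)}

    def test_identical_rows_cluster_adjacent(self):
        rng = np.random.default_rng(23)
        X = rng.normal(0, 1, (5, 12))
        X[3] = X[0]
        frame = pd.DataFrame(X, index=list("abcde"), columns=[f"s{i}" for i in range(12)])
        order = de.hierarchical_order(frame, distance="pearson")
        assert abs(order.index("a") - order.index("d")) == 1

    def test_linkage_matches_average_linkage_oracle(self):
        rng = np.random.default_rng(29)
        X = rng.normal(0, 1, (4, 10))
        frame = pd.DataFrame(X, index=list("abcd"), columns=[f"s{i}" for i in range(10)])
        # brute-force average linkage on 1-r distances
        dist = {}
        for i in range(4):
            for j in range(i + 1, 4):
                r = np.corrcoef(X[i], X[j])[0, 1]
                dist[frozenset([i, j])] = 1 - r
        clusters = {i: [i] for i in range(4)}
        heights = []
        while len(clusters) > 1:
            best = min(
                ((a, b) for a in clusters for b in clusters if a < b),
                key=lambda ab: np.mean([dist[frozenset([x, y])]
                                        for x in clusters[ab[0]] for y in clusters[ab[1]]]),
            )
            h = np.mean([dist[frozenset([x, y])]
                         for x in clusters[best[0]] for y in clusters[best[1]]])
            heights.append(h)
            clusters[best[0]] = clusters[best[0]] + clusters.pop(best[1])
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        Z = hierarchy.linkage(pdist(X, metric="correlation"), method="average")
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)
        order = de.hierarchical_order(frame, distance="pearson")
        assert sorted(order) == list("abcd")

    def test_anticorrelated_rows_have_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        frame = pd.DataFrame([x, -x], index=["a", "b"], columns=[f"s{i}" for i in range(4)])
        from scipy.spatial.distance import pdist

        assert pdist(frame.to_numpy(), metric="correlation")[0] == pytest.approx(2.0)
        assert sorted(de.hierarchical_order(frame)) == ["a", "b"]

    def test_zero_variance_row_handled(self, caplog):
        import logging

        frame = pd.DataFrame([[1, 2, 3], [5, 5, 5], [3, 2, 1]],
                             index=list("abc"), columns=list("xyz"), dtype=float)
        with caplog.at_level(logging.INFO, logger="vinestress"):
            order = de.hierarchical_order(frame, distance="pearson")
        assert sorted(order) == list("abc")
        assert "zero-variance" in caplog.text
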