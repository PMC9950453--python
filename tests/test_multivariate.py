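"""Sequential-SS PERMANOVA, dispersion, FDR, balanced subsampling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bearvoc.datatypes import Stage
from bearvoc.dissimilarity import DissimilarityMatrix, Metric
from bearvoc.multivariate import (
    DESIGN_PRESETS,
    ModelDesign,
    Term,
    adjust_fdr,
    balance_by_subsampling,
    dispersion,
    gower_center,
    permanova,
)
from bearvoc.preprocess import run_preprocess
from bearvoc.dissimilarity import bray_curtis

from conftest import make_metadata, make_table


def euclidean_dm(points, scale=None):
    """Euclidean distances scaled into [0,1] as a DissimilarityMatrix."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    scale = scale or (D.max() * 1.01 + 1e-9)
    ids = [f"s{i + 1}" for i in range(len(points))]
    return DissimilarityMatrix(ids, D / scale, Metric.BRAY_CURTIS), scale


def sex_design():
    return ModelDesign("sex", (Term("sex", ("sex",)),))


def brute_force_permanova_p(dm, labels):
    """Exhaustive-permutation oracle: exact p over all distinct labelings."""
    labels = np.asarray(labels)
    n = len(labels)
    G = gower_center(dm)
    total = np.trace(G)

    def F_of(lab):
        groups = {g: np.flatnonzero(lab == g) for g in np.unique(lab)}
        H = np.zeros((n, n))
        for idx in groups.values():
            H[np.ix_(idx, idx)] = 1.0 / len(idx)
        C = np.eye(n) - np.full((n, n), 1.0 / n)
        Hc = C @ H @ C
        ss_b = np.sum(Hc * G)
        ss_w = total - ss_b
        df_b = len(groups) - 1
        df_w = n - len(groups)
        return (ss_b / df_b) / (ss_w / df_w)

    F_obs = F_of(labels)
    count = 0
    total_perms = 0
    for perm in set(itertools.permutations(labels)):
        total_perms += 1
        if F_of(np.array(perm)) >= F_obs - 1e-12:
            count += 1
    return F_obs, count / total_perms


class TestGowerCenter:
    def test_zero_distances_give_zero_matrix(self):
        dm, _ = euclidean_dm([0.0, 0.0, 0.0])
        assert np.allclose(gower_center(dm), 0.0)

    def test_equilateral_triangle_trace(self):
        # three points pairwise distance 1: total SS = 3 * 1^2 / 3 = 1
        D = np.ones((3, 3)) - np.eye(3)
        dm = DissimilarityMatrix(["a", "b", "c"], D, Metric.BRAY_CURTIS)
        assert np.trace(gower_center(dm)) == pytest.approx(1.0, abs=1e-12)

    def test_trace_identity_random(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 3))
        dm, _ = euclidean_dm(pts)
        G = gower_center(dm)
        n = dm.n
        direct = (dm.values[np.triu_indices(n, 1)] ** 2).sum() / n
        assert np.trace(G) == pytest.approx(direct, abs=1e-10)


class TestPermanovaContracts:
    def test_single_level_term_rejected(self):
        dm, _ = euclidean_dm([0.0, 0.3, 0.6, 0.9])
        meta = make_metadata(4, sexes=["F"] * 4)
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, sex_design(), meta, n_permutations=19)

    def test_saturated_design_rejected(self):
        dm, _ = euclidean_dm([0.0, 0.5, 0.2, 0.9])
        meta = make_metadata(4, individuals=[f"i{k}" for k in range(4)])
        design = ModelDesign("id", (Term("id", ("individual_id",)),))
        with pytest.raises(ValueError, match="[Ss]aturated"):
            permanova(dm, design, meta, n_permutations=19)


class TestPermanovaCorrectness:
    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p agrees with the exact permutation p (6 samples)."""
        rng = np.random.default_rng(17)
        pts = np.concatenate([rng.normal(0, 1, 3), rng.normal(1.5, 1, 3)])
        dm, _ = euclidean_dm(pts)
        labels = np.array(["F", "F", "F", "M", "M", "M"])
        F_oracle, p_exact = brute_force_permanova_p(dm, labels)
        meta = make_metadata(6, sexes=list(labels))
        out = permanova(dm, sex_design(), meta, n_permutations=10_000, seed=5)
        assert out.table.loc["sex", "pseudo_F"] == pytest.approx(F_oracle, abs=1e-8)
        assert out.table.loc["sex", "p_perm"] == pytest.approx(
            p_exact, abs=2 / np.sqrt(10_000))

    @pytest.mark.parametrize("n_per_group", [3, 4])
    def test_oracle_on_small_instances(self, n_per_group):
        """Brute-force oracle equivalence on <= 8-sample instances."""
        rng = np.random.default_rng(n_per_group)
        n = 2 * n_per_group
        pts = rng.normal(0, 1, n)
        pts[n_per_group:] += 1.0
        dm, _ = euclidean_dm(pts)
        labels = ["A"] * n_per_group + ["B"] * n_per_group
        F_oracle, p_exact = brute_force_permanova_p(dm, np.array(labels))
        meta = make_metadata(n, sexes=["F"] * n_per_group + ["M"] * n_per_group)
        out = permanova(dm, sex_design(), meta, n_permutations=10_000, seed=2)
        assert out.table.loc["sex", "pseudo_F"] == pytest.approx(F_oracle, abs=1e-8)
        assert out.table.loc["sex", "p_perm"] == pytest.approx(
            p_exact, abs=2 / np.sqrt(10_000))

    def test_euclidean_univariate_limit_equals_anova_f(self):
        """On 1-D Euclidean data the pseudo-F is the classical ANOVA F."""
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(0, 1, 6), rng.normal(2, 1, 6)])
        dm, _ = euclidean_dm(y)
        meta = make_metadata(12, sexes=["F"] * 6 + ["M"] * 6)
        out = permanova(dm, sex_design(), meta, n_permutations=19, seed=0)
        F_classic, _ = stats.f_oneway(y[:6], y[6:])
        assert out.table.loc["sex", "pseudo_F"] == pytest.approx(F_classic, abs=1e-8)

    def test_ss_additivity_all_presets(self, study_dataset):
        prep = run_preprocess(study_dataset)
        dm = bray_curtis(prep.transformed)
        for name in ("age", "sex", "age_sex", "individual", "body_site", "full"):
            t = permanova(dm, DESIGN_PRESETS[name], study_dataset.metadata,
                          n_permutations=19, seed=0).table
            terms_ss = t.drop(index=["Residual", "Total"])["SS"].sum()
            assert terms_ss + t.loc["Residual", "SS"] == pytest.approx(
                t.loc["Total", "SS"], abs=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 1, 10)
        dm, _ = euclidean_dm(pts)
        sexes = ["F", "M"] * 5
        meta = make_metadata(10, sexes=sexes)
        base = permanova(dm, sex_design(), meta, n_permutations=999, seed=1)
        order = list(rng.permutation(10))
        dm2 = dm.reorder([f"s{i + 1}" for i in order])
        out = permanova(dm2, sex_design(), meta, n_permutations=999, seed=1)
        for col in ("df", "SS", "pseudo_F"):
            a = base.table[col].dropna()
            assert np.allclose(a, out.table[col].dropna(), atol=1e-10)
        # p differs only by permutation-sampling noise
        assert abs(base.table.loc["sex", "p_perm"]
                   - out.table.loc["sex", "p_perm"]) < 3 / np.sqrt(999)

    def test_full_design_df_structure(self, study_dataset):
        """Balanced 8-bear subset: df = 1,1,1,4,24 with 20 residual df."""
        balanced = balance_by_subsampling(study_dataset, "young_M", 2, seed=3)
        prep = run_preprocess(balanced)
        dm = bray_curtis(prep.transformed)
        t = permanova(dm, "full", balanced.metadata, n_permutations=19).table
        assert list(t["df"]) == [1, 1, 1, 4, 24, 20, 51]


class TestFDR:
    def test_hand_computed_bh(self):
        assert adjust_fdr([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2]) == [pytest.approx(0.2)]

    def test_all_equal_unchanged(self):
        assert adjust_fdr([0.03, 0.03, 0.03]) == pytest.approx([0.03] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([])


class TestDispersion:
    def test_duplicated_points_zero_distances(self):
        pts = np.array([0.0, 0.0, 1.0, 1.0])
        dm, _ = euclidean_dm(pts)
        res = dispersion(dm, {"s1": "a", "s2": "a", "s3": "b", "s4": "b"})
        assert np.allclose(res.distances.to_numpy(), 0.0, atol=1e-10)

    def test_euclidean_centroid_oracle(self):
        """Centroid distances match direct Euclidean distances to means."""
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, (12, 2))
        dm, scale = euclidean_dm(pts)
        groups = {f"s{i + 1}": ("a" if i < 6 else "b") for i in range(12)}
        res = dispersion(dm, groups)
        for g, idx in (("a", slice(0, 6)), ("b", slice(6, 12))):
            centroid = pts[idx].mean(axis=0)
            direct = np.linalg.norm(pts[idx] - centroid, axis=1) / scale
            got = res.distances[[f"s{i + 1}" for i in range(12)][idx]]
            assert np.allclose(got.to_numpy(), direct, atol=1e-8)

    def test_inflated_group_has_larger_mean_distance(self):
        rng = np.random.default_rng(9)
        tight = rng.normal(0, 0.05, (8, 2))
        loose = rng.normal(0, 0.5, (8, 2))
        dm, _ = euclidean_dm(np.vstack([tight, loose]))
        groups = {f"s{i + 1}": ("tight" if i < 8 else "loose") for i in range(16)}
        res = dispersion(dm, groups)
        assert res.group_means["loose"] > 3 * res.group_means["tight"]

    def test_singleton_group_excluded_with_warning(self):
        pts = np.array([0.0, 0.1, 0.5, 0.6, 0.9])
        dm, _ = euclidean_dm(pts)
        groups = {"s1": "a", "s2": "a", "s3": "b", "s4": "b", "s5": "c"}
        with pytest.warns(UserWarning, match="singleton"):
            res = dispersion(dm, groups)
        assert res.excluded_groups == ["c"]


class TestBalancedSubsampling:
    def test_study_design_reduction(self, study_dataset):
        """Keeping young males Y864 and Y743 leaves 8 bears, 52 samples."""
        balanced = balance_by_subsampling(
            study_dataset, "young_M", 2, keep_individuals=["Y864", "Y743"])
        meta = balanced.meta_frame()
        assert meta["individual_id"].nunique() == 8
        assert balanced.n_samples == 52

    def test_no_reduction_when_n_equals_count(self, study_dataset):
        same = balance_by_subsampling(study_dataset, "mature_F", 2, seed=0)
        assert same.n_samples == study_dataset.n_samples

    def test_seed_changes_subset_not_individual_count(self, study_dataset):
        a = balance_by_subsampling(study_dataset, "young_M", 2, seed=1)
        b = balance_by_subsampling(study_dataset, "young_M", 2, seed=2)
        assert a.meta_frame()["individual_id"].nunique() == 8
        assert b.meta_frame()["individual_id"].nunique() == 8

    def test_missing_class_rejected(self, study_dataset):
        with pytest.raises(ValueError):
            balance_by_subsampling(study_dataset, "nonexistent", 2, seed=0)
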