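"""Single-cell pipeline: filtering, imputation, normalization, embedding, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpbench.postanalysis import (
    PipelineOrderError,
    cluster_order,
    differential_expression,
    embed,
    filter_missing,
    group_cv_summary,
    impute_min,
    log2_normalize,
)
from scpbench.simulate import simulate_cells

from conftest import make_matrix


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Step-up BH from first principles: q_i = min_{j >= rank(i)} m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def processed(values, conditions, **kw):
    m = make_matrix(values, conditions, **kw)
    return log2_normalize(impute_min(m), mode="zscore_per_protein")


class TestFilterMissing:
    def make(self, n_missing: int, n_cells: int = 30):
        vals = np.ones((2, n_cells)) * 5
        vals[1, :n_missing] = np.nan
        return make_matrix(vals, ["a"] * n_cells)

    def test_fully_observed_kept(self):
        out = filter_missing(self.make(0), 20)
        assert out.shape[0] == 2

    def test_strictly_more_than_threshold_removed(self):
        assert filter_missing(self.make(21), 20).shape[0] == 1

    def test_exactly_threshold_kept(self):
        assert filter_missing(self.make(20), 20).shape[0] == 2

    def test_blanks_do_not_count(self):
        vals = np.ones((1, 4)) * 5
        vals[0, 2:] = np.nan  # missing only in the blanks
        m = make_matrix(vals, ["a"] * 4, is_blank=[False, False, True, True])
        assert filter_missing(m, 0).shape[0] == 1


class TestImputeMin:
    def test_no_missing_is_identity(self):
        m = make_matrix([[1.0, 2], [3, 4]], ["a", "a"])
        out = impute_min(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_missing_cells_get_global_min(self):
        m = make_matrix([[7.0, 9], [np.nan, 12]], ["a", "a"])
        out = impute_min(m)
        assert out.values.iloc[1, 0] == 7.0

    def test_min_unchanged_and_mask_preserved(self):
        m = make_matrix([[0.5, np.nan], [np.nan, 2.0]], ["a", "a"])
        out = impute_min(m)
        assert float(out.values.min().min()) == 0.5
        assert out.observed.to_numpy().sum() == 2  # audit mask untouched

    def test_all_missing_rejected(self):
        m = make_matrix([[np.nan, np.nan]], ["a", "a"])
        with pytest.raises(ValueError):
            impute_min(m)


class TestLog2Normalize:
    def test_hand_computed_zscore(self):
        m = impute_min(make_matrix([[2.0, 8.0]], ["a", "a"]))
        out = log2_normalize(m)
        # log2 -> (1, 3); sample SD sqrt(2) -> (-0.707, 0.707)
        assert out.values.iloc[0].tolist() == pytest.approx(
            [-0.7071067, 0.7071067], abs=1e-6
        )

    def test_constant_row_becomes_zero_with_warning(self):
        m = impute_min(make_matrix([[4.0, 4.0], [2.0, 8.0]], ["a", "a"]))
        with pytest.warns(RuntimeWarning, match="constant"):
            out = log2_normalize(m)
        assert np.allclose(out.values.iloc[0], 0.0)

    def test_mode_none_is_pure_log2(self):
        m = impute_min(make_matrix([[2.0, 8.0]], ["a", "a"]))
        out = log2_normalize(m, mode="none")
        assert out.values.iloc[0].tolist() == pytest.approx([1.0, 3.0])

    def test_unimputed_matrix_rejected(self):
        m = make_matrix([[np.nan, 4.0]], ["a", "a"])
        with pytest.raises(PipelineOrderError, match="impute_min"):
            log2_normalize(m)


class TestEmbed:
    def test_identical_samples_identical_coordinates(self):
        vals = np.tile(
            np.random.default_rng(0).lognormal(3, 1, size=(30, 1)), (1, 4)
        ) * [1.0, 1.0, 3.0, 3.0]
        p = processed(vals, ["a"] * 4)
        emb = embed(p, "linear_pca")
        assert np.allclose(emb.coordinates.iloc[0], emb.coordinates.iloc[1])

    def test_rank_one_data_pc1_explains_everything(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=20)
        coords = rng.normal(size=5)
        vals = np.exp2(10 + np.outer(direction, coords))
        p = processed(vals, ["a"] * 5)
        emb = embed(p, "linear_pca", n_components=2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_cluster_data_separates(self):
        """Simulation oracle: with the type effect dominating (4-fold on 50
        proteins) the true labels are well separated in PCA space."""
        from sklearn.metrics import silhouette_score

        mat, ann, _ = simulate_cells(
            {"A": 12, "B": 12}, n_proteins=600, n_de_proteins=50,
            effect_size_log2=2.0, size_model={"A": (20.0, 0.0), "B": (20.0, 0.0)},
            blank_count=0, seed=7,
        )
        p = log2_normalize(impute_min(filter_missing(mat, 5)))
        emb = embed(p, "linear_pca", seed=0)
        score = silhouette_score(emb.coordinates, ann["cell_type"])
        assert score > 0.5

    def test_umap_like_runs_and_is_seeded(self):
        mat, _, _ = simulate_cells(
            {"A": 8, "B": 8}, n_proteins=150, n_de_proteins=20,
            effect_size_log2=2.0, blank_count=0, seed=3,
        )
        p = log2_normalize(impute_min(filter_missing(mat, 3)))
        a = embed(p, "umap_like", seed=42)
        b = embed(p, "umap_like", seed=42)
        assert np.allclose(a.coordinates, b.coordinates)

    def test_requires_processed_matrix(self):
        m = make_matrix([[1.0, 2, 3]], ["a"] * 3)
        with pytest.raises(PipelineOrderError):
            embed(m)

    def test_n_components_bound(self):
        p = processed(np.random.default_rng(0).lognormal(3, 1, (10, 4)), ["a"] * 4)
        with pytest.raises(ValueError):
            embed(p, n_components=5)


class TestDifferentialExpression:
    def test_identical_groups_null_result(self):
        vals = np.tile([[1.0, 2.0, 3.0]], (1, 2)).reshape(1, 6)
        p = processed(np.vstack([vals, vals * 2]), ["a"] * 3 + ["b"] * 3)
        de = differential_expression(p, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(de["t_stat"], 0.0)
        assert np.allclose(de["p"], 1.0)
        assert not de["upregulated"].any()

    def test_bh_hand_example(self):
        # p = (0.01, 0.02, 0.03), m = 3 -> q = (0.03, 0.03, 0.03)
        q = bh_brute_force(np.array([0.01, 0.02, 0.03]))
        assert q.tolist() == pytest.approx([0.03, 0.03, 0.03])
        from statsmodels.stats.multitest import multipletests

        assert multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1].tolist() == \
            pytest.approx([0.03, 0.03, 0.03])

    @given(st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_bh_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_brute_force(p))

    def test_degenerate_zero_variance_flagged(self):
        vals = np.array([[4.0, 4, 4, 4, 4, 4], [1, 2, 3, 9, 10, 11]])
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        with pytest.warns(RuntimeWarning):
            p = log2_normalize(impute_min(m))
        de = differential_expression(p, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert de["degenerate"].iloc[0]
        assert de["p"].iloc[0] == 1.0

    def test_upregulation_rule_and_orientation(self):
        rng = np.random.default_rng(2)
        null = rng.lognormal(5, 0.1, size=(40, 12))
        up = null[:5] * np.array([1] * 6 + [8] * 6)  # 8-fold higher in group B
        vals = np.vstack([up, null[5:]])
        p = processed(vals, ["a"] * 6 + ["b"] * 6)
        ids_a = [f"s{i}" for i in range(6)]
        ids_b = [f"s{i}" for i in range(6, 12)]
        de = differential_expression(p, ids_a, ids_b)
        assert de["upregulated"].iloc[:5].all()
        assert (de["fc_linear"].iloc[:5] > 1).all()
        # reversed orientation: the same proteins are now downregulated
        rev = differential_expression(p, ids_b, ids_a)
        assert not rev["upregulated"].iloc[:5].any()

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(4, 0.5, size=(50, 12))
        vals[:8, 6:] *= 6.0
        conds = ["a"] * 6 + ["b"] * 6
        ids_a = [f"s{i}" for i in range(6)]
        ids_b = [f"s{i}" for i in range(6, 12)]
        de1 = differential_expression(processed(vals, conds), ids_a, ids_b)
        de2 = differential_expression(processed(vals * 11.0, conds), ids_a, ids_b)
        assert (de1["upregulated"] == de2["upregulated"]).all()

    def test_blanks_rejected_in_groups(self):
        mat, ann, _ = simulate_cells({"A": 4, "B": 4}, n_proteins=60, blank_count=2, seed=1)
        p = log2_normalize(impute_min(filter_missing(mat, 8)))
        blanks = list(ann.index[ann["is_blank"]])
        with pytest.raises(ValueError, match="blank"):
            differential_expression(p, list(ann.index[ann.cell_type == "A"]), blanks)

    def test_pipeline_order_enforced(self):
        m = make_matrix([[1.0, 2, 3, 4]], ["a", "a", "b", "b"])
        with pytest.raises(PipelineOrderError):
            differential_expression(m, ["s0", "s1"], ["s2", "s3"])


class TestGroupCv:
    def test_duplicate_columns_zero_cv(self):
        m = make_matrix([[3.0, 3, 3]], ["a"] * 3, cell_type=["x"] * 3)
        assert group_cv_summary(m, {"x": ["s0", "s1", "s2"]})["x"] == pytest.approx(0.0)

    def test_hand_computed(self):
        m = make_matrix([[1.0, 2, 3]], ["a"] * 3)
        out = group_cv_summary(m, {"g": ["s0", "s1", "s2"]})
        assert out["g"] == pytest.approx(50.0)

    def test_single_cells_noisier_than_pseudobulk(self):
        """Averaging cells shrinks biological variability, mirroring the gap
        between single-cell and multi-cell stock runs."""
        mat, ann, _ = simulate_cells(
            {"A": 30, "B": 30}, n_proteins=300, n_de_proteins=0, blank_count=0, seed=5
        )
        cells = list(ann.index[ann.cell_type == "A"])
        single = group_cv_summary(mat, {"single": cells})["single"]
        pooled_vals = pd.concat(
            [mat.values[cells[i::3]].mean(axis=1) for i in range(3)], axis=1
        )
        pooled = 100.0 * pooled_vals.std(axis=1, ddof=1) / pooled_vals.mean(axis=1)
        assert single > pooled.median()

    def test_grouping_by_metadata_column(self):
        mat, ann, _ = simulate_cells({"A": 4, "B": 4}, n_proteins=50, blank_count=0, seed=2)
        out = group_cv_summary(mat, "cell_type")
        assert set(out.index) == {"A", "B"}

    def test_singleton_group_rejected(self):
        m = make_matrix([[1.0, 2]], ["a", "a"])
        with pytest.raises(ValueError, match="< 2"):
            group_cv_summary(m, {"g": ["s0"]})


def test_cluster_order_groups_similar_samples():
    rng = np.random.default_rng(4)
    base = rng.lognormal(5, 0.4, size=(40, 1))
    cluster1 = base * rng.lognormal(0, 0.05, size=(40, 3))
    cluster2 = base * 4 * rng.lognormal(0, 0.05, size=(40, 3))
    vals = np.hstack([cluster1[:, :1], cluster2[:, :2], cluster1[:, 1:], cluster2[:, 2:]])
    conds = ["a"] * 6
    p = processed(vals, conds)
    order = cluster_order(p, axis="samples")
    # samples from the same cluster end up adjacent
    labels = {0: "c1", 1: "c2", 2: "c2", 3: "c1", 4: "c1", 5: "c2"}
    seq = [labels[int(s[1:])] for s in order]
    assert seq in (["c1"] * 3 + ["c2"] * 3, ["c2"] * 3 + ["c1"] * 3)
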