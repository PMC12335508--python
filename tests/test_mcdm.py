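"""Entropy weighting, TOPSIS and SAW: published values and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from topodrug import reference
from topodrug.mcdm import (
    DecisionMatrix,
    WeightVector,
    entropy_weights,
    saw,
    topsis,
    vector_normalize,
)
from topodrug.synthetic_data import GeneratorConfig, random_decision_matrix


def dm(values: pd.DataFrame, **kw) -> DecisionMatrix:
    return DecisionMatrix(values=values, **kw)


class TestNormalize:
    def test_three_four_five_triangle(self):
        out = vector_normalize(pd.DataFrame({"c": [3.0, 4.0]}))
        assert list(out["c"]) == pytest.approx([0.6, 0.8])

    def test_single_row_normalizes_to_one(self):
        out = vector_normalize(pd.DataFrame({"a": [5.0], "b": [0.2]}))
        assert out.to_numpy().flatten() == pytest.approx([1.0, 1.0])

    def test_published_index_column_reproduces_published_matrix_cell(self, published_indices):
        out = vector_normalize(published_indices.astype(float))
        assert out.loc["metoprolol", "M1"] == pytest.approx(0.230644, abs=1e-6)

    def test_nonpositive_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dm(pd.DataFrame({"c": [1.0, -1.0]}))


class TestEntropyWeights:
    def test_published_decision_matrix_gives_published_weights(self):
        w = entropy_weights(reference.published_decision_matrix())
        expected = reference.published_weights()
        assert w.w.to_numpy() == pytest.approx(expected.to_numpy(), abs=1e-6)

    def test_constant_unit_norm_column_closed_form(self):
        # ten equal entries 1/sqrt(10): E = sqrt(10)/2, divergence |1-E| ~ 0.5811
        m = 10
        col = pd.DataFrame({"a": [1 / math.sqrt(m)] * m, "b": np.linspace(0.1, 0.5, m)})
        arr = col.to_numpy()
        plogp = arr[:, 0] * np.log(arr[:, 0])
        e_a = -plogp.sum() / math.log(m)
        assert e_a == pytest.approx(math.sqrt(m) / 2, abs=1e-12)
        w = entropy_weights(col / np.sqrt((col**2).sum(axis=0)))
        assert w.w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_columns_share_weight(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        norm = vector_normalize(pd.DataFrame({"a": base, "b": base, "c": base**2}))
        w = entropy_weights(norm)
        assert w.w["a"] == pytest.approx(w.w["b"], rel=1e-12)

    def test_degenerate_matrix_is_an_error(self):
        # constant unit-norm columns over m=4 rows have E exactly 1 -> zero divergence
        col = [0.5, 0.5, 0.5, 0.5]
        with pytest.raises(ValueError, match="zero divergence"):
            entropy_weights(pd.DataFrame({"a": col, "b": col}))

    def test_sum_method_differs_from_vector_method(self):
        norm = reference.published_decision_matrix()
        wv = entropy_weights(norm, method="entropy-vector").w
        ws = entropy_weights(norm, method="entropy-sum").w
        assert not np.allclose(wv.to_numpy(), ws.to_numpy(), atol=1e-4)
        assert ws.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.uniform(1, 9, (6, 4)), columns=list("abcd"))
        norm = vector_normalize(mat)
        w = entropy_weights(norm).w
        perm_cols = ["c", "a", "d", "b"]
        w2 = entropy_weights(norm[perm_cols]).w
        assert w2[perm_cols].to_numpy() == pytest.approx(w[perm_cols].to_numpy())
        shuffled_rows = norm.sample(frac=1, random_state=seed)
        w3 = entropy_weights(shuffled_rows).w
        assert w3.to_numpy() == pytest.approx(w.to_numpy())


class TestTopsis:
    def weights_for(self, cols, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.5, 1.5, len(cols))
        return WeightVector(w=pd.Series(w / w.sum(), index=cols), method="user")

    def test_two_alternatives_single_criterion_hit_the_endpoints(self):
        d = dm(pd.DataFrame({"c": [10.0, 2.0]}, index=["good", "bad"]))
        w = WeightVector(w=pd.Series({"c": 1.0}), method="user")
        res = topsis(d, w)
        assert res.closeness["good"] == pytest.approx(1.0)
        assert res.closeness["bad"] == pytest.approx(0.0)
        assert list(res.rank) == [1, 2]

    def test_closeness_matches_brute_force_from_definitions(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.uniform(1, 100, (3, 2)), columns=["x", "y"], index=list("abc"))
        d = dm(vals)
        w = self.weights_for(["x", "y"])
        res = topsis(d, w)
        # independent recomputation, straight from the step formulas
        arr = vals.to_numpy()
        n = arr / np.sqrt((arr**2).sum(axis=0))
        y = n * w.w.to_numpy()
        qp, qm = y.max(axis=0), y.min(axis=0)
        lp = np.sqrt(((y - qp) ** 2).sum(axis=1))
        lm = np.sqrt(((y - qm) ** 2).sum(axis=1))
        assert res.closeness.to_numpy() == pytest.approx(lm / (lp + lm), rel=1e-12)

    def test_cost_criterion_flips_the_ideal(self):
        vals = pd.DataFrame({"c": [10.0, 2.0]}, index=["big", "small"])
        res = topsis(dm(vals, direction={"c": "cost"}), WeightVector(w=pd.Series({"c": 1.0}), method="user"))
        assert res.rank["small"] == 1

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1e3])
    def test_column_rescaling_leaves_closeness_unchanged(self, scale):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.uniform(1, 50, (5, 3)), columns=list("xyz"))
        w = self.weights_for(["x", "y", "z"])
        base = topsis(dm(vals), w).closeness
        scaled_vals = vals.assign(y=vals["y"] * scale)
        scaled = topsis(dm(scaled_vals), w).closeness
        assert scaled.to_numpy() == pytest.approx(base.to_numpy(), rel=1e-9)

    def test_weight_dimension_mismatch_rejected(self):
        d = dm(pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]}))
        w = WeightVector(w=pd.Series({"a": 1.0}), method="user")
        with pytest.raises(ValueError, match="match"):
            topsis(d, w)

    @pytest.mark.parametrize("seed", range(8))
    def test_adding_dominated_alternative_never_changes_the_winner(self, seed):
        mat = random_decision_matrix(GeneratorConfig(seed=seed, n_drugs=6, n_criteria=4))
        w = self.weights_for(list(mat.columns), seed=seed)
        top_before = topsis(dm(mat), w).rank.idxmin()
        dominated = mat.min(axis=0) * 0.5
        mat2 = pd.concat([mat, dominated.to_frame("loser").T])
        res2 = topsis(dm(mat2), w)
        assert res2.rank.idxmin() == top_before
        saw_before = saw(dm(mat), w).rank.idxmin()
        assert saw(dm(mat2), w).rank.idxmin() == saw_before


class TestSaw:
    def test_metoprolol_zagreb_cell_is_ratio_to_column_max(self, published_indices):
        d = dm(published_indices.astype(float))
        w = entropy_weights(vector_normalize(d))
        res = saw(d, w)
        assert res.normalized.loc["metoprolol", "M1"] == pytest.approx(84 / 156, abs=1e-9)
        assert res.normalized.loc["metoprolol", "M1"] == pytest.approx(0.538462, abs=1e-6)

    def test_all_equal_matrix_scores_one(self):
        vals = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [7.0, 7.0, 7.0]})
        w = WeightVector(w=pd.Series({"a": 0.5, "b": 0.5}), method="user")
        res = saw(dm(vals), w)
        assert res.score.to_numpy() == pytest.approx(1.0)

    def test_score_one_iff_all_benefit_maxima_attained(self):
        vals = pd.DataFrame({"a": [5.0, 5.0], "b": [3.0, 2.0]}, index=["top", "runner"])
        w = WeightVector(w=pd.Series({"a": 0.5, "b": 0.5}), method="user")
        res = saw(dm(vals), w)
        assert res.score["top"] == pytest.approx(1.0)
        assert res.score["runner"] < 1.0

    @pytest.mark.parametrize("scale", [0.01, 1000.0])
    def test_column_rescaling_leaves_scores_unchanged(self, scale):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.uniform(1, 20, (4, 3)), columns=list("pqr"))
        w = WeightVector(w=pd.Series([0.2, 0.3, 0.5], index=list("pqr")), method="user")
        base = saw(dm(vals), w).score
        scaled = saw(dm(vals.assign(q=vals["q"] * scale)), w).score
        assert scaled.to_numpy() == pytest.approx(base.to_numpy(), rel=1e-12)

    def test_ranks_are_a_permutation_and_ties_keep_input_order(self):
        vals = pd.DataFrame({"a": [2.0, 2.0, 1.0]}, index=["first", "second", "third"])
        w = WeightVector(w=pd.Series({"a": 1.0}), method="user")
        res = saw(dm(vals), w)
        assert sorted(res.rank) == [1, 2, 3]
        assert res.rank["first"] < res.rank["second"]


class TestWeightVector:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WeightVector(w=pd.Series({"a": 0.5, "b": 0.6}), method="user")

    def test_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            WeightVector(w=pd.Series({"a": 1.5, "b": -0.5}), method="user")
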