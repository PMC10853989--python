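"""MLP grid search, recoding, upsampling, and the two-stage cascade."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radlatent.models import (HyperGrid, MLPParams, STAGE1_PRESET,
                              STAGE2_PRESET, THREE_CLASS_PRESET,
                              TwoStageModel, fit_mlp, fit_two_stage,
                              grid_search_mlp, predict_two_stage,
                              recode_primary, upsample_minority)


def _blobs(n_per_class=100, gap=6.0, seed=0, classes=("A", "B")):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per_class, 2)) + i * gap
                   for i in range(len(classes))])
    y = np.repeat(classes, n_per_class)
    return X, y


class TestGrid:
    def test_default_grid_axes_product(self):
        grid = HyperGrid()
        assert grid.size == len(list(grid.cells()))

    @settings(max_examples=15, deadline=None)
    @given(nb=st.integers(1, 3), nn=st.integers(1, 2), nl=st.integers(1, 3))
    def test_exhaustive_enumeration_of_any_grid(self, nb, nn, nl):
        grid = HyperGrid(batch_sizes=tuple(8 * (i + 1) for i in range(nb)),
                         node_options=tuple(50 * (i + 1) for i in range(nn)),
                         layer_options=tuple(range(1, nl + 1)))
        cells = list(grid.cells())
        assert len(cells) == grid.size == nb * nn * nl * 2 * 2

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty grid axis"):
            HyperGrid(batch_sizes=())

    def test_single_cell_grid_returns_that_cell(self):
        X, y = _blobs(30)
        grid = HyperGrid(batch_sizes=(16,), node_options=(20,),
                         layer_options=(1,), learning_rates=(1e-3,),
                         solvers=("adam",))
        best = grid_search_mlp(X, y, grid, inner_cv_folds=2, seed=0,
                               max_iter=80)
        assert (best.batch_size, best.hidden_nodes, best.hidden_layers,
                best.learning_rate, best.solver) == (16, 20, 1, 1e-3, "adam")

    def test_untrainable_cell_loses_on_separable_data(self):
        X, y = _blobs(40, gap=8.0)
        grid = HyperGrid(batch_sizes=(16,), node_options=(20,),
                         layer_options=(1,), learning_rates=(1e-3, 1e-12),
                         solvers=("sgd",))
        best = grid_search_mlp(X, y, grid, inner_cv_folds=2, seed=0,
                               max_iter=60)
        assert best.learning_rate == 1e-3

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match=">= 2 classes"):
            grid_search_mlp(X, np.repeat("A", 10), HyperGrid())

    def test_documented_presets_match_selected_cells(self):
        # the shipped presets are the documented grid-search winners
        assert (THREE_CLASS_PRESET.batch_size,
                THREE_CLASS_PRESET.hidden_layer_sizes,
                THREE_CLASS_PRESET.learning_rate,
                THREE_CLASS_PRESET.solver) == (16, (150,) * 4, 1e-3, "adam")
        assert STAGE1_PRESET.batch_size == 8
        assert STAGE1_PRESET.hidden_layer_sizes == (150,)
        assert STAGE2_PRESET.batch_size == 16
        assert STAGE2_PRESET.hidden_layer_sizes == (150,)


class TestFitMLP:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = _blobs(100, gap=6.0)
        clf = fit_mlp(X, y, MLPParams(batch_size=32, hidden_nodes=20,
                                      hidden_layers=1, seed=0), max_iter=300)
        assert (clf.predict(X) == y).mean() > 0.95

    def test_probability_rows_sum_to_one(self):
        X, y = _blobs(50, classes=("A", "B", "C"))
        clf = fit_mlp(X, y, MLPParams(hidden_nodes=20, hidden_layers=1,
                                      seed=0), max_iter=100)
        np.testing.assert_allclose(clf.predict_proba(X).sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_seed_determinism(self):
        X, y = _blobs(50)
        params = MLPParams(hidden_nodes=20, hidden_layers=1, seed=3)
        p1 = fit_mlp(X, y, params, max_iter=100).predict_proba(X)
        p2 = fit_mlp(X, y, params, max_iter=100).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_non_finite_inputs_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_mlp(X, np.array(["A", "B"]), MLPParams())


class TestRecode:
    def test_recode_rule(self):
        out = recode_primary(np.array(["GBM", "LYM", "MET", "GBM"]), "GBM")
        assert out.tolist() == ["yes", "no", "no", "yes"]

    def test_all_primary_and_empty(self):
        assert recode_primary(np.array(["GBM", "GBM"]), "GBM").tolist() == \
            ["yes", "yes"]
        assert recode_primary(np.array([], dtype=str), "GBM").size == 0

    def test_unknown_primary_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            recode_primary(np.array(["LYM", "MET"]), "GBM")


class TestUpsample:
    def test_equalizes_minority(self):
        X = np.arange(128 * 2, dtype=float).reshape(128, 2)
        y = np.repeat(["MET", "LYM"], [96, 32])
        X2, y2 = upsample_minority(X, y, seed=0)
        counts = dict(zip(*np.unique(y2, return_counts=True)))
        assert counts == {"LYM": 96, "MET": 96}
        # majority rows untouched, originals first
        np.testing.assert_array_equal(X2[:128], X)

    def test_balanced_unchanged(self):
        X = np.zeros((10, 1))
        y = np.repeat(["A", "B"], 5)
        X2, y2 = upsample_minority(X, y, seed=0)
        assert y2.tolist() == y.tolist()

    def test_seed_determinism(self):
        X = np.arange(30.0).reshape(30, 1)
        y = np.repeat(["A", "B"], [20, 10])
        a = upsample_minority(X, y, seed=5)[0]
        b = upsample_minority(X, y, seed=5)[0]
        np.testing.assert_array_equal(a, b)

    def test_requires_exactly_two_classes(self):
        with pytest.raises(ValueError, match="exactly 2 classes"):
            upsample_minority(np.zeros((3, 1)), np.array(["A", "B", "C"]))


# ---------------------------------------------------------------------------
# Two-stage cascade
# ---------------------------------------------------------------------------


class _StubBinary:
    """Deterministic stand-in classifier: P(classes_[1]) = 1 iff the
    designated feature is positive."""

    def __init__(self, classes, feature):
        self.classes_ = np.array(classes)
        self.feature = feature

    def predict_proba(self, X):
        hot = (np.asarray(X)[:, self.feature] > 0).astype(float)
        return np.column_stack([1.0 - hot, hot])


class _IdentityEncoder:
    def __init__(self, width):
        self.width = width

    def encode(self, X):
        return np.asarray(X, dtype=float)


def _stub_model():
    # stage 1: yes iff feature0 > 0; stage 2: LYM iff feature1 > 0
    return TwoStageModel(
        primary_class="GBM",
        stage1_encoders={"m": _IdentityEncoder(2)},
        stage1_clf=_StubBinary(["no", "yes"], feature=0),
        stage2_encoders={"m": _IdentityEncoder(2)},
        stage2_clf=_StubBinary(["MET", "LYM"], feature=1),
        stage2_classes=("LYM", "MET"),
        mask_order=("m",))


class TestPredictTwoStage:
    def test_manual_trace_on_six_sample_fixture(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0],
                      [-1.0, -1.0], [1.0, 0.5], [-1.0, -0.5]])
        pred = predict_two_stage(_stub_model(), {"m": X})
        # rows 0,1,4 -> GBM; rows 2 (f1>0) -> LYM; rows 3,5 -> MET
        assert pred.final_labels.tolist() == \
            ["GBM", "GBM", "LYM", "MET", "GBM", "MET"]
        assert pred.stage1_labels.tolist() == \
            ["yes", "yes", "no", "no", "yes", "no"]
        # stage-2 scores only exist for the carried-through rows
        assert np.isnan(pred.stage2_score[0]).all()
        assert not np.isnan(pred.stage2_score[2]).any()

    def test_all_yes_boundary(self):
        X = np.ones((4, 2))
        pred = predict_two_stage(_stub_model(), {"m": X})
        assert (pred.final_labels == "GBM").all()
        assert np.isnan(pred.stage2_score).all()

    def test_closure_and_conservation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 2))
        pred = predict_two_stage(_stub_model(), {"m": X})
        assert set(pred.final_labels) <= {"GBM", "LYM", "MET"}
        n_yes = (pred.stage1_labels == "yes").sum()
        n_stage2 = (~np.isnan(pred.stage2_score[:, 0])).sum()
        assert n_yes + n_stage2 == 40
        # stage-1 "yes" labels are never revised
        assert (pred.final_labels[pred.stage1_labels == "yes"] == "GBM").all()

    def test_oracle_stage1_gives_perfect_primary_recall(self):
        # with a ground-truth stage 1, composite accuracy = stage-2 binary
        # accuracy on secondary samples plus perfect primary recall
        X = np.array([[1.0, 0.3], [1.0, -2.0], [-1.0, 1.0], [-1.0, -1.0],
                      [-1.0, 2.0], [-1.0, -0.1]])
        truth = np.array(["GBM", "GBM", "LYM", "MET", "LYM", "MET"])
        pred = predict_two_stage(_stub_model(), {"m": X})
        assert (pred.final_labels[truth == "GBM"] == "GBM").all()
        secondary = truth != "GBM"
        assert (pred.final_labels[secondary] == truth[secondary]).all()


@pytest.fixture(scope="module")
def fitted(small_blocks, small_cohort, fast_ae_cfg):
    params = MLPParams(batch_size=32, hidden_nodes=30, hidden_layers=1)
    return fit_two_stage(
        small_blocks, small_cohort.labels, small_cohort.masks,
        primary_class="GBM", latent_dim=3, ae_cfg=fast_ae_cfg,
        stage1_params=params, stage2_params=params,
        mlp_max_iter=200, seed=4)


class TestFitTwoStage:
    def test_stage_encoders_are_distinct_refits(self, fitted):
        for mask in fitted.mask_order:
            assert fitted.stage1_encoders[mask] is not \
                fitted.stage2_encoders[mask]

    def test_stage2_excludes_primary(self, fitted):
        assert set(fitted.stage2_clf.classes_) == {"LYM", "MET"}
        assert fitted.stage2_classes == ("LYM", "MET")

    def test_stage2_training_counts_equal_after_upsampling(
            self, small_cohort):
        from radlatent.models import _upsample_indices
        labels = small_cohort.labels
        y2 = labels[labels != "GBM"]
        idx = _upsample_indices(y2, seed=0)
        _, counts = np.unique(y2[idx], return_counts=True)
        assert counts[0] == counts[1]

    def test_missing_class_rejected(self, small_blocks):
        n = next(iter(small_blocks.values())).shape[0]
        labels = np.repeat(["LYM", "MET"], [n // 2, n - n // 2])
        with pytest.raises(ValueError, match="three classes"):
            fit_two_stage(small_blocks, labels, list(small_blocks),
                          primary_class="GBM", latent_dim=2)

    def test_cascade_predicts_well_on_separable_cohort(
            self, fitted, small_blocks, small_cohort):
        pred = predict_two_stage(fitted, small_blocks)
        assert (pred.final_labels == small_cohort.labels).mean() > 0.8
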