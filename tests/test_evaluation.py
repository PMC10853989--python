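"""CV planning, AUC/PRF metrics with brute-force oracles, and the
cross-validated pipeline runners."""
from __future__ import annotations

import numpy as np
import pytest

from radlatent.cohort import generate_cohort
from radlatent.evaluation import (PipelineConfig, accuracy, confusion_matrix,
                                  make_cv_plan, micro_prf, ovr_auc,
                                  roc_auc_binary, run_cv_three_class,
                                  run_cv_two_stage, run_latent_grid)
from radlatent.latent import TrainConfig
from radlatent.models import MLPParams

from conftest import make_small_spec


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive pairwise concordance
# ---------------------------------------------------------------------------

def pairwise_concordance(scores, positive):
    """AUC by enumerating every (positive, negative) pair."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos, neg = scores[positive], scores[~positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestCVPlan:
    def test_study_counts_give_exactly_eight_lym_per_fold(self):
        labels = np.repeat(["GBM", "LYM", "MET"], [93, 40, 120])
        plan = make_cv_plan(labels, k=5, repeats=2, seed=0)
        for r in range(2):
            for f in range(5):
                fold_labels = labels[plan.assignments[r] == f]
                assert (fold_labels == "LYM").sum() == 8  # 40 / 5 exact

    def test_folds_partition_and_stratify_within_one(self):
        labels = np.repeat(["GBM", "LYM", "MET"], [41, 23, 52])
        plan = make_cv_plan(labels, k=5, repeats=3, seed=1)
        classes, counts = np.unique(labels, return_counts=True)
        for r in range(3):
            assert sorted(np.unique(plan.assignments[r])) == list(range(5))
            seen = np.zeros(labels.size, dtype=int)
            for _, f, train, test in [s for s in plan.splits() if s[0] == r]:
                seen[test] += 1
                assert np.intersect1d(train, test).size == 0
                for cls, total in zip(classes, counts):
                    got = (labels[test] == cls).sum()
                    assert abs(got - total / 5) <= 1
            assert (seen == 1).all()

    def test_two_seeds_differ(self):
        labels = np.repeat(["GBM", "LYM", "MET"], [93, 40, 120])
        a = make_cv_plan(labels, 5, 1, seed=0).assignments
        b = make_cv_plan(labels, 5, 1, seed=1).assignments
        assert not np.array_equal(a, b)

    def test_class_smaller_than_k_rejected(self):
        labels = np.repeat(["A", "B"], [3, 50])
        with pytest.raises(ValueError, match="fewer than k"):
            make_cv_plan(labels, k=5)


class TestBinaryAUC:
    def test_known_small_cases(self):
        assert roc_auc_binary([0.9, 0.8, 0.3],
                              np.array([True, True, False])) == 1.0
        assert roc_auc_binary([0.4, 0.6], np.array([True, False])) == 0.0
        assert roc_auc_binary([0.5, 0.5, 0.5, 0.5],
                              np.array([True, False, True, False])) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc_binary(scores, labels) == pytest.approx(
            pairwise_concordance(scores, labels))

    def test_one_class_absent_flagged(self):
        with pytest.raises(ValueError, match="one class absent"):
            roc_auc_binary([0.1, 0.2], np.array([True, True]))


class TestOvrAUC:
    def test_perfect_separation(self):
        scores = np.eye(3)[np.array([0, 1, 2, 0, 1, 2])]
        labels = np.array(["A", "B", "C", "A", "B", "C"])
        out = ovr_auc(scores, labels, ["A", "B", "C"])
        assert all(v == 1.0 for v in out.values())

    def test_null_labels_give_half(self):
        rng = np.random.default_rng(0)
        n = 3000
        scores = rng.dirichlet(np.ones(3), size=n)
        labels = rng.choice(["A", "B", "C"], size=n)
        out = ovr_auc(scores, labels, ["A", "B", "C"])
        assert out["micro"] == pytest.approx(0.5, abs=0.03)

    def test_matches_bruteforce_on_six_sample_fixture(self):
        scores = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1],
                           [0.3, 0.3, 0.4], [0.5, 0.4, 0.1],
                           [0.2, 0.2, 0.6], [0.4, 0.4, 0.2]])
        labels = np.array(["A", "B", "C", "B", "C", "A"])
        out = ovr_auc(scores, labels, ["A", "B", "C"])
        for c, cls in enumerate(["A", "B", "C"]):
            assert out[cls] == pytest.approx(
                pairwise_concordance(scores[:, c], labels == cls))
        onehot = labels[:, None] == np.array(["A", "B", "C"])
        assert out["micro"] == pytest.approx(
            pairwise_concordance(scores.ravel(), onehot.ravel()))

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValueError, match="outside declared"):
            ovr_auc(np.ones((2, 2)), np.array(["A", "X"]), ["A", "B"])


class TestMicroPRF:
    def test_micro_equals_accuracy_for_single_label_predictions(self):
        rng = np.random.default_rng(1)
        true = rng.choice(["A", "B", "C"], size=60)
        pred = rng.choice(["A", "B", "C"], size=60)
        out = micro_prf(pred, true, ["A", "B", "C"])
        acc = (pred == true).mean()
        for key in ("precision", "recall", "f1"):
            assert out["micro"][key] == pytest.approx(acc)

    def test_perfect_predictions(self):
        y = np.array(["A", "B", "C"] * 3)
        out = micro_prf(y, y, ["A", "B", "C"])
        assert all(v == 1.0 for d in out.values() for v in d.values())

    def test_hand_counted_nine_sample_fixture(self):
        true = np.array(["A", "A", "A", "B", "B", "B", "C", "C", "C"])
        pred = np.array(["A", "B", "A", "B", "B", "C", "C", "C", "A"])
        out = micro_prf(pred, true, ["A", "B", "C"])
        # class A: TP=2 FP=1 FN=1 -> P=2/3, R=2/3
        assert out["A"]["precision"] == pytest.approx(2 / 3)
        assert out["A"]["recall"] == pytest.approx(2 / 3)
        # class B: TP=2 FP=1 FN=1; class C: TP=2 FP=1 FN=1
        assert out["micro"]["f1"] == pytest.approx(6 / 9)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            micro_prf(np.array([]), np.array([]))


class TestConfusion:
    def test_rows_true_columns_predicted(self):
        true = np.array(["A", "A", "B"])
        pred = np.array(["A", "B", "B"])
        mat = confusion_matrix(pred, true, ["A", "B"])
        np.testing.assert_array_equal(mat, [[1, 1], [0, 1]])

    def test_identity_and_all_wrong(self):
        y = np.array(["A", "B", "A"])
        assert accuracy(confusion_matrix(y, y, ["A", "B"])) == 1.0
        flipped = np.where(y == "A", "B", "A")
        assert accuracy(confusion_matrix(flipped, y, ["A", "B"])) == 0.0

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="outside declared alphabet"):
            confusion_matrix(np.array(["A"]), np.array(["Z"]), ["A", "B"])


# ---------------------------------------------------------------------------
# Cross-validated pipelines (scaled-down cohorts)
# ---------------------------------------------------------------------------

def _fast_cfg(seed=5, repeats=1):
    return PipelineConfig(
        latent_dim=4,
        ae=TrainConfig(max_epochs=60, patience=8),
        mlp=MLPParams(batch_size=32, hidden_nodes=50, hidden_layers=1),
        stage1_mlp=MLPParams(batch_size=32, hidden_nodes=50, hidden_layers=1),
        stage2_mlp=MLPParams(batch_size=32, hidden_nodes=50, hidden_layers=1),
        mlp_max_iter=250, k=5, repeats=repeats, seed=seed)


class TestRunThreeClass:
    def test_report_contract_and_determinism(self):
        cohort = generate_cohort(make_small_spec(effect=4.0))
        rep1 = run_cv_three_class(cohort, _fast_cfg())
        assert rep1.table["class"].tolist() == ["GBM", "LYM", "MET", "ALL"]
        assert rep1.table["auc"].between(0, 1).all()
        conf = rep1.confusions["three_class"]
        np.testing.assert_allclose(conf.sum(axis=1), [40, 25, 45])
        rep2 = run_cv_three_class(cohort, _fast_cfg())
        assert rep1.table.equals(rep2.table)

    def test_learnable_cohort_reaches_high_micro_auc(self):
        cohort = generate_cohort(make_small_spec(effect=4.0))
        rep = run_cv_three_class(cohort, _fast_cfg())
        micro = rep.table.loc[rep.table["class"] == "ALL", "auc"].item()
        assert micro >= 0.85

    def test_latent_grid_emits_one_row_block_per_setting(self):
        cohort = generate_cohort(make_small_spec(effect=4.0))
        rep = run_latent_grid(cohort, _fast_cfg(), [2, 4])
        assert rep.table["setting"].tolist() == \
            ["AE 2 latent"] * 4 + ["AE 4 latent"] * 4
        assert set(rep.confusions) == {"three_class_d2", "three_class_d4"}

    def test_full_set_baseline_runs(self):
        import dataclasses
        cohort = generate_cohort(make_small_spec(effect=4.0))
        cfg = dataclasses.replace(_fast_cfg(), use_autoencoder=False)
        rep = run_cv_three_class(cohort, cfg)
        assert rep.table.loc[rep.table["class"] == "ALL", "auc"].item() > 0.8
        assert rep.table["setting"].iloc[0] == "Full set"


@pytest.fixture(scope="module")
def report():
    cohort = generate_cohort(make_small_spec(effect=4.0))
    return run_cv_two_stage(cohort, _fast_cfg())


class TestRunTwoStage:
    def test_report_shape_and_combined_auc_omitted(self, report):
        settings = report.table["setting"].unique().tolist()
        assert settings == ["Stage1", "Stage2", "Combined"]
        combined = report.table[report.table["setting"] == "Combined"]
        assert combined["auc"].isna().all()     # hard labels only
        assert combined["f1"].notna().all()

    def test_three_confusions_with_conserved_row_sums(self, report):
        assert set(report.confusions) == {"stage1", "stage2", "combined"}
        np.testing.assert_allclose(
            report.confusions["combined"].sum(axis=1), [40, 25, 45])
        # stage 2 evaluated on true secondary samples only
        np.testing.assert_allclose(
            report.confusions["stage2"].sum(axis=1), [25, 45])

    def test_stage1_rest_row_present(self, report):
        stage1 = report.table[report.table["setting"] == "Stage1"]
        assert stage1["class"].tolist() == ["GBM", "REST"]


class TestSeparationResponse:
    """Micro AUC must track the generator's class separation."""

    def test_null_separation_gives_chance_auc(self):
        spec = make_small_spec(effect=0.0, seed=11,
                               counts={"GBM": 60, "LYM": 40, "MET": 60})
        rep = run_cv_three_class(generate_cohort(spec), _fast_cfg(seed=5))
        micro = rep.table.loc[rep.table["class"] == "ALL", "auc"].item()
        assert micro == pytest.approx(0.5, abs=0.05)

    def test_high_separation_gives_near_perfect_auc(self):
        spec = make_small_spec(effect=6.0, seed=11,
                               counts={"GBM": 60, "LYM": 40, "MET": 60})
        rep = run_cv_three_class(generate_cohort(spec), _fast_cfg(seed=5))
        micro = rep.table.loc[rep.table["class"] == "ALL", "auc"].item()
        assert micro >= 0.95
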