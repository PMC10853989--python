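"""Repeated stratified cross-validation and multiclass metrics.

Validation follows the study design: 5-fold stratified cross-validation
repeated 5 times (25 fold-evaluations), with every preprocessing and model
parameter refit inside each training fold.  Headline metrics are one-vs-rest
AUC per class plus a micro average that pools all (sample, class) indicator
pairs, and micro-averaged precision/recall/F1 (which, for single-label
multiclass predictions, all equal accuracy).  The two-stage runner reports
stage-wise binary metrics (without carry-through) alongside the composite
three-class result (with carry-through), whose AUC is deliberately not
computed — the cascade emits hard labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .cohort import RadiomicCohort
from .latent import TrainConfig, encode_concat, train_autoencoder
from .models import (CLASS_ORDER, MLPParams, STAGE1_PRESET, STAGE2_PRESET,
                     THREE_CLASS_PRESET, _argmax_labels, fit_mlp,
                     fit_two_stage, predict_two_stage, recode_primary)
from .preprocessing import (ImputationStrategy, apply_standardizer,
                            fit_standardizer, impute, split_matrix_by_mask)

# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    """Fold assignments for repeated stratified k-fold CV.

    ``assignments[r, i]`` is the fold index of sample ``i`` in repeat
    ``r``; within each repeat the folds partition the samples and each
    class count per fold is within +-1 of n_class / k.
    """

    k: int
    repeats: int
    seed: int
    assignments: np.ndarray

    def splits(self) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
        """Yield (repeat, fold, train_idx, test_idx) in order."""
        n = self.assignments.shape[1]
        idx = np.arange(n)
        for r in range(self.repeats):
            for f in range(self.k):
                test = idx[self.assignments[r] == f]
                train = idx[self.assignments[r] != f]
                yield r, f, train, test


def make_cv_plan(labels: np.ndarray, k: int = 5, repeats: int = 5,
                 seed: int = 0) -> CVPlan:
    """Stratified fold assignments, re-partitioned per repeat."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than k={k} members")
    assignments = np.empty((repeats, labels.size), dtype=int)
    X_dummy = np.zeros((labels.size, 1))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=derive_seed(seed, "repeat", r))
        for f, (_, test) in enumerate(skf.split(X_dummy, labels)):
            assignments[r, test] = f
    return CVPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_auc_binary(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary AUC = Mann-Whitney concordance P(s+ > s-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError(
                f"binary AUC undefined: found classes {uniq.tolist()} "
                "(need exactly two, both present)")
        labels = labels == uniq.max()
    if labels.all() or not labels.any():
        raise ValueError("binary AUC undefined: one class absent")
    return float(roc_auc_score(labels, scores))


def ovr_auc(scores: np.ndarray, labels: np.ndarray,
            class_order: Sequence[str]) -> dict[str, float]:
    """One-vs-rest AUC per class plus the pooled micro AUC.

    ``scores[:, c]`` must be the score for ``class_order[c]``.  The micro
    AUC flattens all (sample, class) one-hot pairs into one binary problem.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    class_order = list(class_order)
    if scores.ndim != 2 or scores.shape[1] != len(class_order):
        raise ValueError(
            f"score matrix has {scores.shape} but {len(class_order)} classes "
            "declared")
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside declared classes")
    out: dict[str, float] = {}
    onehot = labels[:, None] == np.array(class_order)[None, :]
    for c, cls in enumerate(class_order):
        out[cls] = roc_auc_binary(scores[:, c], onehot[:, c])
    out["micro"] = roc_auc_binary(scores.ravel(), onehot.ravel())
    return out


def micro_prf(predicted: np.ndarray, true: np.ndarray,
              class_order: Sequence[str] | None = None
              ) -> dict[str, dict[str, float]]:
    """Per-class one-vs-rest precision/recall/F1 plus micro aggregates.

    Micro pools TP/FP/FN over classes; for single-label predictions micro
    precision = recall = F1 = accuracy.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size == 0 or true.size == 0:
        raise ValueError("empty inputs")
    if predicted.size != true.size:
        raise ValueError(f"length mismatch: {predicted.size} vs {true.size}")
    if class_order is None:
        class_order = sorted(set(true) | set(predicted))
    class_order = list(class_order)
    p, r, f1, _ = precision_recall_fscore_support(
        true, predicted, labels=class_order, zero_division=0)
    mp, mr, mf1, _ = precision_recall_fscore_support(
        true, predicted, labels=class_order, average="micro", zero_division=0)
    out = {cls: {"precision": float(p[i]), "recall": float(r[i]),
                 "f1": float(f1[i])}
           for i, cls in enumerate(class_order)}
    out["micro"] = {"precision": float(mp), "recall": float(mr),
                    "f1": float(mf1)}
    return out


def confusion_matrix(predicted: np.ndarray, true: np.ndarray,
                     label_order: Sequence[str]) -> np.ndarray:
    """Integer confusion matrix with rows = true, columns = predicted."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    outside = (set(predicted) | set(true)) - set(label_order)
    if outside:
        raise ValueError(
            f"labels {sorted(outside)} outside declared alphabet "
            f"{list(label_order)}")
    return _sk_confusion(true, predicted, labels=list(label_order))


def accuracy(matrix: np.ndarray) -> float:
    """Trace over total of a confusion matrix."""
    matrix = np.asarray(matrix, dtype=float)
    total = matrix.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix) / total)


# ---------------------------------------------------------------------------
# Pipeline configurations and the evaluation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Shared configuration of the CV pipelines.

    ``latent_dim`` is the bottleneck size per mask; with
    ``use_autoencoder=False`` the classifier consumes the full standardized
    feature set instead (the full-set baseline).
    """

    latent_dim: int = 15
    use_autoencoder: bool = True
    ae: TrainConfig = field(default_factory=TrainConfig)
    mlp: MLPParams = THREE_CLASS_PRESET
    stage1_mlp: MLPParams = STAGE1_PRESET
    stage2_mlp: MLPParams = STAGE2_PRESET
    mlp_max_iter: int = 300
    imputation: ImputationStrategy = ImputationStrategy("mean")
    primary_class: str = "GBM"
    k: int = 5
    repeats: int = 5
    seed: int = 0
    model_name: str = "Three-Class MLP"
    setting: str = ""

    def label(self) -> str:
        if self.setting:
            return self.setting
        if not self.use_autoencoder:
            return "Full set"
        return f"AE {self.latent_dim} latent"


@dataclass
class EvaluationReport:
    """Aggregated CV results in the study's report layout.

    ``table`` has one row per (model, setting, class) with fold-mean AUC,
    precision, recall, F1 and their standard deviations over the
    repeats x k fold evaluations; ``confusions`` maps a name to a matrix
    whose entries are per-repeat fold sums averaged over repeats (row sums
    therefore equal the true class counts); ``records`` is the tidy
    per-fold log (repeat, fold, class, metric, value).
    """

    table: pd.DataFrame
    confusions: dict[str, pd.DataFrame]
    records: pd.DataFrame

    def write(self, outdir: str | Path, prefix: str = "report") -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / f"{prefix}.csv", index=False)
        self.table.to_json(outdir / f"{prefix}.json", orient="records",
                           indent=1)
        self.records.to_csv(outdir / f"{prefix}_folds.csv", index=False)
        for name, mat in self.confusions.items():
            mat.to_csv(outdir / f"{prefix}_confusion_{name}.csv")
        return outdir


def _preprocess_fold(cohort: RadiomicCohort, train_idx: np.ndarray,
                     test_idx: np.ndarray, strategy: ImputationStrategy
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Standardize on training rows only, impute, split into mask blocks."""
    params = fit_standardizer(cohort.features[train_idx])
    Xtr = impute(apply_standardizer(cohort.features[train_idx], params),
                 strategy)
    Xte = impute(apply_standardizer(cohort.features[test_idx], params),
                 strategy)
    blocks_tr = {b.mask: b.values for b in split_matrix_by_mask(
        Xtr, cohort.column_meta, cohort.masks)}
    blocks_te = {b.mask: b.values for b in split_matrix_by_mask(
        Xte, cohort.column_meta, cohort.masks)}
    return blocks_tr, blocks_te


def _fit_fold_encoders(blocks_tr: dict[str, np.ndarray], latent_dim: int,
                       ae_cfg: TrainConfig, mask_order: Sequence[str],
                       seed: int) -> dict:
    encoders = {}
    for mi, mask in enumerate(mask_order):
        cfg = replace(ae_cfg, seed=derive_seed(seed, "mask", mi))
        encoders[mask] = train_autoencoder(blocks_tr[mask], latent_dim, cfg,
                                           mask_name=mask)
    return encoders


def _class_order_of(cohort: RadiomicCohort) -> list[str]:
    present = set(cohort.labels)
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(ordered))
    return ordered


def _aggregate(records: list[dict], model: str, setting: str,
               class_rows: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    rows = []
    for cls in class_rows:
        sub = df[df["class"] == cls]
        row = {"model": model, "setting": setting, "class": cls}
        for metric in ("auc", "precision", "recall", "f1"):
            vals = sub.loc[sub["metric"] == metric, "value"].to_numpy()
            vals = vals[~np.isnan(vals)] if vals.size else vals
            row[metric] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{metric}_sd"] = float(np.std(vals)) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_cv_three_class(cohort: RadiomicCohort,
                       cfg: PipelineConfig) -> EvaluationReport:
    """Repeated stratified CV of the three-class pipeline.

    Per fold: fit the standardizer on training rows, impute, train one
    autoencoder per mask on the training block, encode both folds,
    fit the MLP, score the held-out fold.  Fully seeded from ``cfg.seed``.
    """
    classes = _class_order_of(cohort)
    plan = make_cv_plan(cohort.labels, cfg.k, cfg.repeats,
                        seed=derive_seed(cfg.seed, "cv"))
    records: list[dict] = []
    conf_sum = np.zeros((cfg.repeats, len(classes), len(classes)))
    for r, f, train_idx, test_idx in plan.splits():
        fold_seed = derive_seed(cfg.seed, "repeat", r, "fold", f)
        blocks_tr, blocks_te = _preprocess_fold(cohort, train_idx, test_idx,
                                                cfg.imputation)
        y_tr = cohort.labels[train_idx]
        y_te = cohort.labels[test_idx]
        if cfg.use_autoencoder:
            encoders = _fit_fold_encoders(blocks_tr, cfg.latent_dim, cfg.ae,
                                          cohort.masks, fold_seed)
            Ztr = encode_concat(encoders, blocks_tr, cohort.masks)
            Zte = encode_concat(encoders, blocks_te, cohort.masks)
        else:
            Ztr = np.hstack([blocks_tr[m] for m in cohort.masks])
            Zte = np.hstack([blocks_te[m] for m in cohort.masks])
        clf = fit_mlp(Ztr, y_tr,
                      replace(cfg.mlp, seed=derive_seed(fold_seed, "mlp")),
                      max_iter=cfg.mlp_max_iter)
        proba = clf.predict_proba(Zte)
        cols = [list(clf.classes_).index(c) for c in classes]
        proba = proba[:, cols]
        aucs = ovr_auc(proba, y_te, classes)
        preds = _argmax_labels(proba, classes)
        prf = micro_prf(preds, y_te, classes)
        conf_sum[r] += confusion_matrix(preds, y_te, classes)
        for cls in classes + ["micro"]:
            name = "ALL" if cls == "micro" else cls
            records.append({"repeat": r, "fold": f, "class": name,
                            "metric": "auc", "value": aucs[cls]})
            for metric in ("precision", "recall", "f1"):
                records.append({"repeat": r, "fold": f, "class": name,
                                "metric": metric, "value": prf[cls][metric]})
    table = _aggregate(records, cfg.model_name, cfg.label(),
                       classes + ["ALL"])
    combined = pd.DataFrame(conf_sum.mean(axis=0), index=classes,
                            columns=classes)
    return EvaluationReport(table=table,
                            confusions={"three_class": combined},
                            records=pd.DataFrame(records))


def run_latent_grid(cohort: RadiomicCohort, cfg: PipelineConfig,
                    latent_dims: Sequence[int]) -> EvaluationReport:
    """Three-class CV at several bottleneck sizes, one row block each.

    The concatenated table mirrors the model-comparison layout: a
    "AE <d> latent" block of per-class and ALL rows per setting.
    """
    tables, records, confusions = [], [], {}
    for d in latent_dims:
        rep = run_cv_three_class(
            cohort, replace(cfg, latent_dim=d, setting=f"AE {d} latent"))
        tables.append(rep.table)
        rec = rep.records.copy()
        rec["setting"] = f"AE {d} latent"
        records.append(rec)
        confusions[f"three_class_d{d}"] = rep.confusions["three_class"]
    return EvaluationReport(table=pd.concat(tables, ignore_index=True),
                            confusions=confusions,
                            records=pd.concat(records, ignore_index=True))


def run_cv_two_stage(cohort: RadiomicCohort,
                     cfg: PipelineConfig) -> EvaluationReport:
    """Repeated stratified CV of the two-stage decomposition cascade.

    Emits stage-1 binary metrics on recoded truth, stage-2 binary metrics
    on true secondary samples only (no stage-1 carry-through), and the
    combined three-class result with carry-through.  The combined AUC is
    not computed (hard labels only).  Three confusion matrices are
    reported: stage 1 (primary vs REST), stage 2 (secondary classes), and
    the composite three-class matrix.
    """
    classes = _class_order_of(cohort)
    primary = cfg.primary_class
    secondary = [c for c in classes if c != primary]
    plan = make_cv_plan(cohort.labels, cfg.k, cfg.repeats,
                        seed=derive_seed(cfg.seed, "cv"))
    records: list[dict] = []
    conf1 = np.zeros((cfg.repeats, 2, 2))
    conf2 = np.zeros((cfg.repeats, len(secondary), len(secondary)))
    conf3 = np.zeros((cfg.repeats, len(classes), len(classes)))
    for r, f, train_idx, test_idx in plan.splits():
        fold_seed = derive_seed(cfg.seed, "repeat", r, "fold", f)
        blocks_tr, blocks_te = _preprocess_fold(cohort, train_idx, test_idx,
                                                cfg.imputation)
        y_tr = cohort.labels[train_idx]
        y_te = cohort.labels[test_idx]
        model = fit_two_stage(
            blocks_tr, y_tr, cohort.masks, primary_class=primary,
            latent_dim=cfg.latent_dim, ae_cfg=cfg.ae,
            stage1_params=cfg.stage1_mlp, stage2_params=cfg.stage2_mlp,
            mlp_max_iter=cfg.mlp_max_iter, seed=fold_seed)
        pred = predict_two_stage(model, blocks_te)

        # --- stage 1: binary vs recoded truth ---------------------------
        y1 = recode_primary(y_te, primary)
        auc1 = roc_auc_binary(pred.stage1_score, y1 == "yes")
        prf1 = micro_prf(pred.stage1_labels, y1, ["yes", "no"])
        records.append({"repeat": r, "fold": f, "class": primary,
                        "stage": "stage1", "metric": "auc", "value": auc1})
        for metric in ("precision", "recall", "f1"):
            records.append({"repeat": r, "fold": f, "class": primary,
                            "stage": "stage1", "metric": metric,
                            "value": prf1["yes"][metric]})
            records.append({"repeat": r, "fold": f, "class": "REST",
                            "stage": "stage1", "metric": metric,
                            "value": prf1["no"][metric]})
        conf1[r] += confusion_matrix(pred.stage1_labels, y1, ["yes", "no"])

        # --- stage 2: true secondary samples, no carry-through ----------
        sec_rows = np.where(np.isin(y_te, secondary))[0]
        sec_blocks = {m: blocks_te[m][sec_rows] for m in cohort.masks}
        scores2 = model.stage2_scores(sec_blocks)
        y2 = y_te[sec_rows]
        preds2 = _argmax_labels(scores2, model.stage2_classes)
        prf2 = micro_prf(preds2, y2, list(model.stage2_classes))
        for ci, cls in enumerate(model.stage2_classes):
            records.append({"repeat": r, "fold": f, "class": cls,
                            "stage": "stage2", "metric": "auc",
                            "value": roc_auc_binary(scores2[:, ci],
                                                    y2 == cls)})
            for metric in ("precision", "recall", "f1"):
                records.append({"repeat": r, "fold": f, "class": cls,
                                "stage": "stage2", "metric": metric,
                                "value": prf2[cls][metric]})
        conf2[r] += confusion_matrix(preds2, y2, list(model.stage2_classes))

        # --- combined: carry-through, hard labels only ------------------
        prf3 = micro_prf(pred.final_labels, y_te, classes)
        for cls in classes + ["micro"]:
            name = "ALL" if cls == "micro" else cls
            for metric in ("precision", "recall", "f1"):
                records.append({"repeat": r, "fold": f, "class": name,
                                "stage": "combined", "metric": metric,
                                "value": prf3[cls][metric]})
        conf3[r] += confusion_matrix(pred.final_labels, y_te, classes)

    df = pd.DataFrame(records)
    tables = []
    for stage, rows in (("stage1", [primary, "REST"]),
                        ("stage2", secondary),
                        ("combined", classes + ["ALL"])):
        sub = df[df["stage"] == stage].to_dict("records")
        tables.append(_aggregate(sub, "Two-Stage", stage.capitalize(), rows))
    table = pd.concat(tables, ignore_index=True)
    confusions = {
        "stage1": pd.DataFrame(conf1.mean(axis=0), index=[primary, "REST"],
                               columns=[primary, "REST"]),
        "stage2": pd.DataFrame(conf2.mean(axis=0), index=secondary,
                               columns=secondary),
        "combined": pd.DataFrame(conf3.mean(axis=0), index=classes,
                                 columns=classes),
    }
    return EvaluationReport(table=table, confusions=confusions, records=df)
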