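"""Standardization, imputation and per-mask partitioning of feature tables.

The preprocessing contract mirrors how the analysis uses it inside
cross-validation: statistics are *fit on training rows only* and frozen for
held-out rows.  Standardization (z-score with population sd over observed
values) comes first, then imputation, so that mean imputation is exactly a
zero-fill on the standardized scale — equivalently the column training mean
on the raw scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import RadiomicCohort

IMPUTATION_KINDS = ("mean", "zero", "flag")


@dataclass(frozen=True)
class ImputationStrategy:
    """How to fill missing cells of a standardized matrix.

    ``mean`` and ``zero`` both fill 0 on the standardized scale (the mean
    strategy is *defined* as the column training mean, which standardizes
    to 0); ``flag`` fills the literal ``flag_value``.
    """

    kind: str = "mean"
    flag_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.kind not in IMPUTATION_KINDS:
            raise ValueError(
                f"unknown imputation kind '{self.kind}'; "
                f"expected one of {IMPUTATION_KINDS}")


@dataclass
class StandardizationParams:
    """Per-column mean/sd fitted over observed (non-missing) values.

    ``sd`` is the population standard deviation (divisor n).  Columns with
    zero spread or no observed values are flagged ``degenerate`` and mapped
    to divisor 1 (mean 0 for all-missing columns).
    """

    mean: np.ndarray
    sd: np.ndarray
    n_obs: np.ndarray
    degenerate: np.ndarray

    @property
    def divisor(self) -> np.ndarray:
        return np.where(self.sd > 0, self.sd, 1.0)

    @property
    def n_columns(self) -> int:
        return self.mean.size

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_obs": self.n_obs.tolist(),
            "degenerate": self.degenerate.tolist(),
        }


def fit_standardizer(features: np.ndarray) -> StandardizationParams:
    """Fit per-column z-score parameters over observed values only."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    observed = ~np.isnan(X)
    n_obs = observed.sum(axis=0)
    all_missing = n_obs == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} all-missing column(s); "
            "standardized with mean 0, divisor 1", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)  # population sd, divisor n
    mean = np.where(all_missing, 0.0, mean)
    sd = np.where(all_missing, 0.0, sd)
    degenerate = all_missing | (sd == 0)
    return StandardizationParams(mean=mean, sd=sd, n_obs=n_obs,
                                 degenerate=degenerate)


def apply_standardizer(features: np.ndarray,
                       params: StandardizationParams) -> np.ndarray:
    """Transform ``(x - mean) / divisor``; missing cells stay missing."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_columns:
        raise ValueError(
            f"shape mismatch: matrix has {X.shape[1] if X.ndim == 2 else '?'} "
            f"columns, params expect {params.n_columns}")
    return (X - params.mean) / params.divisor


def impute(features: np.ndarray,
           strategy: ImputationStrategy = ImputationStrategy("mean"),
           params: StandardizationParams | None = None) -> np.ndarray:
    """Fill missing cells of an already-standardized matrix.

    ``params`` is accepted for interface symmetry (the fill values live on
    the standardized scale defined by it) but is not consulted: mean and
    zero both fill 0, flag fills the strategy's flag value.
    """
    X = np.asarray(features, dtype=float).copy()
    missing = np.isnan(X)
    if not missing.any():
        return X
    if strategy.kind in ("mean", "zero"):
        X[missing] = 0.0
    elif strategy.kind == "flag":
        X[missing] = strategy.flag_value
    else:  # pragma: no cover - guarded by ImputationStrategy
        raise ValueError(f"unknown imputation kind '{strategy.kind}'")
    return X


@dataclass
class MaskBlock:
    """The sub-table of all columns belonging to one ROI mask."""

    mask: str
    column_indices: np.ndarray
    column_names: list[str]
    values: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def split_matrix_by_mask(X: np.ndarray,
                         column_meta: Sequence[tuple[str, str, str]],
                         masks: Sequence[str]) -> list[MaskBlock]:
    """Partition the columns of ``X`` into one block per mask.

    Columns keep their original order inside each block; the blocks
    partition the columns exactly (an error names any column whose mask is
    not in ``masks``).
    """
    X = np.asarray(X)
    if X.shape[1] != len(column_meta):
        raise ValueError(
            f"matrix has {X.shape[1]} columns but metadata describes "
            f"{len(column_meta)}")
    known = set(masks)
    for k, meta in enumerate(column_meta):
        if meta[0] not in known:
            raise ValueError(
                f"column {k} ('{'__'.join(meta)}'): mask '{meta[0]}' not in "
                f"declared masks {list(masks)}")
    blocks = []
    for mask in masks:
        idx = np.array([k for k, m in enumerate(column_meta) if m[0] == mask],
                       dtype=int)
        names = [f"{m}__{s}__{f}" for m, s, f in
                 (column_meta[k] for k in idx)]
        blocks.append(MaskBlock(mask=mask, column_indices=idx,
                                column_names=names, values=X[:, idx]))
    return blocks


def split_by_mask(cohort: RadiomicCohort) -> list[MaskBlock]:
    """Partition a cohort's feature matrix into per-mask blocks."""
    return split_matrix_by_mask(cohort.features, cohort.column_meta,
                                cohort.masks)
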