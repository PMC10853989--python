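"""Synthetic radiomic cohorts with the study's dimensional structure.

The real cohort behind this pipeline — 253 retrospective patients with
multiparametric MRI radiomics for three malignant brain-tumor classes
(glioblastoma GBM, primary CNS lymphoma LYM, parenchymal metastasis MET) —
is not publicly deposited.  This module generates seeded surrogate cohorts
that reproduce the *structure* every downstream stage depends on:

* 4 ROI masks x 5 MRI sequences x 107 radiomic features = 2,140 columns;
* class imbalance 93 GBM / 40 LYM / 120 MET;
* per-(mask, class) block missingness at the study's reported rates
  (a patient missing a mask is missing all 535 of that mask's columns);
* low-rank latent structure per mask so the feature blocks are compressible,
  with class-dependent latent means so GBM and MET separate well while LYM
  separates only weakly.

The generative model is a low-rank Gaussian factor model: per mask ``m``
with intrinsic rank ``r``, a sample of class ``c`` has latent
``z ~ N(mu_c, I_r)`` and features ``W z + eps`` with a seeded loading matrix
``W`` (columns scaled so features have roughly unit variance) and
``eps ~ N(0, noise_sd^2)``.  ``mu_c`` points along a seeded random direction
with magnitude ``class_effect[c]``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed

CLASSES = ("GBM", "LYM", "MET")
DEFAULT_MASKS = ("whole", "enhancing", "necrotic", "edema")
DEFAULT_SEQUENCES = ("T1W", "T2W", "FLAIR", "ADC", "T1-CE")
DEFAULT_CLASS_COUNTS = {"GBM": 93, "LYM": 40, "MET": 120}

# Reported fraction of patients missing each mask, per class.  The study's
# table lists a mask "Enc2" alongside the four named masks; its rates are
# carried by "whole" here (the text names the masks whole / enhancing /
# necrotic / peritumoral edema).
DEFAULT_MISSING_RATES = {
    ("whole", "GBM"): 0.0538, ("whole", "LYM"): 0.10, ("whole", "MET"): 0.0167,
    ("enhancing", "GBM"): 0.0538, ("enhancing", "LYM"): 0.10, ("enhancing", "MET"): 0.0083,
    ("necrotic", "GBM"): 0.0538, ("necrotic", "LYM"): 0.85, ("necrotic", "MET"): 0.367,
    ("edema", "GBM"): 0.0538, ("edema", "LYM"): 0.10, ("edema", "MET"): 0.0083,
}

DEFAULT_CLASS_EFFECT = {"GBM": 2.5, "LYM": 1.0, "MET": 2.5}


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic radiomic cohort.

    Defaults reproduce the study's stated structure: class counts
    93/40/120, 4 masks x 5 sequences x 107 features, block missingness at
    the reported per-mask per-class rates, intrinsic rank 15 per mask.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    masks: Sequence[str] = DEFAULT_MASKS
    sequences: Sequence[str] = DEFAULT_SEQUENCES
    features_per_combination: int = 107
    intrinsic_rank: Mapping[str, int] | int = 15
    class_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECT))
    noise_sd: float = 0.3
    missing_rates: Mapping[tuple[str, str], float] | None = None
    seed: int = 0

    # ---- derived helpers -------------------------------------------------
    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_counts.keys())

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_counts.values()))

    @property
    def features_per_mask(self) -> int:
        return len(self.sequences) * self.features_per_combination

    @property
    def n_features(self) -> int:
        return len(self.masks) * self.features_per_mask

    def rank_of(self, mask: str) -> int:
        if isinstance(self.intrinsic_rank, Mapping):
            return int(self.intrinsic_rank[mask])
        return int(self.intrinsic_rank)

    def rate_of(self, mask: str, cls: str) -> float:
        if self.missing_rates is None:
            return float(DEFAULT_MISSING_RATES.get((mask, cls), 0.0))
        return float(self.missing_rates.get((mask, cls), 0.0))

    def effect_of(self, cls: str) -> float:
        return float(self.class_effect.get(cls, 0.0))

    def validate(self) -> None:
        if not self.class_counts or self.n_samples <= 0:
            raise CohortSpecError("class_counts: total sample count must be > 0")
        for cls, cnt in self.class_counts.items():
            if int(cnt) < 0:
                raise CohortSpecError(f"class_counts[{cls}]: negative count {cnt}")
        if self.features_per_combination < 1:
            raise CohortSpecError(
                f"features_per_combination: must be >= 1, got "
                f"{self.features_per_combination}")
        if len(set(self.masks)) != len(self.masks):
            raise CohortSpecError("masks: duplicate mask names")
        for m in self.masks:
            r = self.rank_of(m)
            if r < 1:
                raise CohortSpecError(f"intrinsic_rank[{m}]: must be >= 1, got {r}")
            if r > self.features_per_mask:
                raise CohortSpecError(
                    f"intrinsic_rank[{m}]: {r} exceeds block width "
                    f"{self.features_per_mask}")
        for m in self.masks:
            for cls in self.classes:
                rate = self.rate_of(m, cls)
                if not 0.0 <= rate <= 1.0:
                    raise CohortSpecError(
                        f"missing_rates[({m}, {cls})]: {rate} outside [0, 1]")
        if not self.noise_sd >= 0:
            raise CohortSpecError(f"noise_sd: must be >= 0, got {self.noise_sd}")

    def to_dict(self) -> dict:
        return {
            "class_counts": dict(self.class_counts),
            "masks": list(self.masks),
            "sequences": list(self.sequences),
            "features_per_combination": self.features_per_combination,
            "intrinsic_rank": (dict(self.intrinsic_rank)
                               if isinstance(self.intrinsic_rank, Mapping)
                               else self.intrinsic_rank),
            "class_effect": dict(self.class_effect),
            "noise_sd": self.noise_sd,
            "missing_rates": (
                None if self.missing_rates is None
                else {f"{m}|{c}": v for (m, c), v in self.missing_rates.items()}),
            "seed": self.seed,
        }


@dataclass
class RadiomicCohort:
    """A samples x features radiomic table with hierarchical column metadata.

    ``features`` holds NaN where a sample's whole mask block is missing;
    ``missing_block[i, j]`` is True iff sample ``i`` is missing mask ``j``
    (in ``masks`` order).  Column ``k`` belongs to
    ``column_meta[k] = (mask, sequence, feature_name)``.
    """

    sample_ids: list[str]
    labels: np.ndarray
    features: np.ndarray
    column_meta: list[tuple[str, str, str]]
    masks: tuple[str, ...]
    sequences: tuple[str, ...]
    missing_block: np.ndarray
    spec: CohortSpec | None = None

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lbl in self.labels:
            if lbl not in seen:
                seen.append(lbl)
        return tuple(seen)

    @property
    def column_names(self) -> list[str]:
        return [f"{m}__{s}__{f}" for m, s, f in self.column_meta]

    def mask_column_indices(self, mask: str) -> np.ndarray:
        idx = [k for k, (m, _, _) in enumerate(self.column_meta) if m == mask]
        return np.asarray(idx, dtype=int)

    def validate_blocks(self) -> None:
        """Check the all-or-none block missingness invariant."""
        for j, mask in enumerate(self.masks):
            cols = self.mask_column_indices(mask)
            nan = np.isnan(self.features[:, cols])
            full = nan.all(axis=1)
            none = ~nan.any(axis=1)
            bad = np.where(~(full | none))[0]
            if bad.size:
                raise ValueError(
                    f"sample {self.sample_ids[bad[0]]}, mask {mask}: "
                    "partially missing block (expected all-or-none)")
            if not np.array_equal(full, self.missing_block[:, j]):
                raise ValueError(f"mask {mask}: missing_block flags do not "
                                 "match NaN pattern")


def generate_cohort(spec: CohortSpec) -> RadiomicCohort:
    """Simulate a cohort under the low-rank Gaussian factor model.

    Deterministic: identical ``spec`` (including seed) yields bit-identical
    output.  Per mask, features are ``W z + eps`` with class-dependent
    latent means; mask blocks are then deleted per the (mask, class)
    missing rates.
    """
    spec.validate()
    classes = spec.classes
    labels = np.concatenate([
        np.repeat(cls, int(spec.class_counts[cls])) for cls in classes
    ]) if spec.n_samples else np.array([], dtype=str)
    n = labels.size
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    d_mask = spec.features_per_mask

    column_meta: list[tuple[str, str, str]] = []
    for m in spec.masks:
        for s in spec.sequences:
            for j in range(spec.features_per_combination):
                column_meta.append((m, s, f"f{j}"))

    features = np.empty((n, spec.n_features), dtype=float)
    class_index = {cls: i for i, cls in enumerate(classes)}
    label_idx = np.array([class_index[c] for c in labels], dtype=int)

    for mi, mask in enumerate(spec.masks):
        rng = np.random.default_rng(derive_seed(spec.seed, "mask", mi))
        r = spec.rank_of(mask)
        # loadings scaled so each feature has ~unit variance from the factors
        W = rng.normal(size=(d_mask, r)) / math.sqrt(r)
        mus = np.empty((len(classes), r))
        for ci, cls in enumerate(classes):
            direction = rng.normal(size=r)
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else direction
            mus[ci] = spec.effect_of(cls) * direction
        Z = mus[label_idx] + rng.standard_normal((n, r))
        block = Z @ W.T + spec.noise_sd * rng.standard_normal((n, d_mask))
        features[:, mi * d_mask:(mi + 1) * d_mask] = block

    # block-wise deletion per (mask, class) rate
    rng_miss = np.random.default_rng(derive_seed(spec.seed, "missing"))
    missing_block = np.zeros((n, len(spec.masks)), dtype=bool)
    u = rng_miss.random((n, len(spec.masks)))
    for mi, mask in enumerate(spec.masks):
        rates = np.array([spec.rate_of(mask, cls) for cls in classes])
        missing_block[:, mi] = u[:, mi] < rates[label_idx]
        rows = np.where(missing_block[:, mi])[0]
        features[np.ix_(rows, np.arange(mi * d_mask, (mi + 1) * d_mask))] = np.nan

    return RadiomicCohort(
        sample_ids=sample_ids,
        labels=labels,
        features=features,
        column_meta=column_meta,
        masks=tuple(spec.masks),
        sequences=tuple(spec.sequences),
        missing_block=missing_block,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Serialization: cohort.csv + cohort.meta.json sidecar
# ---------------------------------------------------------------------------

def write_cohort(cohort: RadiomicCohort, path: str | Path) -> Path:
    """Write ``cohort.csv`` and ``cohort.meta.json`` into directory ``path``.

    Missing cells are written as empty CSV fields; floats use shortest
    round-trip representation so a read-back is value-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cohort.features, columns=cohort.column_names)
    df.insert(0, "label", cohort.labels)
    df.insert(0, "sample_id", cohort.sample_ids)
    df.to_csv(path / "cohort.csv", index=False)
    meta = {
        "masks": list(cohort.masks),
        "sequences": list(cohort.sequences),
        "columns": cohort.column_names,
        "spec": cohort.spec.to_dict() if cohort.spec is not None else None,
        "seed": cohort.spec.seed if cohort.spec is not None else None,
    }
    (path / "cohort.meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _parse_column(name: str) -> tuple[str, str, str]:
    parts = name.split("__")
    if len(parts) != 3:
        raise ValueError(
            f"column '{name}': expected '<mask>__<sequence>__<feature>'")
    return parts[0], parts[1], parts[2]


def read_cohort(path: str | Path) -> RadiomicCohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises ``FileNotFoundError`` if the directory holds no cohort, and
    ``ValueError`` with row/column context on malformed content.
    """
    path = Path(path)
    csv_path = path / "cohort.csv"
    meta_path = path / "cohort.meta.json"
    if not csv_path.exists():
        raise FileNotFoundError(f"no cohort found at {csv_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata sidecar found at {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for required in ("sample_id", "label"):
        if required not in df.columns:
            raise ValueError(f"cohort.csv: missing column '{required}'")
    feature_names = [c for c in df.columns if c not in ("sample_id", "label")]
    if feature_names != meta.get("columns"):
        raise ValueError("cohort.csv feature columns do not match "
                         "cohort.meta.json 'columns'")
    column_meta = [_parse_column(c) for c in feature_names]
    masks = tuple(meta["masks"])
    features = df[feature_names].to_numpy(dtype=float)

    spec = None
    if meta.get("spec"):
        sd = meta["spec"]
        mr = sd.get("missing_rates")
        spec = CohortSpec(
            class_counts=sd["class_counts"],
            masks=tuple(sd["masks"]),
            sequences=tuple(sd["sequences"]),
            features_per_combination=sd["features_per_combination"],
            intrinsic_rank=sd["intrinsic_rank"],
            class_effect=sd["class_effect"],
            noise_sd=sd["noise_sd"],
            missing_rates=(None if mr is None else
                           {tuple(k.split("|")): v for k, v in mr.items()}),
            seed=sd["seed"],
        )

    cohort = RadiomicCohort(
        sample_ids=df["sample_id"].astype(str).tolist(),
        labels=df["label"].to_numpy(dtype=str),
        features=features,
        column_meta=column_meta,
        masks=masks,
        sequences=tuple(meta["sequences"]),
        missing_block=np.zeros((len(df), len(masks)), dtype=bool),
        spec=spec,
    )
    # reconstruct block flags from the NaN pattern, then check the invariant
    for j, mask in enumerate(masks):
        cols = cohort.mask_column_indices(mask)
        if cols.size:
            cohort.missing_block[:, j] = np.isnan(features[:, cols]).all(axis=1)
    cohort.validate_blocks()
    return cohort
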