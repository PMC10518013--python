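"""Feature encoding for Utstein-style records.

Categorical fields are one-hot encoded with an explicit ``missing`` level
(missingness is a category, never imputed).  The three activity times are
one-hot encoded at minute resolution — their relation to prognosis is
non-linear, so minutes become indicator bins 1..t_max plus an overflow bin and,
for interventions that may not happen, a ``no_intervention`` bin.  Selected
continuous variables are z-scored with parameters fitted on training data only;
the prefecture number is either a z-scored continuous column (prefectures are
numbered roughly north to south, so adjacency carries some spatial signal) or a
one-hot block.

A fitted :class:`FeatureSchema` is a frozen description of the whole encoding;
:func:`encode` never refits anything, which is what makes fold-wise encoding
leakage-free.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "missing"

#: categorical fields (one-hot with a "missing" level each)
CATEGORICAL_FIELDS = (
    "sex",
    "onset_month",
    "witnessed",
    "witness_type",
    "bystander_cpr",
    "bystander_ventilation",
    "bystander_defib",
    "ems_witnessed",
    "initial_rhythm",
    "airway_device",
    "rosc",
)

#: default z-scored continuous fields
DEFAULT_ZSCORE_FIELDS = ("age", "onset_year", "time_call_to_contact", "n_defib", "n_drug_doses")

#: time factors: column -> (has a no-intervention state)
TIME_FIELDS = {
    "time_contact_to_hospital": False,
    "time_contact_to_defib": True,
    "time_contact_to_drug": True,
}

DEFAULT_T_MAX = {
    "time_contact_to_hospital": 120,
    "time_contact_to_defib": 60,
    "time_contact_to_drug": 60,
}


@dataclass(frozen=True)
class EncodingOptions:
    prefecture_mode: str = "continuous"  # or "one_hot"
    t_max: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_T_MAX))
    zscore_fields: tuple[str, ...] = DEFAULT_ZSCORE_FIELDS

    def __post_init__(self) -> None:
        if self.prefecture_mode not in ("continuous", "one_hot"):
            raise ValueError(f"unknown prefecture_mode {self.prefecture_mode!r}")


@dataclass(frozen=True)
class TimeSpec:
    t_max: int
    has_no_intervention: bool

    @property
    def n_levels(self) -> int:
        # minute bins 1..t_max, overflow, optionally no_intervention
        return self.t_max + 1 + int(self.has_no_intervention)


@dataclass
class FeatureSchema:
    """Fitted encoding: category lists, minute-bin specs, z-score parameters."""

    categorical_specs: dict[str, list[str]]
    time_specs: dict[str, TimeSpec]
    zscore_params: dict[str, tuple[float, float]]
    prefecture_mode: str
    prefecture_levels: list[int]
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def params_hash(self) -> str:
        """Stable digest of every fitted parameter (leakage guard)."""
        payload = json.dumps(
            {
                "categorical": self.categorical_specs,
                "time": {k: [v.t_max, v.has_no_intervention] for k, v in self.time_specs.items()},
                "zscore": {k: list(v) for k, v in self.zscore_params.items()},
                "prefecture_mode": self.prefecture_mode,
                "prefecture_levels": self.prefecture_levels,
                "feature_names": self.feature_names,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "categorical_specs": self.categorical_specs,
                "time_specs": {
                    k: {"t_max": v.t_max, "has_no_intervention": v.has_no_intervention}
                    for k, v in self.time_specs.items()
                },
                "zscore_params": {k: list(v) for k, v in self.zscore_params.items()},
                "prefecture_mode": self.prefecture_mode,
                "prefecture_levels": self.prefecture_levels,
                "feature_names": self.feature_names,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            categorical_specs=d["categorical_specs"],
            time_specs={
                k: TimeSpec(v["t_max"], v["has_no_intervention"])
                for k, v in d["time_specs"].items()
            },
            zscore_params={k: (v[0], v[1]) for k, v in d["zscore_params"].items()},
            prefecture_mode=d["prefecture_mode"],
            prefecture_levels=[int(x) for x in d["prefecture_levels"]],
            feature_names=list(d["feature_names"]),
        )


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray  # records x features, float64, finite
    row_ids: np.ndarray
    schema_ref: FeatureSchema

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.schema_ref.n_features:
            raise ValueError("column count does not match schema")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")


def _time_level_names(col: str, spec: TimeSpec) -> list[str]:
    names = [f"{col}=min{m}" for m in range(1, spec.t_max + 1)]
    names.append(f"{col}=gt{spec.t_max}")
    if spec.has_no_intervention:
        names.append(f"{col}=no_intervention")
    return names


def fit_schema(table: pd.DataFrame, options: EncodingOptions | None = None) -> FeatureSchema:
    """Fit the encoding on a (filtered) training table.

    Category lists cover the observed levels plus ``missing``; z-score means
    and standard deviations come from this table only.  Raises if a field
    selected for z-scoring has zero variance.
    """
    options = options or EncodingOptions()

    categorical_specs: dict[str, list[str]] = {}
    for col in CATEGORICAL_FIELDS:
        observed = sorted(str(v) for v in table[col].dropna().unique())
        levels = [v for v in observed if v != MISSING] + [MISSING]
        categorical_specs[col] = levels

    time_specs = {
        col: TimeSpec(int(options.t_max[col]), has_none)
        for col, has_none in TIME_FIELDS.items()
    }

    zscore_fields = list(options.zscore_fields)
    if options.prefecture_mode == "continuous":
        zscore_fields.append("prefecture")
    zscore_params: dict[str, tuple[float, float]] = {}
    for col in zscore_fields:
        x = pd.to_numeric(table[col], errors="coerce").to_numpy(float)
        mean, sd = float(np.nanmean(x)), float(np.nanstd(x))
        if sd <= 0:
            raise ValueError(f"field {col!r} has zero variance; cannot z-score")
        zscore_params[col] = (mean, sd)

    prefecture_levels: list[int] = (
        sorted(int(v) for v in table["prefecture"].unique())
        if options.prefecture_mode == "one_hot"
        else []
    )

    # canonical feature order: one-hot groups then continuous, sorted by field
    feature_names: list[str] = []
    for col in sorted(categorical_specs):
        feature_names.extend(f"{col}={lvl}" for lvl in categorical_specs[col])
    if options.prefecture_mode == "one_hot":
        feature_names.extend(f"prefecture={k}" for k in prefecture_levels)
    for col in sorted(time_specs):
        feature_names.extend(_time_level_names(col, time_specs[col]))
    feature_names.extend(f"{col}_z" for col in sorted(zscore_params))

    return FeatureSchema(
        categorical_specs=categorical_specs,
        time_specs=time_specs,
        zscore_params=zscore_params,
        prefecture_mode=options.prefecture_mode,
        prefecture_levels=prefecture_levels,
        feature_names=feature_names,
    )


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def encode(table: pd.DataFrame, schema: FeatureSchema) -> FeatureMatrix:
    """Encode a table with a fitted schema (never refits any parameter).

    Unseen categorical levels map to the ``missing`` level with a warning;
    times above ``t_max`` fall in the overflow bin; an absent intervention
    (NaN time) sets the ``no_intervention`` indicator.
    """
    n = len(table)
    blocks: list[np.ndarray] = []

    for col in sorted(schema.categorical_specs):
        levels = schema.categorical_specs[col]
        idx = {lvl: i for i, lvl in enumerate(levels)}
        missing_code = idx[MISSING]
        values = table[col].astype(str).to_numpy()
        codes = np.array([idx.get(v, -1) for v in values])
        n_unseen = int((codes == -1).sum())
        if n_unseen:
            logger.warning(
                "%d unseen level(s) in %r mapped to the missing category", n_unseen, col
            )
            codes[codes == -1] = missing_code
        blocks.append(_one_hot(codes, len(levels)))

    if schema.prefecture_mode == "one_hot":
        idx = {k: i for i, k in enumerate(schema.prefecture_levels)}
        values = table["prefecture"].astype(int).to_numpy()
        codes = np.array([idx[v] for v in values])
        blocks.append(_one_hot(codes, len(schema.prefecture_levels)))

    for col in sorted(schema.time_specs):
        spec = schema.time_specs[col]
        t = pd.to_numeric(table[col], errors="coerce").to_numpy(float)
        none_mask = np.isnan(t)
        if none_mask.any() and not spec.has_no_intervention:
            raise ValueError(f"{col!r} has absent values but no no-intervention level")
        ti = np.where(none_mask, 1, t).astype(int)
        codes = np.clip(ti, 1, spec.t_max + 1) - 1  # bin t_max is the overflow slot
        if spec.has_no_intervention:
            codes = np.where(none_mask, spec.t_max + 1, codes)
        blocks.append(_one_hot(codes, spec.n_levels))

    for col in sorted(schema.zscore_params):
        mean, sd = schema.zscore_params[col]
        x = pd.to_numeric(table[col], errors="coerce").to_numpy(float)
        blocks.append(((x - mean) / sd).reshape(-1, 1))

    values = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return FeatureMatrix(values=values, row_ids=table.index.to_numpy(), schema_ref=schema)
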