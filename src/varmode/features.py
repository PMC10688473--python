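"""Feature-table preprocessing: encoding, imputation, binning, balancing.

Third-party predictor scores (pathogenicity, conservation, stability, ...)
are ingested as named columns governed by a small schema: each feature is
continuous, categorical or binary and carries a missing-value policy.
Categorical features are ordinally encoded from the training set;
missing values are imputed with a constant (-1) for encoded/binary
features or with the training median for continuous ones.  Zero-variance
training features are dropped from train and test alike.  Class imbalance
is handled by random oversampling of minority classes up to the majority
count — applied to training folds only.  Everything is fitted exclusively
on training data; transform is stateless afterwards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "FittedPreprocessor",
    "fit_preprocessor",
    "transform",
    "oversample",
    "ThresholdRule",
    "MedianSplitRule",
    "categorize",
    "categorize_series",
    "grantham_rule",
    "rsa_rule",
    "probability_rule",
]

KINDS = ("continuous", "categorical", "binary")
POLICIES = ("constant_minus1", "train_median")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str
    missing_policy: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.missing_policy is not None and self.missing_policy not in POLICIES:
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")

    @property
    def policy(self) -> str:
        if self.missing_policy is not None:
            return self.missing_policy
        return "train_median" if self.kind == "continuous" else "constant_minus1"


class FeatureSchema:
    """Ordered collection of feature specs with JSON round-tripping."""

    def __init__(self, specs: list[FeatureSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.specs = list(specs)
        self.by_name = {s.name: s for s in specs}

    def __iter__(self):
        return iter(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    @classmethod
    def infer(cls, table: pd.DataFrame) -> "FeatureSchema":
        """Heuristic schema: object columns categorical, others continuous."""
        specs = []
        for col in table.columns:
            if table[col].dtype == object:
                kind = "categorical"
            elif set(table[col].dropna().unique()) <= {0, 1, True, False}:
                kind = "binary"
            else:
                kind = "continuous"
            specs.append(FeatureSpec(col, kind))
        return cls(specs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.specs], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls([FeatureSpec(**rec) for rec in json.load(fh)])


@dataclass
class FittedPreprocessor:
    category_maps: dict[str, dict[str, int]]
    medians: dict[str, float]
    dropped: list[str]
    feature_order: list[str]
    kinds: dict[str, str]
    policies: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedPreprocessor":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_preprocessor(train: pd.DataFrame, schema: FeatureSchema) -> FittedPreprocessor:
    """Fit encoding/imputation state on the training table only.

    Ordinal maps come from sorted distinct training categories; medians
    ignore missing values; features with zero variance after imputation
    are recorded for dropping from train and test.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    missing_in_schema = [c for c in train.columns if c not in schema]
    extra_in_schema = [s.name for s in schema if s.name not in train.columns]
    if missing_in_schema or extra_in_schema:
        raise ValueError(
            f"schema mismatch: columns without schema {missing_in_schema}; "
            f"schema entries without column {extra_in_schema}"
        )

    category_maps: dict[str, dict[str, int]] = {}
    medians: dict[str, float] = {}
    kinds: dict[str, str] = {}
    policies: dict[str, str] = {}
    for spec in schema:
        kinds[spec.name] = spec.kind
        policies[spec.name] = spec.policy
        col = train[spec.name]
        if spec.kind == "categorical":
            cats = sorted(str(c) for c in col.dropna().unique())
            category_maps[spec.name] = {c: i for i, c in enumerate(cats)}
        if spec.policy == "train_median":
            med = col.dropna().astype(float).median()
            medians[spec.name] = float(med) if not math.isnan(med) else -1.0

    pre = FittedPreprocessor(
        category_maps, medians, dropped=[], feature_order=list(train.columns),
        kinds=kinds, policies=policies,
    )
    encoded = _encode_impute(train, pre)
    pre.dropped = [c for c in encoded.columns if encoded[c].nunique() <= 1]
    pre.feature_order = [c for c in train.columns if c not in pre.dropped]
    return pre


def _encode_impute(table: pd.DataFrame, pre: FittedPreprocessor) -> pd.DataFrame:
    out = {}
    for name in table.columns:
        col = table[name]
        if pre.kinds[name] == "categorical":
            mapping = pre.category_maps[name]
            col = col.map(lambda v: mapping.get(str(v), np.nan) if pd.notna(v) else np.nan)
        col = pd.to_numeric(col, errors="coerce")
        if pre.policies[name] == "train_median":
            fill = pre.medians.get(name, -1.0)
        else:
            fill = -1.0
        out[name] = col.fillna(fill).astype(float)
    return pd.DataFrame(out, index=table.index)


def transform(table: pd.DataFrame, pre: FittedPreprocessor) -> pd.DataFrame:
    """Apply a fitted preprocessor: encode, impute, drop, order columns.

    Unseen categories map to the constant -1 (same path as missing).
    Output is all-numeric with no missing values and a fixed column order.
    """
    missing_cols = [c for c in pre.kinds if c not in table.columns and c not in pre.dropped]
    if missing_cols:
        raise ValueError(f"input lacks expected feature columns: {missing_cols}")
    encoded = _encode_impute(table[[c for c in pre.kinds if c in table.columns]], pre)
    return encoded[pre.feature_order]


def oversample(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    rng: np.random.Generator,
    classes: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Random-oversample minority classes to the majority count.

    Keeps every original row once and appends rows resampled with
    replacement from each minority class.  Training folds only — never
    apply to evaluation data.  When ``classes`` is given, every listed
    class must be present.
    """
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if classes is not None:
        absent = sorted(set(classes) - set(values))
        if absent:
            raise ValueError(f"classes absent from training data: {absent}")
    n_max = counts.max()
    extra_idx = []
    for value, count in zip(values, counts):
        if count < n_max:
            members = np.where(labels == value)[0]
            extra_idx.append(rng.choice(members, size=n_max - count, replace=True))
    idx = np.concatenate([np.arange(len(labels))] + extra_idx) if extra_idx else np.arange(len(labels))
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx].reset_index(drop=True), labels[idx]
    return np.asarray(X)[idx], labels[idx]


# ---------------------------------------------------------------------------
# Categorization rules for enrichment analysis


@dataclass(frozen=True)
class ThresholdRule:
    """value < threshold -> labels[0]; value >= threshold -> labels[1]."""

    threshold: float
    labels: tuple[str, str]


@dataclass(frozen=True)
class MedianSplitRule:
    """value < reference median -> labels[0] ('low'); else labels[1] ('high')."""

    reference_median: float
    labels: tuple[str, str] = ("low", "high")


def grantham_rule() -> ThresholdRule:
    # Substitution severity: below 100 conservative, 100 or above radical.
    return ThresholdRule(100.0, ("conservative", "radical"))


def rsa_rule() -> ThresholdRule:
    return ThresholdRule(0.20, ("buried", "exposed"))


def probability_rule() -> ThresholdRule:
    # Probabilistic scores split at 0.5; 0.5 itself falls on the positive side.
    return ThresholdRule(0.5, ("negative", "positive"))


def categorize(value, rule) -> str:
    """Bin a scalar by a rule; missing values get the 'missing' category."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "missing"
    if isinstance(rule, ThresholdRule):
        return rule.labels[0] if value < rule.threshold else rule.labels[1]
    if isinstance(rule, MedianSplitRule):
        return rule.labels[0] if value < rule.reference_median else rule.labels[1]
    raise TypeError(f"unknown rule type {type(rule)!r}")


def categorize_series(values: pd.Series, rule) -> pd.Series:
    return values.map(lambda v: categorize(v, rule))
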