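"""Typed container for HRV feature tables, CSV I/O and train/test splitting.

The central object is :class:`HRVDataset`: a numeric feature matrix (by
default the nine standard HRV parameters), one integer autonomic-nervous-
system state label per row, and a per-row provenance tag recording whether a
row is an original measurement or was synthesized by in-line or off-line
interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical feature order: time-domain statistics, spectral powers, ratio.
FEATURE_NAMES: tuple[str, ...] = (
    "HR", "SDNN", "rmSSD", "PNN50", "VLF", "LF", "HF", "TSP", "LF/HF",
)

#: The seven autonomic-nervous-system state labels.
LABEL_NAMES: dict[int, str] = {
    1: "Fatigue",
    2: "Sympathetic nervous system disorder",
    3: "Autonomic nervous system excitability",
    4: "Autonomic nervous system balance",
    5: "Dysautonomia",
    6: "Stress",
    7: "Vagus nerve disorder",
}

LABEL_SET: tuple[int, ...] = tuple(sorted(LABEL_NAMES))

PROVENANCE_VALUES: tuple[str, ...] = ("original", "synthetic_inline", "synthetic_offline")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass(frozen=True)
class HRVDataset:
    """Feature matrix + labels + provenance for an HRV cohort.

    Parameters
    ----------
    features
        ``(n_rows, n_features)`` float array; must be finite.
    labels
        ``(n_rows,)`` integer class labels drawn from ``label_set``.
    feature_names
        Ordered column names; defaults to the nine standard HRV parameters.
    provenance
        Per-row tag in ``{"original", "synthetic_inline", "synthetic_offline"}``.
    label_set
        The admissible labels (default 1..7).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    provenance: np.ndarray | None = None
    label_set: tuple[int, ...] = LABEL_SET

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 2:
            raise DatasetError(f"features must be 2-D, got shape {feats.shape}")
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1 or labels.shape[0] != feats.shape[0]:
            raise DatasetError(
                f"labels length {labels.shape} does not match {feats.shape[0]} rows"
            )
        prov = self.provenance
        if prov is None:
            prov = np.full(feats.shape[0], "original", dtype=object)
        else:
            prov = np.asarray(prov, dtype=object)
        if prov.shape[0] != feats.shape[0]:
            raise DatasetError("provenance length does not match row count")
        bad_prov = set(prov) - set(PROVENANCE_VALUES)
        if bad_prov:
            raise DatasetError(f"invalid provenance values: {sorted(bad_prov)}")
        if len(self.feature_names) != feats.shape[1]:
            raise DatasetError(
                f"{len(self.feature_names)} feature names for {feats.shape[1]} columns"
            )
        if feats.size and not np.isfinite(feats).all():
            i, j = np.argwhere(~np.isfinite(feats))[0]
            raise DatasetError(
                f"non-finite feature value at row {i}, column {self.feature_names[j]!r}"
            )
        bad = set(labels) - set(self.label_set)
        if bad:
            raise DatasetError(f"labels outside declared label set: {sorted(bad)}")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", prov)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "label_set", tuple(self.label_set))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        """Rows per label, restricted to labels actually present."""
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def subset(self, indices: np.ndarray) -> "HRVDataset":
        """A new dataset containing the given rows, in the given order."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            provenance=self.provenance[idx],
        )

    def with_features(self, features: np.ndarray) -> "HRVDataset":
        """Same rows and metadata, different feature values."""
        return replace(self, features=np.asarray(features, dtype=float))

    def append_rows(
        self, features: np.ndarray, labels: np.ndarray, provenance: np.ndarray
    ) -> "HRVDataset":
        return replace(
            self,
            features=np.vstack([self.features, np.asarray(features, dtype=float)]),
            labels=np.concatenate([self.labels, np.asarray(labels, dtype=int)]),
            provenance=np.concatenate([self.provenance, np.asarray(provenance, dtype=object)]),
        )

    def equals(self, other: "HRVDataset") -> bool:
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.provenance, other.provenance)
        )


@dataclass(frozen=True)
class SplitSpec:
    """How to carve an 80/20-style train/test partition.

    ``test_fraction`` in (0, 1); ``stratified`` preserves per-class
    proportions (largest-remainder rounding); ``seed`` makes the draw
    reproducible.
    """

    test_fraction: float = 0.2
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0,1), got {self.test_fraction}")


_NAME_TO_LABEL = {name: lab for lab, name in LABEL_NAMES.items()}


def _parse_label(value: object, row: int, column: str) -> int:
    """Accept an integer label or the exact ANS state name."""
    if isinstance(value, str):
        text = value.strip()
        if text in _NAME_TO_LABEL:
            return _NAME_TO_LABEL[text]
        try:
            return int(text)
        except ValueError:
            raise DatasetError(
                f"row {row}: label column {column!r} value {value!r} is neither an "
                f"integer nor a known ANS state name"
            ) from None
    if pd.isna(value):
        raise DatasetError(f"row {row}: missing label in column {column!r}")
    return int(value)


def read_dataset(path, label_column: str = "label") -> HRVDataset:
    """Read a CSV of numeric HRV features plus a label column.

    Any ``provenance`` column written by :func:`write_dataset` is honoured;
    otherwise every row is tagged ``original``. All non-label, non-provenance
    columns must be numeric; a blank or non-numeric cell is reported with its
    row and column.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DatasetError(f"empty file: {path}") from None
    if label_column not in df.columns:
        raise DatasetError(f"label column {label_column!r} not found in {path}")
    labels = np.array(
        [_parse_label(v, i, label_column) for i, v in enumerate(df[label_column])]
    )
    prov = None
    if "provenance" in df.columns:
        prov = df["provenance"].to_numpy(dtype=object)
    feature_cols = [c for c in df.columns if c not in (label_column, "provenance")]
    feats = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise DatasetError(
                f"non-numeric or missing value at row {i}, column {col!r}"
            )
        feats[:, j] = numeric.to_numpy(dtype=float)
    return HRVDataset(
        features=feats,
        labels=labels,
        feature_names=tuple(feature_cols),
        provenance=prov,
    )


def write_dataset(ds: HRVDataset, path, include_provenance: bool = False) -> None:
    """Write the dataset as CSV (17 significant digits, so round-trips are exact)."""
    df = pd.DataFrame(ds.features, columns=list(ds.feature_names))
    df["label"] = ds.labels
    if include_provenance:
        df["provenance"] = ds.provenance
    df.to_csv(path, index=False, float_format="%.17g")


def _test_size(n: int, fraction: float) -> int:
    # ceil with a guard against float fuzz (10*0.2 == 2.0000000000000004)
    return int(math.ceil(round(n * fraction, 9)))


def split_train_test(ds: HRVDataset, spec: SplitSpec) -> tuple[HRVDataset, HRVDataset]:
    """Split into (train, test).

    Test size is ``ceil(n * test_fraction)`` — the convention under which a
    321-participant cohort resampled to 1172 rows splits 937/235 at 20%.
    Stratified mode allocates per-class test counts by largest remainder and
    requires every class to have at least 2 members.
    """
    n = ds.n_samples
    n_test = _test_size(n, spec.test_fraction)
    if n_test < 1 or n - n_test < 1:
        raise ValueError(
            f"test_fraction {spec.test_fraction} leaves an empty partition for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
    else:
        counts = ds.class_counts()
        too_small = [c for c, k in counts.items() if k < 2]
        if too_small:
            raise ValueError(
                f"stratified split requires >=2 members per class; classes {too_small} too small"
            )
        classes = sorted(counts)
        ideal = {c: counts[c] * spec.test_fraction for c in classes}
        base = {c: int(math.floor(ideal[c])) for c in classes}
        short = n_test - sum(base.values())
        # distribute the remainder to the largest fractional parts
        order = sorted(classes, key=lambda c: (ideal[c] - base[c]), reverse=True)
        for c in order[:max(short, 0)]:
            base[c] += 1
        test_parts, train_parts = [], []
        for c in classes:
            rows = np.flatnonzero(ds.labels == c)
            perm = rows[rng.permutation(len(rows))]
            test_parts.append(perm[: base[c]])
            train_parts.append(perm[base[c]:])
        test_idx = np.concatenate(test_parts)
        train_idx = np.concatenate(train_parts)
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))
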