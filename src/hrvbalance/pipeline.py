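"""Standardize → refined SMOTE → refined ENN, with per-class bookkeeping.

Two protocols are offered for combining resampling with a train/test split:

* ``paper_faithful`` resamples the whole dataset first and splits after —
  the simplest flow, but synthetic rows interpolated from what becomes test
  data leak information into training;
* ``leakage_safe`` (the default) splits first and resamples only the
  training partition, so the test set stays all-original.

Interpolation runs in z-score space (per-feature mean 0, population SD 1)
and the optimized dataset is inverted back to raw units, so synthetic rows
are directly comparable with original measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import HRVDataset, SplitSpec, split_train_test
from .enn import EnnConfig, RemovalReport, edit_with_retention
from .smote import SmoteConfig, generate_synthetic


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-score transform z = (x − μ)/σ."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != sigma.shape or mu.ndim != 1:
            raise ValueError("mu and sigma must be matching 1-D arrays")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive for every feature")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


def fit_standardizer(ds: HRVDataset, ddof: int = 0) -> Standardizer:
    """Column means and standard deviations (population SD by default).

    Rejects constant features by name — a zero-variance column cannot be
    z-scored.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    mu = ds.features.mean(axis=0)
    sigma = ds.features.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sigma == 0)
    if len(bad):
        names = [ds.feature_names[j] for j in bad]
        raise ValueError(f"constant feature(s) cannot be standardized: {names}")
    return Standardizer(mu=mu, sigma=sigma)


def apply_standardizer(ds: HRVDataset, s: Standardizer) -> HRVDataset:
    if len(s.mu) != ds.n_features:
        raise ValueError("standardizer dimension does not match dataset")
    return ds.with_features((ds.features - s.mu) / s.sigma)


def invert_standardizer(ds: HRVDataset, s: Standardizer) -> HRVDataset:
    if len(s.mu) != ds.n_features:
        raise ValueError("standardizer dimension does not match dataset")
    return ds.with_features(ds.features * s.sigma + s.mu)


@dataclass(frozen=True)
class ClassCounts:
    original: int
    synthetic_added: int
    removed: int
    final: int


@dataclass(frozen=True)
class ResampleResult:
    """Optimized dataset plus the sample-count ledger of both stages.

    Invariant (checked): per class, final = original + synthetic_added −
    removed, and the finals sum to the dataset's row count.
    """

    dataset: HRVDataset
    per_class_counts: dict[int, ClassCounts]
    mode: str
    smote_config: SmoteConfig
    enn_config: EnnConfig
    removal_report: RemovalReport

    def __post_init__(self) -> None:
        for c, counts in self.per_class_counts.items():
            if counts.final != counts.original + counts.synthetic_added - counts.removed:
                raise AssertionError(f"bookkeeping identity violated for class {c}")
        if sum(v.final for v in self.per_class_counts.values()) != self.dataset.n_samples:
            raise AssertionError("per-class finals do not sum to dataset size")

    def counts_table(self) -> dict[int, dict[str, int]]:
        return {
            int(c): {
                "original": v.original,
                "synthetic_added": v.synthetic_added,
                "removed": v.removed,
                "final": v.final,
            }
            for c, v in sorted(self.per_class_counts.items())
        }


def refined_smote_enn(
    ds: HRVDataset,
    smote_cfg: SmoteConfig | None = None,
    enn_cfg: EnnConfig | None = None,
    mode: str = "standalone",
) -> ResampleResult:
    """Run the full optimization: z-score, oversample, edit, invert."""
    smote_cfg = smote_cfg or SmoteConfig()
    enn_cfg = enn_cfg or EnnConfig()
    if len(ds.class_counts()) < 2:
        raise ValueError("resampling requires at least 2 distinct classes")
    std = fit_standardizer(ds)
    z = apply_standardizer(ds, std)
    augmented = generate_synthetic(z, smote_cfg)
    edited, report = edit_with_retention(augmented, enn_cfg)
    out = invert_standardizer(edited, std)
    # surviving original rows pass through bit-identical (no z-score round-trip)
    kept = report.kept_indices
    original_pos = np.flatnonzero(kept < ds.n_samples)
    feats = out.features.copy()
    feats[original_pos] = ds.features[kept[original_pos]]
    out = out.with_features(feats)

    orig = ds.class_counts()
    aug = augmented.class_counts()
    final = out.class_counts()
    per_class = {}
    for c in sorted(aug):
        o = orig.get(c, 0)
        added = aug[c] - o
        f = final.get(c, 0)
        per_class[int(c)] = ClassCounts(
            original=o, synthetic_added=added, removed=o + added - f, final=f
        )
    return ResampleResult(
        dataset=out,
        per_class_counts=per_class,
        mode=mode,
        smote_config=smote_cfg,
        enn_config=enn_cfg,
        removal_report=report,
    )


def run_protocol(
    ds: HRVDataset,
    mode: str = "leakage_safe",
    split: SplitSpec | None = None,
    smote_cfg: SmoteConfig | None = None,
    enn_cfg: EnnConfig | None = None,
) -> tuple[HRVDataset, HRVDataset, ResampleResult]:
    """Produce (train, test, resample result) under the chosen protocol.

    ``paper_faithful``: resample the whole dataset, then split (synthetic
    rows may land in the test set).  ``leakage_safe``: split first, resample
    the training partition only; the test partition is untouched and
    all-original.
    """
    split = split or SplitSpec()
    if mode == "paper_faithful":
        result = refined_smote_enn(ds, smote_cfg, enn_cfg, mode=mode)
        train, test = split_train_test(result.dataset, split)
    elif mode == "leakage_safe":
        train_raw, test = split_train_test(ds, split)
        result = refined_smote_enn(train_raw, smote_cfg, enn_cfg, mode=mode)
        train = result.dataset
    else:
        raise ValueError(f"unknown protocol mode: {mode!r}")
    return train, test, result
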