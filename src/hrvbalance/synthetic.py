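"""Synthetic HRV cohort generator.

Emulates the structure of a small clinical HRV study: 321 participants, nine
features (seven measured plus two derived), seven autonomic-nervous-system
(ANS) state labels with severely imbalanced counts {63, 6, 9, 195, 12, 24,
12}.  Class-conditional features are drawn log-normally — spectral powers
and time-domain HRV statistics are positive and right-skewed — with a shared
inter-feature correlation structure (SDNN↔rmSSD, rmSSD↔HF, etc.) and
class-specific shifts of the log-means that encode the physiology of each
state directionally (e.g. stress: low SDNN/rmSSD/HF, elevated HR and LF).
The two derived columns respect their definitions: TSP = VLF + LF + HF (up
to configurable relative noise) and LF/HF = LF ÷ HF exactly.

The generator aims at structural realism, not at replicating any particular
cohort's moments; its role is to make every stage of the resampling and
benchmarking machinery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import FEATURE_NAMES, LABEL_NAMES, HRVDataset

#: Generation order of the seven measured (base) features.
BASE_FEATURES: tuple[str, ...] = ("HR", "SDNN", "rmSSD", "PNN50", "VLF", "LF", "HF")

# Log-space population baseline: exp of these ≈ HR 70 bpm, SDNN 45 ms,
# rmSSD 35 ms, PNN50 12 %, VLF 600 / LF 450 / HF 350 ms².
_BASE_LOG_MEAN = np.array([4.25, 3.81, 3.56, 2.48, 6.40, 6.11, 5.86])
# Log-space spread: HR varies little in relative terms, spectral powers a lot.
_BASE_LOG_SD = np.array([0.12, 0.30, 0.35, 0.55, 0.45, 0.45, 0.50])

# Directional class shifts in units of the per-feature log-SD, encoding the
# seven ANS states: columns HR, SDNN, rmSSD, PNN50, VLF, LF, HF.
# The directions carry the physiology; _SHIFT_SCALE sets the default
# between-class separation, chosen so the classes are separable but
# overlapping: an imbalanced no-resampling baseline visibly misses the
# minority states while a balanced training set recovers them.
_SHIFT_SCALE = 2.0
_CLASS_SHIFTS: dict[int, np.ndarray] = {
    1: np.array([-0.8, -0.2, 0.9, 0.7, -0.3, -0.6, 1.0]),   # fatigue: vagal rebound
    2: np.array([-0.5, 0.5, 1.2, 1.0, -0.8, -1.0, 0.8]),    # sympathetic disorder
    3: np.array([0.5, 1.0, 0.8, 0.5, 0.6, 0.8, 0.8]),       # overall excitability
    4: np.zeros(7),                                          # balance: baseline
    5: np.array([0.3, -1.0, -0.8, -0.9, -0.7, -0.7, -0.7]),  # dysautonomia: low HRV
    6: np.array([1.0, -0.9, -1.0, -1.2, 0.2, 0.8, -1.0]),   # stress: sympathetic
    7: np.array([0.6, -0.5, -1.2, -1.3, 0.0, 0.2, -1.3]),   # vagal damage
}

#: Original per-class sample counts of the study cohort being emulated.
DEFAULT_CLASS_COUNTS: dict[int, int] = {1: 63, 2: 6, 3: 9, 4: 195, 5: 12, 6: 24, 7: 12}


def _default_correlation() -> np.ndarray:
    """Shared 7×7 inter-feature correlation (order: BASE_FEATURES)."""
    names = BASE_FEATURES
    r = np.eye(7)
    pairs = {
        ("SDNN", "rmSSD"): 0.70,
        ("rmSSD", "PNN50"): 0.80,
        ("SDNN", "PNN50"): 0.55,
        ("rmSSD", "HF"): 0.60,
        ("PNN50", "HF"): 0.55,
        ("SDNN", "VLF"): 0.50,
        ("SDNN", "LF"): 0.50,
        ("SDNN", "HF"): 0.45,
        ("VLF", "LF"): 0.40,
        ("LF", "HF"): 0.30,
        ("VLF", "HF"): 0.25,
        ("HR", "SDNN"): -0.30,
        ("HR", "rmSSD"): -0.35,
        ("HR", "PNN50"): -0.30,
        ("HR", "HF"): -0.25,
    }
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), v in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


@dataclass(frozen=True)
class ClassProfile:
    """Log-space location/scale and correlation for one ANS state."""

    label: int
    count: int
    log_mean: np.ndarray
    log_sd: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        log_mean = np.asarray(self.log_mean, dtype=float)
        log_sd = np.asarray(self.log_sd, dtype=float)
        corr = np.asarray(self.correlation, dtype=float)
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if np.any(log_sd <= 0):
            raise ValueError("log-space scales must be positive")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError("correlation matrix must be positive definite") from None
        object.__setattr__(self, "log_mean", log_mean)
        object.__setattr__(self, "log_sd", log_sd)
        object.__setattr__(self, "correlation", corr)


@dataclass(frozen=True)
class CohortConfig:
    """Profiles plus global knobs.

    ``overlap`` ≥ 0 shrinks between-class separation: effective shifts are
    divided by (1 + overlap), so 0 keeps the profiles as stated and larger
    values blur the classes.  ``noise_sd`` is the relative noise on the
    spectral-sum identity TSP = VLF + LF + HF.
    """

    profiles: tuple[ClassProfile, ...]
    overlap: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("need at least 2 class profiles")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sum(p.count for p in self.profiles) < 10:
            raise ValueError("total cohort size must be >= 10")
        object.__setattr__(self, "profiles", tuple(self.profiles))


def default_profiles(counts: dict[int, int] | None = None) -> list[ClassProfile]:
    """Seven profiles with the emulated study's class counts and directional
    physiology (e.g. the stress state has lower mean SDNN than balance)."""
    counts = counts or DEFAULT_CLASS_COUNTS
    corr = _default_correlation()
    profiles = []
    for label in sorted(LABEL_NAMES):
        shift = _CLASS_SHIFTS[label]
        profiles.append(
            ClassProfile(
                label=label,
                count=int(counts.get(label, 0)),
                log_mean=_BASE_LOG_MEAN + _SHIFT_SCALE * shift * _BASE_LOG_SD,
                log_sd=_BASE_LOG_SD.copy(),
                correlation=corr,
            )
        )
    return profiles


def default_cohort_config(seed: int = 0, overlap: float = 0.0, noise_sd: float = 0.02) -> CohortConfig:
    return CohortConfig(
        profiles=tuple(default_profiles()), overlap=overlap, noise_sd=noise_sd, seed=seed
    )


def generate_cohort(cfg: CohortConfig) -> HRVDataset:
    """Draw a cohort: correlated log-normal base features per class, then the
    derived TSP and LF/HF columns.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    center = np.mean([p.log_mean for p in cfg.profiles], axis=0)
    shrink = 1.0 / (1.0 + cfg.overlap)
    feats, labels = [], []
    for p in cfg.profiles:
        if p.count == 0:
            continue
        mean = center + (p.log_mean - center) * shrink
        chol = np.linalg.cholesky(p.correlation)
        z = rng.standard_normal((p.count, len(BASE_FEATURES)))
        base = np.exp(mean + (z @ chol.T) * p.log_sd)
        hr, sdnn, rmssd, pnn50, vlf, lf, hf = base.T
        eps = rng.normal(0.0, cfg.noise_sd, size=p.count) if cfg.noise_sd > 0 else 0.0
        tsp = (vlf + lf + hf) * (1.0 + eps)
        ratio = lf / hf
        feats.append(np.column_stack([hr, sdnn, rmssd, pnn50, vlf, lf, hf, tsp, ratio]))
        labels.append(np.full(p.count, p.label))
    return HRVDataset(
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        feature_names=FEATURE_NAMES,
    )


def planted_boundary_cohort(
    n_per_class: int = 20,
    n_planted: int = 3,
    seed: int = 0,
    separation: float = 10.0,
) -> tuple[HRVDataset, np.ndarray]:
    """Two well-separated Gaussian clusters plus mislabeled planted points.

    Clusters carry labels 1 and 2; ``n_planted`` extra points are drawn from
    cluster 1's distribution but labeled 2, so a boundary-flagging routine
    with ground truth can be scored.  Returns (dataset, planted row indices).
    """
    if n_planted >= n_per_class:
        raise ValueError("n_planted must be smaller than n_per_class")
    rng = np.random.default_rng(seed)
    p = len(FEATURE_NAMES)
    mu1 = np.zeros(p)
    mu2 = np.full(p, separation / np.sqrt(p))  # centers separated by `separation`
    c1 = rng.standard_normal((n_per_class, p)) + mu1
    c2 = rng.standard_normal((n_per_class, p)) + mu2
    planted = rng.standard_normal((n_planted, p)) + mu1 if n_planted else np.empty((0, p))
    feats = np.vstack([c1, c2, planted])
    labels = np.concatenate(
        [np.full(n_per_class, 1), np.full(n_per_class, 2), np.full(n_planted, 2)]
    )
    ds = HRVDataset(features=feats, labels=labels, feature_names=FEATURE_NAMES)
    planted_idx = np.arange(2 * n_per_class, 2 * n_per_class + n_planted)
    return ds, planted_idx
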