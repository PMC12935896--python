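"""Refined SMOTE: minority oversampling by in-line and off-line interpolation.

Classic SMOTE synthesizes a minority sample on the segment between a seed
sample x_i and one of its k same-class nearest neighbours x_j.  The refined
variant adds two degrees of freedom:

* **in-line** interpolation allows extrapolation, ``x = x_i + λ (x_j − x_i)``
  with λ drawn from [−1, 1] rather than [0, 1];
* **off-line** interpolation places the synthetic point on the circle (in
  general dimension, a great circle of the sphere) whose diameter is the
  segment x_i–x_j.  By Thales' theorem every such point x satisfies
  ``(x − x_i) · (x − x_j) = 0``, and its distance from x_i is ``d cos θ``
  where d = ‖x_j − x_i‖ and θ ∈ [−π/2, π/2] parameterises the position:
  θ = 0 lands on x_j, θ = ±π/2 on x_i.

The construction is stated in the plane; here it is generalised to any
dimension by drawing a random unit direction orthogonal to x_i→x_j, which
reduces exactly to the planar formula when the data has two features.
All interpolation is meant to run in standardized feature space (see
:mod:`hrvbalance.pipeline`), so distances are not dominated by scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import HRVDataset


@dataclass(frozen=True)
class SmoteConfig:
    """Knobs of the refined SMOTE stage.

    ``per_class_targets`` maps class label -> desired post-oversampling
    count; classes not listed (or a ``None`` mapping) default to the size of
    the largest class.  ``offline_probability`` is the chance each synthetic
    sample uses off-line (circle) rather than in-line (segment)
    interpolation.
    """

    k_neighbors: int = 3
    lambda_range: tuple[float, float] = (-1.0, 1.0)
    theta_range: tuple[float, float] = (-math.pi / 2, math.pi / 2)
    offline_probability: float = 0.5
    per_class_targets: dict[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lambda_range
        if not (-1.0 <= lo <= hi <= 1.0):
            raise ValueError(f"lambda_range must be within [-1, 1], got {self.lambda_range}")
        tlo, thi = self.theta_range
        if not (-math.pi / 2 - 1e-12 <= tlo <= thi <= math.pi / 2 + 1e-12):
            raise ValueError(f"theta_range must be within [-pi/2, pi/2], got {self.theta_range}")
        if not 0.0 <= self.offline_probability <= 1.0:
            raise ValueError("offline_probability must be in [0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def classic_preset(seed: int = 0, per_class_targets: dict[int, int] | None = None) -> SmoteConfig:
    """Classic SMOTE settings: λ ∈ [0, 1], no off-line interpolation."""
    return SmoteConfig(
        lambda_range=(0.0, 1.0),
        offline_probability=0.0,
        per_class_targets=per_class_targets,
        seed=seed,
    )


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two feature vectors of equal length."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def find_same_class_neighbors(ds: HRVDataset, index: int, k: int) -> np.ndarray:
    """Indices of the ``k`` same-class rows nearest to ``ds`` row ``index``.

    The query row itself is excluded; ties in distance are broken by the
    lower row index; the result is in ascending distance order.
    """
    label = ds.labels[index]
    candidates = np.flatnonzero((ds.labels == label))
    candidates = candidates[candidates != index]
    if len(candidates) < k:
        raise ValueError(
            f"class {label} has only {len(candidates) + 1} members; cannot find k={k} neighbors"
        )
    dists = np.linalg.norm(ds.features[candidates] - ds.features[index], axis=1)
    order = np.argsort(dists, kind="stable")  # stable => lower index wins ties
    return candidates[order[:k]]


def inline_interpolate(xi: np.ndarray, xj: np.ndarray, lam: float) -> np.ndarray:
    """Point on the line through xi and xj: ``xi + lam * (xj - xi)``."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"length mismatch: {xi.shape} vs {xj.shape}")
    return xi + lam * (xj - xi)


def offline_interpolate(
    xi: np.ndarray,
    xj: np.ndarray,
    theta: float,
    perp_direction: np.ndarray,
) -> np.ndarray:
    """Point on the Thales circle with diameter xi–xj.

    Returns ``x = xi + d cosθ (cosθ e∥ + sinθ e⊥)`` with d = ‖xj − xi‖,
    e∥ the unit vector xi→xj and e⊥ the supplied unit vector orthogonal to
    it.  Consequences: ‖x − xi‖ = d cosθ, (x − xi)·(x − xj) = 0, θ = 0
    returns xj exactly and θ = ±π/2 returns xi exactly.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    perp = np.asarray(perp_direction, dtype=float)
    if xi.shape != xj.shape or xi.shape != perp.shape:
        raise ValueError("xi, xj and perp_direction must share one shape")
    diff = xj - xi
    d = float(np.linalg.norm(diff))
    if d == 0.0:
        raise ValueError("off-line interpolation undefined for xi == xj")
    e_par = diff / d
    if abs(np.linalg.norm(perp) - 1.0) > 1e-9:
        raise ValueError("perp_direction must have unit norm")
    if abs(float(e_par @ perp)) > 1e-9:
        raise ValueError("perp_direction must be orthogonal to xj - xi")
    if abs(theta) > math.pi / 2 + 1e-12:
        raise ValueError(f"|theta| must be <= pi/2, got {theta}")
    c, s = math.cos(theta), math.sin(theta)
    if abs(abs(theta) - math.pi / 2) < 1e-15:
        return xi.copy()  # cos(pi/2) rounds to ~6e-17; coincidence is exact by definition
    if theta == 0.0:
        return xj.copy()
    return xi + d * c * (c * e_par + s * perp)


def rotate_minus_90(v: np.ndarray) -> np.ndarray:
    """Clockwise quarter turn of a 2-vector — the planar choice of e⊥."""
    v = np.asarray(v, dtype=float)
    if v.shape != (2,):
        raise ValueError("rotate_minus_90 expects a 2-vector")
    return np.array([v[1], -v[0]])


def _random_perp(rng: np.random.Generator, e_par: np.ndarray) -> np.ndarray:
    """Isotropic unit vector orthogonal to ``e_par`` (resamples if degenerate)."""
    p = e_par.shape[0]
    while True:
        v = rng.standard_normal(p)
        v = v - (v @ e_par) * e_par
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def _resolve_targets(ds: HRVDataset, cfg: SmoteConfig) -> dict[int, int]:
    counts = ds.class_counts()
    majority = max(counts.values())
    targets = {c: majority for c in counts}
    if cfg.per_class_targets is not None:
        for c, t in cfg.per_class_targets.items():
            if c not in counts:
                raise ValueError(f"target given for absent class {c}")
            if t < counts[c]:
                raise ValueError(
                    f"target {t} for class {c} is below its current count {counts[c]}"
                )
            targets[c] = int(t)
    return targets


def generate_synthetic(ds: HRVDataset, cfg: SmoteConfig) -> HRVDataset:
    """Append synthetic minority rows until each class reaches its target.

    Seed samples cycle round-robin over the class's rows so every original
    contributes; the partner is drawn uniformly from the seed's k same-class
    nearest neighbours; each sample independently chooses off-line
    interpolation with probability ``offline_probability``, else in-line.
    Original rows are retained unchanged.  Deterministic for a fixed seed.
    """
    targets = _resolve_targets(ds, cfg)
    counts = ds.class_counts()
    rng = np.random.default_rng(cfg.seed)
    new_feats: list[np.ndarray] = []
    new_labels: list[int] = []
    new_prov: list[str] = []
    for c in sorted(targets):
        need = targets[c] - counts[c]
        if need <= 0:
            continue
        rows = np.flatnonzero(ds.labels == c)
        if len(rows) == 1:
            raise ValueError(
                f"class {c} has a single member; no neighbor exists for interpolation"
            )
        k = cfg.k_neighbors
        if k >= len(rows):
            k = len(rows) - 1
            warnings.warn(
                f"class {c}: k_neighbors clamped to {k} (class has {len(rows)} members)",
                stacklevel=2,
            )
        neighbors = {int(i): find_same_class_neighbors(ds, int(i), k) for i in rows}
        lam_lo, lam_hi = cfg.lambda_range
        th_lo, th_hi = cfg.theta_range
        for s in range(need):
            i = int(rows[s % len(rows)])
            xi = ds.features[i]
            j = int(rng.choice(neighbors[i]))
            xj = ds.features[j]
            offline = rng.random() < cfg.offline_probability
            d = np.linalg.norm(xj - xi)
            if offline and d > 1e-12 and ds.n_features >= 2:
                theta = rng.uniform(th_lo, th_hi)
                e_par = (xj - xi) / d
                perp = _random_perp(rng, e_par)
                x = offline_interpolate(xi, xj, theta, perp)
                tag = "synthetic_offline"
            else:
                # duplicate points (d == 0) degrade gracefully to in-line,
                # which then returns xi for any lambda
                lam = rng.uniform(lam_lo, lam_hi)
                x = inline_interpolate(xi, xj, lam)
                tag = "synthetic_inline"
            new_feats.append(x)
            new_labels.append(int(c))
            new_prov.append(tag)
    if not new_feats:
        return ds
    return ds.append_rows(
        np.vstack(new_feats),
        np.asarray(new_labels),
        np.asarray(new_prov, dtype=object),
    )
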