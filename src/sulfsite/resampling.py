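"""Class balancing by interpolation-based oversampling and simple baselines.

The benchmark is heavily imbalanced (roughly 1 sulfenylated cysteine per 7.6
unmodified ones), so minority oversampling is part of the training pipeline.
SMOTE synthesises minority points by linear interpolation
``x_new = x_base + λ·(x_neigh − x_base)`` with λ ~ U[0, 1] and ``x_neigh``
drawn from the k nearest minority neighbours; SVMSMOTE restricts the base
points to the minority-class support vectors of a soft-margin linear SVM, so
new points concentrate near the decision boundary.  Random over-/
under-sampling and NearMiss-1 are provided as baselines.

All methods leave majority rows byte-identical, never delete a minority row
(oversamplers), and are deterministic for a fixed seed.  Resampling operates
on flattened feature vectors; callers reshape back to (21, d) as needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class ResampleConfig:
    method: str = "svmsmote"
    k_neighbors: int = 5
    svm_penalty: float = 2.0
    target_ratio: float = 1.0  # minority:majority after resampling
    seed: int = 0
    #: cap on points used to fit the inner SVC (balanced subsample); the
    #: kernel fit is quadratic in n, interpolation still uses all minority rows
    svm_fit_cap: int = 3000

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.svm_penalty <= 0:
            raise ValueError("svm_penalty must be positive")
        if not (0 < self.target_ratio <= 1):
            raise ValueError("target_ratio must be in (0, 1]")


def _split_classes(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D feature table")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = classes[1], classes[0]  # tie: treat label order
    return X, y, int(minority), int(majority)


def _n_needed(y: np.ndarray, minority: int, majority: int, ratio: float) -> int:
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    return max(0, int(round(ratio * n_maj)) - n_min)


def _interpolate(base: np.ndarray, neigh: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """x_new = x_base + λ·(x_neigh − x_base), λ ∈ [0,1] per synthetic row."""
    return base + lam[:, None] * (neigh - base)


def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest *other* points (k truncated)."""
    k_eff = min(k, len(points) - 1)
    if k_eff < 1:
        raise ValueError("need at least 2 minority points for interpolation")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(points)
    return nn.kneighbors(points, return_distance=False)[:, 1:]


def _generate(X_min: np.ndarray, base_idx: np.ndarray, n_new: int,
              k: int, rng: np.random.Generator,
              lam_override: float | None = None) -> np.ndarray:
    """Synthesise n_new rows from bases in X_min toward k-NN minority neighbours."""
    neigh_idx = _knn_indices(X_min, k)
    bases = rng.choice(base_idx, size=n_new, replace=True)
    pick = rng.integers(0, neigh_idx.shape[1], size=n_new)
    neighbors = neigh_idx[bases, pick]
    lam = (np.full(n_new, lam_override) if lam_override is not None
           else rng.random(n_new))
    return _interpolate(X_min[bases], X_min[neighbors], lam)


def smote(X, y, config: ResampleConfig | None = None, *,
          lam_override: float | None = None):
    """Plain SMOTE: interpolate from random minority bases toward k-NN neighbours.

    ``lam_override`` pins the interpolation proportion (testing hook for the
    λ = 0 / λ = 1 / λ = 0.5 identities).
    """
    config = config or ResampleConfig(method="smote")
    X, y, mino, majo = _split_classes(X, y)
    n_new = _n_needed(y, mino, majo, config.target_ratio)
    if n_new == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed)
    X_min = X[y == mino]
    synth = _generate(X_min, np.arange(len(X_min)), n_new,
                      config.k_neighbors, rng, lam_override)
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(n_new, mino, dtype=y.dtype)]))


def svmsmote(X, y, config: ResampleConfig | None = None, *,
             lam_override: float | None = None):
    """SVMSMOTE: interpolation bases restricted to minority support vectors.

    A soft-margin linear SVC (penalty C = ``svm_penalty``) is fitted on both
    classes; the minority-class support vectors seed the interpolation
    toward their k nearest minority neighbours until the classes balance.
    Falls back to plain SMOTE (with a warning) if no minority support vector
    is found.
    """
    config = config or ResampleConfig(method="svmsmote")
    X, y, mino, majo = _split_classes(X, y)
    n_new = _n_needed(y, mino, majo, config.target_ratio)
    if n_new == 0:
        return X.copy(), y.copy()
    if (y == mino).sum() < 2:
        raise ValueError("need at least 2 minority samples")
    rng = np.random.default_rng(config.seed)

    fit_idx = np.arange(len(y))
    if len(y) > config.svm_fit_cap:
        per_class = config.svm_fit_cap // 2
        parts = []
        for cls in (mino, majo):
            cls_idx = np.flatnonzero(y == cls)
            take = min(per_class, len(cls_idx))
            parts.append(rng.choice(cls_idx, size=take, replace=False))
        fit_idx = np.sort(np.concatenate(parts))
    svc = SVC(kernel="linear", C=config.svm_penalty)
    svc.fit(X[fit_idx], y[fit_idx])
    support = fit_idx[svc.support_]
    min_sv_global = support[y[support] == mino]

    min_idx_global = np.flatnonzero(y == mino)
    X_min = X[min_idx_global]
    if len(min_sv_global) == 0:
        logger.warning("no minority support vectors found; falling back to SMOTE")
        base_idx = np.arange(len(X_min))
    else:
        pos_in_min = {g: i for i, g in enumerate(min_idx_global)}
        base_idx = np.array([pos_in_min[g] for g in min_sv_global])
    synth = _generate(X_min, base_idx, n_new, config.k_neighbors, rng, lam_override)
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(n_new, mino, dtype=y.dtype)]))


def random_over(X, y, config: ResampleConfig | None = None):
    """Duplicate uniformly-drawn minority rows until the classes balance."""
    config = config or ResampleConfig(method="random_over")
    X, y, mino, majo = _split_classes(X, y)
    n_new = _n_needed(y, mino, majo, config.target_ratio)
    if n_new == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed)
    picks = rng.choice(np.flatnonzero(y == mino), size=n_new, replace=True)
    return (np.vstack([X, X[picks]]),
            np.concatenate([y, np.full(n_new, mino, dtype=y.dtype)]))


def random_under(X, y, config: ResampleConfig | None = None):
    """Drop uniformly-drawn majority rows until the classes balance."""
    config = config or ResampleConfig(method="random_under")
    X, y, mino, majo = _split_classes(X, y)
    rng = np.random.default_rng(config.seed)
    n_keep = int(round((y == mino).sum() / config.target_ratio))
    maj_idx = np.flatnonzero(y == majo)
    keep_maj = np.sort(rng.choice(maj_idx, size=min(n_keep, len(maj_idx)),
                                  replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(y == mino), keep_maj]))
    return X[keep], y[keep]


def nearmiss1(X, y, config: ResampleConfig | None = None):
    """NearMiss-1: keep majority rows closest (on average) to their k nearest
    minority neighbours."""
    config = config or ResampleConfig(method="nearmiss1")
    X, y, mino, majo = _split_classes(X, y)
    X_min = X[y == mino]
    maj_idx = np.flatnonzero(y == majo)
    k = min(config.k_neighbors, len(X_min))
    nn = NearestNeighbors(n_neighbors=k).fit(X_min)
    dists, _ = nn.kneighbors(X[maj_idx])
    mean_d = dists.mean(axis=1)
    n_keep = int(round((y == mino).sum() / config.target_ratio))
    n_keep = min(n_keep, len(maj_idx))
    order = np.argsort(mean_d, kind="stable")[:n_keep]
    keep = np.sort(np.concatenate([np.flatnonzero(y == mino), maj_idx[order]]))
    return X[keep], y[keep]


_METHODS = {
    "smote": smote,
    "svmsmote": svmsmote,
    "random_over": random_over,
    "random_under": random_under,
    "nearmiss1": nearmiss1,
}


def resample(X, y, config: ResampleConfig):
    """Dispatch on ``config.method`` ('none' returns the input unchanged)."""
    if config.method in (None, "none"):
        return np.asarray(X, dtype=np.float64).copy(), np.asarray(y).astype(int)
    try:
        fn = _METHODS[config.method]
    except KeyError:
        raise ValueError(f"unknown resampling method '{config.method}'") from None
    return fn(X, y, config)
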