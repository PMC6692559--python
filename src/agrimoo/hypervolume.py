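"""Hypervolume indicators (minimization convention).

Exact sweep for two objectives; deterministic Monte-Carlo estimate for
higher dimension, used only for convergence monitoring and for ratio
comparisons where both fronts share the same sampling box.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hypervolume_2d", "hypervolume_monte_carlo", "hypervolume"]


def hypervolume_2d(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume of a 2-objective point set w.r.t. ``ref``.

    Points at or beyond the reference point contribute nothing.
    """
    points = np.asarray(points, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("hypervolume_2d expects an (n, 2) array")
    mask = np.all(points < ref, axis=1)
    points = points[mask]
    if len(points) == 0:
        return 0.0
    order = np.lexsort((points[:, 1], points[:, 0]))
    points = points[order]
    hv = 0.0
    best_y = np.inf
    xs, ys = [], []
    for x, y in points:
        if y < best_y:
            xs.append(x)
            ys.append(y)
            best_y = y
    xs.append(ref[0])
    for i in range(len(ys)):
        hv += (xs[i + 1] - xs[i]) * (ref[1] - ys[i])
    return float(hv)


def hypervolume_monte_carlo(
    points: np.ndarray,
    ref: np.ndarray,
    lower: np.ndarray | None = None,
    n_samples: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo hypervolume estimate for any number of objectives.

    Samples uniformly in the box ``[lower, ref]`` (``lower`` defaults to
    the per-objective minimum of ``points``) and returns the dominated
    fraction times the box volume. Deterministic given ``rng``; for
    ratio comparisons pass the same box and sample count to both sides.
    """
    points = np.asarray(points, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if lower is None:
        lower = points.min(axis=0)
    lower = np.asarray(lower, dtype=float)
    if np.any(lower >= ref):
        raise ValueError("lower bound must be strictly below the reference point")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    samples = rng.uniform(lower, ref, size=(n_samples, len(ref)))
    dominated = np.zeros(n_samples, dtype=bool)
    # chunk over points to bound memory
    for start in range(0, len(points), 256):
        block = points[start : start + 256]
        dominated |= np.any(np.all(samples[None, :, :] >= block[:, None, :], axis=2), axis=0)
        if dominated.all():
            break
    volume = float(np.prod(ref - lower))
    return volume * float(dominated.mean())


def hypervolume(
    points: np.ndarray,
    ref: np.ndarray,
    n_samples: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Exact for 2 objectives, Monte-Carlo otherwise."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        return hypervolume_2d(points, ref)
    return hypervolume_monte_carlo(points, ref, n_samples=n_samples, rng=rng)
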