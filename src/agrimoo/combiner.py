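"""Stage-2 landscape combination.

Given one Pareto frontier per land unit (soil), choose a point index per
unit so that the equal-area arithmetic means of the objectives are
Pareto-optimal. Indices are categorical, so the search is a plain
NSGA-II over integer genomes (uniform crossover, random-reset mutation)
without differential evolution. An exhaustive enumerator provides an
exact oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moo import Frontier, _sort_minimized, _to_minimized, crowding_distance

__all__ = [
    "CombinedAssignment",
    "CombinerConfig",
    "mean_combine",
    "run_combiner",
    "brute_force_combine",
]


@dataclass(frozen=True)
class CombinedAssignment:
    """One frontier index per land unit plus the combined objectives."""

    indices: tuple[int, ...]
    combined: np.ndarray


@dataclass(frozen=True)
class CombinerConfig:
    pop_size: int = 1000
    n_generations: int = 60
    crossover_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")


def mean_combine(points) -> np.ndarray:
    """Elementwise arithmetic mean of one objective vector per unit."""
    arrays = [np.asarray(p, dtype=float) for p in points]
    if not arrays:
        raise ValueError("mean_combine: no points")
    m = arrays[0].shape
    if any(a.shape != m for a in arrays):
        raise ValueError("mean_combine: mismatched objective sets")
    return np.mean(arrays, axis=0)


def _check_frontiers(frontiers: list[Frontier]) -> np.ndarray:
    if len(frontiers) < 1:
        raise ValueError("at least one frontier required")
    for i, f in enumerate(frontiers):
        if len(f) == 0:
            raise ValueError(f"frontier {i} is empty")
    directions = np.asarray(frontiers[0].directions)
    for f in frontiers:
        if not np.array_equal(np.asarray(f.directions), directions):
            raise ValueError("frontiers disagree on objective directions")
    return directions


def _combined_objectives(frontiers: list[Frontier], indices: np.ndarray) -> np.ndarray:
    """Mean objectives for an (n, n_units) integer index array."""
    total = np.zeros((len(indices), frontiers[0].objectives.shape[1]))
    for u, f in enumerate(frontiers):
        total += f.objectives[indices[:, u]]
    return total / len(frontiers)


def run_combiner(
    frontiers: list[Frontier], config: CombinerConfig = CombinerConfig()
) -> list[CombinedAssignment]:
    """Categorical NSGA-II search over per-unit frontier indices.

    Sites are assumed independent: combined objectives depend only on
    the chosen per-unit points. Returns the deduplicated rank-0 set of
    assignments. Deterministic given ``config.seed``.
    """
    directions = _check_frontiers(frontiers)
    sizes = np.array([len(f) for f in frontiers])
    n_units = len(frontiers)
    rng = np.random.default_rng(config.seed)

    if n_units == 1:
        # identity: the combined frontier is the unit's own frontier
        return [
            CombinedAssignment((i,), frontiers[0].objectives[i].copy())
            for i in range(sizes[0])
        ]

    n = config.pop_size
    pop = rng.integers(0, sizes, size=(n, n_units))
    pop_min = _to_minimized(_combined_objectives(frontiers, pop), directions)

    for _ in range(config.n_generations):
        fronts, ranks = _sort_minimized(pop_min)
        crowd = np.zeros(n)
        for front in fronts:
            crowd[front] = crowding_distance(pop_min[front])
        # binary tournament on (rank, crowding)
        a = rng.integers(0, n, size=n)
        b = rng.integers(0, n, size=n)
        better = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] >= crowd[b]))
        parents = np.where(better, a, b)
        children = pop[parents].copy()
        # uniform crossover between consecutive parent pairs
        do_cx = rng.random(n // 2) < config.crossover_prob
        mask = rng.random((n // 2, n_units)) < 0.5
        p1 = children[0::2][: n // 2]
        p2 = children[1::2][: n // 2]
        swap = mask & do_cx[:, None]
        p1_new = np.where(swap, p2, p1)
        p2_new = np.where(swap, p1, p2)
        children[0::2][: n // 2] = p1_new
        children[1::2][: n // 2] = p2_new
        # random-reset mutation, expected one gene per child
        mut = rng.random((n, n_units)) < (1.0 / n_units)
        resets = rng.integers(0, sizes, size=(n, n_units))
        children = np.where(mut, resets, children)

        child_min = _to_minimized(_combined_objectives(frontiers, children), directions)
        pool = np.vstack([pop, children])
        pool_min = np.vstack([pop_min, child_min])
        keep = _nsga_truncate(pool_min, n)
        pop = pool[keep]
        pop_min = pool_min[keep]

    fronts, _ = _sort_minimized(pop_min)
    front0 = pop[fronts[0]]
    uniq, uidx = np.unique(front0, axis=0, return_index=True)
    combined = _combined_objectives(frontiers, uniq)
    order = np.lexsort(combined.T[::-1])
    return [
        CombinedAssignment(tuple(int(v) for v in uniq[i]), combined[i].copy())
        for i in order
    ]


def _nsga_truncate(minimized: np.ndarray, pop_size: int) -> np.ndarray:
    fronts, _ = _sort_minimized(minimized)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= pop_size:
            chosen.extend(front.tolist())
            if len(chosen) == pop_size:
                break
            continue
        cd = crowding_distance(minimized[front])
        order = np.argsort(-cd, kind="stable")
        chosen.extend(front[order[: pop_size - len(chosen)]].tolist())
        break
    return np.array(chosen, dtype=int)


def brute_force_combine(
    frontiers: list[Frontier], cap: int = 1_000_000
) -> tuple[list[CombinedAssignment], int]:
    """Enumerate every index combination and return the exact non-dominated set.

    Also reports the Cartesian-product size. Refuses instances whose
    product exceeds ``cap``.
    """
    directions = _check_frontiers(frontiers)
    sizes = [len(f) for f in frontiers]
    product_size = int(np.prod(sizes))
    if product_size > cap:
        raise ValueError(
            f"product size {product_size} exceeds cap {cap}; refusing to enumerate"
        )
    grids = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
    indices = np.stack([g.ravel() for g in grids], axis=1)
    combined = _combined_objectives(frontiers, indices)
    minimized = _to_minimized(combined, directions)

    keep = _pareto_filter(minimized)
    kept = indices[keep]
    kept_obj = combined[keep]
    order = np.lexsort(kept_obj.T[::-1])
    return (
        [
            CombinedAssignment(tuple(int(v) for v in kept[i]), kept_obj[i].copy())
            for i in order
        ],
        product_size,
    )


def _pareto_filter(minimized: np.ndarray) -> np.ndarray:
    """Indices of the non-dominated subset (archive sweep, independent of
    the front-peeling sorter)."""
    n = len(minimized)
    order = np.lexsort(minimized.T[::-1])
    kept: list[int] = []
    kept_vals: list[np.ndarray] = []
    for idx in order:
        p = minimized[idx]
        if kept_vals:
            arr = np.asarray(kept_vals)
            dominated = np.any(np.all(arr <= p, axis=1) & np.any(arr < p, axis=1))
            if dominated:
                continue
        kept.append(idx)
        kept_vals.append(p)
    return np.array(sorted(kept), dtype=int)
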