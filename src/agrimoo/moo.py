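"""Hybrid multi-objective optimizer.

NSGA-II machinery (fast non-dominated sorting, crowding distance,
crowded elitist truncation) with differential-evolution variation
(rand/1/bin) over box-bounded numeric genomes. Includes sparse-aware
population seeding for the management genome, archive trimming to a
fixed frontier size, and per-generation hypervolume logging.

All operations are direction-aware: a ``directions`` vector of +1
(maximize) / -1 (minimize) entries accompanies every objective array.
Internally objectives are converted to minimization form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hypervolume import hypervolume
from .surrogate import (
    GENOME_LENGTH,
    MAX_FYM_AMOUNT,
    MAX_FYM_WEEKS,
    MAX_N_RATE,
    N_APPLICATIONS,
    ManagementPlan,
    ValidationError,
    management_bounds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "OptimizerConfig",
    "Frontier",
    "EvolveResult",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "de_trial_vector",
    "random_management_population",
    "seed_initial_population",
    "evolve",
    "trim_frontier",
]

_WORST = 1e18  # minimized-space penalty for failed evaluations


@dataclass
class Individual:
    """One population member: genome, raw objectives, NSGA-II bookkeeping."""

    genome: np.ndarray
    objectives: np.ndarray
    rank: int = -1
    crowding: float = 0.0


@dataclass(frozen=True)
class OptimizerConfig:
    pop_size: int = 100
    n_generations: int = 1500
    de_F: float = 0.8
    de_CR: float = 0.9
    seed: int = 0
    archive_size: int = 100
    sparse_seed_fraction: float = 0.5
    hv_every: int = 10
    hv_samples: int = 2048
    # optional hypervolume-stagnation early stop (None disables)
    hv_stagnation_window: int | None = None
    hv_stagnation_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValidationError("pop_size must be >= 4 (DE needs 3 donors + target)")
        if not (0.0 <= self.sparse_seed_fraction <= 0.5):
            raise ValidationError("sparse_seed_fraction must lie in [0, 0.5]")


@dataclass(frozen=True)
class Frontier:
    """A mutually non-dominated set of (genome, objectives) points."""

    genomes: np.ndarray
    objectives: np.ndarray
    directions: np.ndarray
    crowding: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class EvolveResult:
    frontier: Frontier
    history: list[dict] = field(default_factory=list)
    population_genomes: np.ndarray | None = None
    population_objectives: np.ndarray | None = None


def _to_minimized(objectives: np.ndarray, directions: np.ndarray) -> np.ndarray:
    sign = np.where(np.asarray(directions) > 0, -1.0, 1.0)
    return np.asarray(objectives, dtype=float) * sign


def dominates(a, b, directions) -> bool:
    """Standard Pareto dominance: a no worse everywhere, better somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    directions = np.asarray(directions)
    if a.shape != b.shape or a.shape != directions.shape:
        raise ValueError("objective vectors and directions must have equal length")
    am = _to_minimized(a, directions)
    bm = _to_minimized(b, directions)
    return bool(np.all(am <= bm) and np.any(am < bm))


def _sort_minimized(minimized: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    n = len(minimized)
    le = np.all(minimized[:, None, :] <= minimized[None, :, :], axis=2)
    lt = np.any(minimized[:, None, :] < minimized[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    rank = 0
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dominators == 0))
        if len(front) == 0:  # cannot happen for a finite partial order
            front = np.flatnonzero(remaining)
        ranks[front] = rank
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - dom[front].sum(axis=0)
        rank += 1
    return fronts, ranks


def fast_nondominated_sort(objectives, directions) -> tuple[list[np.ndarray], np.ndarray]:
    """Partition points into Pareto fronts F0, F1, ...

    Returns ``(fronts, ranks)`` where each front is an index array and
    ``ranks[i]`` is the front index of point ``i``.
    """
    objectives = np.atleast_2d(np.asarray(objectives, dtype=float))
    if len(objectives) == 0:
        raise ValueError("population must be non-empty")
    return _sort_minimized(_to_minimized(objectives, directions))


def crowding_distance(objectives) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Boundary points along each objective get +inf; interior points
    accumulate range-normalized neighbour gaps. Objectives with zero
    spread contribute nothing. Stable sorting makes ties deterministic.
    """
    objectives = np.atleast_2d(np.asarray(objectives, dtype=float))
    n, m = objectives.shape
    d = np.zeros(n)
    if n <= 2:
        d[:] = np.inf
        return d
    for j in range(m):
        vals = objectives[:, j]
        order = np.argsort(vals, kind="stable")
        d[order[0]] = np.inf
        d[order[-1]] = np.inf
        spread = vals[order[-1]] - vals[order[0]]
        if spread > 0:
            interior = order[1:-1]
            gaps = (vals[order[2:]] - vals[order[:-2]]) / spread
            finite = np.isfinite(d[interior])
            d[interior] = np.where(finite, d[interior] + gaps, d[interior])
    return d


def de_trial_vector(
    target_index: int,
    genomes: np.ndarray,
    config: OptimizerConfig,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    integer_mask: np.ndarray | None = None,
) -> np.ndarray:
    """rand/1/bin trial: donor = x_r1 + F (x_r2 - x_r3), binomial crossover.

    One donor gene is always inherited; out-of-bound genes are clipped
    and integer genes rounded after variation.
    """
    n, d = genomes.shape
    if n < 4:
        raise ValueError("population too small for DE (need >= 4)")
    choices = [i for i in range(n) if i != target_index]
    r1, r2, r3 = rng.choice(choices, size=3, replace=False)
    donor = genomes[r1] + config.de_F * (genomes[r2] - genomes[r3])
    cross = rng.random(d) < config.de_CR
    cross[rng.integers(d)] = True
    trial = np.where(cross, donor, genomes[target_index])
    trial = np.clip(trial, lower, upper)
    if integer_mask is not None and integer_mask.any():
        trial[integer_mask] = np.round(trial[integer_mask])
    return trial


def random_management_population(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random management genomes within bounds."""
    genomes = np.empty((n, GENOME_LENGTH))
    genomes[:, :N_APPLICATIONS] = rng.uniform(0, MAX_N_RATE, size=(n, N_APPLICATIONS))
    genomes[:, N_APPLICATIONS] = rng.uniform(0, MAX_FYM_AMOUNT, size=n)
    genomes[:, N_APPLICATIONS + 1] = rng.integers(0, MAX_FYM_WEEKS + 1, size=n)
    return genomes


def seed_initial_population(
    config: OptimizerConfig,
    user_seeds: list[ManagementPlan] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial management population: user seeds, sparse members, randoms.

    Sparse members carry 6-8 zero N-application genes (count and
    positions uniform at random) to make low-application plans reachable;
    their share of the population is ``sparse_seed_fraction`` (<= 0.5).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    user_seeds = user_seeds or []
    for plan in user_seeds:
        plan.validate()
    n_user = len(user_seeds)
    if n_user > config.pop_size:
        raise ValidationError("more user seeds than population slots")
    n_sparse = min(int(round(config.sparse_seed_fraction * config.pop_size)),
                   config.pop_size - n_user)
    n_random = config.pop_size - n_user - n_sparse

    genomes = np.empty((config.pop_size, GENOME_LENGTH))
    row = 0
    for plan in user_seeds:
        genomes[row] = plan.to_genome()
        row += 1
    for _ in range(n_sparse):
        g = random_management_population(1, rng)[0]
        n_zero = rng.integers(6, 9)  # 6, 7 or 8
        zero_pos = rng.choice(N_APPLICATIONS, size=n_zero, replace=False)
        g[zero_pos] = 0.0
        genomes[row] = g
        row += 1
    if n_random:
        genomes[row:] = random_management_population(n_random, rng)
    return genomes


def _evaluate_genomes(evaluate, genomes, directions, sign) -> np.ndarray:
    m = len(directions)
    out = np.empty((len(genomes), m))
    for i, g in enumerate(genomes):
        try:
            out[i] = np.asarray(evaluate(g), dtype=float)
        except Exception:  # noqa: BLE001 - documented worst-objective policy
            logger.warning("evaluation failed for genome %s; assigning worst objectives", g)
            out[i] = _WORST * sign
    return out


def _truncate(minimized: np.ndarray, pop_size: int) -> np.ndarray:
    """NSGA-II environmental selection: fill by front, break by crowding."""
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
        need = pop_size - len(chosen)
        chosen.extend(front[order[:need]].tolist())
        break
    return np.array(chosen, dtype=int)


def evolve(
    evaluate,
    directions,
    config: OptimizerConfig,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    integer_mask: np.ndarray | None = None,
    init_genomes: np.ndarray | None = None,
) -> EvolveResult:
    """Run the hybrid NSGA-II/DE loop and return the trimmed frontier.

    ``evaluate`` maps a genome to raw objective values on the scale given
    by ``directions``. Bounds default to the management genome's. Each
    generation builds one DE trial per member, pools parents and trials,
    and truncates by non-dominated rank and crowding. The rank-0 set of
    the final population, trimmed to ``config.archive_size``, is returned
    together with a per-generation history (front size, best-per-objective
    values, periodic hypervolume of the current front).
    """
    directions = np.asarray(directions)
    sign = np.where(directions > 0, -1.0, 1.0)
    if lower is None or upper is None:
        lo, up, imask = management_bounds()
        lower = lo if lower is None else lower
        upper = up if upper is None else upper
        integer_mask = imask if integer_mask is None else integer_mask
    rng = np.random.default_rng(config.seed)

    if init_genomes is None:
        d = len(lower)
        genomes = rng.uniform(lower, upper, size=(config.pop_size, d))
        if integer_mask is not None and integer_mask.any():
            genomes[:, integer_mask] = np.round(genomes[:, integer_mask])
    else:
        genomes = np.array(init_genomes, dtype=float)
        if len(genomes) != config.pop_size:
            raise ValidationError(
                f"init_genomes has {len(genomes)} rows, expected pop_size={config.pop_size}"
            )

    minimized = _to_minimized(_evaluate_genomes(evaluate, genomes, directions, sign), directions)
    # fixed hypervolume reference from the initial population
    span = minimized.max(axis=0) - minimized.min(axis=0)
    hv_ref = minimized.max(axis=0) + 0.05 * np.where(span > 0, span, 1.0) + 1e-12
    hv_rng = np.random.default_rng(config.seed + 0x5EED)

    history: list[dict] = []
    recent_hv: list[float] = []
    for gen in range(config.n_generations):
        trials = np.empty_like(genomes)
        for i in range(len(genomes)):
            trials[i] = de_trial_vector(i, genomes, config, rng, lower, upper, integer_mask)
        trial_min = _to_minimized(
            _evaluate_genomes(evaluate, trials, directions, sign), directions
        )
        pool_genomes = np.vstack([genomes, trials])
        pool_min = np.vstack([minimized, trial_min])
        keep = _truncate(pool_min, config.pop_size)
        genomes = pool_genomes[keep]
        minimized = pool_min[keep]

        fronts, _ = _sort_minimized(minimized)
        front0 = fronts[0]
        record: dict = {
            "generation": gen,
            "front_size": int(len(front0)),
            "best_minimized": minimized.min(axis=0).tolist(),
        }
        if config.hv_every and (gen % config.hv_every == 0 or gen == config.n_generations - 1):
            pts = minimized[front0]
            pts = pts[np.all(pts < hv_ref, axis=1)]
            hv = (
                hypervolume(pts, hv_ref, n_samples=config.hv_samples, rng=hv_rng)
                if len(pts)
                else 0.0
            )
            record["hypervolume"] = hv
            recent_hv.append(hv)
            logger.info("gen %d: front=%d hv=%.6g", gen, len(front0), hv)
            if (
                config.hv_stagnation_window
                and len(recent_hv) > config.hv_stagnation_window
            ):
                window = recent_hv[-config.hv_stagnation_window - 1 :]
                if abs(window[-1] - window[0]) <= config.hv_stagnation_tol * max(
                    abs(window[0]), 1e-12
                ):
                    history.append(record)
                    logger.info("hypervolume stagnated at generation %d; stopping", gen)
                    break
        history.append(record)

    fronts, _ = _sort_minimized(minimized)
    front0 = fronts[0]
    frontier = Frontier(
        genomes=genomes[front0].copy(),
        objectives=(minimized[front0] * sign).copy(),
        directions=directions,
        crowding=crowding_distance(minimized[front0]),
    )
    frontier = trim_frontier(frontier, config.archive_size)
    return EvolveResult(
        frontier=frontier,
        history=history,
        population_genomes=genomes,
        population_objectives=minimized * sign,
    )


def trim_frontier(frontier: Frontier, archive_size: int) -> Frontier:
    """Trim a frontier to ``archive_size`` points by crowding.

    Iteratively removes the point with the lowest (finite) crowding
    distance, recomputing distances after each removal so boundary
    points are never dropped while interior points remain.
    """
    if len(frontier) <= archive_size:
        return frontier
    minimized = _to_minimized(frontier.objectives, frontier.directions)
    keep = np.arange(len(frontier))
    while len(keep) > archive_size:
        cd = crowding_distance(minimized[keep])
        finite = np.isfinite(cd)
        drop_local = int(np.argmin(cd)) if not finite.any() else int(
            np.flatnonzero(finite)[np.argmin(cd[finite])]
        )
        keep = np.delete(keep, drop_local)
    cd = crowding_distance(minimized[keep])
    return Frontier(
        genomes=frontier.genomes[keep].copy(),
        objectives=frontier.objectives[keep].copy(),
        directions=frontier.directions,
        crowding=cd,
    )
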