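"""End-to-end pipeline: per-soil optimization, landscape combination,
strategy clustering and figure-data export.

Every run is reproducible from its config and seeds alone; all artifacts
are plain CSV/JSON and a run manifest records the configuration hash,
seeds, package/library versions and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import DEFAULT_CALIBRATION, load_calibration
from .clusters import (
    cluster_histograms,
    cluster_strategies,
    features_matrix,
    flag_profitable_points,
    rank_clusters_by_profit,
    summarize_plan,
)
from .combiner import CombinerConfig, run_combiner
from .moo import Frontier, OptimizerConfig, evolve, seed_initial_population
from .objectives import (
    DIRECTIONS,
    MINIMIZED,
    OBJECTIVE_NAMES,
    EconomicParams,
    evaluate_plan,
)
from .surrogate import (
    GENOME_NAMES,
    ManagementPlan,
    SoilProfile,
    ValidationError,
    WeatherSeries,
    load_soils,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "PipelineConfig",
    "run_pipeline",
    "optimize_soil",
    "combine_stage",
    "cluster_stage",
    "report_stage",
    "frontier_to_dataframe",
    "frontier_from_dataframe",
    "pairwise_projections",
    "default_seed_plans",
    "Manifest",
]


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 9
    top_profitable: int = 3
    profitable_fraction: float = 0.3


@dataclass(frozen=True)
class PipelineConfig:
    soils: tuple[str, ...] = ("Clay", "Sandy Clay", "Sandy Loam")
    soil_table: str | None = None  # None = packaged fixture table
    weather_seed: int = 42
    n_seasons: int = 9
    stage1: OptimizerConfig = field(default_factory=OptimizerConfig)
    stage2: CombinerConfig = field(default_factory=CombinerConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    economics: EconomicParams = field(default_factory=EconomicParams)
    calibration_path: str | None = None
    output_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if not self.soils:
            raise ValidationError("config field 'soils' must list at least one soil")
        available = load_soils(self.soil_table)
        for name in self.soils:
            if name not in available:
                raise ValidationError(
                    f"config field 'soils': unknown soil {name!r}; "
                    f"available: {sorted(available)}"
                )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "soils" in raw:
            kwargs["soils"] = tuple(raw.pop("soils"))
        for scalar in ("soil_table", "weather_seed", "n_seasons", "calibration_path", "output_dir"):
            if scalar in raw:
                kwargs[scalar] = raw.pop(scalar)
        if "stage1" in raw:
            kwargs["stage1"] = OptimizerConfig(**raw.pop("stage1"))
        if "stage2" in raw:
            kwargs["stage2"] = CombinerConfig(**raw.pop("stage2"))
        if "clustering" in raw:
            kwargs["clustering"] = ClusteringConfig(**raw.pop("clustering"))
        if "economics" in raw:
            kwargs["economics"] = EconomicParams(**raw.pop("economics"))
        if raw:
            raise ValidationError(f"unknown config fields: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["soils"] = list(self.soils)
        return d


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


class Manifest:
    """Run manifest: config hash, seeds, versions, per-stage records."""

    def __init__(self, config: PipelineConfig, path: Path):
        self.path = path
        self.data = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stages": {},
        }

    def record(self, stage: str, status: str, **details) -> None:
        self.data["stages"][stage] = {"status": status, **details}
        self.write()

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


def default_seed_plans() -> list[ManagementPlan]:
    """Hand-picked seeds: current practice plus both extremes."""
    return [
        ManagementPlan(n_rates=(0.0,) * 9),  # unmanaged extreme
        ManagementPlan(n_rates=(100.0,) * 9, fym_amount=3.0),  # maximal extreme
        # conventional practice: three mid-spring dressings, no manure
        ManagementPlan(n_rates=(0.0, 0.0, 60.0, 60.0, 60.0, 0.0, 0.0, 0.0, 0.0)),
    ]


def frontier_to_dataframe(frontier: Frontier) -> pd.DataFrame:
    """Frontier as a CSV-ready frame, rows sorted lexicographically by objectives."""
    df = pd.DataFrame(frontier.genomes, columns=list(GENOME_NAMES))
    for j, name in enumerate(OBJECTIVE_NAMES):
        df[name] = frontier.objectives[:, j]
    df["rank"] = 0
    df["crowding"] = (
        frontier.crowding if frontier.crowding is not None else np.zeros(len(df))
    )
    order = np.lexsort(frontier.objectives.T[::-1])
    return df.iloc[order].reset_index(drop=True)


def frontier_from_dataframe(df: pd.DataFrame) -> Frontier:
    genomes = df[list(GENOME_NAMES)].to_numpy(dtype=float)
    objectives = df[list(OBJECTIVE_NAMES)].to_numpy(dtype=float)
    crowding = df["crowding"].to_numpy(dtype=float) if "crowding" in df else None
    return Frontier(
        genomes=genomes, objectives=objectives, directions=DIRECTIONS, crowding=crowding
    )


def _load_context(config: PipelineConfig):
    soils = load_soils(config.soil_table)
    calib = (
        load_calibration(config.calibration_path)
        if config.calibration_path
        else DEFAULT_CALIBRATION
    )
    weather = WeatherSeries.generate(
        config.weather_seed, n_seasons=config.n_seasons, calib=calib
    )
    return soils, calib, weather


def optimize_soil(
    config: PipelineConfig,
    soil_name: str,
    manifest: Manifest | None = None,
) -> Frontier:
    """Stage 1 for one soil: hybrid NSGA-II/DE over management genomes."""
    if soil_name not in config.soils:
        raise ValidationError(f"soil {soil_name!r} not in config field 'soils'")
    soils, calib, weather = _load_context(config)
    soil = soils[soil_name]
    econ = config.economics
    # independent, named seed stream per soil
    stage_cfg = replace(
        config.stage1, seed=config.stage1.seed + 1000 * config.soils.index(soil_name)
    )

    def evaluate(genome: np.ndarray) -> np.ndarray:
        plan = ManagementPlan.from_genome(genome)
        return evaluate_plan(plan, soil, weather, econ, calib).to_array()

    rng = np.random.default_rng(stage_cfg.seed)
    init = seed_initial_population(stage_cfg, default_seed_plans(), rng)
    result = evolve(evaluate, DIRECTIONS, stage_cfg, init_genomes=init)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = frontier_to_dataframe(result.frontier)
    csv_path = outdir / f"frontier_{_slug(soil_name)}.csv"
    df.to_csv(csv_path, index=False)
    history_path = outdir / f"history_{_slug(soil_name)}.csv"
    pd.DataFrame(result.history).drop(columns=["best_minimized"]).to_csv(
        history_path, index=False
    )
    if manifest is not None:
        manifest.record(
            f"optimize_soil:{soil_name}",
            "complete",
            pop_size=stage_cfg.pop_size,
            n_generations=stage_cfg.n_generations,
            archive_size=stage_cfg.archive_size,
            seed=stage_cfg.seed,
            n_points=len(df),
            frontier_csv=csv_path.name,
        )
    logger.info("soil %s: frontier of %d points -> %s", soil_name, len(df), csv_path)
    return result.frontier


def combine_stage(
    config: PipelineConfig, manifest: Manifest | None = None
) -> pd.DataFrame:
    """Stage 2: categorical NSGA-II over per-soil frontier indices."""
    outdir = Path(config.output_dir)
    frontiers = []
    for name in config.soils:
        path = outdir / f"frontier_{_slug(name)}.csv"
        if not path.exists():
            raise ValidationError(f"missing stage-1 frontier for soil {name!r}: {path}")
        frontiers.append(frontier_from_dataframe(pd.read_csv(path)))
    assignments = run_combiner(frontiers, config.stage2)
    rows = []
    for a in assignments:
        row = {f"idx_{_slug(n)}": i for n, i in zip(config.soils, a.indices)}
        row.update({name: a.combined[j] for j, name in enumerate(OBJECTIVE_NAMES)})
        rows.append(row)
    df = pd.DataFrame(rows)
    csv_path = outdir / "combined_frontier.csv"
    df.to_csv(csv_path, index=False)
    if manifest is not None:
        manifest.record(
            "combine",
            "complete",
            pop_size=config.stage2.pop_size,
            n_generations=config.stage2.n_generations,
            seed=config.stage2.seed,
            n_points=len(df),
            combined_csv=csv_path.name,
        )
    logger.info("combined frontier: %d points -> %s", len(df), csv_path)
    return df


def cluster_stage(
    config: PipelineConfig, manifest: Manifest | None = None
) -> dict[str, pd.DataFrame]:
    """Cluster each soil's frontier genomes into named strategies."""
    outdir = Path(config.output_dir)
    ccfg = config.clustering
    outputs: dict[str, pd.DataFrame] = {}
    for name in config.soils:
        path = outdir / f"frontier_{_slug(name)}.csv"
        if not path.exists():
            raise ValidationError(f"missing stage-1 frontier for soil {name!r}: {path}")
        df = pd.read_csv(path)
        plans = [
            ManagementPlan.from_genome(row)
            for row in df[list(GENOME_NAMES)].to_numpy(dtype=float)
        ]
        feats = [summarize_plan(p) for p in plans]
        k = min(ccfg.k, len(feats))
        result = cluster_strategies(feats, k)
        profits = df["profit_mean"].to_numpy()
        ordered, flagged = rank_clusters_by_profit(result, profits, ccfg.top_profitable)
        point_flags = flag_profitable_points(profits, ccfg.profitable_fraction)

        assign = pd.DataFrame(
            {
                "point": np.arange(len(df)),
                "cluster": result.labels,
                "profitable_cluster": np.isin(result.labels, flagged),
                "profitable_point": point_flags,
            }
        )
        summary = pd.DataFrame(
            {
                "cluster": ordered,
                "profit_rank": np.arange(1, len(ordered) + 1),
                "n_points": [int((result.labels == c).sum()) for c in ordered],
                "mean_profit": [profits[result.labels == c].mean() for c in ordered],
                "flagged_profitable": [c in flagged for c in ordered],
            }
        )
        hists = cluster_histograms(result, features_matrix(feats))
        slug = _slug(name)
        assign.to_csv(outdir / f"clusters_{slug}_assignments.csv", index=False)
        summary.to_csv(outdir / f"clusters_{slug}_summary.csv", index=False)
        hists.to_csv(outdir / f"clusters_{slug}_histograms.csv", index=False)
        outputs[name] = assign
        if manifest is not None:
            manifest.record(
                f"cluster:{name}",
                "complete",
                k=int(result.k),
                top_profitable=ccfg.top_profitable,
                profitable_fraction=ccfg.profitable_fraction,
            )
    return outputs


def pairwise_projections(
    frontier_df: pd.DataFrame,
    objective_names: tuple[str, ...] = OBJECTIVE_NAMES,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format table of all unordered objective pairs.

    Each frontier point appears exactly once per pair; minimized axes are
    flagged so plots can invert them.
    """
    names = [n for n in objective_names if n in frontier_df.columns]
    if len(names) < 2:
        raise ValueError("need at least two objectives to project")
    rows = []
    for ox, oy in combinations(names, 2):
        block = pd.DataFrame(
            {
                "objective_x": ox,
                "objective_y": oy,
                "point": np.arange(len(frontier_df)),
                "x": frontier_df[ox].to_numpy(),
                "y": frontier_df[oy].to_numpy(),
                "x_minimized": ox in MINIMIZED,
                "y_minimized": oy in MINIMIZED,
            }
        )
        if labels is not None:
            block = block.merge(labels, on="point", how="left")
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def report_stage(
    config: PipelineConfig, manifest: Manifest | None = None
) -> None:
    """Export pairwise projection tables and combined profitability flags."""
    outdir = Path(config.output_dir)
    for name in config.soils:
        slug = _slug(name)
        fpath = outdir / f"frontier_{slug}.csv"
        if not fpath.exists():
            raise ValidationError(f"missing stage-1 frontier for soil {name!r}: {fpath}")
        df = pd.read_csv(fpath)
        lpath = outdir / f"clusters_{slug}_assignments.csv"
        labels = pd.read_csv(lpath) if lpath.exists() else None
        proj = pairwise_projections(df, labels=labels)
        proj.to_csv(outdir / f"projections_{slug}.csv", index=False)
    cpath = outdir / "combined_frontier.csv"
    if cpath.exists():
        cdf = pd.read_csv(cpath)
        pairwise_projections(cdf).to_csv(outdir / "projections_combined.csv", index=False)
        # per-soil 30% profitability of the points each assignment selects
        flags = {}
        for name in config.soils:
            slug = _slug(name)
            soil_df = pd.read_csv(outdir / f"frontier_{slug}.csv")
            soil_flags = flag_profitable_points(
                soil_df["profit_mean"].to_numpy(), config.clustering.profitable_fraction
            )
            flags[f"profitable_{slug}"] = soil_flags[cdf[f"idx_{slug}"].to_numpy()]
        pd.DataFrame({"point": np.arange(len(cdf)), **flags}).to_csv(
            outdir / "combined_profitability.csv", index=False
        )
    if manifest is not None:
        manifest.record("report", "complete")


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Run all stages in order, recording progress in the manifest.

    On stage failure the manifest marks the stage failed (and later
    stages absent) before the exception propagates.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, outdir / "manifest.json")
    manifest.write()
    stages: list[tuple[str, callable]] = [
        *[
            (f"optimize_soil:{name}", lambda n=name: optimize_soil(config, n, manifest))
            for name in config.soils
        ],
        ("combine", lambda: combine_stage(config, manifest)),
        ("cluster", lambda: cluster_stage(config, manifest)),
        ("report", lambda: report_stage(config, manifest)),
    ]
    for stage_name, fn in stages:
        try:
            fn()
        except Exception as exc:
            manifest.record(stage_name, "failed", error=str(exc))
            raise
    return manifest
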