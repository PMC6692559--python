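# agrimoo

Multi-objective optimization of agricultural land management.

A surrogate crop–soil simulator maps an 11-gene management plan (nine
biweekly mineral-N applications, a farm-yard-manure amount and its
pre-sowing timing) to per-season yield, N₂O emissions, leached N, SOC
trajectory and a nitrogen ledger. A hybrid NSGA-II / differential-
evolution optimizer builds a 100-point Pareto frontier over six
objectives (yield, profit, N₂O, ΔSOC, NUE, N surplus) for each of three
soils; a categorical second stage combines the per-soil frontiers under
equal-area mean objectives with a genetic population of 1000; Ward
clustering of summarized management genes (total N, number of
applications, first-application week, FYM amount) names the profit-
ranked strategies behind each frontier region.

The simulator is a deliberately simple surrogate calibrated to
qualitative response structure (saturating yield response to N, convex
N₂O response, fine-textured soils emitting more N₂O, FYM raising both
SOC and N₂O) — not to absolute field values. Every surrogate constant
lives in `src/agrimoo/data/calibration.toml`; soil profiles ship in
`src/agrimoo/data/soils.csv`.

## Layout

| module | role |
| --- | --- |
| `agrimoo.surrogate` | soils, management plans, weather, crop–soil simulator |
| `agrimoo.objectives` | six objectives, nitrogen accounting, profit, EU-panel check |
| `agrimoo.moo` | NSGA-II sorting/crowding + DE variation, seeding, archive trimming |
| `agrimoo.hypervolume` | exact 2-D and Monte-Carlo hypervolume indicators |
| `agrimoo.combiner` | stage-2 categorical NSGA-II over frontier indices + exhaustive oracle |
| `agrimoo.clusters` | strategy summarization, Ward clustering, profit ranking, histograms |
| `agrimoo.pipeline` / `agrimoo.cli` | end-to-end driver, manifests, CSV export, CLI |

## CLI

```sh
agrimoo run-all --config config.yaml            # whole pipeline
agrimoo optimize-soil Clay --config config.yaml # stage 1, one soil
agrimoo combine --config config.yaml            # stage 2
agrimoo cluster --config config.yaml
agrimoo report --config config.yaml
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. A minimal config:

```yaml
soils: [Clay, Sandy Clay, Sandy Loam]
weather_seed: 42
stage1: {pop_size: 100, n_generations: 300, seed: 1, archive_size: 100}
stage2: {pop_size: 1000, n_generations: 60, seed: 2}
clustering: {k: 9, top_profitable: 3, profitable_fraction: 0.3}
output_dir: runs/demo
```

A run writes per-soil frontier CSVs (11 genome + 6 objective columns),
the combined-frontier CSV with per-soil index columns, cluster
assignment/summary/histogram CSVs, pairwise-projection tables and a
`manifest.json` recording the config hash, seeds, versions and
per-stage status. Reruns with the same config are byte-identical.

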