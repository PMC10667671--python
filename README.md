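# coresat

Analysis toolkit for **core and satellite microeukaryotic plankton
subcommunities around a complete reservoir-mixing disturbance**, resolved at
two water depths (surface and bottom).

A deep reservoir normally stratifies: a thermocline separates a warm surface
layer from a cold, hypoxic bottom layer. When an artificial or seasonal
mixing event erases the thermocline, the whole water column is homogenised
for weeks — a severe disturbance for the plankton. This package implements
the full analysis chain for asking *who* responds, *how fast* each
subcommunity returns (or fails to return) to its pre-disturbance state, and
*which* environmental drivers explain the trajectories:

- **Hydrology** — thermocline detection from temperature profiles and
  run-length labelling of visits into `before` / `mixing` / `after` periods
  (`thermocline_depth`, `label_periods`).
- **Community preparation** — low-count filtering, rarefaction,
  occupancy-based partitioning into core (occupancy ≥ 0.75), satellite
  (< 0.50) and intermediate taxa, abundance categories, and qPCR-scaled
  absolute abundances (`partition_taxa`, `absolute_abundance`).
- **Stability** — moving-window 1/CV temporal stability of total absolute
  abundance per subcommunity, and how closely each subcommunity's stability
  tracks the entire community's (`stability_series`, `stability_relation`).
- **Beta diversity** — Bray–Curtis dissimilarity, NMDS, ANOSIM (with exact
  enumeration for small designs), SIMPER decomposition, time-lag regression
  and period-pair dissimilarity contrasts (`bray_curtis`, `anosim`,
  `simper`, `time_lag`, `period_pair_dissimilarity`).
- **Co-occurrence networks** — Spearman |ρ| ≥ 0.8 with
  Benjamini–Hochberg-corrected p < 0.01 edges, per-sample induced
  subnetworks and topological metrics (density, average path length,
  betweenness centralization, greedy modularity).
- **Nutrient function** — a multi-nutrient cycling index (MNC: mean of
  z-scored log1p nutrient concentrations) and Lohmöller/centroid mode-A PLS
  path modelling with collinearity pre-filtering, weak-indicator pruning and
  bootstrap path inference (`mnc_index`, `fit_plspm`, `bootstrap_paths`).
- **Synthetic generator** — a two-depth, 34-visit scenario generator that
  encodes the study design (surface community recovers after mixing; the
  bottom community and its environment shift to a new state) for testing and
  demonstration (`generate_scenario`).
- **Pipeline and CLI** — `run_pipeline(RunConfig(...))` runs everything and
  writes CSV/TSV/GraphML artefacts plus a `manifest.json`; the `coresat`
  CLI exposes `simulate`, `partition`, `mnc` and related verbs.

## Worked example

```python
import numpy as np
from coresat import (
    ScenarioConfig, generate_scenario, filter_low_count_taxa, rarefy,
    partition_taxa, occupancy_sets, absolute_abundance, stability_series,
    stability_relation, bray_curtis, anosim, label_periods,
    thermocline_depth, profiles_by_visit,
)

# 1. Simulate the two-depth mixing scenario (34 visits, 20k reads/sample)
ds = generate_scenario(ScenarioConfig(seed=7))

# 2. Label visits from the temperature profiles
by_visit = profiles_by_visit(ds.profiles)
presence = [thermocline_depth(by_visit[v]) is not None for v in sorted(by_visit)]
periods = np.asarray(label_periods(presence))
print({p: int((periods == p).sum()) for p in ("before", "mixing", "after")})
# {'before': 14, 'mixing': 11, 'after': 9}

# 3. Prepare the surface table and partition taxa by occupancy
table = rarefy(filter_low_count_taxa(ds.community["surface"], 10), seed=7)
part = partition_taxa(table)
print(part["occupancy_class"].value_counts().to_dict())
# {'satellite': 352, 'intermediate': 44, 'core': 43}

# 4. Moving-window stability: core taxa track the whole community
groups = occupancy_sets(part)
sums = absolute_abundance(table, ds.qpcr, part)["group_sums"]
stab = {s: stability_series(sums[s].to_numpy(), periods, 5, s)
        for s in ("entire", "core", "satellite")}
for s in ("core", "satellite"):
    rel = stability_relation(stab[s], stab["entire"])
    print(f"{s}: r={rel['r']:.3f} slope={rel['slope']:.3f}")
# core: r=0.953 slope=0.805
# satellite: r=0.904 slope=0.193

# 5. The disturbance restructures the core subcommunity
core = table.subset_taxa(groups["core"])
res = anosim(bray_curtis(core), periods, n_perm=999, seed=7)
print(f"ANOSIM R={res['R']:.3f} p={res['p']:.3f}")
# ANOSIM R=0.568 p=0.001
```

The full pipeline over both depths is one call:

```python
from coresat import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(output_dir="results", seed=0))
```

or from the shell:

```bash
coresat simulate --seed 0 --out data/
coresat partition --input-dir data/ --depth surface --seed 0 --out partition.csv
```

## Reproduction

- **Tests** (unit, property-based and acceptance):

  ```bash
  python -m pytest -q tests/
  ```

- **Headline numbers** — run the end-to-end analysis and write the main
  quantities (ANOSIM R/p, stability relations, period-pair dissimilarity
  medians, network sizes, PLS-PM goodness of fit and R², significant paths)
  as a flat JSON file:

  ```bash
  python scripts/acceptance.py --seed 1 --out results.json
  ```

  With seed 1 this reports, e.g., surface core before-vs-after median
  Bray–Curtis ≈ 0.30 (back to the ≈ 0.30 baseline: recovery) while the
  bottom core stays at ≈ 0.47 against a 0.21 baseline (a persistent new
  state), in ≈ 18 s.

All computations are deterministic given the seed. Methodological details,
parameter defaults and their rationale are documented in
[docs/methods.md](docs/methods.md).
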