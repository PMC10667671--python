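# Methods

This document records the modelling assumptions, parameter defaults and
numerical choices behind `coresat`, and the limitations a user should be
aware of. Everything stated here about package behaviour is implemented and
exercised by the test suite; no field-data results are claimed.

## 1. Study design encoded by the package

A deep reservoir is sampled at two depths (surface and bottom) over 34
visits. A complete mixing event erases the thermocline mid-series, giving
three periods: `before` (stratified), `mixing` (isothermal column) and
`after` (restratified). The analysis contrasts how the **core** (high
occupancy) and **satellite** (low occupancy) fractions of the
microeukaryotic community respond at each depth.

## 2. Hydrology

- `thermocline_depth` scans successive depth pairs from the surface down and
  reports the deeper endpoint of the first pair whose absolute gradient
  exceeds the threshold. Default threshold **0.2 °C/m**, a standard
  limnological criterion for thermocline presence; the comparison is strict
  (`>`) so a gradient exactly at the threshold counts as mixed.
- `label_periods` run-length encodes the presence sequence and requires the
  thermocline-absent visits to form a single contiguous run; otherwise it
  raises `AmbiguousPeriodsError` rather than guessing. This matches a single
  complete disturbance and refuses partial/multiple mixing episodes.

## 3. Community preparation

- Low-count filtering removes taxa with fewer than **10** reads summed over
  all samples (standard denoising of sequencing tables), then samples are
  rarefied to the minimum sample sum with a seeded
  multivariate-hypergeometric draw (deterministic, without replacement).
- Occupancy classes: **core ≥ 0.75**, **satellite < 0.50**, the rest
  intermediate. Boundaries are inclusive for core and exclusive for
  satellite.
- Abundance categories use per-sample relative abundances with an abundant
  threshold of **1 %** and a rare threshold of **0.01 %**, counting samples
  at or above the abundant cut and strictly below the rare cut.
- Absolute abundances multiply each sample's relative abundances by its
  qPCR total 18S copy concentration, so subcommunity sums are in
  copies/mL and sum exactly to the sample total.

## 4. Stability

Temporal stability of a subcommunity is **mean/SD (1/CV)** of its total
absolute abundance over a **5-sample moving window** (34 samples → 30
windows; SD uses ddof = 1). Windows are assigned to the period of their last
sample, giving the 10/15/5 window grouping with mixing-influenced windows
11–25. `stability_relation` reports the OLS slope and Pearson r between two
stability series; 1/CV is scale-invariant, so qPCR units do not affect it.

## 5. Beta diversity

- **Bray–Curtis** on (rarefied) counts; `1 − 2W/(A+B)` with the usual
  min-sum numerator.
- **NMDS** via scikit-learn `MDS(metric=False, dissimilarity="precomputed",
  normalized_stress=True)`: one classical-scaling start plus `n_starts`
  (default 8) seeded random starts, keeping the lowest-stress 2-axis
  configuration, with coordinates rotated to principal axes for
  reproducibility. Non-metric stress-1 is the quantity reported.
- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (M/2), M = number of pairwise distances. p uses the add-one permutation
  estimate `(n_ge + 1)/(n_perm + 1)`; for ≤ 7 samples an exact
  full-enumeration mode is available and tested against brute force.
- **SIMPER** decomposes average between-group Bray–Curtis into per-taxon
  percentage contributions; contributions sum to 100 % by construction and
  the implementation is tested against an independent brute-force oracle at
  1e-12.
- **Time-lag regression** regresses dissimilarity on time lag in months
  (days / 30.44, fractional); a positive slope indicates directional change,
  a flat slope stochastic fluctuation.
- **Period-pair contrasts** bin all pairwise dissimilarities by the period
  pair of their endpoints (B-B, B-M, B-A, M-M, M-A, A-A) and compare bins
  with Kruskal–Wallis plus pairwise Mann–Whitney letters. Recovery shows as
  B-A returning to the B-B baseline; a persistent new state shows as B-A
  staying elevated.

## 6. Co-occurrence networks

- Node filter: taxa present (non-zero) in all three periods with overall
  mean relative abundance ≥ **0.05 %** — the network is restricted to taxa
  shared across the whole series and never marginal.
- Edges: Spearman **|ρ| ≥ 0.8** on relative abundances **and**
  Benjamini–Hochberg adjusted **p < 0.01** (`statsmodels.multipletests`).
  Correlations use the t-distribution approximation for p-values (see
  Limitations).
- Per-sample subnetworks are the induced subgraph on taxa present in that
  sample; metrics are density, average path length (averaged over connected
  pairs within components), betweenness centralization (normalised so the
  star graph scores 1), and greedy (Clauset–Newman–Moore) modularity.
  Greedy modularity is a lower bound on the optimum; the tests verify this
  against exhaustive search for ≤ 6 nodes.

## 7. Nutrient function

- **MNC** (multi-nutrient cycling index) is the row mean of column-wise
  z-scores (ddof = 1) of log1p-transformed concentrations of the 8 nutrient
  variables (TC, TOC, TN, NH4, NO3, NO2, TP, PO4). It is mean-zero by
  construction. Negative concentrations and zero-variance columns are
  rejected.
- **Collinearity filter**: greedily keeps columns in order, dropping any
  whose squared Spearman correlation with an already-kept column exceeds the
  threshold (0.5 for environment blocks, 0.6 for network-metric blocks).
- **PLS-PM**: Lohmöller's algorithm, **mode A** outer estimation, centroid
  inner weighting, standardized data, convergence at 1e-6 on outer weights.
  Latent scores are unit-variance; path coefficients are OLS of each
  endogenous score on its predecessors, so a single-indicator-per-block
  model degenerates exactly to OLS regression (tested at 1e-10). GoF is the
  geometric mean of average communality and average R². Indicators with
  |loading| < 0.7 are pruned once and the model refit; pruning refuses to
  empty a block. Bootstrap path inference resamples rows (999 draws by
  default, 199 in the pipeline) and reports percentile CIs and a two-sided
  add-one sign-count p-value.
- The reservoir inner model points every driver block (WT, Phys, Nutr,
  Chla) at every community block (NMDS axes, network metrics) and the
  community blocks at MNC. The direct Nutr → MNC path is excluded because
  MNC is computed from the same nutrient measurements.

Mode-A PLS estimates are consistent for composite (emergent) constructs;
for reflective factor models they are attenuated. The package treats blocks
as composites.

## 8. Synthetic generator

### Scope

The generator produces data *shaped like* the study — two depths, 34 visits,
counts + qPCR totals + 12 environmental variables + temperature profiles —
with a known ground truth (`dataset.truth`) for testing the analysis chain.
It encodes the study's qualitative structure (which depth recovers, which
taxa are core, how drivers move); it is not a calibrated biogeochemical
model, and its quantitative outputs (e.g. exact R values) have no field
meaning.

### Structure and defaults

- **Pool**: 40 core, 60 intermediate, 400 satellite taxa with log-normal
  weights (core log-weight ln 20, intermediate ln 1.5, satellite ln 0.3;
  SDs 1.0/1.0/1.3) and occupancy probabilities 1.0/0.62/0.25. Counts are
  multinomial draws of 20 000 reads per sample from the per-sample weight
  composition.
- **Disturbance response**: each taxon is down/neutral/up with probability
  0.4/0.4/0.2 and multiplicative mixing shift 0.02/1.0/8.0. Core down-taxa
  use a milder 0.1 (they persist through disturbance by definition —
  otherwise they would not be core). Down-taxa also drop to 55 % presence
  during mixing samples at the non-recovering depth.
- **Recovery**: at recovering depths the composition returns to baseline
  after mixing. At non-recovering depths the after-period keeps the mixing
  shift for down-taxa while up-bloomers fade partially (shift^0.25): a
  *third* community state, distinct from both baseline and mixing, as a
  persistent regime shift implies.
- **Latent totals**: log-normal around 1e6 copies/mL; mixing crashes totals
  by ×0.2; unrecovered depths keep depressed, drifting totals with one
  boom-bust pulse (×25) mid-after — disturbed systems stay volatile.
- **Covariance**: taxa within a response group share a per-sample log
  factor (SD 0.5, loadings ~N(1, 0.2)) so co-occurrence edges exist to be
  detected; satellites form 12 guilds of 10 with shared presence windows
  and a guild factor (SD 0.8). Per-sample composition jitter SD is 0.45 at
  the surface and 0.2 at the bottom: surface communities are noisier, so
  environmental models explain less of their variance.
- **Environment**: per-period normal means/SDs per depth. Surface variables
  rebound after mixing; bottom DO pulses during mixing (oxygenation of a
  formerly hypoxic layer) and bottom pH/Chla/N/P species settle at *new*
  after-period levels rather than returning — the drivers of the persistent
  community shift.
- **Profiles**: stratified visits get a two-layer profile with a sharp
  gradient; mixing visits are isothermal within noise, so the 0.2 °C/m
  criterion recovers the designed period labels.

These constants were calibrated once, as a set, to make the designed
qualitative structure (core occupancy, recovery contrast, network
detectability, driver asymmetry) hold robustly across seeds, and then
frozen; they are not tuned to individual test outcomes.

## 9. Pipeline and I/O

- `RunConfig` carries all thresholds (defaults as above) and hashes to a
  SHA-based config fingerprint stored in the manifest.
- Stage-level seeds are derived from the run seed and a stage name, so
  adding a stage does not perturb earlier stages' randomness.
- Formats: TSV for tables and distance matrices (sample/taxon IDs must not
  contain tab/newline), BIOM 1.0 JSON for community tables, GraphML for
  networks, JSON for the manifest. All artefacts are text.

## 10. Limitations

- Spearman edge p-values use the large-sample t approximation, not the
  exact permutation null; with 34 samples this is standard practice but
  borderline pairs near |ρ| = 0.8 can cross the threshold either way.
- Greedy modularity is a heuristic lower bound; only graphs ≤ 6 nodes are
  verified against exhaustive search.
- NMDS is a local optimiser; multiple seeded starts reduce but do not
  eliminate the chance of a poor local minimum.
- ANOSIM permutation p-values have resolution 1/(n_perm + 1); exact
  enumeration is only feasible for very small n.
- Rarefaction discards reads; it is used for comparability, not as an
  estimator of true richness.
- The PLS-PM bootstrap resamples rows of a time series, ignoring temporal
  autocorrelation; its p-values are approximate for autocorrelated data.
- The generator draws samples independently given the period structure
  (no explicit AR(1) community dynamics beyond the period means and the
  altered-state drift).
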