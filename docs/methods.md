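# Methods

This note documents the models, algorithms and design choices in
`gddrn`, in the package's own words. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Thermal-time environmental characterization

Growing degree-days (GDD) are accumulated from the sowing date as
`sum(max(tavg, 0))`: a day's average temperature contributes its value
when above 0 °C and nothing otherwise. The season runs from sowing to a
fixed calendar end date (mid-August for Danish-style winter wheat);
whether the crop actually matured inside the covered stages is the
user's responsibility, surfaced through the incomplete-stage flag
rather than through a phenology simulation.

The season is partitioned into consecutive stages of `stage_size`
(default 100) GDD. A stage closes on the first day on which its own
accumulated GDD reaches `stage_size`. We chose within-stage
accumulation (rather than fixed cumulative thresholds `k * 100`)
because it guarantees every complete stage accumulates at least
`stage_size` and at most `stage_size` plus one day's increment, so
stages are comparable units of thermal time even when a hot day
overshoots a boundary. A trailing partial stage is emitted flagged
`complete = False` and excluded from the covariate matrix by default.

Within each complete stage, 17 climatic covariates are computed
(means and accumulations of temperature, radiation, vapour-pressure
deficit, the precipitation-minus-evaporation balance split into
positive/negative/total parts, dry-day and frost-day counts, and
low-radiation summaries). Conventions that needed fixing:

* The low-radiation threshold of 1,045 J/cm² is used as 10.45 MJ/m² to
  match the radiation unit of the input series.
* A "dry day" is `precip <= evap`; ties count as dry.
* The frost accumulations (`cumnsti4`, `cumsti0`, `cumndt0`) are
  computed on daily minimum temperature, falling back to the daily
  average only when no `tmin` column exists. The negative balance
  `cumnegpetp` is stored with its (non-positive) sign.
* The photothermal ratio `ratrdtmp` is accumulated radiation per unit
  of stage thermal time (stage GDD), undefined when the stage
  accumulates no positive thermal time.
* A missing day inside a stage makes the dependent covariates missing
  for that environment ("missing stays missing, never zero"); the QC
  step then decides whether the column survives.

Soil is described by seven depth-resolved variables (clay, fine sand,
coarse sand, silt, carbon, plant-available water, saturated hydraulic
conductivity) over four layers (0–30, 30–60, 60–100, 100–200 cm),
giving 28 raw columns per location, broadcast to every year at that
location. Water storage capacity is carried in the soil table but is
not depth-expanded.

**Quality control** removes covariate columns with strictly more than
10 % missing values or strictly more than 30 % repeated values (the
most frequent value's share of rows). It is idempotent. Note the
repeated-value rule interacts with the number of environments: a
location-constant soil column survives only when no location accounts
for more than 30 % of the environments, so in small synthetic studies
(6 environments over 3 locations) soil columns are legitimately
removed at QC while the climatic stage covariates survive.

**W and Omega.** Surviving covariates are centered and scaled to unit
sample standard deviation at the environment level by default, then
expanded to observation rows; this guarantees the environmental kernel
`Omega = W W' / q` is constant within an environment, which is what an
environment-level similarity should be. Scaling at the expanded
observation level (weighting environments by their plot counts) is
available as an option; with balanced designs the two coincide up to a
constant. Residual missing values are set to 0 after centering
(i.e. to the column mean).

## Kernels

* **G** (genomic): VanRaden method 1, `G = ZZ' / (2 Σ p(1-p))` with
  `Z = M - 2(p - 0.5)` on -1/0/1 calls. The centering frequency `p` is
  the sample frequency of the +1-coded allele (not folded); folding is
  applied only when testing the MAF threshold. This makes `Z` columns
  exactly centered, hence `G·1 = 0`. Missing calls are mean-imputed
  (zero contribution to `Z`). SNP QC removes markers with MAF < 0.05
  or call rate < 0.90, both strict.
* **S** (spatial): each plot loads on the nine grid squares centered
  on itself and its eight Chebyshev neighbours; virtual plots complete
  borders and holes. `S = XX' / (tr(XX')/n)` has unit diagonal and
  off-diagonal entries `shared squares / 9 ∈ {0, 1/9, …, 6/9}`.
  Spatial ids are scoped per environment, so S is block-diagonal
  across year-locations and replicate plots of one line occupy
  distinct rows. Coordinates must be integers; nothing is inferred.
* **GW** (reaction norm): `(Zg G Zg') ∘ Omega`, the Hadamard product
  of the line-expanded GRM with the environmental kernel; positive
  semidefinite by the Schur product theorem. Materialized dense up to
  a configurable observation cap (the desk-scale studies here stay
  well under it).

## The mixed models

M1 fits fixed trial effects (trial nested in year-location-cycle,
reference level dropped lexicographically, flat priors) plus random
line `l ~ N(0, I σ²_l)`, line-by-environment `f ~ N(0, I σ²_f)` and
spatial `s ~ N(0, S σ²_s)` effects. M2 adds genomic `g ~ N(0, G σ²_g)`;
M3 adds `gw ~ N(0, GW σ²_gw)`. M4 and M5 are the bivariate forms in
which each effect's scalar variance becomes a 2×2 between-trait
covariance with Kronecker structure (e.g. `G ⊗ K`). The line effect is
retained alongside `g` to absorb non-additive and marker-uncaptured
genetic variance; `f` is retained alongside `gw` because covariates
never capture all environmental variability.

### Gibbs sampler

Each kernel-structured effect is reparameterized once, at design-build
time: with `K = U D U'` (eigenvalues below `1e-10 × max` truncated)
and incidence `Z`, set `W0 = Z U D^{1/2}`; a second eigendecomposition
of `W0'W0` yields an orthogonal `V` such that the working design
`W = W0 V` has diagonal cross-product. Coefficients on `W` are a
priori i.i.d. with the effect's (co)variance, so their full
conditional factorizes over coordinates and the whole effect is
updated in one vectorized block draw per iteration (for two traits, a
batched 2×2 solve per coordinate). Identity-kernel effects use their
sparse incidence directly (the cross-product is the level-count
diagonal); fixed effects use an orthonormal QR basis with flat priors.
This one-time orthogonalization is also why a `ModelDesign` is shared
across models, trait subsets and cross-validation folds.

Variances get scaled-inverse-χ² full conditionals (single trait) and
2×2 inverse-Wishart full conditionals (bivariate; sampled via the
Bartlett decomposition). Prior hyperparameters follow an R² partition:
each of the `k` random effects' prior mode implies an equal share of
`R² · var(y)` (default R² = 0.90), the residual prior mode is
`(1-R²) · var(y)`, and the added prior degrees of freedom are
`df = 1e-4` (near-uninformative; the prior scale contributes
`≈ 2 × share` to the posterior sum of squares). For the bivariate
case the inverse-Wishart degrees of freedom are `traits + df` and the
prior scale matrix is diagonal with the same per-trait shares.

Missing phenotype cells — genuinely missing or deliberately masked for
validation — are handled by residual data augmentation: each
iteration imputes them from the current conditional distribution
(using the observed co-trait residual when only one trait is missing).
This is the mechanism behind trait-assisted prediction. A consequence
worth knowing: fixed effects of a fully masked trial are informed only
by augmented data and drift as a slow random walk; they are finite,
harmless to the genetic predictions, and never used downstream
(corrected line means use the whole-information fit).

Observations and factor levels are canonically sorted, so fits are
bit-for-bit invariant to input row order given a seed. Retained draws
number `(n_iter − burn_in)/thin`. Default desk-scale chains are
5,000/1,000/5; study-scale settings (50,000/10,000/10) are plain
parameter values.

### Derived posterior quantities

Plot-level heritabilities are computed per retained draw:
`h² = d(G) σ²_g / σ²_P`, `H² = (σ²_l + d(G) σ²_g) / σ²_P` with
`σ²_P = σ²_l + d(G) σ²_g + σ²_f + σ²_s + σ²_e` and `d(G)` the mean
GRM diagonal (≈ 1 + mean genomic inbreeding; near 1.9 for the inbred
synthetic material). Between-trait correlations per effect are
`cov₁₂ / √(σ²₁ σ²₂)` per draw, with zero-variance draws skipped and
counted. Convergence diagnostics use autocorrelation-adjusted
effective sample sizes with `MCSE = sd / √ESS`.

## Validation protocol

CV1 masks one year-location per fold; CV2 masks one breeding cycle per
fold; under trait-assisted masking only the target trait is hidden.
Check plots are never masked (reference varieties are always
phenotyped). Predictive ability is the Pearson correlation between
fixed-effect-corrected line means per year-location (fixed effects
estimated once on the full data, accepting the mild leakage that
protocol implies) and predictions pooled across all masked cells —
one PA per scheme, matching a single-number-per-scheme bootstrap;
per-fold PAs are also emitted for inspection. Bootstrap SEs resample
(line, environment) cells with replacement at full sample size.

Model contrasts use a two-tailed paired t-test on per-cell squared
prediction errors (the paired unit had to be chosen; squared error per
masked cell is the default and the function accepts any per-cell
metric). The maximum-PA bound is `n h²_f / (1 + (n-1) h²_f)` with `n`
the realized mean replicate count per year-location and `h²_f` a
family-mean heritability assembled from plot-level posterior variance
components: fully shared terms (`σ²_l + d(G) σ²_g`, plus the
kernel-scaled `σ²_gw` for reaction-norm predictions) over the same
terms plus `σ²_f` plus `(σ²_s + σ²_e)/n`. The inflation slope is
`b_wp = cov(û_w, û_p)/var(û_p)` over masked cells, computed separately
for `g` and `gw` predictions; it is exactly 1 when nothing is masked.

## Synthetic data

The generator emulates a commercial line-breeding programme:

* **Genotypes**: founder allele frequencies uniform on [0.10, 0.50];
  per-cycle frequencies drift via a Beta distribution with variance
  `drift · p(1-p)` (default 0.08), making within-cycle relatedness
  exceed across-cycle relatedness. Inbreeding is emulated by forcing a
  fraction (default 0.90) of loci homozygous, putting the mean GRM
  diagonal near 1.9 — selfing generations are not tracked explicitly.
* **Weather**: sinusoidal annual temperature (base ≈ 10 °C, amplitude
  ≈ 8 °C, coastal-temperate), seasonal radiation/evaporation/VPD,
  intermittent exponential rainfall; every season accumulates > 2,700
  GDD so at least 27 complete 100-GDD stages exist.
* **Layout**: per environment, blocks of 21 lines × 2 replicate plots
  plus check plots on a contiguous X–Y grid; trials are nested in
  (environment, cycle). Trial fixed effects are drawn with a large
  standard deviation (0.7) so the fixed-effect correction is genuinely
  exercised.
* **Phenotypes**: drawn from the full bivariate reaction-norm model
  against the same kernels the fit uses, with default per-trait
  variances on the scale of yield/protein trial components, a genomic
  between-trait correlation of −0.5 and a strong marker-by-EC
  interaction share. All effect draws and generating parameters are
  returned as a truth record.

What the generator does *not* emulate: linkage maps and LD decay,
pedigree recombination, selection between cycles, weather-station
error, and spatial gradients beyond the 9-square structure. Passing
recovery and ordering tests therefore show internal consistency of the
method under its own assumptions, not field performance on real data.

## Problem sizes used by tests and the acceptance script

The emulated study conditions (300 lines, 1,000 SNPs, 6 environments,
2 traits) are the generator defaults, and the parameter-recovery
acceptance test runs at exactly those conditions with a
5,000-iteration chain on one seed (roughly eight minutes on one core).
Recovery genuinely needs that scale: with environment-level EC
scaling, `Omega` is constant within an environment, so the `gw` effect
is collinear with the line-by-environment effect `f` at the
(line, environment) level and their split is identified only through
cross-line and cross-environment kernel structure — at 150–200 lines
the posterior visibly over-assigns variance to `l` and `f`, and
credible-interval coverage of the generating values falls below
nominal.

The predictive-ability ordering studies run at 20 lines per cycle
(3 cycles) with 9 environments and 1,000-iteration chains over three
seeds. The environment count is deliberately higher than the
generator's default six: leave-one-environment-out prediction through
an environmental kernel needs a reasonably sampled population of
environments (the emulated commercial programme had 17
year-locations). With very few environments the centered kernel is
dominated by centering artefacts and out-of-environment reaction-norm
predictions degrade — an instructive limitation of the method itself,
not only of the emulation. The acceptance script mirrors these two
studies at 150 lines (recovery) and the same CV configuration, one
seed each.

## Known limitations

* Bivariate only; the inverse-Wishart machinery generalizes to more
  traits but the interface does not expose it.
* REML fitting is not provided; an external REML fit is used only as a
  test oracle.
* The GW kernel is dense; very large observation counts need the
  factorized path that is deliberately out of scope here.
* Variance-component posteriors at small numbers of lines show the
  usual weak-identifiability behaviour between `l`, `g` and `gw`
  (right-skewed, mildly confounded); credible-interval coverage of
  generating values approaches nominal as the line count grows.
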