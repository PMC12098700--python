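# Methods

`hydroshift` implements, end to end and at desk scale, an analysis chain
that links hydrological drought in hydropower watersheds to excess fine
particulate matter (PM2.5) around combustion power plants, to premature
deaths among adults 65 and older, to monetized losses, and to projected
burdens under climate, demographic, and plant-retirement scenarios. This
note records the models, the conventions fixed where the underlying
definitions leave room, the synthetic data-generating process used for
verification, and the numerical choices.

## 1. Drought exposure

**Runoff anomalies.** Monthly runoff (mm/h) on a regular grid is
converted to anomalies by subtracting a calendar-month climatology
computed over a reference period (default 2000–2019). The climatology is
calendar-month specific, so any seasonal cycle that repeats identically
is absorbed. Anomalies with magnitude below `1e-12 x` the runoff scale
are snapped to exactly zero: the strict "negative anomaly" drought rule
would otherwise misread ±1-ulp cancellation residues as drought in
degenerate (constant or perfectly periodic) series.

**Watersheds.** Basin topology is an input: a forest of sub-basins with
at most one downstream pointer each, plus a basin→grid-cell membership
map. A plant's watershed is its outlet basin together with every basin
from which a downstream-pointer path reaches it (breadth-first upstream
trace; verified against a transitive-closure oracle). Watershed runoff
is the unweighted mean over member cells — grid cells are close to
equal-area at the synthetic scale; area weighting would be a one-line
change and is deliberately not a configuration switch.

**Drought indicators.** Anomalies are smoothed by a *trailing* moving
window of k months (t−k+1..t, default k = 3; 1, 6, 9, 12 supported,
other values allowed with a warning). A plant-month is in drought when
the rolled anomaly is strictly below zero; a rolled anomaly of exactly
zero is *not* drought ("less water than normal" excludes equality, and
the event has measure zero on continuous data). The severe variant
flags rolled anomalies more than one standard deviation below normal,
with the standard deviation taken over reference-period anomalies
(ddof = 1). A watershed with identically-zero anomalies has no
dispersion and is never severely dry.

**Market aggregation (FHD).** Markets are countries. The fraction of
hydropower capacity in drought, FHD(c, m) = Σ w_i D_i(m) / Σ w_i with
static installed-capacity weights w_i (snapshot registry; no
repowering), lies in [0, 1] and is missing — not zero — for markets
with no hydropower, which are excluded from the analysis sample. An
arithmetic-weight variant, the severe variant, and a capacity-weighted
mean-anomaly intensity measure are produced alongside. Merged-market
analyses are expressed through a market→market mapping rather than a
separate code path.

## 2. The plant panel

Each combustion plant-month carries the mean PM2.5 over cells whose
centers lie within 50 km of the plant (great-circle distance; 10 km and
other radii supported), the same radial means of temperature,
precipitation, relative humidity, surface pressure, and wind speed at
10 m and 100 m, a local-drought indicator (the 3-month rolled runoff
anomaly of the plant's own grid cell, negative rule — the construction
mirrors the hydropower indicator because no separate definition
exists), and market-level heating and cooling degree-days computed from
the market mean of plant temperatures with the IEA convention:
HDD = days·(18 − T) when T ≤ 15 °C else 0, CDD = days·(T − 18) when
T ≥ 21 °C else 0. The piecewise form is fixed here and unit-tested; in
the dead band 15 < T < 21 both are zero, so they are never jointly
positive.

Plant-months with any positive fire-emission cell within the exclusion
radius (50 km default; 75/100 km variants) are dropped with a logged
reason; an optional dust filter takes an explicit season→calendar-month
mapping because hemisphere-dependent season timing should not be
guessed. Exclusion is monotone in the radius. "Operational" is resolved
at year granularity — commissioning year is all the registry offers —
so pre-operational placebo months are all months of years strictly
before commissioning.

**Population.** Exposed population is the sum of raster cells within
50 km, with overlapping plant radii partitioned by nearest-plant
(Thiessen) assignment so the per-plant counts sum exactly to the union
population; coincident plants tie-break by id with a warning. Five-year
raster steps are linearly interpolated to an annual series (no
extrapolation), and the 65+ population is the all-age count times the
country-year elderly share (uniform age distribution within country).

## 3. Estimation

The benchmark model is

    PM_icmy = β·FHD_cmy + X'_icmy γ + α_i + α_my + α_cm + ε_icmy

with plant effects α_i, month-by-year effects α_my, and
market-by-calendar-month effects α_cm, estimated by OLS. Below 5,000
rows the fixed effects are partialled out exactly by dense least-squares
projection on the dummy design; above, by alternating within-group
demeaning (relative tolerance 1e-10, at most 10,000 sweeps). The two
agree to 1e-8 on every fixture small enough to run both — this oracle
equivalence, plus a Frisch–Waugh check and an independent statsmodels
comparison, is the estimator's correctness argument. Observations that
are singletons within any fixed-effect group are dropped iteratively
(logged) before estimation. An exposure absorbed by the fixed effects
raises a diagnostic error naming the absorbing factor.

**Inference.** Standard errors cluster at the market level with the CR1
small-sample convention: (X'X)⁻¹[Σ_g X'_g e_g e'_g X_g](X'X)⁻¹ scaled
by G/(G−1)·(N−1)/(N−K), where K counts the exact rank of the design
when feasible (≤ 5,000 rows) and an analytic level-count approximation
otherwise — at panel scale the difference moves (N−1)/(N−K) by well
under 0.1%. p-values are two-sided t with G−1 degrees of freedom, the
standard choice with few clusters. With 19 clusters, simulation shows
95% interval coverage near 93% — the mild under-coverage expected of
CR1 at this cluster count; wild-bootstrap and spatial-kernel
alternatives are out of scope.

**Variants.** The dose-response specification bins FHD into [0, .25),
[.25, .5), [.5, .75), [.75, 1] with the lowest bin as reference.
Heterogeneity fits interact FHD with the full set of subgroup
indicators (size ≥ 30 MW — the US DoE large-plant cut — or fuel), so
each coefficient is directly the subgroup marginal effect; this is a
reparametrization of base-plus-interaction, and pairwise differences
use the delta rule on the cluster covariance. The implied total at
exposure f is `baseline + β·f`, where the baseline is the sample-mean
prediction with exposure set to zero (mean(y) − β·mean(FHD)); the
underlying "predicted level in the absence of drought" has no explicit
formula, and this interpretation makes the implied total at the mean
exposure equal the observed outcome mean. Placebo runs re-estimate the
identical model on (a) non-combustion plants with no combustion plant
within the radius and (b) pre-operational combustion plant-months.
Controls enter in levels only, matching the linear X'γ of the benchmark
(polynomial/interaction robustness belongs to the out-of-scope
post-double-selection analysis).

## 4. Health burden and valuation

Excess PM2.5 is β·FHD; monthly deaths are

    CRF_rate × days × excess × pop65 / 1e6

with a constant concentration-response rate (default 0.69 daily deaths
per million adults 65+ per µg m⁻³, scaled by a fixed 30 days/month;
calendar-true month lengths are a config option, off by default).
Alternative CRFs plug in through `CrfSpec` alone; relative-risk
functional forms are out of scope. Uncertainty is propagated by drawing
the coefficient 1000 times from N(1.55, 0.31²) — its estimated sampling
distribution — and re-evaluating the chain per draw. Negative draws
(probability ≈ 3e-7) are kept: the Monte Carlo represents estimation
uncertainty, and truncation would bias the distribution. Because deaths
are linear in the drawn coefficient, requesting an aggregated draw
table (plant, country-year, region-year) sums the per-unit-β base
*before* crossing with the draws; this is exactly equivalent to
aggregating the full plant-month draw table and is what keeps a
1000-draw, 21-year run cheap. Population 65+ enters at annual
resolution, constant within the year.

Deaths are monetized with a country-year VSL transferred from a US base
value with unit income elasticity: VSL_cy = base·(GNI_cy/GNI_US,y)^η.
The base VSL is a required config number; the shipped default ($7.0M,
2019 USD) is a placeholder in the range of recent US meta-analyses and
is labelled non-authoritative because the source value is not printed
anywhere usable. Which GNI series variant (Atlas vs PPP) feeds the
ratio is likewise the caller's choice and is recorded in run metadata.
All monetary outputs are constant 2019 USD; inputs must be pre-deflated.

## 5. Projections

Projected runoff (per climate model × SSP-RCP scenario, 2020–2059 with
two warm-up months) is converted to FHD with the historical
calendar-month climatology and historical anomaly dispersion — the same
code path as the retrospective analysis, anchored to the same baseline.
Percent change in FHD compares the 2020–2059 mean to the 2000–2019
mean. Retirement schedules order plants by exposed population
(descending, ties by id) and retire them against a per-year quantity
path supplied in config — the underlying capacity schedules are
external inputs the pipeline cannot derive. RES retires nothing; the
default SSP-RCP↔policy pairing (SSP1-2.6↔APS, SSP2-4.5↔STEPS,
SSP3-7.0↔RES) is overridable so the full cross can be run. Projected
deaths use the constant CRF and constant β (no adaptation, no
technological change, no new combustion plants); population and VSL
scale by scenario country-year multipliers. A run over M models and S
scenarios produces exactly M·S paths, enforced.

## 6. The synthetic world

The generator produces every input with known truth so each stage can
be checked against ground rather than against itself.

**Geometry.** Markets are square tiles (default 3°) side by side near
the equator; one market = one country. Emitting plants (combustion and
non-combustion) sit on lattice slots separated by more than twice the
dispersion radius, so every cell within a plant's radius is nearer to
that plant than to any other emitter; configurations that cannot honor
the separation raise a geometry error. Hydropower plants sit anywhere
and attach to sub-basins of a per-market river network (column stripes
of runoff cells linked into a random forest). No real geography is
imitated.

**Runoff.** A deterministic per-cell seasonal cycle (calendar-month
sinusoid, market-specific phase) interrupted by negative-anomaly
episodes: per watershed-month, with probability 0.08, runoff over the
watershed's cells is scaled down by a factor drawn from U(0.3, 0.8) for
4 months. With the rate at zero the cycle repeats identically and FHD
is identically zero. The defaults make the analysis-sample mean FHD
≈ 0.44, in the neighborhood of the ratio implied by the worked
examples (0.83/1.55 ≈ 0.54), and let FHD span [0, 1]. At this episode
occupancy the realized climatology is itself depressed, so a shallow
episode month need not lie below it; the episode-below-climatology
property is guaranteed (and tested) in the sparse-episode regime where
the minimum depth exceeds the expected climatology depression.

**PM2.5.** The surface equals, cell by cell, the panel-model value of
the nearest emitter: plant effect (N(15, 2²)) + month-year effect
(N(0, 0.5²)) + market-calendar-month effect (N(0, 0.8²)) + γ'X + β·FHD
for operational combustion plants + a monthly N(0, 1) noise draw shared
across the plant's whole neighborhood (spatially correlated within the
radius, independent across months — the simplest structure consistent
with the panel error). The regression design X is built by calling the
*same* panel-assembly code the analysis uses, which is what makes
zero-noise recovery exact rather than approximate. Degree-days for a
panel are computed from the market mean over the plants in that panel,
so combustion and non-combustion panels are each internally consistent.
Wildfire events (per-cell probability 0.01/month, log-normal emission)
splash extra PM onto cells within 5 km of the burning cell; fires are
independent of drought in this world, so the exclusion filter is
exercised mechanically but wildfire *confounding* is deliberately not
emulated — the placebo tests detect the absence of a generation-shift
effect, not fire contamination.

**Bookkeeping defaults.** 22 markets of which 3 lack hydropower, so 19
markets (clusters) enter the analysis; 4 combustion + 1 non-combustion
+ 3 hydropower plants per market; monthly panel 2000–2020; a quarter of
combustion plants commission mid-panel (pre-operational placebo
months); capacities log-normal (combustion median ≈ 30 MW, straddling
the size cut); fuel mix coal/gas/oil/biomass = .15/.35/.30/.20;
population rasters at five-year steps with per-market growth; country
tables with rising elderly shares and GNI paths plus a US GNI row. The
true drought effect defaults to 1.55 µg m⁻³ at FHD = 1 and can be made
fuel- or size-specific for heterogeneity exercises. Runoff, fire, and
meteorology grids use 0.25°; the PM2.5/population grid uses 0.05°, fine
enough that a 50 km radius covers ≈ 250 cells while keeping a full
21-year world regenerable in ≈ 1.5 s — the property the repeated-
simulation checks below rely on. Randomness is stream-split per
component, so changing one component's parameters leaves the others'
draws untouched.

**Projected runoff.** Per (model, scenario): the historical seasonal
cycle scaled by a linearly growing drying factor (scenario means
ordered SSP1 < SSP2 < SSP3, a persistent per-model offset shared across
scenarios) with multiplicative month-cell noise (sd 0.15). Ensemble
magnitudes are not calibrated to any real ensemble; only signs and
orderings are meaningful, and tests treat them that way.

**What passing tests do and do not show.** The synthetic world shares
the real data's *structure* (panel dimensions, fixed-effect hierarchy,
error clustering by market-month exposure, exclusion filters, censored
first window) but not its physics: no atmospheric transport, no
wind-direction asymmetry, no spatially correlated meteorology across
markets, no drought-fire dependence, no storage/reservoir dynamics, and
an exactly linear dose-response. Passing therefore certifies the
statistical machinery — that the estimator, counterfactual, and
projection code compute what they claim on data whose truth is known —
not the substantive magnitudes of any real region.

## 7. Verification summary

- Hand-built 2-market, 24-month fixture with pencil-and-paper drought
  measures and an exactly recoverable (zero-noise) coefficient.
- Oracle equivalences: demeaned ≡ dummy OLS (1e-8); CR1 ≡ brute-force
  sandwich (1e-10); watershed tracing ≡ transitive closure; Thiessen
  conservation exact.
- Calibration: across 200 regenerated default worlds, mean bias of the
  estimated drought coefficient is ≈ 0.3% and 95% CI coverage ≈ 93%
  (bounds asserted: bias < 2%, coverage within [88%, 99%]).
- Every figure quoted in this note is computed by the test suite or by
  `scripts/acceptance.py`; none is asserted from memory.

## 8. Known limitations

Single 65+ age band and uniform within-country age structure; constant
linear CRF only; no morbidity, productivity, or quality-of-life
outcomes; no socioeconomic vulnerability weighting (real-world
estimates are argued to be lower bounds for exactly this reason); no
wild-cluster bootstrap or spatial standard errors; retirement quantity
paths and the base VSL are config inputs, not derived quantities; the
approximate dummy-rank correction for panels above 5,000 rows; and the
synthetic world's simplifications listed above.
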