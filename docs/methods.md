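# Methods

This note documents the models, the synthetic survey the tests rely on, the
numerical choices, and the known limitations.

## Pipeline overview

Input is a per-station catch table (station, season, species, catch weight,
tow duration) and a per-station bottom-environment table (temperature °C,
salinity ‰, depth m, with a measured/modelled/missing source flag). The
analysis chain is: dominance screening → per-factor suitability curves →
BRT factor weights → composite habitat suitability (AMM/GMM, CV + AIC
choice) → ordinary kriging → optimal-habitat overlap index.

## Dominance screening

Per season, a species' proportion is its total catch weight over the
all-species season total; species with proportion **strictly** above the
threshold (default 0.05) are retained, ordered by descending biomass, with
the cumulative proportion computed down the retained list. Using the
all-species denominator means the cumulative proportion measures how much of
the community the dominant set represents (it is generally well below 1).
Ties at exactly the threshold are excluded. Screening is per-season: a
species may be dominant in some seasons only.

## Suitability curves

SI(x) = (Ŷ(x) − Ŷ_min)/(Ŷ_max − Ŷ_min), with Ŷ a LOESS fit of yield (g/h)
on the factor, evaluated on an equispaced grid (default 100 points) over the
observed factor range. Choices:

- **LOESS**: tricube-weighted local polynomial, default span 0.75 and degree
  2 — common LOESS practice; both config-exposed. The implementation is a
  fully vectorised local weighted least squares with a tiny ridge
  (1e-10 × trace) for degenerate neighbourhoods; it reproduces polynomials
  up to the local degree exactly and matches the statsmodels local-linear
  smoother at degree 1 (cross-checked in the tests).
- Fitted values are **clipped at 0** before normalisation: a negative
  smoothed yield is physically meaningless, and clipping cannot move the
  argmax. Consequence: SI is exactly invariant to positive *scaling* of
  yields always, and to affine shifts whenever the fit stays nonnegative —
  clipping can break exact shift invariance when the unshifted fit dips
  below zero.
- Stations with zero yield are **included** in the fit; absence at a fixed
  station is information about unsuitability.
- A constant smoothed response (relative variation below 1e-6, the solver's
  numeric jitter is ~1e-7) raises a flat-response error: SI is undefined.
- Evaluation between grid points is linear interpolation; outside the
  observed range the endpoint SI is used (clamping).
- Optimal ranges at a level (default 0.7) are maximal grid intervals with
  SI ≥ level; several disjoint intervals capture secondary suitable ranges.

## Factor importance (BRT)

Gradient-boosted regression trees of log1p(yield) on temperature, salinity
and depth; the log1p tames the heavy right tail of trawl catches and does
not affect importance ranking. Relative influence is the classic split-gain
(Friedman) measure — each factor's share of the total squared-error
reduction over all splits — normalised to sum to 1 (scikit-learn's
impurity-based feature importance). Defaults follow gbm/dismo conventions:
1000 trees, learning rate 0.01, depth 3, bag fraction 0.75, all
config-exposed. A factor is called *dominant* when its weight beats the
runner-up by ≥ 0.1 (the margin operationalises "no predominant factor");
a constant response yields uniform weights with a warning.

## Composite HSI and model choice

AMM = Σwᵢ·SIᵢ/Σwᵢ; GMM = (Π SIᵢ^wᵢ)^(1/Σwᵢ). Both are monotone in each SI,
bounded in [0,1], equal s when all inputs are s, and GMM ≤ AMM (weighted
AM–GM). GMM has veto semantics: one SI of 0 with positive weight gives
HSI 0 (no epsilon floor — total unsuitability in one factor vetoes the
habitat). A factor with zero weight has no influence (SI⁰ = 1 convention).

Model choice: 100 seeded random 80/20 splits. Within each repetition the
suitability curves are refit on the training stations (honest
cross-validation; `cv.refit_curves: false` fits once on all data), HSI is
predicted at held-out stations, and observed suitability — the
min–max-normalised raw station yield, normalised once over **all** stations
so the observation does not depend on the split — is regressed on predicted
HSI by OLS. The per-repetition Gaussian AIC uses three parameters (slope,
intercept, error variance); the model with the lower **mean** AIC across
repetitions is selected, ties to AMM. Splits depend only on the seed, so
AMM/GMM comparisons are paired. Repetitions with fewer than three test
stations, a degenerate curve fit, or a constant prediction are skipped with
a warning and counted.

A structural note that shaped the recovery test: the smoothed *marginal*
response under a multiplicative (GMM) data-generating process is a
power-compressed version of the true factor curve, so the refit composite
relates nonlinearly to the observation and the AIC gap between AMM and GMM
narrows. What reliably discriminates the two composites is GMM's veto
region: when the true factor curves actually reach zero inside the sampled
range, only the geometric composite reproduces the observed zeros. The
model-selection recovery test therefore uses min–max-normalised true curves
(which reach 0 at the range edges), 300 stations, weak multiplicative noise
(σ = 0.05) and LOESS span 0.5 — under which the generating composite is
recovered decisively in both directions.

## Kriging and classification

Ordinary kriging in decimal degrees (no projection; downstream areas are
cell counts, so geodesic correction is unnecessary). The empirical
semivariogram uses 15 linear lag bins up to half the maximum pairwise
distance; a parametric model (spherical default; exponential and gaussian
available) is fitted by least squares weighted by √(pair count per bin).
The kriging system is factorised once per species-season and solved for all
grid cells (default 0.1° cell centres, finer than the 0.5° station
spacing). Duplicate station coordinates are rejected by name (singular
system). Negative predictions are retained — kriging can undershoot even
though suitability is nonnegative — and the display classification maps
value ≤ 0 to category 0, then (0, 0.25] → 1, (0.25, 0.5] → 2,
(0.5, 0.75] → 3, (0.75, ∞) → 4 (the half-open convention puts 0 in the
zero category; values above 1 fall in the top class). Cells outside the
convex hull of the stations are flagged and excluded from all area
accounting, since extrapolation artifacts would distort overlap fractions.

## Overlap index

Optimal habitat = in-hull cells with interpolated suitability **strictly**
greater than the cutoff (default 0.7). The cutoff is applied to the kriged
HSI surface by default; `overlap.target: si` instead kriges and thresholds
the per-station observed suitability (the two readings of "suitability above
0.7" differ and both are supported). Occupied cells are labelled by the
number of covering species (single/pair/multi ≥ 3); area fractions Aᵢ use
the union of optimal cells as denominator — the only reading under which
ΣAᵢ = 1 as the index requires — and I = −0.5·A_single + 1·A_pair +
2·A_multi ∈ [−0.5, 2]. Exact per-subset intersection counts (disjoint,
upset-diagram semantics) are exported for plotting elsewhere. A species
whose optimal mask is smaller than `overlap.min_cells` (default 0 = keep
all) can be excluded, mirroring the practice of dropping a species with a
negligible optimal range from the overlap comparison. With no occupied
cells the index is defined as 0 with a warning. Seasons are reported ranked
by index, stable under ties.

## Synthetic survey generator

The generator emulates a seasonal fixed-station bottom-trawl survey of the
East China Sea shelf: a 0.5° (30′) lattice over 27–34° N, 122–127° E (165
stations), smooth linear-gradient bottom fields per season (temperature
base 16/26/20/11 °C for spring/summer/autumn/winter with latitudinal
cooling; salinity ~30–34 ‰ increasing offshore; depth 20–161 m deepening
eastward), and species with Gaussian preference responses: expected yield
q_max·Π exp(−((x−μ)/σ)²), multiplied by lognormal noise (σ = 0.3) and
zeroed with probability 0.2 — heavy-tailed, zero-rich catches. Tow duration
is fixed at 1 h so weight and yield coincide. Defaults: five dominant
species (q_max 7 000–30 000 g/h) plus six low-biomass background species
per season; 10 % of stations lose their CTD cast at random (a
`missing_block_south_of` flag reproduces geographically structured
missingness instead); gap-filling by inverse-squared-distance (default) or
nearest-station imputation stands in for an external ocean-model product.
Catch is always sampled from the *true* fields, never the gap-filled ones.

The default scenario's species preference optima are placed at
centre + spread × offset with per-season spread 2.0/1.2/0.7/0.1 (factor
units scaled per factor): habitat preferences converge progressively from
spring (dispersed, post-overwintering) to winter (shared overwintering
grounds), so the seasonal overlap index rises strictly across the four
seasons. The spread schedule was set so the designed between-season gaps
exceed the estimation noise of the index (the main noise source being the
AMM/GMM choice flipping optimal-mask sizes); with narrower autumn/winter
gaps the trend is not reliably identifiable at survey size.

What the generator does **not** emulate: ocean circulation or fronts
(fields are smooth parametric surfaces), species interactions (responses
are independent given the environment), gear selectivity, day/night or
tidal effects, and interannual variability. Passing recovery tests
therefore demonstrate that the estimation chain recovers known responses
under realistic noise — not that the pipeline's ecological conclusions
transfer to any particular real survey.

## Determinism and problem sizes

A single top-level seed deterministically derives every stage seed (hashed
per stage × season × species, all below 2³¹); two runs with the same seed
produce byte-identical outputs (verified by manifest checksums). The test
suite and the acceptance script use the survey-scale defaults throughout:
165 stations, 0.1° kriging grid (3 621 cells), 100 CV repetitions, 20
replicates for recovery rates — a full four-season pipeline run takes about
a minute on one CPU.

## Known limitations

- Euclidean distance in degrees ignores the ~12 % longitude/latitude metric
  anisotropy at 30° N; at survey scale this is far below the variogram's
  estimation error.
- The LOESS grid spans the observed factor range only; SI outside it is the
  clamped endpoint value.
- BRT importance is impurity-based and shares its known bias toward
  high-cardinality predictors; with three continuous factors this is moot.
- Observed suitability for validation is min–max-normalised raw yield, so a
  single extreme station compresses all other observations toward 0.
- The overlap index weights {−0.5, 1, 2} are a fixed convention
  (config-exposed); the index is not a statistical test and no uncertainty
  is attached to it.
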