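# habsuit

Seasonal habitat-suitability modelling and spatial niche-overlap analysis for
fixed-station trawl surveys.

Fishery surveys that tow the same station grid every season produce, per
station, a catch weight for each species and a bottom CTD cast (temperature,
salinity, depth). `habsuit` turns those two tables into a quantitative
picture of where each dominant species' suitable habitat lies, which
environmental factor drives it, and how strongly the species' optimal
habitats overlap in space — and how that overlap shifts season by season.
Because real survey data of this kind is often confidential, the package
ships a synthetic survey generator with known ground-truth species responses,
so every stage is verifiable by parameter recovery.

## The model

For each season, species whose share of total catch biomass exceeds 5 % are
retained (*dominance screening*). For each retained species and each factor
*x* ∈ {temperature, salinity, depth}:

1. **Suitability index.** Station yield (g/h, weight per tow hour) is
   LOESS-smoothed against *x* and min–max normalised:

   SI(x) = (Ŷ(x) − Ŷ_min) / (Ŷ_max − Ŷ_min) ∈ [0, 1].

2. **Factor weights.** A boosted-regression-tree fit of log1p(yield) on the
   three factors supplies each factor's relative influence *wᵢ* (share of
   total split-gain, normalised to Σwᵢ = 1).

3. **Composite HSI.** Per station, the three SI values are combined by the
   weighted arithmetic-mean model, HSI = Σwᵢ·SIᵢ / Σwᵢ, or the weighted
   geometric-mean model, HSI = (Π SIᵢ^wᵢ)^(1/Σwᵢ). The composite is chosen
   by 100 repetitions of an 80/20 random split: curves are refit on the
   training stations, observed suitability (min–max-normalised raw yield) is
   regressed on predicted HSI over the held-out stations, and the model with
   the lower mean Gaussian AIC wins.

4. **Mapping.** Station HSI is interpolated onto a 0.1° grid by ordinary
   kriging (WLS-fitted spherical semivariogram); cells are classified into
   five display categories (≤ 0, then four equal intervals of (0, 1]).

5. **Overlap.** A species' *optimal habitat* is the in-hull cells with
   HSI > 0.7. Each occupied cell is labelled single / pair / multi (1, 2,
   ≥ 3 overlapping species) and the seasonal overlap index is

   I_overlap = Σ wᵢ·Aᵢ, w = {single: −0.5, pair: 1, multi: 2},

   where Aᵢ are level area fractions (cell counts). The index lives in
   [−0.5, 2]: −0.5 = fully separated niches, 2 = every optimal cell shared
   by three or more species.

## Worked example

Run the whole pipeline on the built-in synthetic four-season survey (165
stations on a 0.5° grid over 27–34° N, 122–127° E; five dominant species
whose habitat preferences converge progressively from spring to winter):

```sh
habsuit run-all --outdir out --seed 42
```

which prints the seasonal overlap report (also written to
`out/seasonal_report.csv`):

```
season  count_area  n_single  n_pair  n_multi  a_single   a_pair  a_multi  overlap_index
spring        2766      2559     207        0  0.925163 0.074837 0.000000      -0.387744
summer        2582      1358    1224        0  0.525949 0.474051 0.000000       0.211077
autumn        2796       967     985      844  0.345851 0.352289 0.301860       0.783083
winter        1608       248     191     1169  0.154229 0.118781 0.726990       1.495647
```

Reading it: in spring 92.5 % of optimal-habitat cells belong to a single
species (index −0.39, niches nearly separated); by winter 72.7 % of cells are
shared by three or more species (index 1.50) — the overlap index rises
strictly as the generator draws the species' preference optima closer
together. `count_area` is the number of occupied grid cells. The other
outputs under `out/` are the dominance table, SI curves, BRT weights, CV
report, station HSI, kriged surfaces, optimal-habitat masks and upset-style
intersection counts; `manifest.json` records the config and output checksums
(a rerun with the same seed is bit-identical).

Stages can also be run one at a time (`habsuit simulate`, `screen`, `si`,
`importance`, `hsi`, `krige`, `overlap`, `report`); each consumes the
previous stage's CSV.

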