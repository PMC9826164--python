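# Methods

`ifmaudit` implements a remote-sensing audit of the additionality of
improved-forest-management (IFM) carbon-offset projects: given annual maps of
aboveground-live (AGL) forest carbon density, annual binary harvest masks,
single-year species-composition layers, project polygons with crediting
documents, and covariate rasters, it asks whether enrolled lands behave any
differently from comparable unenrolled lands — before enrollment (stocks,
trends, harvest pressure, species mix) and after it (change in carbon
accumulation and in harvest). This note records the models, parameter
choices, and numerical conventions, and what the synthetic-data experiments
do and do not demonstrate.

## The audit design

Five falsifiable hypotheses structure the audit (H1–H5 in the report):

1. **Pre-project carbon trend.** Offset crediting against a *static* baseline
   presumes stocks would not otherwise grow. A significantly positive
   historical trend on project lands (and controls) contradicts that premise.
   We fit an OLS trend to the area-weighted portfolio carbon series over the
   pre-period and express it as a percent of the period-mean stock.
2. **Pre-project harvest.** Projects harvested significantly *more* than
   controls suggest crediting of stands already recovering from harvest;
   significantly *less* suggests low harvest risk. Either direction, when
   significant in a paired t-test across years, is scored as inconsistent
   with additionality; an indistinguishable rate is inconclusive.
3. **Pre-project species composition.** Enrichment of a low-timber-value
   species (tanoak in the coastal system) inside projects signals low
   opportunity cost of not harvesting. Fractions are species carbon over
   total carbon within a mask; the test is a paired t across projects.
4. **Post-initiation carbon.** A Chow F-test for a slope break at the start
   year, applied to the **project-minus-control** carbon series over equal
   before/after windows. Differencing against the control first is essential:
   shocks shared by project and control — weather, regional harvest-intensity
   years — integrate into the carbon *stock* and give the raw series
   near-unit-root errors on which a Chow test grossly over-rejects; and the
   common exponential growth trajectory has curvature that a two-segment fit
   mistakes for a break. The contrast series removes both, leaving
   project-specific change, which is the quantity of interest.
5. **Post-initiation harvest.** A paired t-test of harvest fractions over
   equal windows, paired by year-offset from the start (year `start+i`
   against `start−w+i`), scored against the control's own change.

Verdicts are three-way: an effect in the additionality direction significant
at α = 0.05 is *consistent-with-additionality*; a significant effect in the
opposite direction — or, for H1/H4/H5, the absence of any detectable change,
since the protocol's premise is that enrollment changes behavior — is
*inconsistent*; anything else, including insufficient data, is
*inconclusive* with a recorded reason. The five verdicts are reported
separately; no combined additionality score is computed, because any such
combination would be a convention of this package rather than a measurement.

Cohort rules for the before/after comparisons: a project enters the H4/H5
cohort when its start year allows at least 3 annual carbon observations and
7 annual harvest observations afterwards; the window length `w` is the number
of post-start years available (capped by the record), and the before-window
is the `w` years ending at the start year.

## Crediting arithmetic

Registry documents report total carbon stocks (ton CO2e or ton C) and credit
issuances (ton CO2e). Conversions: C = CO2 × 12.01/44.01; AGL = total ×
0.806 (the mean AGL share where both are reported, applied when a document
reports totals only); carbon = biomass × 0.47. The crediting summary treats
the first issuance as the initial above-baseline stocking payout and averages
subsequent issuances per year of the span they cover; when the annual stream
is positive, the break-even time (years for cumulative incremental credits
to equal the initial payout) equals the initial-to-annual ratio. Per-project
reported accumulation rates are OLS slopes of reported AGL stock on year
(endpoint differences are an alternative the data cannot distinguish; the
slope is less sensitive to a single bad inventory). Portfolio rates are
area-weighted means with an *unweighted* standard error across projects, so
the error bar describes the project sample.

## Control systems

* **Buffer**: all private-forest pixels within 2 km of the project boundary
  (Euclidean, in the projected CRS), excluding the project, other projects'
  interiors, urban/agricultural and public land. When a regional label is
  available the ring is clipped to the project's own region; without the
  clip, a ring straddling a regional boundary mixes lands under different
  harvest regimes and biases the harvest contrast (on synthetic scenes by
  tens of percent).
* **Region**: every private-forest pixel carrying the project's region label,
  with enrolled land excluded by default (a flag restores the
  all-private-forest variant).
* **Matched**: on a coarse (~800 m) grid, the `n` candidate cells nearest the
  project's mean covariates (mean annual temperature, precipitation, site
  productivity class) by Mahalanobis distance, with `n` = round(project area
  / coarse cell area). Covariates are z-scored over the candidate pool and
  the covariance is taken in that standardized space; the project's mean is
  computed over its coarse footprint (cells ≥ 50% covered, or the
  best-covered cell for sub-cell projects); candidates exclude every cell
  touched by any project; ties in distance break by flat cell index so runs
  are reproducible; a singular covariance falls back to its diagonal with a
  warning.

Every control mask is disjoint from every project footprint; this is
asserted in tests for all three systems.

## Raster conventions

Grids are row-major with (row, col) indexing; the affine transform maps
pixel corners and pixel centers sit at half-integer offsets. A pixel belongs
to a polygon iff its center is covered (the standard unbiased zonal
convention). Zonal statistics use valid pixels only; a region-year with
fewer than 50% valid pixels is reported missing (NaN), never zero. Block
aggregation to the coarse covariate grid takes the mean of valid fine cells
and yields nodata below the same 50% rule; 30 m → 800 m uses the nearest
integer factor (27, i.e. 810 m) to preserve exact mean-aggregation
semantics. On disk each year is a single-band TIFF whose ImageDescription
tag carries a JSON georeference record (year, transform, CRS, nodata,
units), so stacks are self-describing and consistency is checked per file;
polygons travel as GeoJSON, documents and extracted series as tidy CSV.

## The synthetic landscape generator

The generator fabricates the full input complement with known ground truth.
Design targets, in order: (i) regional carbon dynamics matching the study
system — a coastal analogue growing ≈ 1%/yr and an interior analogue near
0%/yr; (ii) patchy harvest with post-harvest drop and recovery, producing
the decline–recovery sawtooth visible in Landsat biomass series; (iii) a
saturating measurement model; (iv) species layers with an enrichable
low-value species; (v) documents whose reported accumulation can exceed the
measured rate by a configurable factor.

**Stand dynamics.** Per-pixel biomass grows at the regional relative rate
`g` (coastal 1.05%/yr, interior 0.1%/yr by default), ramping linearly to
zero over the top 20% of a regional carrying capacity (900 / 400 ton
biomass/ha — old coastal redwood stands exceed 900 Mg/ha, interior mixed
conifer saturates far lower). Harvest multiplies biomass by a retention
fraction (0.1, clear-cut-like). Each pixel tracks a target trajectory —
its initial stand biomass drifting at `exp(g)` — and recovers toward it at
rate ln 2 / half-life (10 yr) whenever that exceeds the growth term; this
realizes the "recovery toward the pre-harvest path" behavior with one
interpretable parameter. A 50-year spin-up, with the target back-dated so it
reaches the configured initial biomass (250 / 110 ton/ha) exactly at the
first recorded year, equilibrates the harvest/recovery sawtooth in the
growing regime; without it the record's first decade absorbs the transient
and the realized trend undershoots `g` by a few tenths of a percent per
year. Realized regional rates land within ±0.1 %/yr of the configured
values; realized regional mean stocks (~100 coastal, ~48 interior ton C/ha)
fall in the range the biomass maps report for the corresponding private
forestlands.

**Noise model.** Two components, chosen to reflect how Landsat-calibrated
biomass maps actually err. A small *persistent* lognormal pixel-year
perturbation (cv 0.03) represents real growth variability and compounds over
time. A *transient*, spatially correlated perturbation (cv 0.035,
correlation length 8 pixels) applied only to the recorded value represents
map and imputation error that does not propagate between years — without a
transient component the zonal series is an almost pure random walk, which no
classical test survives. The transient amplitude is the one genuinely free
noise knob; it was fixed so that the before/after machinery is approximately
calibrated on null scenes (type-I well under 10%) while retaining ≥ 80%
power for the +0.5 ton C/ha/yr recovery experiment, and then frozen.

**Harvest.** Square patches (side 2 pixels) with Poisson yearly counts per
region; expected area fractions default to 3%/yr (coastal) and 1%/yr
(interior); a lognormal year factor (cv 0.3) adds the strong interannual
fluctuation real harvest records show — the year-to-year variance is
deliberately an exposed parameter. The patch size is set relative to the
default project footprints (≈ 450–900 pixels) so the patches-per-project
ratio (~150) approximates the study system, where ~46 km² projects contain
~20 ha harvest units (~230); the harvest-count noise a project series sees
is then comparable, at desk scale, to the real setting.

**Projects, effects, documents.** Rectangular projects are placed on valid
windows (inside one region, ≥ 60% private forest, non-overlapping — found by
integral-image window sums, with a relax-then-shrink fallback on crowded
scenes). Placement bias picks the candidate with the highest pre-start
harvest frequency or low-value-species share, optionally restricted to one
owner class (mirroring the strategy attributed to large timber companies).
Effect injection is a tuple so harvest cessation and an accumulation boost
can be applied together; both reuse the identical random draws as the
unperturbed scene, so a treated and untreated run of one seed differ only
through the injected mechanism. Documents report stocks on the
total-carbon convention with the accumulation rate equal to the measured
(true zonal) rate times the inflation factor, a baseline at a configured
fraction (0.7) of the initial stock, and issuances in ton CO2e — initial
above-baseline stock first, annual increments thereafter.

**Scope of the emulation.** The generator does not simulate fire, drought,
pest mortality, spectral saturation beyond the piecewise-linear model,
harvest intensity (its masks are binary, like the real disturbance product),
landowner economics, or leakage. Passing recovery tests therefore show that
the *statistical machinery* detects management signals of the stated size
under realistic noise and autocorrelation — not that such signals would be
detectable in any particular real landscape, where confounding (fires,
markets, protocol behavior) is richer.

## Numerical choices

* Chow test: classic F with k = 2 parameters per segment, p from the F
  distribution; both-segments-exact fits report F = ∞, p = 0; a pooled fit
  that is itself exact reports F = 0, p = 1. Heteroskedasticity-robust
  variants are out of scope.
* Paired tests with zero-variance differences are flagged degenerate:
  identical series give t = 0, p = 1; a constant nonzero difference has no
  valid t and is reported as such rather than as p = 0.
* Percent rates divide the OLS slope by the period-mean value; the
  initial-year denominator is available as an option (for slowly changing
  stocks the two differ by under a tenth of a percentage point per year).
* Relative differences are expressed on the control mean.
* No multiple-testing correction is applied across the hypothesis suite;
  the audit reports per-comparison p-values.
* Masks, tie-breaks, and candidate orderings are deterministic; re-running
  an audit on the same scene and configuration is byte-identical.

## Problem sizes

The default scene is a 120×120 grid of 30 m cells (~13 km², three projects
of 40–80 ha) over 1986–2017 carbon / 1986–2021 harvest with a 50-year
spin-up — small enough that a full scene generates in about a second and the
replication experiments (2,000-replicate test calibrations; 200 scenes per
arm for the detection study) complete in minutes on one CPU, while keeping
enough pixels per project and per ring for the zonal statistics to behave
like their large-raster counterparts. The recovery experiment evaluates a
cohort starting in 2009, giving 8 annual carbon and 12 annual harvest
observations per window; the study-period defaults (start ≤ 2014, ≥ 3
carbon / ≥ 7 harvest points) remain the audit's defaults.
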