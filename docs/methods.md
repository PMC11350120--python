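# Methods

This note documents the models implemented in `dendrowue`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting or
extending a result.

## Study design being modelled

Four even-species European beech stands along a ~900 km latitudinal
transect (north to south: TRE, LAZ, CAM, CAL), analysed over the common
interval **1965–2014** (50 years, set by the youngest stand). Stand
structure: 40/20/65/50 trees with mean ages at coring height of
78 ± 15 / 53 ± 8 / 102 ± 20 / 63 ± 7 years and mean ring widths of
1.01/2.05/0.98/1.43 mm. Site climate: mean annual temperature
9.0/14.3/9.8/11.0 °C, annual precipitation 929/829/825/1003 mm, with soil
water holding capacity classed low/high/high/moderate. These constants are
the defaults of `synthetic.default_study_fixture` and of `RunConfig`.

## Ring widths and basal area increment

Ring widths (mm, 0.01 mm precision) are read and written in the Tucson
decadal layout; both stop-marker dialects are supported (999 ⇒ units of
0.01 mm, −9999 ⇒ 0.001 mm). Basal area increment assumes a circular stem:
`BAI_t = π(R_t² − R_{t−1}²)`, R_t = pith offset + cumulative width. The
pith is assumed at the innermost ring (offset 0) unless stated — cores are
treated as pith-to-bark. Truncating a series to the analysis period folds
the pre-period growth into the pith offset, so radii (and hence BAI) remain
true; this matters and is tested. No detrending or standardization is
applied to ring widths or BAI anywhere: site chronologies are plain
arithmetic means with sample depth, because long-term cumulative climate
effects are part of the signal of interest.

GLK (Gleichläufigkeit) scores the sign agreement of year-to-year changes
over the common overlap; a zero change in either series scores 0.5
(classical tie convention), and at least 3 common years are required.

## Isotope discrimination and iWUE

The simple discrimination form is used, with a = 4.4 ‰ (stomatal diffusion)
and b = 27 ‰ (carboxylation); mesophyll conductance and photorespiration
terms are deliberately out of scope. The implementation derives
`iWUE = (ca − ci)/1.6` directly from the ci relation, so the two operations
cannot disagree algebraically (an identity the tests verify to 1e−12).
Units: ca in ppm ⇒ ci in ppm, iWUE in µmol mol⁻¹. Years whose implied ci
falls outside (0, ca) are flagged, never dropped.

The packaged atmospheric table (`data/atm_co2_d13c_synthetic.csv`) is a
*synthetic stand-in*: Mauna Loa annual CO₂ means (widely published values)
and a smooth monotone quadratic for the industrial-era δ¹³C_atm decline
(−7.25 ‰ in 1965 to −8.46 ‰ in 2014). No test or reported quantity depends
on its exact digits — only on its invariants (ca nondecreasing, δ¹³C_atm
decreasing). Users with a measured series supply it via `read_atm_csv`
(columns `year, co2_ppm, d13c_atm_permil`). Beyond entering δ¹³C_atm(t)
year by year, no additional fossil-fuel correction is applied.

## Climate indices

* **VPD** (hPa) from the Tetens curve on daily Tmean and RH (one value per
  day; no sub-daily scheme).
* **Extraterrestrial radiation** from standard FAO-56 solar geometry
  (latitude + day of year), rather than converting measured surface
  radiation — the only desk-reproducible choice. Units MJ m⁻² day⁻¹.
* **PET**: the study form `0.0029·Ra·(Tmean + 20)·TR^0.4` is the default
  (`modified_hargreaves`), taken verbatim; whether the 0.0029 coefficient
  absorbs the MJ→mm conversion is an unstated unit convention, so PET is
  read as mm day⁻¹ and the classical coefficients
  (`0.0023, +17.8, TR^0.5`; `classic_hargreaves`) are available behind the
  `pet_variant` switch for comparison. Negative values are clamped to 0.
* **CMI**: `P/PET − 1` when P < PET, `1 − PET/P` when P > PET — bounded in
  [−1, 1], antisymmetric, 0 at balance, undefined at P = PET = 0. Computed
  for the May–October growing season (fixed window, used consistently
  throughout the package).
* **SPEI**: k-month rolling sums of D = P − PET; for each calendar month a
  3-parameter log-logistic distribution is fitted by *unbiased*
  probability-weighted moments and the fitted CDF is mapped to
  standard-normal units via the Abramowitz–Stegun rational approximation.
  The full series is its own calibration period (no reference split), so
  per-calendar-month mean ≈ 0 and SD ≈ 1 by construction. A left-skewed
  monthly sample (where this parameterisation has no valid shape) is fitted
  on its mirror image with the CDF flipped — both skew directions then
  standardize cleanly. Extreme values are never clamped; non-finite
  transforms are flagged with a warning. Months with missing days are
  excluded from fits, not imputed; at least 25 years of monthly data are
  required for stable per-month fits.

## Climate–growth response

For response year t, the 24 predictor cells are the monthly values of
January(t−1)…December(t−1) (labelled `Jan*`…`Dec*`) and
January(t)…December(t). Deletion is pairwise-complete per cell, keeping n
maximal per month. Significance is the analytic two-tailed t threshold
`r_crit = t_{1−α/2,n−2}/√(t² + n − 2)`; no multiplicity correction is
applied (24 × 4 cells are reported as-is, so ~5 % of null cells are flagged
by design — the type-I calibration test pins this down). The SPEI scale
screen correlates annual BAI with each scale's **October** value, a
declared convention: the k-month window then covers the May–October growing
season plus the months leading into it.

Because seven partially dependent scales are screened without correction,
the *family-wise* probability of at least one significant scale under a
climate-independent response is ≈ 25–30 %, not α; the tests check per-scale
calibration and construction-based ranking (a response built from 18-month
smoothed D ranks scale 18 first), not a family-wise null.

## Growth trends

* **loess**: local polynomial regression (default span 0.75, degree 2 —
  common defaults) with tricube weights; the 95 % band is
  fit ± 1.96·σ̂·‖l_i‖ from the equivalent-kernel rows, σ̂² estimated from
  residuals and the smoother's effective df. Exact for polynomials up to
  the local degree.
* **Linear trends**: OLS with the two-sided slope t-test, and a Theil–Sen
  variant (median pairwise slope) paired with the Mann–Kendall p-value.
* **Additive growth model**: `BAI ~ s(year) + s(age) + s(SPEI) + α_tree`,
  fitted by backfitting. Each smooth is a cubic B-spline basis with
  **4 basis functions** and a second-difference penalty; the penalty weight
  is chosen by GCV on a fixed log-grid (10⁻⁴…10⁸, 25 points — seedless and
  deterministic). Per-tree intercepts absorb tree identity; components are
  centered every sweep, so they are identifiable up to additive constants
  *provided the covariates are not linearly linked* (year and age are
  exchangeable up to a linear function by construction, age = year − birth;
  the identifiability test therefore uses year + SPEI). Convergence:
  maximum component change < 1e−6, 200-iteration cap, non-convergence
  returned flagged with a warning. AIC = n·log(RSS/n) + 2·(smoothing
  traces + intercepts): the penalty counts every coefficient effectively
  estimated, while the reported per-smooth edf is the identifiable
  nonlinear df (trace − 1, so a maximally shrunk smooth reads edf ≈ 1,
  a line). This model is a deliberately simplified stand-in for a
  generalized additive mixed model: no thin-plate bases, no internal
  cross-validation of the smoother, no formal random-effect variance. It
  reproduces the inferential role (which terms matter, ranked by AIC), not
  any particular mixed-model software's numbers. The per-site year smooth
  realizes a year-by-site interaction by fitting sites separately.

## Early warning signals

Per tree: (1) remove the low-frequency signal with a Gaussian-kernel local
mean — bandwidth (kernel SD) defaults to 10 % of the series length (5 years
at n = 50), a conventional choice since the filter's bandwidth is otherwise
unspecified; edge weights are renormalised, so a constant series leaves
exactly zero residuals, while a linear trend leaves small edge residuals
(the local mean is edge-biased — quantified in the tests). (2) compute
lag-1 autocorrelation (lag-1 sample autocorrelation; shift- and
scale-invariant) and SD (n−1 denominator) in 15-year right-aligned moving
windows — 36 windows for 50 years, the first labelled 1979 (= 1965–1979),
15/50 = 30 %. A constant window leaves AR1 undefined (NaN + warning, then
excluded from the trend). (3) summarise each trajectory by Mann–Kendall τ
(tau-b with tie-corrected variance and continuity-corrected normal p).
Per site, the per-tree τ values are averaged, reported with their SE, and
tested one-sided (H₁: mean τ > 0) with a one-sample t-test; the symmetric
falling-trend p is the complement. Detrending is per tree, not on the site
chronology, since the per-tree statistics are what get averaged.

**Detectability.** With 15-year windows over 50 years, the window AR1
estimates carry sampling SD ≈ 1/√15 ≈ 0.26, which bounds the power of any
trend test on them. Simulation at exactly these dimensions shows that an
AR(1) drift of 0.01/yr from mid-series is detected at the 5 % level in only
~40 % of 20-tree stands — an information limit of the statistic, not an
implementation artifact. The recovery checks therefore inject 0.02/yr from
year 15 (base φ = 0.3), where measured power is ≥ 0.93. A late-onset drift
(e.g. starting at year 38 of 50, as in the TRE fixture narrative) affects
only the last third of the windows and is flagged in some but not all
replicates — a faithful property of late signals.

## The synthetic-data generator

What it emulates: per-site mean climate, linear decadal trends (warming at
all sites; VPD rising in the north and falling in the southernmost stand
via RH trends; precipitation rising at TRE/CAM, falling at LAZ), seasonal
cycles, stand age structure, age-related growth decline, growth responses
to growing-season temperature/VPD/precipitation scaled by the soil-water
class (low SWHC ⇒ 1.3× VPD sensitivity, high ⇒ 0.7×), AR(1) growth memory
with optional upward drift (the critical-slowing-down signal), the
Suess-effect δ¹³C_atm decline, and site δ¹³C offsets chosen so fixture
means land on −25.9/−25.1/−26.4/−24.8 ‰ (TRE/LAZ/CAM/CAL).

Key choices:

* Temperature noise has a **daily** term and a **year-scale anomaly** term
  (0.6 °C SD; likewise RH). Without interannual coherence, monthly climate
  shares almost no variance with the growing-season mean that drives
  growth, and no monthly correlation could recover an injected effect; a
  year-scale anomaly is also how real weather behaves. A corollary: the
  anomaly is common to all 12 months, so an injected growing-season effect
  also produces correlations in adjacent non-growing-season months —
  month-level specificity is *not* something passing tests demonstrate.
* Trends are anchored at a reference year (the fixture uses mid-period,
  1989) so the configured site means hold over 1965–2014 even when climate
  is generated back to the oldest tree's germination.
* Growth is multiplicative log-linear (`w = w0·e^{−decay·age}·e^{signal+ε}`):
  widths stay positive and injected effects are linear on the log scale
  where correlations are computed. The β coefficients act per SD of the
  standardized May–October anomaly.
* Precipitation: winter-peaking wet-day occurrence with gamma amounts whose
  expectation matches the configured annual total exactly — no claim of
  meteorological realism beyond the invariants the pipeline needs.
* One core per tree is emitted (within-tree core averaging is not
  modelled); ages are counted at coring height.

What it does **not** emulate: masting and late-frost biology, CO₂
fertilisation of growth, soil-moisture memory (SWHC enters only as a
sensitivity class), spatially correlated climate between sites, measurement
error structure of real cores. Two emergent artifacts are worth knowing:
young stands entering the analysis period near germination show a fast
early BAI rise whose residual curvature biases the site mean AR1-trend τ
slightly negative (~−0.05); and because site BAI chronologies trend upward
geometrically while VPD trends are site-signed, the *non-detrended*
correlation of BAI with a trending VPD can take the trend's sign at sites
where VPD rises, masking an injected negative sensitivity — the recovery
tests therefore inject effects one at a time, which is also what they are
meant to certify.

## Numerical conventions and degenerate inputs

Fixed seeds everywhere (`numpy.random.default_rng`); identical seed +
configuration ⇒ bit-identical outputs, including the pipeline manifest.
Zero-variance inputs to correlations, constant EWS windows, degenerate SPEI
samples, empty series collections, gap years in ring files, RH outside
(0, 100] and temperature-ordering violations are all rejected or flagged
explicitly rather than propagated as NaN. The A&S inverse-normal
approximation has absolute error < 4.5e−4, negligible against the SPEI's
sampling noise. Problem sizes used by the shipped tests and the acceptance
script (e.g. 200/400 calibration replicates, 20 recovery seeds, 1000-year
AR(1) recovery) were chosen so each rate's Monte-Carlo error is small
against the band it is checked to; the methods are O(n) to O(n²) in series
length and run in seconds at study scale.

## Known limitations

* The additive model is a stand-in, not a mixed-model smoother; its AIC is
  comparable across candidates on the same data only.
* PET follows the study form verbatim; its absolute scale (mm) inherits the
  unstated unit convention noted above. CMI and SPEI, which use PET only
  relatively, are insensitive to this.
* The bundled atmospheric table is approximate by design; absolute iWUE
  levels shift by a few µmol mol⁻¹ under a measured δ¹³C_atm series, while
  trends and orderings are robust.
* EWS power at 15-year windows is intrinsically limited (see above); a
  non-significant site trend is weak evidence of stability.
* The Tucson reader supports the two stop-marker dialects only; headers and
  exotic layout variants are out of scope.
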