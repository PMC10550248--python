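# Methods

This note documents the models implemented in `crossfence`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the analysis
left genuine latitude.

## Aging from molar progression

Macropod age is estimated from the molar index *M* (number of molars
past the posterior rims of the zygomatic arches) as
`A = exp(2.2278 + 0.359 M)` days, converted to years with 365.25 d/y.
Implemented exactly as printed, the curve yields ages under a year for
molar indices up to ~6, which is in tension with multi-year adult ages;
the source curve's unit convention cannot be verified here. We
therefore expose a post-hoc multiplicative `scale` (default 1.0) on the
formula's output rather than silently rescaling. The synthetic
generator side-steps the tension by drawing ages directly in years and
back-solving *M* through the exact inverse, so the round trip
age → M → age is an identity regardless of the convention.

## Demography

The sex-ratio test is Pearson's chi-squared on the 2×2
population-by-sex table, continuity correction **on** by default
(matching the conventional default for 2×2 tables), with the
uncorrected variant behind a flag. For the printed study composition
(78/37 vs 20/31) the statistic is 10.81 corrected / 11.96 uncorrected.

Age-range trimming restricts the *trimmed* population (default:
dingoes-rare) to the closed `[min, max]` age interval of the
*reference* population (dingoes-common). Boundary ages are kept —
exclusion requires strict exteriority — and the reference population is
never touched. The operation is idempotent and reports exclusions per
side.

Generation arithmetic uses `floor((y1 − y0) · 12 / months_per_gen)`;
30-month generations from 1975 to 2018 give 17.

## Growth curves

`L(t) = L∞(1 − e^{−k(t−t₀)})` with ages in years, so `k` is per year.
Fitting is damped Gauss–Newton (Levenberg–Marquardt via
`scipy.optimize.least_squares`, tolerances 1e-12, bounded at 200·(p+1)
residual evaluations). Initialisation: `L∞⁰ = 1.05·max(size)`, `k⁰`
from the slope of `log(1 − size/L∞⁰)` on age, `t₀⁰ = 0`. Standard
errors come from the Jacobian at the optimum
(`cov = s²(JᵀJ)⁻¹`, `s² = RSS/(n−p)`).

Two-group contrasts refit jointly with every parameter written as
baseline + delta·I(group 2); the per-group heuristic fits seed the
joint optimisation (a pooled start can land the mixed-sex cranial fit
in a degenerate basin). Contrasts are Wald `t = Δ/SE(Δ)` with
`df = n − 6`, chosen over likelihood-ratio tests to match the
`t`-statistic presentation conventional for these models. Individual
deltas can be pinned at zero; pinning all three reproduces the pooled
single-group fit exactly (tested).

Divergence age is the smallest `t` at which the absolute difference of
the two fitted curves exceeds a threshold (we report the residual sd as
the default threshold), found by grid scan plus bisection; a
non-monotone difference yields its first crossing, identical curves
yield +∞.

## Procrustes machinery

GPA centres each configuration, scales it to unit centroid size, and
iteratively rotates it to the running consensus using the proper
orthogonal (det +1) Kabsch solution; the consensus is re-averaged and
re-normalised each round until it changes by < 1e-10. Reflections are
excluded everywhere except the deliberate mirroring step below. The
reported consensus is the plain coordinate-wise mean of the aligned
configurations. Centroid sizes stay on the original measurement scale;
the "cranial size" used in growth and interpopulation models is
centroid size, never the aligned coordinates.

Object symmetry: each specimen's mirror image (x-coordinates negated,
paired landmark labels swapped) joins the originals in one GPA; the
symmetric component is the mean of a specimen's aligned original and
mirror, the asymmetric component half their difference, so the two
reconstruct the aligned coordinates exactly and their squared norms
partition the squared shape norm (unit-size shapes make the components
orthogonal). The midsagittal plane is checked per specimen by least
squares through the midline landmarks (only informative with ≥ 4 of
them); midline points further than 5% of centroid size off-plane raise
a warning, not an error.

Shape models use the **symmetric** component by default (switchable to
the full Procrustes coordinates); whether the original analyses used
symmetric or full residuals is not documented, and the symmetric choice
matches the stated removal of asymmetry.

Predicted shapes along the ontogenetic axis come from the multivariate
regression of shape on log centroid size alone (the regression passes
through the mean shape at the mean log size, which the tests pin at
1e-9); sex enters the allometry *test* but not the prediction axis.
Extrapolation beyond a 1.2×-inflated observed size range warns.

## RRPP permutation models

Sequential (type I) sums of squares from nested QR projections; every
term's F uses the full-model residual mean square. The null
distribution for term *j* permutes the residuals of the model
containing terms 1..j−1, adds them back to that reduced fit, and
recomputes F; `p = (1 + #{F* ≥ F_obs})/n_perm` counts the observed
arrangement, so min p = 1/n_perm. One shared permutation per iteration
covers all terms. A full-randomization alternative (permuting raw
response rows) is behind a flag. Rank-deficient designs raise an
aliasing error naming the offending term. Univariate single-covariate
F equals the classical regression F to 1e-10 (tested), and null
p-values are uniform by Kolmogorov–Smirnov over 200 replicates
(tested).

Interpopulation tests run per sex — the species is strongly dimorphic —
as `response ~ age + population` for cranial shape (multivariate),
centroid size, body weight and pes length, all on the age-trimmed
sample. The `age:population` interaction is added and its model
retained when the interaction's permutation p ≤ α (default 0.05); the
selection rule is ours, since only the retention outcome, not the rule,
is conventionally reported.

## Vegetation anomalies

Composites with EVI < 0 are clamped to zero (bare ground/water).
Anomalies standardize each observation against its own cell's
calendar-month mean and **sample** (n−1) sd over the whole record; the
sd convention is unstated in the field description, and n−1 is the
default a statistician would reach for. Zero-spread cell-months yield
anomaly 0 and are flagged; singleton cell-months are an error. The
moving window averages `window` (default 6, i.e. 96 days at 16-day
cadence) *consecutive* composites starting at t and is undefined where
the window overruns the series; the per-composite stride is used (a
literal 8-composite stride would contradict the stated 96-day span).

The randomization test compares the south-minus-north difference of
pooled anomaly medians (all cells and dates per site — pooling choice
ours) with `n_iter` reassignments: `full_shuffle` pools all values and
re-splits at the original sizes (default); `within_time_swap` flips the
two sites' per-date values. Two-sided p by |difference|, observed
counted in numerator and denominator; the 2.5th/97.5th null percentiles
delimit the pure-chance band. The test runs on raw anomalies by
default, on the smoothed values by flag.

## The synthetic-data generator

`gen_specimens` draws two populations with the study composition:
dingoes-rare n=115 (67.8% female, ages 0.25–12 y), dingoes-common n=51
(39.2% female, ages 1.1–9.5 y), so the trimming rule removes rare-side
individuals at both ends. Sexes are Bernoulli draws (exact counts
optional for reconstructing the printed 2×2 table), ages uniform — the
simplest distribution with the range-overlap structure trimming needs,
not a field age distribution. Traits (centroid size, weight, pes
length) follow sex-specific von Bertalanffy curves (female/male
asymptotes 600/720 size units, 26/55 kg, 47/56 cm — adult values
realistic for the species) plus Gaussian noise; the dingoes-common
population's growth coefficients are scaled ×1.3 toward the same
asymptotes, making young animals larger for a given age with the
difference dissipating in adults.

`gen_landmarks` builds each cranium as a fixed bilaterally symmetric
point cloud (explicitly non-anatomical) scaled to the specimen's
centroid size, deformed along one fixed mirror-symmetric allometric
direction proportionally to centred log size, plus symmetric individual
variation and antisymmetric noise constructed as +v on a left landmark
and −mirror(v) on its pair (x-only on midline points), guaranteeing a
nonzero asymmetric component exactly when `asym_sd > 0`. Configurations
are arbitrarily rotated and translated before output.

`gen_evi` simulates both properties' 16-day series 2011–2021:
`baseline + offset·I(south) + amplitude·sin(2π·doy/365.25) + AR(1)`,
AR coefficient 0.5 (so the 6-composite smoother visibly acts),
innovation sd 0.04, 4 cells per site. The baseline is 0.03 — arid
rangeland barely above the bare-ground floor — and that choice is
load-bearing: standardizing each cell against its own month climatology
would cancel a constant site offset *exactly* on an unclamped series,
leaving the median test without a target. The zero-clamping floor
breaks that invariance — the drier north is left-censored far more
often than the offset-lifted south, its month anomalies skew negative —
and a constant offset of 1.34 within-cell (stationary AR) sd produces a
pooled median difference of ~0.27 detected at the randomization floor.
An optional `offset_onset` date delays the offset for step-change
experiments. Note the implied magnitude ceiling: per-cell
standardization bounds each site's pooled anomaly median near ±1, so
very large reported median differences are not reproducible as pooled
medians of cell-month-standardized values; detection, sign and
calibration are the reproducible properties, and those are what the
tests assert.

What passing tests show — and don't. The generator matches the
analysis's distributional assumptions by construction (independent
Gaussian trait noise, uniform ages, AR(1) vegetation noise, a single
global allometric direction). Real samples bring survivorship bias,
heteroscedastic measurement error, anatomical landmark schemes and
spatially correlated cloud-contaminated imagery; green tests certify
the estimators and their calibration, not robustness to those
departures.

## Problem sizes

Default study sizes throughout: 166 specimens, 12 landmarks, 8 grid
cells × 252 composites. Calibration suites use 200 replicates (KS at
α = 0.01), power checks 200 replicates at n = 80/group, the
randomization test 10,000 iterations. The full pipeline runs in a few
seconds; the complete test suite in well under a minute.

## Known limitations

* The printed sex-ratio statistic (χ²₁ = 15.32) is not recoverable from
  the printed 2×2 counts (10.81/11.96 by either convention); the
  package reports what the counts give.
* Wald contrasts report `df = n − 6`; a printed df of 159 at n = 166
  would correspond to n − 7 and is left unexplained.
* No sliding semilandmarks, mesh warping, mixed-effects growth models,
  or satellite-data handling (reprojection, QA masking) — numeric
  predicted configurations stand in for rendered shape figures.
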