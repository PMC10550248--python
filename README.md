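# crossfence

Cross-fence comparison of red kangaroo (*Osphranter rufus*) populations
living on either side of the Australian dingo barrier fence: demographic
structure, molar-index aging, von Bertalanffy growth, 3D cranial shape,
and the vegetation context of the two properties. The package is aimed
at wildlife ecologists and morphometricians who want the full analysis
chain — from specimen tables and landmark files to permutation tests —
as tested, reusable Python, driven end to end by a synthetic-data
generator that emulates the study design (no field data or satellite
downloads required).

## What it computes

**Aging.** Age in days from the molar index *M* (molars progressed past
the posterior rims of the zygomatic arches):
`log_e(A) = 2.2278 + 0.359 M`, converted to years at 365.25 d/y. A
configurable post-hoc scale factor is exposed because the source
curve's unit convention cannot be verified from the printed formula
alone (see `docs/methods.md`).

**Demography.** Population-by-sex composition, a chi-squared sex-ratio
test (continuity correction on by default for the 2×2 table), and the
age-range trimming rule: before any between-population comparison, the
larger population is restricted to the closed age interval observed in
the smaller one, with exclusions counted per side.

**Growth.** The von Bertalanffy curve
`L(t) = L∞ (1 − e^{−k (t − t₀)})` fitted by Levenberg–Marquardt least
squares, and two-group contrasts fitted jointly as baseline + delta per
parameter with Wald `t = Δ/SE(Δ)`, `df = n − 6`, plus the age at which
two fitted curves diverge by more than a threshold.

**Shape.** Generalized Procrustes superimposition (centring, unit
centroid size, proper rotations), object-symmetry decomposition into
symmetric and asymmetric components via jointly aligned mirror copies,
ontogenetic allometry (`shape ~ log centroid size × sex`), and
predicted shapes along the size axis.

**Permutation inference.** A residual-randomization permutation
procedure (RRPP) engine with sequential sums of squares: each term's
reduced-model residuals are permuted, added back to the reduced fit,
and the F statistic recomputed; `p = (1 + #{F* ≥ F}) / n_perm`.

**Vegetation.** Enhanced-vegetation-index preprocessing (negative
composites clamped to zero), per-cell calendar-month standardized
anomalies `ΔEVI(i,t) = (EVI(i,t) − mean_m) / sd_m`, a 6-composite
(96-day) moving average, and a randomization test for the
south-minus-north difference of pooled anomaly medians (10,000
reassignments, 2.5th/97.5th null percentiles).

## Worked example

```python
from crossfence.core_io import RunConfig
from crossfence.pipeline import run_pipeline

art = run_pipeline(RunConfig())
demo = art.report.blocks["demography"]
print(demo["sex_ratio"]["chi2"])            # 10.805041965635361
print(demo["generations_since_fence"])      # 17
print(art.report.blocks["vegetation"]["p"]) # 9.999000099990002e-05
```

The sex-ratio statistic is the continuity-corrected chi-squared for the
study composition (78/37 females/males where dingoes are rare vs 20/31
where they are common; 11.96 uncorrected): a strong female bias where
dingoes are rare. The 17 is the minimum number of 30-month generations
between the fence becoming an effective barrier (1975) and collection
(2018). The vegetation p-value is at the randomization floor for 10,000
iterations: the simulated south-of-fence greening (a constant offset of
1.34 within-cell standard deviations over an arid baseline) yields a
pooled anomaly median difference of ~0.27 that no random reassignment
of values between the sites reproduces.

The same stages can be run as numbered drivers that write their tables
under `results/`:

```sh
python analysis/01_simulate.py      # specimen / landmark / EVI tables
python analysis/02_demography.py    # composition, sex ratio, trimming
python analysis/03_growth.py        # von Bertalanffy sex contrasts
python analysis/04_morphometrics.py # GPA, allometry, interpopulation tests
python analysis/05_vegetation.py    # anomalies + randomization test
python analysis/06_figures.py       # growth curves, anomaly violins
```

or through the CLI: `crossfence run-all --seed 7 --out-dir results`.

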