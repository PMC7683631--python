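# Methods

`petquant` implements a quantitative correction chain for 2-[18F]FDG PET
uptake metrics of liver lesions — recovery-coefficient (RC) based partial
volume correction with phantom cold-wall compensation, tumor-to-liver and
tumor-to-blood ratio metrics, uptake-time normalization — and the two-group
separation statistics used to relate the corrected metrics to a binary
molecular label (KRAS missense mutation vs wild-type-grouped). Because no
per-lesion clinical data is publicly deposited, the package is exercised
entirely on a digital phantom and synthetic cohorts whose parameters are the
published study conditions.

## Recovery-coefficient model

A uniform hot sphere of radius `R` in warm background, imaged by a scanner
with an isotropic Gaussian point-spread function (PSF) of standard deviation
`sigma`, produces the radial profile of the ball indicator convolved with the
Gaussian. The convolution has the closed form

    f(r) = 1/2 [erf((R−r)/(σ√2)) + erf((R+r)/(σ√2))]
           − σ/(r√(2π)) [exp(−(R−r)²/2σ²) − exp(−(R+r)²/2σ²)]

with the analytic `r → 0` limit substituted near the origin. A walled phantom
sphere decomposes linearly into background everywhere, minus background over
the outer (interior + wall) ball, plus sphere activity over the interior
ball; each term is blurred independently, so the model profile is an exact
superposition of three `f` terms. The closed form agrees with a brute-force
3-D grid convolution at 0.25 mm voxels to better than 0.5% (absolute, on
unit-background scale) for all six phantom diameters; this cross-check is
part of the test suite.

Recovery coefficients use the contrast-recovery form

    RC = (C / C_B − 1) / (a_H / a_B − 1)

where `C` is the statistic evaluated on the (model or measured) image — the
mean over a spherical VOI matching the inner diameter, the central/maximum
value, or the mean over a centered 1.0 mL peak VOI — `C_B` the background
level, and `a_H / a_B` the true sphere-to-background activity ratio (SBR).
The noiseless model RC is bounded by 1 and increases with sphere diameter;
RC values above 1 for max/peak arise only from noise (positive bias of the
maximum), which lives in measured data, never in the model.

### Cold-wall correction

Phantom spheres have ~1 mm inactive plastic walls; lesions do not. The wall
displaces warm background around the hot interior and depresses the measured
uptake. The correction factor for each sphere and statistic is the ratio of
the modeled VOI uptake values (absolute-uptake recovery) of the wall-free and
walled spheres,

    factor = C_model(no wall) / C_model(with wall)  ≥  1,

applied multiplicatively to the measured RCs. The ratio of contrast-form RCs
was considered and rejected: dividing out the common warm-background baseline
before taking the ratio roughly triples the apparent wall effect for the mean
statistic (~31% instead of ~10% for a 1 mL sphere at 6.5 mm FWHM), far beyond
what walled-vs-wall-free simulations of these spheres show in the image
domain. With the adopted form the factor minus one is 9.8–10.1% at 1 mL for
the mean statistic (FWHM 6–8 mm), under 5% above 10 mL, and under 0.2% for
the maximum statistic above 10 mL — consistent with reported magnitudes for
this phantom geometry. A known limitation: the reported ~13% wall effect for
the *maximum* statistic at 1 mL is not reproduced by the adopted form at any
FWHM in the 6–8 mm range (it would require the contrast-form ratio at
FWHM ≈ 7 mm); the two published magnitudes cannot be reproduced
simultaneously under a single form and PSF width.

### RC curves

Final RC curves are built per statistic from the six wall-corrected measured
knots, interpolated by a monotone piecewise-cubic (PCHIP) in
(log10 volume, RC) — monotone interpolation avoids overshoot between widely
spaced knot volumes. Outside the knot range (lesions from 0.2 mL, below the
0.52 mL smallest sphere, up to 43 mL, above the 26.52 mL largest) the curve
follows the wall-free convolution model's RC-vs-volume shape rescaled to pass
through the terminal knot, so evaluation is continuous on (0, ∞).

### Parameters

- `psf_fwhm_mm = 6.5` — the reconstructed-image resolution is not published
  for the study scanner protocol; 6.5 mm is a typical effective value for a
  time-of-flight reconstruction with a 6.4 mm post-filter. All wall-correction
  magnitudes depend on it; it is exposed in the config.
- `model_sbr = 2.26` — sphere-to-background ratio of the model, the midpoint
  between the phantom fill ratio (2.19 = 9.284/4.240 kBq/mL) and the mean
  patient tumor-to-liver ratio.
- `peak_voi_ml = 1.0` — conventional SUV_peak VOI (12.4 mm diameter sphere)
  centered at the hottest voxel.

## Digital phantom

`phantom.nema_iq_spec` builds an image-quality-phantom-like scene: six hot
spheres (inner diameters 10/13/17/22/28/37 mm, 1 mm cold walls) coplanar on a
57.2 mm ring around a cold 50 mm cylinder (lung-insert analog), background
4.240 and spheres 9.284 kBq/mL. Rendering voxelizes with 3³ sub-voxel
sampling (partial-volume-accurate occupancy), blurs with the Gaussian PSF,
and optionally adds zero-mean Gaussian voxel noise scaled to the background —
a post-reconstruction noise surrogate, not projection-space Poisson noise; it
is sufficient to reproduce the positive noise bias of the maximum statistic.
Background ROIs for `C_B` are twelve 37 mm spheres at documented offsets
(ring radius 110 mm, two axial planes), a simplified stand-in for the
standard's 60-ROI layout.

Default grid: 200×200×120 voxels at 2 mm. At 2 mm the voxel box-filter adds
an effective blur (σ² += voxel²/12) that biases measured RCs of the smallest
spheres ~3–6% low relative to the continuous model; the model-agreement
oracle tests therefore render the same phantom at 1 mm voxels, where the
agreement is within 2% for all spheres and statistics. Sphere centers are
snapped to voxel centers so the maximum statistic samples the true profile
center.

## Lesion corrections

Order of operations is fixed and regression-locked: peak fallback → RC
lookup by lesion volume → partial-volume correction per statistic → ratio
metrics from PVE-corrected values → uptake-time correction last.

- **Peak fallback.** Lesions smaller than the peak VOI cannot host a genuine
  SUV_peak; their `suv_peak` is replaced by `suv_mean` and flagged.
- **PVEC.** `SUV_pvec = SUV/RC − SUV_bg·(1/RC − 1)` — the exact inverse of
  the forward attenuation model `measured = RC·true + (1−RC)·bg`; the same
  formula serves mean, peak and max with the statistic-matched RC. Values
  that come out non-positive (background above lesion signal at small RC) are
  flagged as implausible, never clipped.
- **Ratios.** `SUVTLR = SUV_pvec / SUV_liver_mean`;
  `SUR = SUV / SUV_blood_mean` (descending-aorta mean). SUR cancels common
  multiplicative SUV miscalibrations — injected/residual activity, weight,
  scanner calibration — which is its rationale.
- **Uptake-time normalization** to T0 = 60 min with apparent volume of
  distribution `V_r = 0.53` and blood-decay exponent `b = 0.313`:

      SUR_0 = (T0/T)(SUR_T − V_r) + V_r   ≈  SUR_T·(T0/T)
      SUV_0 = SUV_T·(SUR_0/SUR_T)·(T0/T)^−b  ≈  SUV_T·(T0/T)^(1−b)

  Both forms are implemented; the approximate forms are the default (the
  forms actually applied in the source analysis). Note that the approximation
  drops the `V_r` offset, so the two forms diverge substantially far from T0
  for small SUR (e.g. ~39% at T = 206 min, SUR_T = 2); they agree well only
  within roughly ±20 min of T0 or for large SUR. In exact mode the SUV
  correction consumes the exact-form SUR for self-consistency.

Six metric families are emitted per statistic: raw SUV, SUV+PVEC,
SUVTLR+PVEC, SUV+PVEC+time, SUR+time, SUR+PVEC+time.

## Molecular labels

KRAS annotations are parsed from clinical-report-style strings (missense
`G12D (c.35G > A) exon 2`, whole-gene amplification with optional fold
change, blank = wild type); unrecognized non-empty strings raise rather than
silently becoming wild type. Two grouping policies produce binary labels:
amplification grouped with wild type (primary; missense and amplification are
mutually exclusive events with different clinical significance) or with the
mutants (sensitivity analysis).

## Statistics

Group 0 is wild-type-grouped, group 1 mutant; metrics are higher in group 1.
Per metric cell the package reports: two-sided pooled-variance Student t and
Welch t p-values (both, since published tables cannot disambiguate the
variant at 1-significant-figure rounding), Wilcoxon rank-sum p with tie and
continuity correction (normal approximation), empirical AUC via the
Mann–Whitney relation with ties counted half, and a univariate logistic fit
(statsmodels ML) with an operating cutoff. "Optimal cutoff" is defined as the
empirical-ROC threshold maximizing Youden's J (ties broken toward higher
sensitivity); the logistic probability-0.5 crossing is reported alongside.
Complete separation flags the fit as non-convergent while the ROC cutoff is
still reported. No multiple-testing correction is applied across the grid,
matching the source analysis (none was reported). Group sizes default to
36 wild-type-grouped vs 24 mutant lesions, a split inferred from published
sensitivity/specificity denominators (0.72 = 26/36, 0.83 = 20/24); it is
configurable.

## Synthetic cohorts

Two generator modes stand in for the unavailable per-lesion data:

- **Summary-matched** draws final corrected metric values per group from
  truncated normals with the published per-cell (mean, SD). The underlying
  parameters are solved so the *truncated* distribution has exactly the
  specified moments. This mode supports reproducing the scale of the
  separation statistics, which depend only on the final metric's group
  distributions.
- **Forward-model** samples ground-truth standard-time SUV_0 per group,
  degrades it through the forward chain (power-law time scaling to the scan
  time, RC attenuation at the lesion volume against a sampled local
  background, optional 5% multiplicative measurement noise) and emits a raw
  lesion table plus ground truth. Running the correction chain on this
  cohort recovers SUV_0 exactly in the noise-free case (the chain is the
  algebraic inverse), with median relative error under 5% at 5% metric
  noise.

Nuisance distributions are the published cohort summaries: uptake time
lognormal, mean 83.8 min, SD 34, truncated to the observed [40.7, 205.7];
blood SUV 2.2 ± 0.6, liver 2.7 ± 0.6, local background 2.4 ± 0.7 (truncated
normals, lower bound 0.5); lesion volume lognormal, mean 5.7 mL, truncated to
the observed [0.2, 43.0] mL. Where only mean/SD/range are published, the
family choice (lognormal for right-skewed positive quantities) is ours. The
max/mean coupling in forward mode (max = mean × U[1.3, 1.7], peak halfway
between) is a documented heuristic consistent with the published ratios of
group means. Lesions are generated independently; the per-patient clustering
of the real cohort (60 lesions in 37 patients) is ignored, as it was in the
source analysis.

What passing tests show — and do not show. The synthetic cohorts reproduce
the group-level moment structure, not real lesion biology: no spatial
heterogeneity, no segmentation-method differences beyond separate moment
sets, no correlated per-patient effects, Gaussian rather than Poisson noise.
Pipeline correctness (algebra, ordering, RC modeling) is fully testable this
way; clinical effect sizes are only reproduced to the extent the published
summary moments determine them.

## Numerical choices

- VOI averages of the model use adaptive quadrature with a breakpoint at the
  ball edge (the profile is steep there for narrow PSFs); `fwhm → 0`
  recovers RC = 1 to 1e-4.
- RC-curve interpolation in log10-volume with PCHIP preserves monotonicity
  between knots; tails are continuity-matched model shapes.
- All randomness flows from explicit integer seeds through NumPy's
  `default_rng` (PCG64); replicate seeds are spawned with `SeedSequence` and
  kept below 2^31.
- Degenerate statistical inputs (all-tied groups) return p = 1 with a flag
  instead of NaN.
- Simulation sizes in the test suite (1 mm phantom grid for oracle
  agreement, 1000 replicates for the headline AUC, n = 6000 per group for
  binormal convergence) were chosen to keep sampling error well under each
  assertion's tolerance while running on a single CPU in minutes.
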