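# Methods

## Signal model

All three contrasts are spoiled multi-echo gradient-echo (FLASH)
acquisitions. The package's reference forward model is the rational
small-flip-angle approximation of the spoiled-GRE steady state,

    S(TE) = A · α · R1 · TR / (R1·TR + α²/2 + δ) · exp(−TE · R2*),

with amplitude `A` (arbitrary units, proportional to proton density and
receive sensitivity), longitudinal rate `R1 = 1/T1` (1/s), effective
transverse rate `R2*` (1/s), excitation flip angle `α` (radians),
repetition time `TR` (s) and the per-TR MT saturation fraction `δ`
(applied only when the off-resonance MT pulse is on). This model is the
exact algebraic inverse of the MT-saturation estimator

    δ = (A·α / S_MT − 1) · R1 · TR − α²/2,

so a noiseless simulation round-trips through the estimation chain to
machine precision — which is what makes the pipeline testable end to end.
A full Ernst-equation forward model (`ernst_signal`) is provided for the
MT-free contrasts only, to quantify the approximation bias of the rational
model: across T1 ∈ [0.5, 2] s at the default protocols the R1 estimated by
the rational closed forms from Ernst-generated signals is biased by well
under 5% (tested).

The three default protocols are: PD-weighted TR 24 ms, α 6°, 8 echoes
2.51–21.9 ms; T1-weighted TR 19 ms, α 20°, 4 echoes 2.51–10.82 ms;
MT-weighted TR 30 ms, α 12°, the same 4 echoes, MT pulse on. Interfaces
accept milliseconds and degrees; everything internal is SI (seconds,
radians, rates in 1/s).

## Map estimation

1. **R2\*** — ordinary least squares of `ln S(t)` on echo time over the
   PD-weighted echo train; slope = −R2*. Echoes with non-positive signal
   are dropped voxelwise; voxels with fewer than 3 usable echoes are
   invalid; negative fitted rates are clamped to 0 and flagged.
2. **TE=0 amplitudes** — each contrast's amplitude is `exp(ln S0)` from
   the same log-linear fit, not an echo average. An average would retain
   R2* weighting; the extrapolated amplitude makes the MT-saturation map
   exactly independent of R2*, which is the mechanism under study.
3. **A and R1** — closed forms from the dual-flip-angle PD-w/T1-w pair:

       R1 = (S_T1·α_T1/TR_T1 − S_PD·α_PD/TR_PD) / (2·(S_PD/α_PD − S_T1/α_T1))
       A  = S_PD/α_PD + S_PD·α_PD / (2·TR_PD·R1)

   These are exact (not approximate) solutions of the rational model's
   two-equation system; tests verify them against a numerical two-unknown
   solver. Voxels with non-positive denominator or R1 are invalid.
4. **MT saturation** — the estimator above with the MT-weighted protocol's
   α and TR. δ is stored as a fraction; reports print percent. Voxels with
   S_MT ≤ 0 or δ outside [0, 1) are invalid.

Invalid voxels are masked, never imputed. No B1/flip-angle error
correction is applied (none is modelled in the simulation either).

## Why iron spares MTsat but not T1-weighted contrast

Striatal iron raises R2* and, through T1 shortening, R1. In the
T1-weighted image the R1 rise brightens the striatum toward white matter:
with R1 moved ~45% of the GM→WM distance the striatal intensity sits
closer to WM than to GM and an intensity-driven segmenter assigns it to
WM. In the MT-saturation map the R2* change is removed by the TE=0
extrapolation and the R1 change cancels inside the estimator, so the
striatum keeps its grey-matter value. The iron→R1 coupling used by the
simulator, `iron_r1_slope = 0.035` (ΔR1 per unit ΔR2*, both 1/s), is an
assumption — no measured value is available for this cohort — chosen
within the range reported for iron-dominated relaxometry changes and such
that striatal intensity remains below WM across the swept R2* range
10–25 1/s; the package treats it as an explicit, documented parameter.

## Phantom and cohort generator

The phantom is a sphere (default radius 27 mm in a 48³ grid of 1.25 mm
voxels): CSF core (5 mm), white matter, a 4 mm cortical GM ribbon, and two
striatal GM spheres (5 mm radius, ±11 mm offsets) inside the WM. A
32-cube variant (`PhantomSpec.small()`) scales the geometry down for
permutation-heavy experiments. Default 1.5 T tissue parameters:

| tissue       | A    | R1 (1/s) | R2* (1/s) | δ (%) |
|--------------|------|----------|-----------|-------|
| CSF          | 1000 | 0.25     | 1.0       | 0.2   |
| cortical GM  | 800  | 0.90     | 12.0      | 2.0   |
| WM           | 700  | 1.60     | 16.0      | 3.5   |
| striatal GM  | 800  | 0.90     | 13.26     | 2.0   |

Striatal R2* defaults to the control-group ventral-striatum mean; the
patient effect adds 0.94 1/s (the published group difference) with the
coupled R1 rise. Amplitudes follow relative proton density; R1 values
correspond to T1 ≈ 4 s / 1.1 s / 0.63 s; δ is low in CSF, intermediate in
GM, highest in myelin-rich WM.

Cohorts are two groups (default 30/group, the study's size). Patient
effects: striatal radius reduced by `atrophy_fraction` (default 0.15),
striatal R2* +0.94 1/s, optional focal cortical ribbon thinning (the
iron-free "parietal" comparison effect, sized to match the striatal GM
volume change on the small phantom). Covariates (age, BDI, STAI, TIV,
months-on-medication) are drawn from the published group means/SDs; TIV
uses a typical adult distribution (not reported in the source).

Between-subject variability is deliberate and three-fold, each component
needed to avoid a degenerate artifact:

- **Head size**: all lengths scale isotropically by 1 ± 3% (clipped at
  3 SD), so TIV varies ~9% across subjects. Without it, TIV is almost a
  pure proxy for the atrophy effect and the TIV covariate absorbs the
  group difference.
- **Local anatomy**: striatal radius and ribbon thickness jitter by ±3%.
- **Alignment**: a uniform ±0.4 mm sub-voxel offset of the whole phantom.
  Exactly co-centred phantoms share bit-identical partial-volume voxels at
  tissue interfaces, which gives those voxels zero between-subject
  variance and produces spurious, highly significant interface clusters;
  real co-registered brains never align at sub-voxel precision.
- **Iron**: subject-level striatal R2* SD of 1.0 1/s plus an age slope of
  0.05 1/s per year (anchored at the cohort mean age), both feeding R1
  through the iron coupling. These make the ROI statistics (group F, age
  correlation) estimable quantities rather than bookkeeping identities.

All per-subject draws are matched pairwise across groups (subject *i* of
each group shares anatomy/alignment/iron deviations before group effects),
so zeroing every effect and variability knob yields a bit-exact null
cohort. Noise is additive Gaussian with SD expressed as a fraction of the
mean noiseless first-echo WM PD-weighted signal (default 0.005); Rician
bias at magnitude-image SNR this high is negligible and is a stated
limitation. No B1 inhomogeneity, slice profiles, k-space artifacts or
motion are simulated, and all subjects share one space — there is no
registration stage, so the group analysis tests everything downstream of
normalization, not normalization itself.

## Segmentation and VBM front end

Segmentation is a 1-D, three-class Gaussian mixture on intensities inside
the brain mask, EM to a 1e-6 relative tolerance or 500 iterations,
components assigned CSF < GM < WM by fitted mean (the ordering holds for
both the T1-weighted image and the δ map). Initialization uses means
spread evenly across the robust intensity range (0.5–99.5 percentiles)
with uniform weights: a data-driven k-means start loses the small CSF
compartment (<1% of voxels) in a fraction of runs. No spatial priors,
bias-field model or MRF — intentionally, because the claim under test is
about *input contrast*, and a spatially regularized segmenter would
partially mask it. "GM volume" is the GM posterior summed times voxel
volume; TIV is the GM+WM+CSF posterior volume, computed per modality.
Smoothing is a separable Gaussian, FWHM 5 mm (σ = FWHM/2.355 per axis).

## Group statistics

Voxelwise OLS GLM on smoothed GM posteriors with intercept, group
indicator and centred covariates (age, TIV, BDI, STAI trait); directional
t for control > patient (the reported direction), df = n − rank(X).
Clusters form at voxel p < 0.001 under 18-connectivity. Cluster p-values
come from the permutation distribution of the maximum cluster extent using
the Freedman–Lane scheme (residuals of the nuisance-only model are
permuted and added back to its fit), p = (1 + #{max extent ≥ k})/(1 +
n_perm); Benjamini–Hochberg FDR is applied across the observed clusters.
The modality × diagnosis interaction is computed as the group contrast on
per-subject difference images (MT − T1 GM maps), which is algebraically
the mixed-model interaction when each subject contributes one observation
per modality. Cluster-to-region attribution in the experiments uses region
masks dilated by ~4 mm: a smoothed atrophy effect peaks at a structure's
rim (where the variance is lowest just outside it), so an annulus around
the structure is the expected cluster shape. Peak ties break to the lowest
linear voxel index; coordinates are reported as 0-based voxel indices.

The summary-statistics ANOVA (`anova_from_summary`) reconstructs the
two-group one-way F from printed means/SDs/sizes: F = SSB/MSW with SSB =
Σ nᵢ(x̄ᵢ − x̄)² and MSW = Σ(nᵢ−1)sᵢ²/(N−2). It equals the ANOVA on any raw
data realizing those summaries. Reconstructed values can differ from
printed ones by the rounding of the printed summaries (e.g. depression
scores reconstruct to 16.88 where 17.01 was computed from unrounded data).

## Validation experiment design and problem sizes

- **Null FDR calibration**: 200 null cohorts of 15+15 subjects on the
  32-cube mask, 200 permutations each. The per-subject maps are the
  reference GM posterior plus 5-mm-smoothed Gaussian noise: the
  calibration question concerns the statistics stage only, and a smoothed
  noise field is precisely the between-subject variability structure the
  GLM sees after segmentation and smoothing. Under the global null the
  false-discovery proportion is binary (any discovery is false), so its
  mean estimates the realized FDR; the check allows 2 binomial SEs above
  q = 0.05.
- **Power comparison**: 6 seeded cohorts of 30+30 on the 32-cube phantom
  with elevated striatal iron in both groups (striatal R1 shifted 45%
  toward WM), striatal atrophy 0.15 and the matched cortical effect in
  patients, 199 permutations. Both modality pipelines run on identical
  subjects. The medication regression (months-on-medication, patients
  only, no simulated effect) is run on the same features as a false-positive
  control.
- **Segmentation Dice**: 10 replicates on the 48-cube phantom at 0.5%
  noise and elevated iron.

Grid sizes, permutation counts and seed counts are the package's own
scaled-down validation settings: the statistical questions (calibration,
ordering of detection rates, Dice ordering) do not depend on grid
resolution, and these sizes keep a full validation sweep to minutes on a
single CPU.

## What passing these tests does and does not show

The phantoms have piecewise-constant tissue, spherical geometry, no
registration errors, Gaussian noise and a segmenter with no spatial
priors. Passing shows the estimators are algebraically correct, the
inference is calibrated, and the iron-contrast mechanism behaves as
modelled; it does not show that effect sizes, Dice values or detection
rates transfer quantitatively to real brains, real VBM segmentation or
other field strengths. Known limitations: no Rician noise, no B1 error in
either simulation or δ estimation, single common space, and the
ventral-striatum atlas mask of the original analysis is not bundled (any
NIfTI mask can be supplied; simulations use the ground-truth striatal
mask).
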