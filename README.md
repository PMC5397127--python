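# mtvbm

Quantitative MRI mapping and voxel-based morphometry for studies where
subcortical iron confounds conventional T1-weighted imaging.

Striatal grey matter accumulates iron, which shortens T1 and raises R2*.
On a T1-weighted image the iron-brightened striatum blends into white
matter, so intensity-driven tissue segmentation — and every group
statistic built on it — loses sensitivity exactly where the biology is.
Magnetization-transfer saturation (MTsat) maps do not have this problem:
the MT saturation per repetition is estimated in a way that cancels both
the R2* decay and the R1 change, leaving a myelin-weighted contrast that
iron cannot corrupt. `mtvbm` implements the full analysis chain around
that idea and a synthetic-phantom simulator that makes every stage
testable without any scan data.

## What it computes

For a spoiled multi-echo FLASH acquisition the signal is modelled as

    S(TE) = A·α·R1·TR / (R1·TR + α²/2 + δ) · exp(−TE·R2*)

and three co-localized contrasts (PD-weighted: TR 24 ms/α 6°/8 echoes;
T1-weighted: 19 ms/20°/4 echoes; MT-weighted: 30 ms/12°/4 echoes, MT pulse
on) determine the four unknowns per voxel:

- **R2\*** — ordinary least squares of ln S(t) against echo time,
  ln S(t) = ln S0 − t·R2*;
- **A, R1** — exact closed forms from the dual-flip-angle PDw/T1w pair of
  TE=0-extrapolated amplitudes;
- **MTsat (δ)** — δ = (A·α/S_MT − 1)·R1·TR − α²/2.

Downstream: Gaussian-mixture tissue segmentation (CSF/GM/WM), 5 mm FWHM
smoothing, a voxelwise GLM (group + age, TIV, BDI, trait-anxiety
covariates), cluster formation at voxel p < 0.001 (18-connectivity),
cluster-extent p-values by Freedman–Lane permutation of the maximum
cluster size, Benjamini–Hochberg FDR across clusters, a modality ×
diagnosis interaction on difference images, summary-statistics ANOVA,
and striatal R2* ROI statistics with Spearman covariate correlations.

The phantom simulator generates two-group cohorts with controllable
striatal atrophy, striatal iron (R2* with coupled R1 increase), an
iron-free cortical comparison effect, realistic covariates and
between-subject anatomy/alignment variability. See `docs/methods.md` for
the model, parameter defaults and what the synthetic data do and do not
emulate.

## Worked example

`examples/03_iron_invariance.py` sweeps striatal R2* from 10 to 25 1/s
with the coupled R1 rise, simulates the three contrasts noiselessly, fits
the maps and prints:

```
 striatal_r2star  striatal_r1  estimated_striatal_mtsat  t1w_striatum_wm_contrast
              10       0.7859                      0.02                 3.724e+08
              13       0.8909                      0.02                 2.829e+08
              16       0.9959                      0.02                 2.055e+08
              19        1.101                      0.02                  1.38e+08
              22        1.206                      0.02                 7.871e+07
              25        1.311                      0.02                 2.631e+07

MT saturation spread over the sweep: 2.22e-12 % of its mean
T1w striatum-WM contrast drop:        92.9 %
```

The estimated striatal MTsat stays at its generating value of 2% across
the entire iron sweep, while the T1-weighted striatum–WM contrast loses
93% — the mechanism by which iron hides striatal effects from T1-weighted
analyses. `examples/05_group_analysis.py` carries this through to group
statistics on a simulated cohort (15 per group, elevated striatal iron):

```
MT-saturation VBM clusters (control > patient):
 cluster_id  peak_i  peak_j  peak_k  peak_stat  extent  p_unc  p_fdr
          1      22      16      16      11.47     889  0.005  0.005

Striatal R2* ROI analysis:
  group difference (patient - control): 0.954 1/s
  F(1,28) = 12.75, p = 0.0013
 covariate    rho     p  n
       age  0.425 0.019 30
```

One FDR-significant cluster covers the striatum (the injected atrophy),
the ROI recovers the injected 0.94 1/s iron difference, and striatal R2*
correlates positively with age through the simulated age–iron coupling.

The other examples cover phantom simulation (`01`), map fitting with
noise (`02`) and the segmentation Dice comparison (`04`). A thin CLI
exposes the stages for file-based use:

```
mtvbm simulate --config cohort.yaml --out data/ --seed 1
mtvbm fit-maps --pdw data/con001/pdw.nii.gz --t1w ... --mtw ... --out maps/
mtvbm segment --map maps/mtsat.nii.gz --mask data/con001/brain_mask.nii.gz --out seg/
mtvbm vbm --config cohort.yaml --modality mtsat --seed 1 --out out/
mtvbm roi --map r2star_4d.nii.gz --mask striatum.nii.gz --covariates cov.csv --out roi.csv
mtvbm report --config cohort.yaml --seed 1 --out report.md
```

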