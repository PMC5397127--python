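"""Whole-brain VBM and striatal R2* ROI statistics on a simulated cohort.

Simulates a two-group cohort (striatal atrophy + iron in patients) on the
small phantom, runs the MT-saturation VBM pipeline (GLM with age, TIV, BDI
and trait-anxiety covariates; permutation cluster-extent inference at
voxel p < 0.001; cluster-level FDR) and prints the cluster table, then the
ROI iron analysis.
"""

from mtvbm.phantom import CohortSpec, PhantomSpec
from mtvbm.pipeline import run_roi_analysis, run_vbm

spec = PhantomSpec.small(striatal_r1_shift=0.45)
cohort = CohortSpec(n_per_group=15, seed=0)

result = run_vbm(cohort, spec, modality="mtsat", n_perm=199, seed=0)
print("MT-saturation VBM clusters (control > patient):")
print(result.clusters.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
sig = result.significant(q=0.05)
print(f"\n{len(sig)} cluster(s) significant at cluster FDR < 0.05")

roi = run_roi_analysis(cohort, spec)
g = roi["group"]
print("\nStriatal R2* ROI analysis:")
print(f"  group difference (patient - control): {g['group_difference']:.3f} 1/s")
print(f"  F({g['df1']:.0f},{g['df2']:.0f}) = {g['F']:.2f}, p = {g['p']:.4f}")
print(roi["correlations"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nPositive age-iron correlation and elevated patient striatal R2* "
      "mirror the intended cohort effects.")
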