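"""Why T1-weighted images lose striatal contrast while MTsat maps do not.

Striatal iron raises R2* and, through T1 shortening, R1.  The sweep raises
striatal R2* from 10 to 25 1/s with the coupled R1 increase and prints the
estimated striatal MT saturation (flat — the TE=0 extrapolation removes
the R2* decay and the estimator cancels the R1 change) next to the
striatum-vs-WM contrast of the T1-weighted image (collapsing — the
brightened striatum blends into white matter).
"""

from mtvbm.pipeline import iron_invariance_sweep

sweep = iron_invariance_sweep()
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

d = sweep["estimated_striatal_mtsat"]
c = sweep["t1w_striatum_wm_contrast"]
print(f"\nMT saturation spread over the sweep: "
      f"{100 * (d.max() - d.min()) / d.mean():.2e} % of its mean")
print(f"T1w striatum-WM contrast drop:        "
      f"{100 * (1 - c.iloc[-1] / c.iloc[0]):.1f} %")
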