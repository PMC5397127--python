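"""Striatal segmentation accuracy: MT-saturation map vs T1-weighted image.

Ten noisy phantom replicates with elevated striatal iron (striatal R1
shifted 45% of the way toward the WM value).  On the T1-weighted image the
iron-brightened striatum is classified as white matter; on the MTsat map
it keeps grey-matter values.  Dice scores the hard GM class against the
ground-truth striatal mask.
"""

from mtvbm.experiments import dice_experiment

df = dice_experiment(n_replicates=10, seed=0)
print(df.to_string(index=False))
wins = int((df["dice_mtsat"] > df["dice_t1w"]).sum())
print(f"\nmean striatal Dice — MTsat: {df['dice_mtsat'].mean():.3f}, "
      f"T1w: {df['dice_t1w'].mean():.3f}")
print(f"MTsat strictly better in {wins}/10 replicates")
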