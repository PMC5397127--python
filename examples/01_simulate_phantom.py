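"""Build a brain-like phantom and simulate the three FLASH contrasts.

Prints the noiseless per-tissue signal of each contrast's first echo.
Higher values on the T1-weighted contrast for white matter (short T1) and
on the PD-weighted contrast for CSF (high proton density) show the
expected weighting of each sequence.
"""

import numpy as np

from mtvbm.phantom import (
    DEFAULT_PROTOCOLS,
    PhantomSpec,
    make_phantom,
    simulate_acquisition,
)

spec = PhantomSpec()
phantom = make_phantom(spec)
print(f"phantom grid {spec.grid_shape}, voxel {spec.voxel_size_mm} mm")
print(f"brain voxels: {phantom.brain_mask.sum()}, GM: {phantom.gm_mask.sum()}, "
      f"striatum: {phantom.striatal_mask.sum()}")

masks = {
    "CSF": phantom.labels == 1,
    "cortical GM": phantom.labels == 2,
    "WM": phantom.labels == 3,
    "striatal GM": phantom.labels == 4,
}
print(f"\n{'tissue':<14}" + "".join(f"{name:>10}" for name in DEFAULT_PROTOCOLS))
volumes = {
    name: simulate_acquisition(phantom.fields, proto)
    for name, proto in DEFAULT_PROTOCOLS.items()
}
for tissue, mask in masks.items():
    row = [np.mean(volumes[name].data[mask, 0]) for name in DEFAULT_PROTOCOLS]
    print(f"{tissue:<14}" + "".join(f"{v:>10.1f}" for v in row))
print("\nfirst-echo signal in arbitrary units; note the MT-weighted signal of "
      "WM is suppressed most (largest MT saturation).")
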