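"""Cursor-based phasor segmentation and component fingerprints.

In the SHG emission channel, collagen (instantaneous SHG) sits at
(g, s) = (1, 0) while elastin fluorescence leaking through the filter sits
at its ~2.2 ns phasor point.  Two circular cursors separate the populations;
each selected region is fingerprinted by its intensity-weighted phasor
centroid and phase lifetime.
"""

import numpy as np

import phasorflim as pf
from phasorflim import scene as sc
from phasorflim.io import default_cursors
from phasorflim.selection import assign_cursors, region_centroid

TAU_REF = 2.5

for group in ("healthy", "tumor"):
    cfg = sc.demo_scene_config(group, image_size=(128, 128), seed=5)
    stacks, gt = sc.simulate_scene(cfg)
    ref = sc.simulate_reference(TAU_REF, 1e6, seed=9)
    corr = pf.calibration_from_reference(pf.phasor_transform(ref), TAU_REF)
    shg = pf.apply_calibration(pf.phasor_transform(stacks[sc.CHANNEL_SHG]), corr)

    cursors = default_cursors(shg.omega, radius=0.1)
    labels = assign_cursors(shg, cursors)
    print(f"\n{group} FOV, SHG channel ({sc.CHANNEL_SHG}):")
    for idx, cur in enumerate(cursors):
        mask = labels == idx
        if not mask.any():
            print(f"  cursor '{cur.label}': empty")
            continue
        fp = region_centroid(shg, mask, label=cur.label)
        frac = shg.intensity[mask].sum() / shg.intensity[shg.valid].sum()
        print(f"  cursor '{cur.label}': centroid (g, s) = "
              f"({fp.centroid[0]:.3f}, {fp.centroid[1]:.3f}), "
              f"tau_phi = {fp.mean_tau_phi:.2f} ns, "
              f"{fp.n_pixels} px, {frac:.0%} of channel intensity")

print("\nHealthy tissue concentrates SHG-channel intensity at the zero-lifetime "
      "collagen cursor; the tumor-like scene shifts it to the long-lifetime "
      "elastin cursor (elastosis signature).")
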