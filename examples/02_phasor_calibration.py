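"""Phasor transform + reference calibration: fit-free lifetime recovery.

Simulates a coumarin-like mono-exponential reference of known lifetime,
derives the rotate-and-scale calibration that cancels the instrument
response, then recovers the lifetimes of noisy mono-exponential decays from
their calibrated phasor angle alone — no exponential fitting anywhere.
"""

import numpy as np

import phasorflim as pf
from phasorflim import scene as sc

REP_RATE, N_BINS, PERIOD, IRF_SIGMA = 80.0, 256, 12.5, 0.1
TAU_REF = 2.5  # ns; the reference lifetime is a config choice, never hard-coded
OMEGA = 2 * np.pi * REP_RATE / 1000.0

ref = sc.simulate_reference(TAU_REF, 1e6, n_bins=N_BINS, irf_sigma=IRF_SIGMA, seed=0)
corr = pf.calibration_from_reference(pf.phasor_transform(ref), TAU_REF)
print(f"calibration from tau_ref = {TAU_REF} ns: "
      f"rotation {corr.delta_phi:+.4f} rad, modulation x{corr.mod_factor:.4f}")

print("\n   true tau      (g, s) calibrated      tau_phi   tau_mod")
for tau in (0.5, 1.5, 2.23, 2.31, 4.0):
    h = sc.simulate_decay_histogram([(1.0, tau)], 1e6, N_BINS, PERIOD,
                                    IRF_SIGMA, seed=int(tau * 100))
    stack = pf.DecayStack(h[None, None], REP_RATE, N_BINS, PERIOD / N_BINS, 0.2, "demo")
    f = pf.apply_calibration(pf.phasor_transform(stack), corr)
    g, s = f.g[0, 0], f.s[0, 0]
    print(f"   {tau:5.2f} ns   ({g:.4f}, {s:.4f})      "
          f"{pf.phase_lifetime(g, s, OMEGA):5.3f}    {pf.modulation_lifetime(g, s, OMEGA):5.3f}")

print("\nPhase and modulation lifetimes agree because mono-exponential decays "
      "sit on the universal semicircle; each is recovered from 1e6 Poisson "
      "photons to within a few 10s of ps.")
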