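"""Shared fixtures: acquisition constants, calibration, small simulated scenes."""

import numpy as np
import pytest

import phasorflim as pf
from phasorflim import scene as sc

REP_RATE = 80.0          # MHz
PERIOD = 12.5            # ns
N_BINS = 256
IRF_SIGMA = 0.1          # ns
OMEGA = 2 * np.pi * REP_RATE / 1000.0  # rad/ns
TAU_REF = 2.5            # ns, coumarin-like reference (config choice)


def mono_stack(tau: float, total_counts: float, *, noise: bool = False,
               seed: int = 0, n_bins: int = N_BINS, irf_sigma: float = IRF_SIGMA,
               shape=(1, 1)) -> pf.DecayStack:
    """DecayStack of identical mono-exponential pixels."""
    expected = sc.expected_decay([(1.0, tau)], n_bins, PERIOD, irf_sigma) * total_counts
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(np.broadcast_to(expected, (*shape, n_bins))).astype(float)
    else:
        counts = np.broadcast_to(expected, (*shape, n_bins)).copy()
    return pf.DecayStack(counts=counts, rep_rate=REP_RATE, n_bins=n_bins,
                         bin_width=PERIOD / n_bins, pixel_size=0.207, channel="test")


@pytest.fixture(scope="session")
def omega() -> float:
    return OMEGA


@pytest.fixture(scope="session")
def calibration() -> pf.CalibrationCorrection:
    """Correction from a noise-free reference sharing the default IRF."""
    ref = sc.simulate_reference(TAU_REF, 1e6, n_bins=N_BINS, irf_sigma=IRF_SIGMA,
                                noise=False)
    return pf.calibration_from_reference(pf.phasor_transform(ref), TAU_REF)


@pytest.fixture(scope="session")
def healthy_scene():
    """Small healthy-like scene: (stacks, ground truth, config)."""
    cfg = sc.demo_scene_config("healthy", image_size=(96, 96), seed=11)
    stacks, gt = sc.simulate_scene(cfg)
    return stacks, gt, cfg


@pytest.fixture(scope="session")
def tumor_scene():
    cfg = sc.demo_scene_config("tumor", image_size=(96, 96), seed=12)
    stacks, gt = sc.simulate_scene(cfg)
    return stacks, gt, cfg
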