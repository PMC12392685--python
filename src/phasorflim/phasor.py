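"""Phasor transform, calibration and lifetime estimation for time-domain FLIM.

The phasor approach maps each pixel's photon-count decay histogram to a single
point ``(g, s)``: the first-harmonic cosine and sine Fourier coefficients of
the normalised decay.  Mono-exponential decays fall on the *universal
semicircle* (radius 1/2 centred at (1/2, 0)); mixtures fall inside it along
the chord joining their components (law of linear combination).  An
instantaneous, laser-coherent signal such as second harmonic generation has
zero lifetime and sits at ``(g, s) = (1, 0)``.

Raw phasors carry the instrument response (IRF) as a multiplicative factor in
Fourier space.  Measuring a reference fluorophore of known mono-exponential
lifetime and rotating/scaling every phasor so the reference lands on its
theoretical semicircle point cancels the IRF — no decay fitting anywhere.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import generic_filter

__all__ = [
    "DecayStack",
    "PhasorField",
    "CalibrationCorrection",
    "LifetimeSummary",
    "phasor_transform",
    "mono_exp_phasor",
    "calibration_from_reference",
    "apply_calibration",
    "phase_lifetime",
    "modulation_lifetime",
    "linear_unmix_two",
    "median_filter_phasor",
    "aggregate_phasor",
    "summarize_region",
]


@dataclass(frozen=True)
class DecayStack:
    """Per-pixel photon-count histograms over one laser period.

    Parameters
    ----------
    counts : ndarray, shape (ny, nx, n_bins)
        Non-negative photon counts per time bin.
    rep_rate : float
        Laser repetition rate in MHz; the period is ``1000 / rep_rate`` ns.
    n_bins : int
        Number of uniform time bins per period.
    bin_width : float
        Bin width in ns; must satisfy ``n_bins * bin_width == period``.
    pixel_size : float
        Linear pixel size in µm.
    channel : str
        Emission-channel label (e.g. ``"shg_405_10"``).
    """

    counts: np.ndarray
    rep_rate: float
    n_bins: int
    bin_width: float
    pixel_size: float
    channel: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError(f"counts must be 3-D (ny, nx, n_bins), got ndim={counts.ndim}")
        if counts.shape[-1] != self.n_bins:
            raise ValueError(
                f"counts last axis ({counts.shape[-1]}) does not match n_bins ({self.n_bins})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        period = 1000.0 / self.rep_rate
        if not math.isclose(self.n_bins * self.bin_width, period, rel_tol=1e-6):
            raise ValueError(
                f"n_bins * bin_width = {self.n_bins * self.bin_width:g} ns does not equal "
                f"the laser period {period:g} ns (rep_rate {self.rep_rate} MHz)"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def period(self) -> float:
        """Laser period in ns."""
        return 1000.0 / self.rep_rate

    @property
    def bin_centers(self) -> np.ndarray:
        """Time-bin centers in ns; all phasor integrals are taken here."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=-1)


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates at one harmonic.

    ``g`` and ``s`` are NaN wherever ``valid`` is False (zero-intensity
    pixels); every consumer must honour the mask so flags never turn into
    silent zeros.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    omega: float
    harmonic: int = 1
    calibrated: bool = False
    pixel_size: float | None = None
    channel: str | None = None

    def copy(self) -> "PhasorField":
        return dataclasses.replace(
            self, g=self.g.copy(), s=self.s.copy(),
            intensity=self.intensity.copy(), valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class CalibrationCorrection:
    """Phase rotation + modulation scale mapping measured phasors onto theory.

    Derived from a reference of known mono-exponential lifetime ``tau_ref``;
    applying it to the reference's own aggregate phasor reproduces
    ``mono_exp_phasor(tau_ref, omega)``.
    """

    delta_phi: float
    mod_factor: float
    tau_ref: float
    omega: float

    def __post_init__(self) -> None:
        if self.mod_factor <= 0:
            raise ValueError("mod_factor must be positive")


@dataclass(frozen=True)
class LifetimeSummary:
    """Mean ± SE of the per-pixel phase lifetime over one region."""

    mean_tau_phi: float
    se_tau_phi: float
    n_pixels: int
    label: str

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.se_tau_phi < 0:
            raise ValueError("se must be >= 0")


def phasor_transform(stack: DecayStack, harmonic: int = 1) -> PhasorField:
    """Map a decay stack to phasor space at the given harmonic.

    For a pixel with counts ``c(t)`` and total ``N > 0``::

        g = sum(c(t) * cos(omega * t)) / N
        s = sum(c(t) * sin(omega * t)) / N

    with ``t`` at bin centers and ``omega = 2*pi*harmonic*rep_rate`` (rad/ns,
    rep_rate in GHz).  Zero-count pixels are marked invalid (g = s = NaN).
    Harmonics above 1 are accepted but experimental.
    """
    if harmonic < 1:
        raise ValueError(f"harmonic must be >= 1, got {harmonic}")
    omega = 2.0 * np.pi * harmonic * stack.rep_rate / 1000.0  # rad/ns
    t = stack.bin_centers
    counts = stack.counts.astype(np.float64)
    intensity = counts.sum(axis=-1)
    valid = intensity > 0
    safe_n = np.where(valid, intensity, 1.0)
    g = counts @ np.cos(omega * t) / safe_n
    s = counts @ np.sin(omega * t) / safe_n
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(
        g=g, s=s, intensity=intensity, valid=valid, omega=omega,
        harmonic=harmonic, calibrated=False,
        pixel_size=stack.pixel_size, channel=stack.channel,
    )


def mono_exp_phasor(tau, omega: float):
    """Closed-form phasor of a mono-exponential decay.

    ``g = 1 / (1 + (omega*tau)^2)``, ``s = omega*tau / (1 + (omega*tau)^2)``;
    the point lies on the universal semicircle ``(g - 1/2)^2 + s^2 = 1/4``
    for every ``tau >= 0`` (``tau = 0`` gives (1, 0), ``tau -> inf`` gives
    (0, 0)).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    wt = omega * tau
    g = 1.0 / (1.0 + wt**2)
    s = wt / (1.0 + wt**2)
    if g.ndim == 0:
        return float(g), float(s)
    return g, s


def aggregate_phasor(field: PhasorField, mask: np.ndarray | None = None,
                     weighted: bool = True) -> tuple[float, float]:
    """Intensity-weighted mean phasor over valid pixels (optionally masked)."""
    sel = field.valid if mask is None else (field.valid & mask)
    if not np.any(sel):
        raise ValueError("no valid pixels selected for aggregation")
    w = field.intensity[sel] if weighted else np.ones(int(sel.sum()))
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("selected pixels carry zero total intensity")
    return float(np.sum(w * field.g[sel]) / wsum), float(np.sum(w * field.s[sel]) / wsum)


def calibration_from_reference(reference: PhasorField, tau_ref: float) -> CalibrationCorrection:
    """Derive the rotate-and-scale correction from a known-lifetime reference.

    The reference field's intensity-weighted aggregate phasor is compared to
    the closed-form mono-exponential phasor of ``tau_ref``:
    ``delta_phi = phi_theory - phi_meas`` and
    ``mod_factor = m_theory / m_meas`` with ``phi = atan2(s, g)`` and
    ``m = sqrt(g^2 + s^2)``.
    """
    if reference.calibrated:
        raise ValueError("reference field is already calibrated")
    if tau_ref <= 0:
        raise ValueError("tau_ref must be positive (the reference must be fluorescent)")
    g_meas, s_meas = aggregate_phasor(reference)
    m_meas = math.hypot(g_meas, s_meas)
    if m_meas < 1e-12:
        raise ValueError("reference aggregate modulus is ~0; reference signal unusable")
    g_th, s_th = mono_exp_phasor(tau_ref, reference.omega)
    delta_phi = math.atan2(s_th, g_th) - math.atan2(s_meas, g_meas)
    mod_factor = math.hypot(g_th, s_th) / m_meas
    return CalibrationCorrection(
        delta_phi=delta_phi, mod_factor=mod_factor,
        tau_ref=tau_ref, omega=reference.omega,
    )


def apply_calibration(field: PhasorField, corr: CalibrationCorrection) -> PhasorField:
    """Rotate by ``delta_phi`` and scale by ``mod_factor`` about the origin."""
    if not math.isclose(field.omega, corr.omega, rel_tol=1e-9):
        raise ValueError(
            f"omega mismatch: field {field.omega:g} vs correction {corr.omega:g} rad/ns"
        )
    c, sn = math.cos(corr.delta_phi), math.sin(corr.delta_phi)
    g = corr.mod_factor * (field.g * c - field.s * sn)
    s = corr.mod_factor * (field.g * sn + field.s * c)
    out = field.copy()
    out.g, out.s = g, s
    out.calibrated = True
    return out


def phase_lifetime(g, s, omega: float):
    """Phase lifetime ``tau_phi = s / (g * omega)`` in ns.

    Pixels with ``g <= 0`` (or NaN inputs) are flagged as NaN — an
    out-of-range lifetime, never silently zeroed.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(g > 0, s / (g * omega), np.nan)
    if tau.ndim == 0:
        return float(tau)
    return tau


def modulation_lifetime(g, s, omega: float):
    """Modulation lifetime ``tau_m = sqrt(1/(g^2+s^2) - 1) / omega`` in ns.

    Equals the phase lifetime exactly on the universal semicircle.  Pixels
    with modulus 0 or > 1 (unphysical after calibration) are flagged NaN.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    m2 = g**2 + s**2
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where((m2 > 0) & (m2 <= 1.0), np.sqrt(np.maximum(1.0 / m2 - 1.0, 0.0)) / omega, np.nan)
    if tau.ndim == 0:
        return float(tau)
    return tau


def linear_unmix_two(point, end_a, end_b):
    """Two-component unmixing by the law of linear combination.

    Projects ``point`` orthogonally onto the segment joining the endmember
    phasors ``end_a`` and ``end_b``; returns ``(fraction_a, residual)`` where
    ``fraction_a`` is the intensity fraction of component *a*, clipped to
    [0, 1], and ``residual`` is the perpendicular distance of the point from
    the chord (noise / third-component indicator).
    """
    p = np.asarray(point, dtype=float)
    a = np.asarray(end_a, dtype=float)
    b = np.asarray(end_b, dtype=float)
    ab = a - b
    denom = float(ab @ ab)
    if denom < 1e-24:
        raise ValueError("degenerate endpoints: end_a and end_b coincide")
    frac = float((p - b) @ ab) / denom
    proj = b + frac * ab
    residual = float(np.hypot(*(p - proj)))
    return float(np.clip(frac, 0.0, 1.0)), residual


def median_filter_phasor(field: PhasorField, window: int) -> PhasorField:
    """Median-filter g and s independently over valid neighbours.

    Invalid pixels stay invalid and are ignored (NaN-aware median) in their
    neighbours' windows; intensity is untouched.  ``window = 1`` is the
    identity.  Default pipeline behaviour is *no* filtering.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return field.copy()
    out = field.copy()
    for name in ("g", "s"):
        arr = getattr(field, name)
        filt = generic_filter(arr, np.nanmedian, size=window, mode="nearest")
        filt = np.where(field.valid & np.isfinite(filt), filt, arr)
        setattr(out, name, filt)
    return out


def summarize_region(field: PhasorField, mask: np.ndarray, label: str = "region") -> LifetimeSummary:
    """Mean ± SE of per-pixel phase lifetimes over a masked region."""
    sel = field.valid & mask
    tau = phase_lifetime(field.g[sel], field.s[sel], field.omega)
    tau = np.asarray(tau)[np.isfinite(np.asarray(tau))]
    if tau.size == 0:
        raise ValueError(f"region '{label}' has no valid finite-lifetime pixels")
    mean = float(np.mean(tau))
    se = 0.0 if tau.size == 1 else float(np.std(tau, ddof=1) / math.sqrt(tau.size))
    return LifetimeSummary(mean_tau_phi=mean, se_tau_phi=se, n_pixels=int(tau.size), label=label)
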