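"""Cursor-based selection in phasor space and back-mapping to the image.

A *cursor* is a circle in the phasor plot: pixels whose (g, s) falls inside
it belong to the lifetime population it selects (fibers, cells, red blood
cells, ...).  Selections are mapped back onto the intensity image as colour
tints, regions are fingerprinted by their intensity-weighted phasor centroid,
and whole acquisition batches are pooled into cumulative phasor histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phasor import PhasorField, phase_lifetime

__all__ = [
    "Cursor",
    "Fingerprint",
    "cursor_mask",
    "assign_cursors",
    "backmap_colormap",
    "region_centroid",
    "cumulative_phasor",
]

DEFAULT_HIST_RANGE = ((-0.1, 1.1), (-0.1, 0.7))


@dataclass(frozen=True)
class Cursor:
    """Circular phasor-plot cursor: center (g, s), radius, label, RGB color."""

    center: tuple
    radius: float
    label: str
    color: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"cursor '{self.label}': radius must be > 0")
        if not all(math.isfinite(c) for c in self.center):
            raise ValueError(f"cursor '{self.label}': center must be finite")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "color", tuple(float(c) for c in self.color))


@dataclass(frozen=True)
class Fingerprint:
    """Optical signature of one segmented region: phasor centroid + lifetime."""

    label: str
    centroid: tuple
    mean_tau_phi: float
    n_pixels: int


def cursor_mask(field: PhasorField, cursor: Cursor) -> np.ndarray:
    """Pixels that are valid and whose phasor lies inside the cursor circle."""
    _require_calibrated(field)
    g0, s0 = cursor.center
    d2 = (field.g - g0) ** 2 + (field.s - s0) ** 2
    return field.valid & (d2 <= cursor.radius**2)


def assign_cursors(field: PhasorField, cursors) -> np.ndarray:
    """Label image from a cursor set.

    Each valid pixel inside at least one cursor gets the index of the
    nearest covering cursor center (exact ties go to the first in the list);
    pixels in no cursor get -1.  Cursor labels must be unique.
    """
    _require_calibrated(field)
    cursors = list(cursors)
    if not cursors:
        raise ValueError("at least one cursor is required")
    labels = [c.label for c in cursors]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate cursor labels: {labels}")
    d2 = np.stack([
        (field.g - c.center[0]) ** 2 + (field.s - c.center[1]) ** 2 for c in cursors
    ])
    covered = d2 <= np.array([c.radius**2 for c in cursors])[:, None, None]
    d2 = np.where(covered, d2, np.inf)
    with np.errstate(invalid="ignore"):
        nearest = np.nanargmin(np.where(np.isnan(d2), np.inf, d2), axis=0)
    any_cover = covered.any(axis=0) & field.valid
    out = np.where(any_cover, nearest, -1).astype(np.int32)
    return out


def backmap_colormap(intensity: np.ndarray, label_image: np.ndarray, cursors) -> np.ndarray:
    """Colour-code the intensity image by cursor membership.

    Labeled pixels are tinted with their cursor's RGB colour scaled by the
    intensity normalised to its maximum; unlabeled pixels render grayscale.
    Returns an (ny, nx, 3) float image in [0, 1].
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != label_image.shape:
        raise ValueError("intensity and label image shapes differ")
    vmax = intensity.max()
    norm = intensity / vmax if vmax > 0 else np.zeros_like(intensity)
    out = np.repeat(norm[..., None], 3, axis=-1)  # grayscale base
    for idx, cur in enumerate(cursors):
        sel = label_image == idx
        out[sel] = norm[sel, None] * np.asarray(cur.color)
    return np.clip(out, 0.0, 1.0)


def region_centroid(field: PhasorField, mask: np.ndarray, label: str = "region",
                    weighted: bool = True) -> Fingerprint:
    """Intensity-weighted phasor centroid of a region and its phase lifetime.

    The centroid of a nonempty region always lies within the convex hull of
    its member phasors (it is a convex combination).  ``weighted=False``
    gives the unweighted mean for sensitivity checks.
    """
    sel = field.valid & np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError(f"region '{label}' selects no valid pixels")
    w = field.intensity[sel] if weighted else np.ones(int(sel.sum()))
    wsum = w.sum()
    g = float(np.sum(w * field.g[sel]) / wsum)
    s = float(np.sum(w * field.s[sel]) / wsum)
    return Fingerprint(
        label=label, centroid=(g, s),
        mean_tau_phi=phase_lifetime(g, s, field.omega),
        n_pixels=int(sel.sum()),
    )


def cumulative_phasor(fields, bins: int = 200, hist_range=DEFAULT_HIST_RANGE):
    """Pool many phasor fields into one intensity-weighted 2-D histogram.

    All fields must share omega and calibration state.  The histogram covers
    ``hist_range`` = ((g_min, g_max), (s_min, s_max)); its total weight is
    the summed intensity of all valid in-range pixels, and it is exactly
    additive under list concatenation.  Returns ``(hist, g_edges, s_edges)``
    with ``hist[i, j]`` counting bin (g_i, s_j).
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no fields given")
    omega = fields[0].omega
    calibrated = fields[0].calibrated
    for f in fields[1:]:
        if not math.isclose(f.omega, omega, rel_tol=1e-9):
            raise ValueError(f"mixed omega: {f.omega:g} vs {omega:g} rad/ns")
        if f.calibrated != calibrated:
            raise ValueError("mixed calibration state across fields")
    hist = None
    for f in fields:
        sel = f.valid
        h, g_edges, s_edges = np.histogram2d(
            f.g[sel], f.s[sel], bins=bins, range=hist_range, weights=f.intensity[sel]
        )
        hist = h if hist is None else hist + h
    return hist, g_edges, s_edges


def _require_calibrated(field: PhasorField) -> None:
    if not field.calibrated:
        raise ValueError("phasor field must be calibrated before cursor selection")
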