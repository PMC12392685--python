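"""Phasor-plot rendering with the universal semicircle overlay."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless rendering; the package never opens windows
import matplotlib.pyplot as plt

from .phasor import PhasorField
from .selection import DEFAULT_HIST_RANGE

__all__ = ["semicircle", "plot_phasor_field", "plot_cumulative_hist"]


def semicircle(n: int = 200):
    """(g, s) points of the universal semicircle (mono-exponential locus)."""
    theta = np.linspace(0.0, np.pi, n)
    return 0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta)


def _decorate(ax):
    g, s = semicircle()
    ax.plot(g, s, "k-", lw=1)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_xlim(DEFAULT_HIST_RANGE[0])
    ax.set_ylim(DEFAULT_HIST_RANGE[1])
    ax.set_aspect("equal")


def plot_phasor_field(field: PhasorField, ax=None, bins: int = 200, cursors=()):
    """2-D histogram of a field's phasors with semicircle and cursor overlays."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    sel = field.valid
    ax.hist2d(field.g[sel].ravel(), field.s[sel].ravel(), bins=bins,
              range=DEFAULT_HIST_RANGE, weights=field.intensity[sel].ravel(),
              cmap="inferno", cmin=1e-12)
    for cur in cursors:
        circle = plt.Circle(cur.center, cur.radius, fill=False,
                            color=cur.color, lw=1.5, label=cur.label)
        ax.add_patch(circle)
    _decorate(ax)
    return ax


def plot_cumulative_hist(hist, g_edges, s_edges, ax=None, title: str | None = None):
    """Render a pooled phasor histogram from :func:`cumulative_phasor`."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    masked = np.ma.masked_where(hist.T == 0, hist.T)
    ax.pcolormesh(g_edges, s_edges, masked, cmap="inferno")
    _decorate(ax)
    if title:
        ax.set_title(title)
    return ax
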