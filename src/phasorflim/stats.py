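"""Paired healthy-vs-tumor statistics in the study's reporting conventions.

Per-frame metrics from matched healthy and tumor region batches are compared
with the Wilcoxon signed-rank test (non-parametric, paired); summaries are
mean ± SE; significance is banded as n.s. / * / ** / *** with strict
inequalities at 0.05, 0.01, 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "wilcoxon_signed_rank",
    "summarize_mean_se",
    "significance_stars",
    "paired_report",
]

# Above this pair count the exact null distribution gives way to the normal
# approximation with continuity correction.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSample:
    """Matched per-frame metric lists for one sample's two regions."""

    sample_id: str
    healthy_values: tuple
    tumor_values: tuple
    metric_name: str

    def __post_init__(self) -> None:
        if not self.healthy_values or not self.tumor_values:
            raise ValueError(f"sample '{self.sample_id}': value lists must be nonempty")
        if len(self.healthy_values) != len(self.tumor_values):
            raise ValueError(
                f"sample '{self.sample_id}': healthy and tumor lists must pair up "
                f"({len(self.healthy_values)} vs {len(self.tumor_values)})"
            )
        object.__setattr__(self, "healthy_values", tuple(float(v) for v in self.healthy_values))
        object.__setattr__(self, "tumor_values", tuple(float(v) for v in self.tumor_values))

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.tumor_values) - np.asarray(self.healthy_values)


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original rule).  The null
    distribution is exact for n <= 25 remaining pairs and the normal
    approximation with continuity correction above.  Returns
    ``(W, p_two_sided)`` where W is the smaller signed-rank sum.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences given")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    method = "exact" if d.size <= EXACT_N_MAX else "approx"
    if method == "exact":
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def summarize_mean_se(values) -> tuple[float, float]:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n).

    A single value yields SE = 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    mean = float(values.mean())
    if values.size == 1:
        warnings.warn("single value: reporting SE = 0", stacklevel=2)
        return mean, 0.0
    se = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, se


def significance_stars(p: float) -> str:
    """Band a p-value: *** P<0.001, ** P<0.01, * P<0.05, else n.s. (strict)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def paired_report(samples) -> pd.DataFrame:
    """One-row-per-sample table of paired Wilcoxon results.

    Columns: sample_id, metric, n_pairs, healthy_mean, healthy_se,
    tumor_mean, tumor_se, W, p, stars.  NaN metric values (e.g. undefined
    ECI frames) are dropped pairwise and the retained pair count reported.
    """
    rows = []
    for s in samples:
        h = np.asarray(s.healthy_values)
        t = np.asarray(s.tumor_values)
        keep = np.isfinite(h) & np.isfinite(t)
        h, t = h[keep], t[keep]
        if h.size == 0:
            raise ValueError(f"sample '{s.sample_id}': no finite pairs")
        w, p = wilcoxon_signed_rank(t - h)
        hm, hse = summarize_mean_se(h)
        tm, tse = summarize_mean_se(t)
        rows.append({
            "sample_id": s.sample_id, "metric": s.metric_name, "n_pairs": int(h.size),
            "healthy_mean": hm, "healthy_se": hse,
            "tumor_mean": tm, "tumor_se": tse,
            "W": w, "p": p, "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)
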