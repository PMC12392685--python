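# phasorflim

Phasor-FLIM + SHG analysis of tissue autofluorescence, built for
quantifying fiber remodeling (elastin vs collagen) in unstained tissue
sections — the kind of label-free readout used to discriminate healthy from
tumor regions in lung biopsies.  The package is a library first: simulate
time-resolved multiphoton image stacks with known composition, transform
them to phasor space, calibrate against a known-lifetime reference, select
lifetime populations with circular cursors, quantify the elastin/collagen
balance per field of view, and compare paired region batches with
non-parametric statistics.  A thin `phasorflim` CLI wraps the same
functions for shell use.

## The method

Each pixel of a FLIM acquisition is a photon-count histogram c(t) over one
laser period T = 1/f (f = 80 MHz → T = 12.5 ns).  Its **phasor** at the
first harmonic is

    g = Σ c(t)·cos(ωt) / N,   s = Σ c(t)·sin(ωt) / N,   ω = 2πf

A mono-exponential decay of lifetime τ maps to the closed-form point

    g = 1/(1+(ωτ)²),   s = ωτ/(1+(ωτ)²)

on the *universal semicircle* (g−½)² + s² = ¼; mixtures fall inside it on
the chord joining their components (law of linear combination).  Coherent
SHG from fibrillar collagen has zero lifetime and sits at (g, s) = (1, 0);
elastin autofluorescence sits at its ~2.2 ns point.  Measuring a reference
fluorophore of known lifetime gives a rotation + modulation scaling that
cancels the instrument response — no decay fitting anywhere.  The *phase
lifetime* is τφ = s/(g·ω).

Fiber balance per field of view is summarised by the Elastin/Collagen
Index over thresholded fiber areas measured in paired emission channels of
the same FOV:

    ECI = (E − C) / (E + C)  ∈ [−1, +1]

0 means a balanced fiber network, +1 pure elastin (elastosis), −1 pure
collagen.  Paired healthy/tumor frame batches are compared with the
Wilcoxon signed-rank test (exact null for ≤ 25 pairs) and reported as
mean ± SE with n.s./*/**/*** bands.

## Worked example

`examples/` holds one short script per capability.  For instance
`python examples/04_fiber_eci.py` simulates a healthy-like and a
tumor-like FOV, segments both fiber channels and prints:

```
healthy frame:
  elastin area  =   104.0 um^2 (ground truth   104.1)
  collagen area =    90.8 um^2 (ground truth    91.9)
  ECI = +0.068   collagen = 12.9% of FOV

tumor frame:
  elastin area  =   205.2 um^2 (ground truth   205.8)
  collagen area =    12.3 um^2 (ground truth    13.5)
  ECI = +0.887   collagen = 1.8% of FOV
```

Segmented areas track the simulator's ground truth to ~1 µm²; the healthy
frame sits near ECI = 0 (balanced fibers) while the elastotic tumor-like
frame approaches +1 with collapsed collagen coverage.
`python examples/05_paired_stats.py` runs the full pipeline over six
frames per region and prints the paired Wilcoxon table (both metrics reach
p = 0.03125, the smallest two-sided p attainable with six pairs).

The same pipeline is scriptable from the shell:

```sh
phasorflim run --outdir out_demo --seed 8
```

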