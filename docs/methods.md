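# Methods

## Decay model and simulator

A pixel's expected photon arrival density over one laser period (repetition
rate f, period T = 1000/f ns; default 80 MHz, 12.5 ns) is the periodic
convolution of a Gaussian instrument response (IRF) with a sum of
exponential terms,

    d(t) = IRF_σ ⊛ Σᵢ aᵢ (1/τᵢ) e^(−t/τᵢ),   Σᵢ aᵢ = 1,

where the aᵢ are intensity fractions and τ = 0 denotes an instantaneous,
laser-coherent (SHG-like) term that contributes the IRF shape itself.  Each
exponential term is evaluated with the exponentially-modified-Gaussian
closed form (erfcx-stabilised against overflow) summed over enough laser
periods that the truncated tail is below 10⁻¹² of the total; the wrapped
Gaussian is summed over ±3 periods.  Expected bin intensities are the
density at the **bin centers** of n_bins uniform bins (default 256),
normalised so the expectation sums exactly to the requested photon total;
realised counts are independent Poisson draws.  Noise-free mode returns
the expectation itself, which is what exactness tests use.

The IRF is a wrapped Gaussian with σ = 0.1 ns by default, centred at t = 0.
Real digital frequency-domain instruments do not expose their IRF; the
whole analysis is designed so that reference calibration cancels it, and
the simulator gives the tests a *known* IRF to verify that cancellation.

### Spatial patterns and ground truth

Scenes are composed of labelled components drawn in order; later components
overwrite earlier ones (simple, reproducible layering).  Patterns:

- `curved_fiber` — dilated random-walk paths (step 1 px, heading noise
  σ = 0.2 rad, dilation radius 2 px) added until the requested coverage is
  reached; the last fiber's walk is shortened in proportion to the
  remaining deficit so realised coverage tracks the target closely.
- `blob` — Gaussian-smoothed white noise (σ = 4 px) thresholded at the
  coverage quantile.
- `disc` — random circles (radius 2–6 px) accumulated to coverage.
- `uniform` — covers everything (background).

The emitted ground truth (label map, per-label masks, areas = pixel count ×
pixel_size², generating lifetimes) is the oracle for all recovery tests.

### Default palette

| component    | lifetimes (fraction @ ns) | counts/px | main channels (weight) |
|--------------|---------------------------|-----------|------------------------|
| background   | 1.0 @ 3.0 (mounting-medium-like) | 15 | all (1.0) |
| nadph_cells  | 0.7 @ 0.4, 0.3 @ 3.2 (free/bound) | 800 | nadph 1.0, fluo 0.08 |
| collagen_shg | 1.0 @ 0.0 (instantaneous) | 2500 | shg 1.0, fluo 0.05 |
| elastin      | 1.0 @ 2.23 (healthy) / 2.31 (tumor) | 2500 | fluo 1.0, shg 0.12 |
| lipopigment  | 1.0 @ 0.6 | 600 | nadph 0.5 |
| rbc (healthy only) | 1.0 @ 0.2 | 1000 | nadph 0.6 |

Elastin and collagen values are the study conditions the pipeline targets;
the NAD(P)H, RBC and lipopigment entries are literature-typical
placeholders, flagged as such and overridable in any config.  Healthy
scenes balance elastin and collagen coverage (0.15/0.15) with visible
RBCs; tumor scenes are elastotic (0.30 elastin, 0.03 collagen, no RBCs)
and the elastin weight of 0.12 in the SHG channel reproduces the
long-lifetime leakage that dominates tumor SHG-channel phasors.  Cellular
signal in the fiber channels is an order of magnitude dimmer than fibers,
which is what makes threshold segmentation feasible.

What the generator does **not** emulate: optical blur/PSF, emission
spectra (beyond channel weights), detector afterpulsing or dead time,
spatially varying background, mosaic stitching, and co-located mixed
pixels (components are disjoint after layering; mixed decays occur only
*within* a component's lifetime list).  Passing tests therefore demonstrate
correctness of the transforms, calibration, selection and quantification on
well-posed inputs — not robustness to every instrumental artifact of real
acquisitions.

## Phasor transform and calibration

Transforms use the bin-center convention throughout, matching the
simulator, with ω = 2π·harmonic·f (harmonic 1 by default; higher harmonics
are accepted but experimental).  Zero-count pixels are invalid and carry
NaN coordinates; every consumer honours the validity mask, so flags never
become silent zeros in metrics.

Calibration measures the intensity-weighted aggregate phasor of a
reference field of known mono-exponential lifetime τ_ref and maps it onto
its closed-form point by a phase rotation and modulation scaling.  Because
convolution is multiplication in Fourier space, the same correction
cancels the IRF factor for every pixel.  With a Gaussian IRF of σ at least
about one bin width, bin-center sampling also reduces to a pure
multiplicative factor (aliasing of the Fourier coefficients is suppressed
by the IRF), so calibration cancels discretisation too — the test suite
verifies semicircle residuals below 10⁻³ across τ ∈ [0.1, 10] ns and
machine-precision recovery in noise-free mode.  The reference lifetime is
a required configuration parameter (defaults in examples use 2.5 ns, a
typical coumarin-in-ethanol value); it is never a constant inside the
calibration code.

Two-component unmixing projects a phasor onto the chord joining two
endmembers; fractions are clipped to [0, 1] and the perpendicular residual
is reported rather than raising on off-chord points, because noisy real
mixtures are never exactly on the chord.  An optional NaN-aware median
filter (off by default) is available for phasor smoothing before cursor
selection.

## Cursor selection

Cursors are circles in phasor space (the only shape provided).  When
cursors overlap, a pixel goes to the nearest covering center, with exact
ties resolved to the first cursor in the list — deterministic and
order-independent except at exact ties.  Region fingerprints use the
intensity-weighted phasor centroid (matching the photon-weighted semantics
of the phasor itself); an unweighted mode exists for sensitivity checks.
Cursor radii are configuration, not constants; 0.05 is the default.
Cumulative phasor histograms are intensity-weighted 2-D histograms over
(g, s) ∈ [−0.1, 1.1] × [−0.1, 0.7] and are exactly additive under batch
concatenation.

## Fiber segmentation and ECI

Default segmentation is Otsu thresholding followed by removal of objects
smaller than `min_object_px` (default 16 px).  Otsu always returns *some*
threshold, so the split is accepted only if its effectiveness — the
between-class fraction of total variance, η = w₀w₁(μ₁−μ₀)²/σ² — reaches
0.75.  A genuinely bimodal fiber/background image scores near 1; unimodal
shot noise (e.g. the SHG channel of a collagen-free FOV) scores near 0.64,
the unimodal-Gaussian limit, and yields an empty mask instead of
percolating thresholded noise.  A `fixed:<value>` mode exists for
regression tests and manual thresholds.

`collagen_pct` uses the FOV area as denominator (a per-frame coverage
figure); elastin-vs-collagen *balance* is always expressed through the
ECI, so the denominator choice only affects coverage-style outputs.
Frames where both areas are zero have undefined ECI, are flagged NaN,
excluded from aggregation and counted in the run report.  The paired
elastin (505/90-like) and collagen (405/10-like) images must come from the
same FOV; shape and frame-id pairing enforce this.

Pixel size is treated as a **linear** size in µm (default 0.207 µm/px).
Instrument metadata sometimes quotes "pixel size" with area units; this
package standardises on the linear convention and documents it here
rather than guessing per input.

## Paired statistics

The Wilcoxon signed-rank test drops zero differences (the original rule),
uses the exact null distribution up to 25 remaining pairs and the normal
approximation with continuity correction above; implemented over
scipy.stats with this policy fixed, and validated in the tests against an
independent brute-force enumeration of all 2ⁿ sign assignments for n ≤ 12
plus a 2000-replicate null calibration of the rejection rate.  The pairing
unit is the frame within a sample's region batch; pooling frames across
samples for a patient-level test is a separate aggregation the caller
performs on the per-frame CSV, so both granularities are reproducible.
Summaries are mean ± SE (sample SD, n−1 denominator); significance bands
use strict inequalities at 0.05, 0.01, 0.001.

## Problem sizes

Tests and examples run scenes of 64–128 px squared with 256 time bins and
photon budgets of 10³–10⁶ counts — sizes chosen so the full suite
completes in seconds while every stochastic check retains comfortable
margins (e.g. lifetime recovery uses ≥ 2×10⁵ aggregate counts where the
tolerance is 0.05 ns, an order of magnitude above the shot-noise floor).
The acceptance script uses 50 regions × 2×10⁴ counts per lifetime.

## Known limitations

- Blind or >2-component unmixing, multi-harmonic global analysis, and
  fitting-based lifetime estimation are out of scope.
- The Otsu-effectiveness gate assumes bright fibers on dim background; a
  channel with genuine but extremely low-contrast fibers (η < 0.75) is
  reported as fiber-free.
- Component layering makes masks disjoint: the simulator cannot express a
  pixel containing two labelled components at once.
- CLI subcommands cover simulate / phasor (with optional calibration) /
  select / fibers (areas + ECI) / stats / run; calibration, ECI and report
  generation are folded into those rather than exposed as separate verbs.
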