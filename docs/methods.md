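# Methods

This note records the models, parameter choices and numerical policies
behind `mtdyn`, in the spirit of a methods supplement: what is simulated,
what is measured, and where the package had to make a choice the
published measurements leave open.

## Tip-trajectory model

The plus-end state chain is a continuous-time Markov chain over up to
four states (fast growth, slow growth, pause, shrinkage) with per-minute
hazard rates. Dwell times are exact exponentials; the dwell log is kept
on the trajectory (`Trajectory.events`) with continuous times, and the
test suite checks it against the closed-form exponential law and the
stationary distribution obtained directly from the generator matrix.

Two discretization choices matter:

- **Velocity switches take effect at the next sampling instant.** The
  sampled positions are therefore exactly piecewise linear with vertices
  on the 3-s grid. At the camera's sampling rate this is indistinguishable
  from mid-interval switching for all realistic rates, and it makes the
  piecewise-linear segmentation model exact, which is what lets the
  pipeline attribute recovery errors to tracing and pooling rather than
  to a modelling mismatch. The one regime where it is consequential is
  control-speed shrinkage (≈37 µm min⁻¹ ≈ 1.85 µm per interval), where
  mid-interval switching would contaminate roughly one interval per
  episode and bias pooled shrinkage rates ~10% low.
- **Seed floor.** Position is floored at 0 µm (the stabilized seed). A
  shrinkage step reaching the floor either enters a terminal pause
  ("block", probability `block_at_seed_prob`) or regrows; with
  `terminal_block` set, any pause entry is permanent, emulating
  CEP104-style blocking where no regrowth is seen for the remainder of
  the experiment.

Per-step velocity noise is Gaussian with s.d. `velocity_sd` (µm min⁻¹,
scaled by dt/60) — the simplest noise model consistent with fitting
straight lines to kymograph episodes. The printed per-condition
uncertainties are adopted as the default `velocity_sd`; being standard
errors of pooled means, they are conservative (small) as per-step
spreads, which keeps the velocity anchors, not the noise model, in charge
of the recovered means.

### Condition presets

Velocities are the published condition means (µm min⁻¹): full module
0.19; CEP104+TOGARAM1 0.12; minimal trio (2 nM CEP104 + 2 nM CSPP1 +
10 nM TOGARAM1) 0.022; TOGARAM1 alone 2.27; control shrinkage −36.91;
CEP104+CCDC66 shrinkage −0.12. Growth of EB3-only controls is not printed
and defaults to 2.5 µm min⁻¹, a typical EB3-stimulated rate at 15 µM
tubulin.

Transition hazards are not printed anywhere and are package defaults,
chosen so that percent-time-per-state and event-count ratios are
qualitatively consistent with the published dynamic-state panels: the
full module spends most time in slow growth with occasional pausing
(pause entry 0.15 min⁻¹, exit 1.0 min⁻¹); CEP104+TOGARAM1 pauses more
often (entry 0.3 min⁻¹ — matching the reported ≈2.7:1 growth:pause event
ratio — exit 1.2 min⁻¹); controls catastrophe at 0.25–0.3 min⁻¹. Each
preset value carries a `provenance` string saying whether it is a
measured value or a package default.

Each preset's growth state is labelled by the classification of its mean
velocity (TOGARAM1's 2.27 µm min⁻¹ growth is `fast_growth`; the module
conditions are `slow_growth`), so generative labels and classifier
output live in the same vocabulary.

## Kymograph rendering and tracing

Rendered kymographs follow the reslice convention: one row per 3-s
frame, time downward, 0.045 µm px⁻¹. Each row carries a lattice plateau
from seed to tip (PSF-blurred step edges, computed with erf) plus a
brighter Gaussian line at the tip, with Poisson shot noise and Gaussian
read noise; `snr` is the tip amplitude over the shot-noise s.d. at the
peak (default 25; `snr=None` renders the noiseless expectation).

Tracing estimates, per row, the distal-most local maximum above a
fraction (default 0.3) of the row's peak-over-background, refined by
quadratic interpolation; background statistics come from the distal
margin columns (beyond the tip in every frame), never from the whole
image, whose median sits on the lattice level when the microtubule fills
the field. The seed origin is the sub-pixel 50% crossing of the proximal
lattice edge (the midpoint of a blurred step sits exactly at the step).
Rows without signal are imputed by interpolation and flagged. Despiking
removes only isolated impulses — a point far from the running median
whose two neighbours agree with each other — so genuine one-frame
depolymerization excursions survive.

## Phase segmentation and classification

Changepoints minimize total squared residuals of per-segment straight
lines plus a per-changepoint penalty, solved exactly by dynamic
programming over O(n²) candidate segments with O(1) segment costs from
cumulative sums (an exhaustive-search oracle verifies cost and
changepoint equality on small instances). The default penalty is
3·log(n)·σ̂², with σ̂ a robust (MAD-based) noise scale from second
differences; it is exposed as configuration.

Phases are fitted on the partition's own half-open sample ranges. Two
post-processing rules keep the event pools clean:

- Segments shorter than a minimum duration (default 2 sampling
  intervals, measured over the fitted samples) donate their **time span**
  to the rate-closer neighbour but never their **samples** — remnants
  such as the partial step where shrinkage meets the seed cannot drag a
  genuine phase's rate across a class boundary.
- Adjacent same-class segments are merged only when the joint refit
  keeps the class *and* raises the residual by no more than the penalty,
  i.e. when the two segments genuinely lie on one line. This prevents a
  sawtooth of growth excursions separated by absorbed full-depth
  collapses from collapsing into one bogus phase.

Classification uses the published thresholds (fast > 0.5; slow in
(0.02, 0.5]; shrinkage < −0.02; otherwise pause; boundaries go to the
slower class — `classify_phase` implements exactly this). On top of the
point thresholds, a fitted segment whose slope is statistically
indistinguishable from zero (|rate| below ~2 standard errors, using the
Student-t quantile for the segment's degrees of freedom) is labelled a
pause: the automated counterpart of an analyst calling a visually flat
stretch flat. For noiseless input the standard error vanishes and the
rule reduces to the pure thresholds.

Blocks are terminal pauses persisting to the end of the observation;
block duration is censored at the 600-s video length, which is therefore
also the maximum reportable pause duration. Summaries report pooled and
per-experiment (mean-of-means) statistics; frequencies with zero-time
denominators are reported as absent, never 0. Microtubules with no
growth events contribute to time fractions but not to rate pools.

## Photometry

Spot fits are symmetric 2D Gaussians with constant offset over a window
of 4σ (rounded up); integrated intensity is 2π·A·σ²; non-converged fits
are flagged and excluded from histograms. Histogram modes come from a
Gaussian KDE with Silverman bandwidth — the mode, not the mean, because
the right tail (overlapping spots, aggregates) is heavy. Stoichiometry is
the mode ratio against a monomer standard from the same coverslip,
rounded to the nearest integer with a bootstrap CI; a CI spanning two
integers flags the call as ambiguous. The inference is scale-invariant by
construction.

FRAP normalization anchors the last pre-bleach frame at 1 and the first
post-bleach frame at 0 (the ratio form; a single pre-bleach frame by
default, with an option to average several). The recovery fit is
plateau·(1 − e^(−kt)) on post-bleach time; a plateau below 0.05 is
classified "no exchange" and k is reported absent rather than 0, since a
rate is unidentifiable without recovery.

## Flare geometry

Generated ends place protofilament wall segments on a 12-nm-radius
cylinder at azimuths 360°/n with ≤±2° per-protofilament jitter (pairwise
spacing stays within the ±4° acceptance window used when tracing real
tomograms), wall-exit heights drawn with the raggedness s.d., and planar
circular-arc flares (in the plane of the axis and the outward radial)
with drawn lengths and curvatures. Flared (control-like) defaults: mean
length 30 ± 12 nm, curvature 2.86 deg nm⁻¹ (a 20-nm radius of
curvature), raggedness 8 nm. Corked defaults: 8 ± 3 nm, 1.8 deg nm⁻¹,
3.5 nm — shorter, straighter, more even, the direction of the published
contrasts.

Metrics: wall exit at the first >10° deviation from the axis (supplied
or estimated as the principal direction of the point cloud, oriented
root→tip); flared length from the last in-wall segment through the tip
(for blunt traces with the one-pixel third-point convention this floors
at one pixel, ≈0.434 nm at the binned tomogram pixel size); local
curvature as turning angle over mean adjacent segment length, averaged
per protofilament and then per microtubule without length weighting;
raggedness as the n−1 s.d. of wall-exit axial projections. All metrics
are rigid-motion invariant (tested to 1e-6 relative). Polarity is a
supplied label; determining it from densities is out of scope. The
deg nm⁻¹ curvature unit follows the protofilament-tracing script lineage
this analysis descends from.

The wall-exit rule detects the exit slightly late on a smooth arc (the
direction must accumulate 10° of bend, ≈3.5 nm at control curvature), so
measured flared lengths are a few nm shorter and measured raggedness
slightly wider than the generative parameters; the parameter-recovery
tests bound this at the defaults (raggedness within 15%).

## Statistics

Two-group contrasts use the two-sided Mann-Whitney U (exact for small
samples); multi-group contrasts use Kruskal-Wallis followed by Dunn's
pairwise z tests with the standard tie correction, against a designated
control or all pairs, Holm-adjusted by default (the adjustment is
configurable; no particular adjustment is conventional for these
panels). Degenerate all-identical
input returns H = 0, p = 1 rather than dividing by zero.

## Problem sizes and reproducibility

Acceptance-style rate recovery uses 100 trajectories of 600 s at 3-s
sampling per condition — the scale of one pooled three-experiment
dataset — and runs in seconds per condition. Every generator and
pipeline stage takes an integer seed; a single global seed fans out to
per-stage child seeds through `numpy.random.SeedSequence`, so rerunning a
pipeline with the same configuration is byte-identical, and every written
artifact is accompanied by a manifest recording configuration, seed and
package version.

## What the synthetic data do and do not establish

The generators reproduce the statistical structure the analyses consume:
state-switching kinematics on a camera grid, shot-noise-limited line
profiles, sums of monomer intensities, single-exponential recovery,
arc-flared end geometry. They deliberately omit several features of real
data — microtubule-to-microtubule parameter heterogeneity, drift and
stage jitter, uneven illumination, EB-comet intensity gradients at tips,
photobleaching within movies, doublet geometry, and tomographic
missing-wedge distortion of traces. Passing the recovery suites
therefore shows that the measurement pipeline is unbiased and correctly
calibrated under the stated noise model, not that it is robust to every
artifact of a real microscope; the tracing and segmentation entry points
expose their tolerances (`threshold_sd`, `peak_fraction`, `penalty`,
`min_duration`, `rate_se_factor`) so real-data users can adapt them.

Known limitations: pauses much shorter than the time needed for a
0.02 µm min⁻¹ rate difference to exceed tracing noise are fundamentally
invisible at 0.045 µm pixels (they dilute slow-growth rates by a few
percent, exactly as they would for a human tracer); block detection is
censoring-dependent by definition; and the minimal-trio condition sits
so close to the pause threshold (0.022 vs 0.02 µm min⁻¹) that
classification truncation biases its recovered mean upward by ~10% — an
intrinsic property of the threshold convention, visible in the recovery
table.
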