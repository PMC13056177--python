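# Methods

This note documents the models, conventions and numerical choices
behind `mucotrack`, and what the built-in simulator does and does not
emulate.

## Microrheology model

A tracer bead of radius `a` in a viscoelastic medium at temperature `T`
performs thermal motion whose two-dimensional, time-averaged mean
squared displacement `⟨Δr²(τ)⟩` determines the complex shear modulus in
the local power-law (Mason) approximation:

```
|G*(ω)| = 2 k_B T / (3 π a ⟨Δr²(1/ω)⟩ Γ[1 + α(ω)]),   ω = 1/τ
G′ = |G*| cos(π α / 2),  G″ = |G*| sin(π α / 2),  η* = |G*| / ω
```

`α(ω)` is the local logarithmic slope of the MSD, estimated by a
quadratic fit in log–log space over a 5-point window (edge-truncated;
linear for fewer than 3 points) and clipped to `[0, 1]`. The factor
2/3 folds the 3/2 projection from a 2-D observation of isotropic 3-D
motion into the modulus, so for a Newtonian fluid with `⟨Δr²⟩ = 4Dτ`
and `D = k_B T / (6 π η a)` the identity `η*(ω) = η` holds exactly —
this is asserted to 1e-9 relative in the tests.

Conventions and defaults:

* **Reporting frequency.** The scalar `η*` is read at 1 Hz
  (`ω = 2π rad/s`) by log–log interpolation of the spectrum;
  configurable via `omega_ref`.
* **Lag window.** Per-track MSDs run to 0.3 of the track span; the
  ensemble curve is additionally cut below 3 frame intervals. Short
  lags are dominated by localization noise, long lags by poor
  averaging.
* **Ensemble averaging.** Per-track curves are combined on their
  common lag grid, weighted by the number of displacement pairs. Tracks
  spanning less than half the longest span are dropped first so the
  common grid stays informative.
* **Drift correction.** With at least 5 simultaneous tracks, the
  per-frame ensemble-mean displacement is accumulated and subtracted
  (on by default for beads, never applied to sperm, whose directed
  motion is the signal). The correction also removes `1/n` of the
  diffusive variance, biasing `η*` upward for very small ensembles
  (~20% at n = 5, < 4% for n ≥ 25); the default bead counts keep this
  negligible.
* **Static localization error is not subtracted** by default; the
  noise floor adds ≈ `4σ²` to the MSD intercept and biases `η*`
  downward when the true displacement per lag approaches `σ`. The
  effect is visible in the simulated cohort at the most concentrated
  points and is monotonicity-preserving.
* **Temperature** defaults to 293.15 K and is a required assumption of
  the method (`η*` scales linearly with the assumed `T`); it is echoed
  in pipeline reports.

## Tracking

The detector/linker follows the classic colloid-tracking scheme:
Gaussian blur at the noise scale minus a boxcar background at the
feature scale (clipped at zero); local maxima above an intensity
percentile (default 64, with a relative floor that rejects numerical
residue in flat regions); iterative masked-centroid refinement (radius
= half the feature diameter, up to 10 iterations, window re-centred
while the centroid offset exceeds half a pixel); mass, radius of
gyration and eccentricity from intensity moments; duplicate maxima
within one feature diameter merged keeping the larger mass.
Eccentricity uses the angular second-moment form
`√[(ΣI cos2θ)² + (ΣI sin2θ)²] / (mass − I_center)`, which is ~0 for a
circular spot and ≈ 0.33 for a 2:1 elongated Gaussian — placing bead
and sperm-head regimes cleanly on either side of the 0.3 / 0.5
cutoffs.

Linking minimises total squared displacement per frame pair, solved
globally with the Hungarian algorithm on a cost matrix in which links
beyond the search range are forbidden and track death/birth each cost
the squared search range; this is exact for arbitrarily entangled
candidate subnetworks, with a hard size cap that raises an error
instead of degrading. A particle unmatched for at most `memory` frames
may resume its identity, leaving a gap that lag-based statistics
respect. Defaults: beads search 5 px / memory 3; sperm search 15 px /
memory 0 — sized from expected per-frame displacements (bead rms step
at buffer viscosity ≪ 1 px at 30 fps; sperm up to ~6 px/frame at the
highest dilutions).

Duration convention: a track's recorded duration is
`(last_frame − first_frame) / frame_rate`; the sperm chain keeps tracks
of at least 1 s (so 21 frames spanned at 20 fps pass, 20 do not).

## Kinematics

VSL uses the first-to-last displacement of the whole track over its
duration; VCL the summed step lengths; VAP the path length of a
centred moving-average path (default window 5 frames ≈ one wobble
period at 20 fps). Windows shrink **symmetrically** at the edges
(half-width `min(half, i, n−1−i)`), pinning the smoothed endpoints to
the raw ones so a straight path has VAP = VCL exactly rather than
being shortened by edge truncation. ALH is twice the mean absolute
perpendicular deviation of the raw path from the average path
(components taken against the local tangent); a twice-the-maximum
variant is selectable, as CASA vendors differ. The moving average
absorbs part of the oscillation at these frame rates, so ALH
underestimates the geometric wobble amplitude; it is used as a
relative, not absolute, readout.

## Simulator

The generator encodes the study conditions of the paired assay:

* **Beads:** increments are exact Gaussian steps of variance `2DΔt`
  per axis at the frame interval (no integration error), 10 s at
  30 fps, 1 um bead diameter; optional constant drift and localization
  noise (default 0.02 um, a typical centroiding precision) applied to
  reported positions only.
* **Swimmers:** each sperm draws a progressive speed lognormal
  (dispersion 0.15 in log10 units by default) around the median
  `base_speed · c^(−β)` with `β = 0.5` — diluting the mucus speeds
  swimmers up along a square-root law. The path is a persistent
  heading (rotational diffusion, correlation time 50 s, giving the
  high path straightness seen in mucus) plus a sinusoidal lateral
  displacement (amplitude 2 um, 2 Hz — resolvable at 20 fps). 5 s at
  20 fps. `base_speed` defaults to 10 um/s at neat mucus, putting the
  1:128 dilution near 113 um/s, spanning a realistic sperm velocity
  range.
* **Dilution cohorts:** sample viscosity interpolates between buffer
  (1e-3 Pa s) and neat mucus along
  `η(c) = η_buffer + (η_neat − η_buffer) c³`; the steep cubic reflects
  the strong concentration dependence typical of mucin networks, and
  only the monotone direction is constrained by the assay it emulates.
  `η_neat` defaults to 0.1 Pa s — a mid-range mucus viscosity whose
  bead displacements remain well above the localization floor.
  Animal-level heterogeneity multiplies each animal's `η_neat` and
  `base_speed` by independent lognormal factors (sd 0.2 log10 units).
  Bead movies run in technical duplicate, sperm in triplicate.
* **Rendering:** particles become 2-D Gaussian spots (optionally
  elongated along the direction of motion, for sperm heads) over a
  flat background with Gaussian or Poisson camera noise, clipped to
  the bit depth. Out-of-field particles are silently clipped.

Not emulated: hydrodynamic interactions, 3-D diffusion with defocus,
flagellar waveforms, photobleaching, non-uniform illumination and
mucus spatial heterogeneity. Passing tests therefore validate the
measurement chain's correctness on ideal-optics data, not robustness
to every real-microscope artifact.

## Statistics

Analysis scale is chosen by Anderson–Darling normality tests on each
ensemble raw and log10-transformed, selecting the scale with more
non-rejections at α = 0.05 and breaking ties toward log10 (lognormal
measurement noise is the simulator's construction, and log scale is
the field's convention for spans of several decades). Replicates are
aggregated as the median of log10 values (mean available). The pooled
Pearson correlation across all animal × dilution points uses two-sided
p-values from the t distribution with n − 2 df; a per-animal stratified
analysis is possible by filtering the aggregated points. No
multiple-testing correction is applied. Power-law exponents come from
least-squares fits in log10–log10 space, reported as |slope| with the
regression standard error.

## Problem sizes and determinism

Default verification sizes — 100 beads for the buffer reference, 50
sperm per dilution for the scaling fit, 6 animals × 8 dilutions with
30 beads × 2 replicates and 30 sperm × 3 replicates per point for the
cohort — give sampling errors comfortably inside the tolerances
asserted (η* within 15%, exponent within 2 SE of 0.5, correlation
p ≪ 0.001) while keeping the whole suite fast on one CPU. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; replaying a seed reproduces outputs
bit-identically, and cohort child streams are spawned so per-movie
seeds never collide.

## Degenerate inputs and tie-breaks

Non-positive MSD values are excluded from the GSER (all-excluded is an
error); constant ensembles are skipped in scale selection (all-skipped
is an error); zero-variance axes and n < 3 are correlation errors;
non-positive replicate values are excluded from log aggregation with
counts logged; equal-mass duplicate detections break ties toward lower
(y, x); `eta_star_at` refuses frequencies outside the spectrum rather
than extrapolating.
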