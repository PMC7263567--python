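# Methods

## Scope and data model

The package analyses three kinds of input: basal-surface image scenes
(a grayscale frame plus an integer label image of cell IDs, a genotype
map, tricellular-junction coordinates and a μm/pixel calibration),
uniformly sampled intensity/geometry traces, and vertex-distance traces
around a laser cut.  Because the source study deposited no imaging
data, all validation runs on synthetic inputs from `epimech.synth`,
whose presets encode the published effect sizes as ground truth.

## Synthetic scenes

Cells are Voronoi regions of a jittered hexagonal lattice (pitch 64 px,
jitter ±6% of pitch, 0.25 μm/px); an extra ring of virtual seeds maps
to label 0 so cell-free background exists for background estimation.
This tessellation produces realistic tricellular junctions with minimal
machinery.  Pixel convention: 0-based row-major indices, pixel centres
at integer coordinates; physical outputs in μm via the calibration.

Per cell the renderer draws:

- **Stress fibers**: vertical line segments with a Gaussian
  cross-section (σ = 1 px, truncated at 3σ) at integer columns spaced
  7 px apart, centred in the cortically eroded interior.  The spacing
  exceeds twice the truncation half-width, so fiber footprints never
  overlap and each peak sample equals the preset intensity exactly —
  this makes noiseless intensity ratios and peak counts exact rather
  than approximate, which the recovery tests rely on.
- **Cortical rings**: both pixels of every 4-adjacent cross-boundary
  pair, at an intensity set by the flanking genotypes (mutant-mutant
  boundaries at twice the control level; mixed boundaries at control
  level, matching the observed mixed-junction null result).
- **Whips**: polylines 2–4 μm long walking along the cell edge from a
  leading-edge tricellular junction.  Whips are rendered only in the
  F-actin channel (they contain no myosin) and hug the cortex, so they
  never contaminate the fiber-region interior.  Whip counts per cell
  are the integer part of the preset mean plus a Bernoulli draw of the
  fractional part (control 2.0 → exactly two; mutant 5.5 → five or six).

Noise is Poisson shot noise on the noiseless render plus additive
Gaussian read noise of sd `noise_sd` (a standard confocal
approximation), applied after truth is recorded; `noise_sd = 0`
disables both so noiseless renders are exact.  The clipped read noise
raises the apparent background slightly; background subtraction uses
the same label-0 statistics the analyses use, so the bias largely
cancels in ratios.

The "leading edge" (direction of tissue rotation) is a declared scene
attribute rather than a simulated motion, defaulting to west; a
junction is leading-edge for a cell when it lies on that side of the
cell centroid.

## Synthetic traces

Oscillations are sinusoids — the simplest waveform with an exact period,
amplitude and spectral line: myosin `2A + A·sin(φ(t))` with A the
preset amplitude; protrusion area phase-locked by the preset coupling
phase; basal area in anti-phase (myosin accumulation contracts the
surface); D-V and A-P lengths `L·(1 − e·sin(φ))` with strains in the
preset anisotropy ratio (A-P strain fixed at 0.05).  Cycle-to-cycle
period jitter (CV 0.05 control, 0.15 mutant — mutants cycle more
stochastically) makes the phase piecewise linear; with jitter and noise
zero the traces satisfy their closed forms to machine precision.
Traces default to 30 s frames, matching the live-imaging cadence, and
trace noise is Gaussian with sd expressed as a fraction of each trace's
oscillation amplitude (default 0.05).

Recoil traces follow `L(t) = L0 + ΔLmax(1 − e^(−t/τ))` after the cut,
sampled every 0.8 s with 12.8 s of pre-cut baseline.  τ = 2 s and
L0 = 5 μm are typical epithelial scales (the study prints neither);
ΔLmax per boundary class is derived from the published initial
velocities by inverting v0 = ΔLmax(1 − e^(−0.8/τ))/0.8, so the printed
velocities are the generator's ground truth.  Noise sd defaults to 5%
of ΔLmax.

## Morphometry presets

The study reports growth fold changes, not absolute areas.  Absolute
stage means are anchored at control S8 = 50 μm² and chosen so the folds
equal the published values exactly (control 1.7× S8→S9 and 1.8×
S9→S10; mutant 1.5× and 1.3×).  Nuclear size is identical between
genotypes (the published null result).  Per-cell values are Gaussian
with CV 0.15 by default, floored at 5% of the mean to keep areas
positive.

## Analysis choices

- **Fiber peaks**: a raw local maximum rises strictly on the left and
  falls non-strictly on the right, so plateaus yield their leftmost
  sample (deterministic tie-break).  Peaks count when their height is
  at or above (control mean − 1 SD).  The inclusive comparison keeps
  the degenerate but legitimate zero-SD reference (identical control
  peaks) self-consistent: control peaks must re-detect against their
  own reference.  Candidates closer than 0.5 μm are merged greedily,
  keeping the higher peak — sub-resolution doublets are one fiber.
- **Peak density** divides by profile *line length* (peaks/μm), the
  unit of the published axis; dividing by cell area would change the
  unit to peaks/μm².
- **Profile chord**: the dominant variation direction of the per-cell
  structure tensor (normal to the fiber axis), snapped to the image
  axis when within ~6°, which keeps sampling on the pixel grid and peak
  heights exact for axis-aligned fibers.  A 1 μm cortical margin is
  eroded before profiling (configurable); cells whose chord is shorter
  than 2 μm are reported as degenerate.
- **Whole-cell intensity** is the background-subtracted mean pixel
  intensity in the mask (integrated intensity / area); fiber-region
  masks are reconstructed from scene truth since fibers are not
  re-segmented.
- **Cortical bars** sum samples taken at pixel pitch over ±1 μm along
  the boundary normal (gradient of a smoothed signed distance between
  the two cell masks).  Summing versus averaging across the bar cancels
  in class ratios, which are what is reported.  Idealised straight
  boundaries recover preset ratios to machine precision; generated
  mosaics recover them to a few percent because rings of different
  classes meet at junctions under max-compositing.
- **Smoothing** uses a Gaussian of σ = 3 samples truncated at 3σ,
  reflect padding — a single smoothing scale.  Because that kernel
  attenuates the oscillation itself at typical period-to-frame ratios
  (~50% at 16 samples/period), cycle *windows* are found on the
  smoothed signal but cycle *amplitudes* are measured on the unsmoothed
  background-subtracted signal; otherwise amplitude recovery within 10%
  would be impossible.
- **Cycle detection** requires a prominence of 0.2× the signal range
  (configurable); runs of same-type extrema are merged keeping the most
  extreme, so peaks and troughs alternate.
- **PSD period**: mean-subtract, normalized biased autocorrelation
  (lag 0 = 1), unwindowed FFT magnitude; the dominant period is the
  reciprocal of the argmax frequency at or above 1/(total duration)
  (DC and slower trends excluded).  Off-bin peaks resolve to the
  nearest bin; no interpolation is attempted, so spectral estimates
  carry one-bin quantisation.
- **Recoil**: the baseline window is the 10 s immediately before the
  cut, excluding the cut frame itself; velocities are computed per
  trace and then averaged (group n equals trace count).  Welch's
  unequal-variance t-test is the group comparison; zero-variance
  degenerate pairs are flagged rather than propagating infinities.
  Viscosity is not modelled: v0 is a relative tension proxy under the
  equal-viscosity assumption.
- **Anisotropy**: per-cycle fractional length change is
  (max − min)/mean within trough-to-trough windows detected on the D-V
  trace; the same windows score the A-P trace, so window placement
  cancels in the ratio.  An unchanging A-P length yields infinity,
  flagged to the caller.
- **Whip counting** assigns a whip to the cell owning the leading-edge
  junction nearest its anchor within 1 μm (configurable anchor radius).

## Problem sizes and tolerances

Validation uses 16-cell scenes (~320×384 px), one-hour traces at 30 s
frames, and group sizes matching the published experiments (14-24
recoil traces, 20 trace bundles, 10 scenes).  Noiseless recoveries are
asserted at 1e−6 relative error or better; stochastic recoveries at
5-10% depending on the quantity, with Monte-Carlo repetition counts
(50 seeded runs for period recovery, 100 for baseline estimation)
chosen to make pass/fail stable across seeds.

## What the generator does not emulate

No point-spread function or 3-D stacks (a single in-focus frame stands
in for a max projection), no tissue rotation or cell motion, no
photobleaching, no fiber curvature or orientation dispersion within a
cell, and no late-stage (S10B) basal-surface collapse.  Passing
recovery tests therefore demonstrates that the estimators are unbiased
and correctly calibrated under the stated noise model — not that they
are robust to out-of-focus light, segmentation errors or motion
artefacts in real movies.  Detected mutant fiber densities of zero on
noiseless scenes are expected behaviour of the SD-threshold rule when
mutant fiber intensity sits far below the control reference, mirroring
the near-disappearance of mutant stress fibers at late stages.
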