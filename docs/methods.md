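# Methods

## Physical model

The package treats the extraction region of a single-stage linear TOF as a
uniform field E = V/d over a gap d, followed by a field-free drift L.  An
ion is modelled as appearing at the surface (z = 0) at its ejection time
t_E — ejection is a step event; before t_E the ion reports position zero —
and moving thereafter with constant acceleration a = qeE/m:

    z(τ) = v0 τ + (a/2) τ²,        τ = Δt − t_E,
    τ(z) = [−v0 + √(v0² + 2az)]/a.

Assumptions baked into these closed forms:

- one spatial dimension (the TOF axis); radial plume expansion is ignored;
- no space charge, no collisions after ejection, non-relativistic motion;
- the probed region (z ≤ 4.6 mm) lies well inside the gap (12.712 mm), so
  the propagation model never needs the drift region — the drift matters
  only for rendering spectra;
- the instrument is single-stage: no Wiley–McLaren second stage, no
  reflectron (a reflectron would erase the spatial information the
  missing-segment method depends on).

Internally everything is strict SI; ns/mm/kV appear only at interfaces
(config files, CSV/JSON dialects, CLI output), converted once at the
boundary.  Constants: e = 1.602176634e-19 C, u = 1.66053906660e-27 kg.
Species masses are monoisotopic (the kinematic difference from nominal
masses is < 0.05%); nominal m/z is retained for labels.

The gap length is not an independently known quantity; it is derived once
from the printed 4.5 kV ↔ 3.54e5 V/m pair (d = 12.712 mm) and used for all
three voltages, which reproduces the other two printed field values to
3 significant figures.  The drift length defaults to 1.0 m; it affects
only absolute flight times, never any t_E result.

## Synthetic-data generator

`plumetrace.plume` draws per-shot ensembles of (t_E, v0) pairs:

| parameter | default | why |
| --- | --- | --- |
| monomer t_E | N(46 ns, 11 ns), truncated at 0 | the reported distribution parameters |
| dimer t_E | N(64 ns, 12 ns), truncated at 0 | the reported distribution parameters |
| v0 | N(500 m/s, 150 m/s), truncated at 0 | 500 m/s is the literature mean; the spread is not reported, 150 m/s is a documented tunable |
| ions per shot | 5000 per species | smooth profiles at interactive run times |
| shots per spectrum | 20 | matches ~20-shot signal averaging |
| dissociation probability | 1.0 | probe fluence is ~15x the MALDI fluence; depletion looks saturated |
| probe slab | sharp 1-mm top-hat | the probe is a 1-mm slit; beam softness unmodelled |
| probe jitter | off (optional gaussian, sd 1 ns) | negligible against 50-ns delay steps |
| fragment masses | 27, 39, 51, 63, 77 u | generic CnHm+ series; cosmetic, excluded from inference |

Truncation redraws negative values rather than clipping, so the realized
distribution is the gaussian conditioned on positivity (at mean/sd ≈ 4 the
induced mean shift is < 0.1%).  A lognormal t_E shape is available for
sensitivity studies.

Shot noise is per-bin Poisson on each shot's integer histogram, then
averaged over shots.  With fragments on, every dissociated parent is
re-rendered as one low-mass fragment ion (inheriting the parent's velocity
at the dissociation point and accelerated over the remaining gap), so total
ion counts are conserved exactly at zero noise.

What the generator does *not* emulate: radial expansion and the consequent
(Δt-dependent) overlap of the plume with the probe sheet's 7-mm width;
detector response and electronic baselines; chemical noise; matrix
photochemistry (removal is a Bernoulli event, not a kinetic model);
correlations between t_E and v0.  Passing closed-loop tests therefore
demonstrate the *inverse pipeline's* correctness under the stated
statistical model, not the realism of that model for any particular
instrument.

A consequence of the reported widths worth noting: with t_E spreads of
11–12 ns, the packet's spatial sd at Δt ≈ 150 ns is only ~0.2 mm, so a
1-mm slab at a centre hit removes most of the packet rather than roughly a
third of it as in the original observations (whose packets were broadened
by mechanisms outside this model, plausibly the wide velocity spread).
The depletion-window sequences, their species ordering and the recovered
t_E statistics are insensitive to this difference; the remnant-area
z-correction has less signal to work with than in the real experiment but
still beats the slab-midpoint assignment in closed loop.

## Inverse pipeline

1. **Differencing.** Per-bin fractional depletion d_i = max(0, (b_i −
   p_i)/b_i) inside a species' peak window, computed only where the
   baseline exceeds 1% of the window maximum (bins below that floor are
   set to zero — this avoids 0/0 at the tails).  Peak windows come from
   flight-time bounds over t_E ∈ [0, 250] ns, v0 ∈ [0, 1500] m/s; the
   CHCA species are far apart in TOF, so windows never overlap.
2. **Segment.** The contiguous run with d ≥ 0.15 spanning ≥ 3 bins whose
   integrated depletion is maximal (ties to the earliest run).
3. **Centre hit.** The segment's depletion-weighted centroid must lie
   within 0.5 x FWHM of the baseline peak centroid.  Half a FWHM encodes
   "the packet centre lies somewhere inside the probed slab": the slab's
   TOF image (~50 ns) is about twice the peak FWHM (~28 ns) at the default
   packet widths, so demanding a much smaller offset would only accept
   slabs whose midpoint happens to coincide with the packet centre on the
   coarse 50-ns delay grid and would discard most usable cells.  The
   tolerance is configurable (`analysis.center_tolerance`).
4. **z-correction.** With A_f the remnant area at earlier TOF than the
   segment (ions spatially ahead — in a linear TOF, ions ahead in space
   arrive earlier) and A_b the later remnant area, the packet centre is
   placed at z_low + w·A_f/(A_f + A_b).  This linear area-ratio rule is one
   defensible reading of "weight by the forward/backward remnants"; its
   error is bounded by the slab width, and in closed loop it reduces the
   distance to the true centre relative to the slab midpoint in most
   centre-hit cells.  If the probe removed the entire peak (no remnant on
   either side) the slab midpoint is used, since no correction information
   exists.
5. **Inversion and aggregation.** Each point inverts under v0 = 500 m/s
   (fixed for inference regardless of the simulator's v0 spread — the same
   assumption the measurement analysis makes; `sweep-v0` quantifies the
   sensitivity, a few ns over 0–1000 m/s).  Points with t_E < 0 are
   *unphysical* (z unreachable even at t_E = 0): they are flagged and
   excluded from moments but never silently dropped.  Means are unweighted;
   sd is the sample standard deviation (ddof = 1); histograms use 10-ns
   bins aligned at zero.  A global single-t_E propagation curve is fit by
   bounded scalar least squares over t_E ∈ [0, min Δt].

## Numerical choices

- The inversion discriminant v0² + 2az is strictly positive for z > 0, so
  the positive root always exists; no iteration is involved anywhere in the
  kinematics.
- Negative v0 values are tolerated by `propagate_distance` only while the
  trajectory stays non-negative; re-entering trajectories raise a domain
  error.
- Spectra are uniform histograms (10-ns bins by default) spanning all
  plausible arrivals including fragments; arrivals outside the range are an
  error that lists the offending times rather than silent clipping.
- Segment tie-breaks: larger integrated depletion wins, then the earlier
  run.  FWHM uses linear interpolation of the half-maximum crossings.
- Reproducibility: every stochastic stage takes a seed; scenario generation
  derives per-cell seeds from the grid seed via `numpy` seed sequences, so
  archives regenerate bitwise and cells are independent.

## Closed-loop validation and problem sizes

`recovery_experiment` regenerates the full measurement design (3 voltages x
4 slabs x 11 delays, one baseline per voltage), scans it and estimates
t_E, reporting bias and per-point rmse against the generator truth.  At the
default conditions this recovers 46 ± 10 ns (monomer, n = 7 centre-hit
points) and 64 ± 15 ns (dimer, n = 10), bias well under 10 ns, with the
monomer-before-dimer ordering stable across seeds.  The test suite runs the
loop at full scale over 20 seeds for the recovery criteria and at reduced
ion counts (800–2000 ions/shot, fewer shots) for unit-level checks, sizes
chosen to keep the whole suite interactive while leaving the statistical
conclusions unchanged.

In the delta-distribution limit (zero t_E/v0 spread, fine delay grid) the
probe removes the entire single-bin peak, the midpoint fallback applies,
and the residual bias equals the concavity of τ(z) across the slab (~2 ns)
— reproduced exactly by a closed-form prediction in the tests.

## Known limitations

- The t_E/v0 spreads jointly set the packet width; only their combined
  effect is observable, and the generator's defaults adopt the reported
  t_E parameters while treating the v0 spread as a free tunable.
- Whether per-point inversion should use the delay at which the centre hit
  was recorded or a sub-grid interpolated delay is undecidable from a
  50-ns grid; the pipeline uses the recorded delay (interpolation would
  require assuming the very trajectory being measured).
- The centre-hit delay quantization (50 ns) and slab width (1 mm) dominate
  the per-point scatter; the recovered histogram width (~30–40 ns span)
  reflects both the true t_E spread and this quantization, and the two are
  not separated.
- Multiple species are rendered into one merged spectrum, but peak windows
  are computed per species; strongly overlapping species would require
  deconvolution, which is out of scope.
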