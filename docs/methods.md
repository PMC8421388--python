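# Methods

## The readout and its model

A death indicator with dissociation constant far above physiological
cytosolic Ca²⁺ behaves, at equilibrium, as a switch: the Hill occupancy
`ca^n / (Kd^n + ca^n)` is near zero through activity transients (~0.1–1 µM)
and approaches one when membrane integrity fails and cytosolic Ca²⁺ rises
toward organellar/extracellular levels (~0.1–2 mM). The `sensors` module
implements exactly this equilibrium model — fluorescence is affine in
occupancy between `f_min` and `f_max` — and nothing more: binding kinetics,
pH sensitivity, and spectral properties are out of scope. Because published
Kd/Hill values vary by construct and calibration method, the module ships no
literature constants; sensor parameters are configuration inputs
(`examples/sensors.yaml` carries clearly-marked placeholders).

ΔF/F₀ uses the mean over an explicit baseline index window as F₀ (default:
all samples before the first stimulus). The stimulation:death response
ratio `max ΔF/F₀(stim) / max ΔF/F₀(death)` is reported unclamped — a
stimulation window that dips below baseline legitimately yields a negative
ratio, and clamping would hide it.

## Death calling

The GEDI ratio of a segmented soma is `mean_gedi / mean_morph` on
median-background-subtracted images. The death threshold is the quarter
point between calibration means,

    threshold = mean_live + w · (mean_dead − mean_live),  w = 0.25,

with `w` overridable in configuration; the weight is treated as a fixed
convention, not derived. The threshold is affine in the two means, hence
equivariant under rescaling or shifting of all ratios. Classification is
strict (`ratio > threshold` is dead): a ratio exactly at the threshold is
live. Calibration populations default to every object at the pre-treatment
timepoint (live) and every object in designated lethal-treatment
positive-control wells (dead); when neither is configured, the pooled ratio
distribution — strongly bimodal by construction — is split at Otsu's
threshold and the two sides supply the means. Thresholds are recalibrated
per experiment rather than reused: expression levels shift the band centers
between plates even though the separation persists.

Death time is the earlier of the first strict threshold crossing and track
loss; track loss is dated at the first *missing* timepoint (where the loss
is observed), not the last sighting — interval-censoring refinements are
deliberately out of scope. Tracks whose ratio exceeds the threshold and
later falls below it ("reversals") are flagged and excluded from survival
analysis by default: with an irreversible commitment to death, a reversal
can only be a segmentation or tracking artifact, and silently re-classifying
it would bias either call.

## Image processing

Background is the per-image median (a sparse fluorescence image is mostly
background); negatives after subtraction clamp to zero so intensity ratios
stay non-negative. Stitching places tiles on the declared grid and averages
overlap strips. Registration is translation-only phase correlation against
the first frame, with shifts clamped at a configurable cap (default 25 px)
and zero-variance frames registered as zero-shift with a warning.

Segmentation targets the bright soma, not the neurites: Gaussian smooth
(σ = 1 px), threshold at `max(0.5 · Otsu, median + 8·1.4826·MAD)`,
8-connected components, size filter at 100 px. The half-Otsu cut keeps the
dim skirt of fading post-death debris above the fixed size floor, while the
robust MAD floor makes noise-only frames yield no objects (plain Otsu would
bisect the noise). Components above a 1200 px cap are re-cut to pixels above
the 0.75 intensity quantile of the component — a neurite-merged blob
collapses back to its somatic core. The whole operator is a parameter block
(`SegmentationParams`) and can be swapped out.

Tracking links frames by minimum-total-distance bipartite assignment
(`scipy.optimize.linear_sum_assignment`) gated at `max_link_dist`
(default 20 px, ≈2× soma diameter). A gated optimal assignment was chosen
over greedy nearest-neighbour because greedy linking lets one object steal
its neighbour's match (total distance 11 vs 3.5 in a two-object
counterexample), and the optimal assignment is auditable against exhaustive
enumeration on small scenes — the test suite does exactly that. No gap
closing by default: a missed detection terminates the track, consistent
with treating segmentation-label loss as a death observation; a one-frame
gap tolerance exists for sensitivity analysis.

## Survival statistics

Kaplan–Meier and Nelson–Aalen estimators are computed directly from their
product-limit / cumulative-sum definitions. Cumulative risk-of-death is
reported both as 1 − S(t) and as the Nelson–Aalen cumulative hazard, since
"risk of death over time" is printed either way in the literature; group
contrasts come from the Cox model regardless.

The Cox fit maximises the Efron-tie partial likelihood by Newton iteration
with step halving, with Wald SEs from the inverse observed information and
95% CIs `exp(β ± 1.96·SE)`. Efron (not Breslow) because 12–24 h imaging
intervals put many deaths on the same grid point, and Breslow's bias grows
with tie mass. The implementation is authored in this package and is
cross-checked against lifelines to 4 decimals on tied fixtures in the test
suite; convergence is declared at a partial-log-likelihood change < 1e-10
and gradient sup-norm < 1e-6. Complete separation or an event-free group
raises rather than returning a divergent estimate. Per-neuron records are
treated as independent by default (matching common practice for these
experiments); an optional well-cluster bootstrap resamples wells with
replacement and replaces the Wald SE/CI/p with bootstrap ones when
within-well correlation is a concern.

Decay kinetics: OLS of log₂ intensity on time, so slope = −1/t½ directly;
non-positive samples are dropped with a warning and fewer than three
remaining samples is an error; a flat trace reports t½ = ∞. Rise kinetics:
flat baseline followed by one-phase association
`F₀ + (plateau − F₀)(1 − e^{−(t−t₀)/τ})`, fitted by least squares with a
multi-start grid over the onset t₀ (the discontinuous parameter), keeping
the best residual; traces with no appreciable rise are returned flagged
unidentifiable instead of fitting noise. Standard two-sample comparisons
(Mann–Whitney by default) delegate to scipy.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, at
defaults fixed once:

- 4 wells × 125 neurons on 600×600 px frames (42 px minimum spacing —
  sized so the placement grid has capacity), imaged every 24 h for 168 h;
- somata as Gaussian blobs (σ = 3 px, peak ≈ 4000 on a 16-bit scale,
  ±10% lognormal brightness), faint neurite strokes, background 100 with
  Gaussian noise σ = 8, global per-frame stage jitter σ = 1.5 px;
- death times exponential (Weibull optional) with per-well hazards —
  defaults 0.010/h control vs 0.020/h disease (HR 2); positive-control
  wells kill every neuron at t = 0;
- GEDI ratio bands 0.01 (live) and 0.5 (dead) with 5% lognormal spread —
  placeholder centers, as real band positions depend on construct and
  expression; the pipeline only needs the separation;
- after death both channels decay exponentially with near-equal half-lives
  (20.45 h / 20.73 h); an object disappears when its peak falls below
  2×noise σ; optional fragmentation splits dead somata into 2–4 sub-blobs
  (off by default to keep segmentation tests interpretable).

Identical config + seed reproduces images and truth bit-for-bit (per-well
RNG streams are derived from the plate seed and a CRC of the well name).

What the generator does **not** emulate: photobleaching, realistic PSFs,
3D stacks, uneven illumination, debris scavenging, neurite-overlap
segmentation ambiguity, or expression-level drift over days. Passing
end-to-end tests therefore demonstrates that the pipeline's logic is
correct under its own assumptions — not that those assumptions hold for any
particular microscope or culture.

## Temporal discretization and recovered hazard ratios

An imaging experiment observes death only on its sampling grid. Snapping
continuous event times to a 24 h grid concentrates large fractions of the
risk set on identical times, and the Efron partial likelihood — like any
tie approximation — attenuates the estimate: a continuous-time HR of 2.0
becomes ≈1.5 for *any* observer of the gridded experiment, including a
perfect one reading the generator's own truth table. End-to-end accuracy is
therefore judged at matched resolution: the pipeline's fitted HR is
compared against a Cox fit of the ground-truth death times snapped to the
same imaging grid (in the tests, the two agree call-for-call). Cohorts
generated directly with continuous lifetimes (no imaging grid) recover
their generator hazard ratios without this attenuation.

## Problem sizes

Test and script problem sizes are the package's own choices: decay-bias
checks use 500 replicates of 33-point traces; coverage checks use 200
cohorts of 500 per group; the end-to-end check uses the default 500-neuron
plate. These sizes put Monte-Carlo noise well below the tolerances being
asserted while keeping a full run in the low minutes on one core.

## Known limitations

- Track identity is centroid-only; appearance models and division handling
  are out of scope, so dense cultures (spacing ≲ 2×link distance) will
  produce identity switches the artifact filter may not catch.
- The threshold model assumes unimodal live and dead ratio populations; a
  plate mixing constructs with very different band centers needs per-group
  calibration.
- The Cox implementation covers categorical group contrasts (the package's
  use case), not arbitrary covariate matrices with time-varying terms,
  stratification, or time-varying terms; robust SEs are available only as
  the cluster bootstrap.
- Death dating is right-continuous on the imaging grid; genuinely
  interval-censored likelihoods are not implemented.
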