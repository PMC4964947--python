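# Methods

## Model

Mitoses in a fixed field of view are modelled as a nonhomogeneous
Poisson process (NHPP).  With `N₀` cells at `t = 0` and per-capita
division rate `γ` (h⁻¹), the expected cell number is
`N(t) = N₀ e^{γt}`, the event rate is `λ(t) = γ N₀ e^{γt}` and the
cumulative intensity `M(t) = N₀(e^{γt} − 1)`.  This is the Gompertz
form: the conditional event probability doubles every `ln 2/γ` hours.
Assumptions: cell death is negligible relative to growth; events are
independent given the rate (no synchronization, unless modelled
explicitly below); `N₀` is supplied by the user from the first frame.

Because `λ(t)` varies over ~24 h while interevent gaps last minutes to
hours, gaps anywhere in a measurement period `t′` are treated as
exponential with the period-averaged rate `Λ = M(t′)/t′`
(`P(Δt > τ) = e^{−Λτ}`).  In the homogeneous limit `γt′ → 0` this
reduces exactly to the constant-rate law with `λ = γN₀`; `expm1`/`log1p`
are used throughout so that limit is numerically exact.  The averaged-
rate relation inverts in closed form,

    γ = ln(1 + Λ t′ / N₀) / t′,

which is used directly (no root search is needed; the relation is
monotone in γ so the closed form is the unique solution).

The intermitotic (doubling) time is `t_IMT = ln 2 / γ`.  `Λ` and `λ`
are field-level rates (events per hour for all `N₀` cells); all times
are hours.

## Simulator

Event times are sampled exactly by time rescaling: the event count is
Poisson with mean `M(t′)` and, conditional on the count, the rescaled
variables `M(tᵢ)` are uniform order statistics on `[0, M(t′)]`, so
sorted uniforms are mapped through the closed-form inverse
`t = ln(1 + m/N₀)/γ`.  No thinning or rejection is involved, so the
sampled law is exact at any rate.

Synchronization windows `(start, end, f)` are applied by independent
binomial thinning: each event in the window is kept with probability
`f` (the fraction still dividing at random; `1 − f` is the synchronized
fraction).  The thinned process is an NHPP with intensity `f(t)λ(t)`.
Note the thinning does not feed back into the subsequent rate — the
model's expected accumulated curve makes the matching assumption (full-
rate accrual resumes after the window), so simulator and fit are
consistent with each other.

Positions are uniform over the field (default 640 × 540 px), with
rejection resampling outside an optional circular void emulating the
cell-free area of a scratch-wound assay.  Frame-interval censoring maps
each event to frame `⌊t/Δ⌋` (Δ = 0.25 h by default): consecutive events
in frames `i < j` yield a resolved gap `(j − i)Δ`; co-frame events
yield gaps known only to be "below one frame".

All samplers take explicit integer seeds; a master seed is split into
independent per-stage streams via `numpy.random.SeedSequence`.

## Rate estimation

Two likelihoods are implemented for `Λ` from censored gaps.

**Interval likelihood** (`method="interval"`): resolved gaps contribute
the exponential density `Λe^{−ΛΔt}`, unresolved gaps the mass
`1 − e^{−ΛΔ}`.  With no censored gaps the MLE is exactly `1/mean(gaps)`.
This is the correct likelihood when short gaps are censored *because
they are short* (true interval censoring at Δ).

**Frame likelihood** (`method="frame"`, the default for growth fits):
when gaps are produced by *reading frames*, censoring is by frame
sharing, not by gap length — a 10-min gap that straddles a frame
boundary is recorded as a resolved 15-min gap.  At the reference
conditions (Λ ≈ 4.5 /h, Δ = 15 min) the mean gap (~13.5 min) is shorter
than the frame interval, roughly 40% of gaps are co-frame, and the
interval likelihood is materially inconsistent (≈ −16% bias in Λ,
≈ +10% in t_IMT, verified by simulation).  For a Poisson stream of rate
`Λ` read at interval Δ the frame difference `k` of consecutive events
has the exact law

    P(k = j) = e^{−μ(j−1)} (1 − e^{−μ})² / μ ,  j ≥ 1
    P(k = 0) = 1 − (1 − e^{−μ}) / μ ,           μ = ΛΔ

and maximizing this likelihood recovers Λ without bias (≈ 2.8% median
t_IMT error at the reference conditions, dominated by sampling noise).
Both MLEs are computed by safeguarded bisection on the (monotone) score,
vectorized across bootstrap resamples; the search bracket is
`Λ ∈ [10⁻⁹, 10⁴]` h⁻¹ (`μ ∈ [10⁻⁹, 60]`), halved 80 times, i.e.
converged far below any statistical precision.

**Uncertainty**: 95% confidence intervals for `t_IMT` are percentile
bootstrap over the pooled gap set (resolved frame-differences plus
censored markers), 1000 resamples by default, seeded.
`bootstrap_reps=0` collapses the interval onto the point estimate.

**Goodness of fit**: the sup distance between the empirical survival of
frame-snapped gaps and the model-implied snapped-gap survival
`P(k > j) = (1 − e^{−μ})e^{−μj}/μ`, comparable to a one-sample KS
distance on the gap sample size.

Degenerate inputs: an all-censored gap set (every event in one frame)
leaves Λ unidentifiable and raises an error; fewer than five resolved
gaps triggers a warning.

## Synchronization fit

The growth model for a synchronization analysis comes from an
unsynchronized reference phase (e.g. the initial exponential phase),
refitted with the frame likelihood.  For each candidate window the
primary estimate of the active fraction is the count ratio

    f̂ = (observed events in window) / (M(end) − M(start)),

clipped to [0, 1] — this is the per-window Poisson MLE and is unbiased
with variance `f/(expected count)`.  A joint least-squares fit of all
fractions against the accumulated-event curve on the frame grid is also
reported (`fractions_curve`) for parity with curve-overlay figures, but
it is not the primary estimate: the cumulative Poisson noise accrued
after a window is of the same order as a short window's own expected
count, which makes the curve fit noisy and, through the [0, 1] clipping,
biased for small fractions (verified by simulation: true 0.15 recovered
at 0.205 ± 0.215 by the curve fit vs 0.149 ± 0.066 by the ratio).

Recovering the fraction requires a usable reference γ.  With ~65 cells
and a short reference phase (e.g. 0–10 h, ~20 events) the reference-fit
noise is amplified about 40-fold into the window's expected count and
the fraction becomes statistically unidentifiable at single-field
scale; the recovery guarantees therefore hold for a correctly fitted
growth model, and the pipeline with a refitted reference is exercised
only where the reference phase contains enough events.

## Spatial analysis

Event counts are accumulated in `n` equal radius steps up to the
largest circle fully inside the field around a user-chosen centre.
Capping at the inscribed circle keeps the CSR expectation exactly
linear in area (no circle–rectangle intersection corrections), matching
the straight reference line `density × area`.  Under CSR the squared
distance of an event from the centre is uniform on `[0, r_max²]`, so
the departure statistic is

    D = max over radii |counts(r)/counts(r_max) − r²/r_max²| ∈ [0, 1],

a KS-type quantity: compare with `1.628/√n` for an α = 0.01 test.  A
central void of radius `r_max/2` produces a deterministic deficit of
0.25 at the half radius, so `D ≥ 0.2` whenever the void is truly empty.
Position units (px or µm) are metadata carried on the series; any
µm-per-pixel conversion must be supplied explicitly.

## Imaging

Detection pipeline per frame: invert intensities (mitotic cells are
dark and become the bright foreground; inversion also makes every
downstream step invariant to additive intensity shifts), Gaussian
smooth (σ = 2 px), global threshold, fill holes, label 8-connected
components, keep components with area in [20, 600] px² and circularity
`4πA/P² ≥ 0.8`.  The perimeter `P` is the 4-direction Crofton estimator
— fixed and documented because discrete perimeters are ambiguous; it
scores digital discs ≈ 1.0 and a 1-px line ≈ 0.17, whereas the classic
weighted boundary estimator scores thin lines ≈ 0.8 and cannot separate
elongated cells from round ones.  Components of ≤ 2 px score 1 by
convention.

The default threshold is a three-class Otsu on the inverted smoothed
frame, keeping the class darkest in the original image
(background | adherent carpet | mitotic cells).  A two-class Otsu is
retained as an option but fails a characteristic way on frames that
happen to contain no mitotic cell: the threshold falls to the
background/adherent split and the carpet floods the mask.  A manual
threshold override is available.

Detections are chained across frames by greedy nearest-neighbour
linking (radius 10 px, maximum frame gap 1): one mitosis visible in
several consecutive frames becomes one event, timed at its first frame
and placed at its first centroid.  Event scoring against ground truth
is one-to-one greedy spatiotemporal matching (5 px, 1 frame by
default); recall = matched/truth, precision = matched/detected, with
precision defined as 1 (with a warning) when nothing was detected.

The synthetic generator renders: uniform background (0.55), Gaussian
pixel noise (σ = 0.02), a static carpet of elongated adherent cells
(semi-axes ~20 × 5 px, drawn at a fixed level 0.05 below background so
overlaps do not darken additively), and dark discs (radius 4–8 px,
0.35 below background) at simulated event positions, each visible for 2
consecutive frames.  It emulates the features the detector keys on —
contrast, compactness, persistence — and *not* real bright-field optics
(no shading, debris, focus drift, halo rings, chromosome texture, cell
crowding or migration).  Passing detection scores on these stacks
validate the pipeline's logic, not its cut-offs on any particular
microscope; on real data the size/circularity bounds and threshold
choice must be tuned to the instrument.

## Problem sizes and tolerances used in the tests

The pipeline-level suite runs at the reference conditions (N₀ = 65,
γ = 0.033 h⁻¹, t′ = 40 h, Δ = 15 min): 2000 simulator replicates for
the count law (mean within 2%, Fano factor in [0.9, 1.1]), 500
fit replicates (median t_IMT error ≤ 5%, bootstrap CI coverage in
[90%, 98%]), 200 replicates per synchronization scenario (mean
recovered fraction within 0.05), 1000 seeds for the homogeneous-limit
KS check — run at N₀ = 4000, γ = 2.5 × 10⁻⁴ h⁻¹ so that γt′ = 0.01
still yields ~40 events per series (at N₀ = 65 that limit would leave
under one event per field) — and three 80-frame 640 × 540 stacks for
detection (pooled recall and precision ≥ 0.95).  The closed-form/
quadrature agreement is checked to 10⁻⁹ relative error on 1000 random
parameter triples.

## Known limitations

- The averaged-rate exponential approximation for gaps degrades when
  γt′ is large (rate no longer "slowly varying" across a gap); at the
  reference γt′ ≈ 1.3 the residual bias is within sampling noise.
- Thinning-based synchronization has no demographic feedback: a
  synchronized window does not reduce the later cell count.
- The detector is validated only against the synthetic generator (see
  above); linking assumes mitoses are sparse enough that nearest-
  neighbour chaining within 10 px is unambiguous.
- Weibull/power-law rate laws and overdispersed (compound Poisson /
  negative binomial) variants are out of scope, as are cell-death
  terms and per-cell lineage tracking.
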