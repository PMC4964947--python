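# mitopoisson

Poisson time-series analysis of mitotic events in time-lapse microscopy.

Proliferation of an adherent cell culture can be quantified without
tracking any individual cell: it is enough to record the *division
events* — the moments when cells round up, detach and split — visible in
ordinary bright-field frames.  For a field of view holding `N₀` cells at
time zero and growing exponentially at rate `γ` (per hour), the mitoses
form a nonhomogeneous Poisson process (NHPP) with rate

    λ(t) = γ N₀ e^{γt}          (events per hour, whole field)

and cumulative intensity `M(t) = N₀ (e^{γt} − 1)`.  Averaged over a
measurement period `t′` the rate is `Λ = M(t′)/t′`, and interevent gaps
are approximately exponential, `P(Δt > τ) = e^{−Λτ}`, because λ varies
over ~24 h while gaps last only a few hours.  Fitting Λ from the
observed gap distribution and inverting `Λ = (N₀/t′)(e^{γt′} − 1)` gives
the growth rate and hence the intermitotic (population doubling) time

    t_IMT = ln 2 / γ.

The package provides:

- **`model`** — the closed-form NHPP mathematics (rates, cumulative
  intensity, averaged rate, interevent survival, inversions, and
  expected accumulated-event curves under partial synchronization).
- **`simulate`** — an exact NHPP event simulator (time-rescaling
  inversion), frame-interval censoring, synchronization thinning, and
  uniform spatial placement with an optional scratch-like void.
- **`fit`** — statsmodels-style `ProliferationModel` / `SynchronizationModel`
  whose `fit()` returns results objects with estimates, 95% bootstrap
  confidence intervals, goodness of fit, `summary()` tables and plots.
  Gap censoring at the frame interval (events sharing a 15-min frame are
  known only as `Δt < 15 min`) is handled by maximum likelihood.
- **`spatial`** — accumulation of events in circles of increasing area
  around a chosen centre, with a complete-spatial-randomness reference
  and a KS-type deviation statistic (scratch-wound analysis).
- **`imaging`** — bright-field mitotic-cell detection (inversion,
  smoothing, global thresholding, size/circularity masking, cross-frame
  linking) plus a synthetic frame generator with ground truth.
- **`mitopoisson`** CLI — `simulate`, `fit`, `sync-fit`, `spatial`,
  `detect`, `synth-images`, `report`.

## Worked example

Simulate a 65-cell field growing at γ = 0.033 /h (t_IMT ≈ 21 h),
observed for 40 h at 15-min frames, then fit it back:

```sh
$ mitopoisson simulate --n0 65 --gamma 0.033 --horizon 40 --seed 7 -o events.csv
wrote 180 events to events.csv

$ mitopoisson fit events.csv --n0 65 --seed 1
NHPP proliferation fit
==============================================
events observed                            180
gaps censored (< 1 frame)                   77
horizon t` (h)                           40.00
frame interval (h)                        0.25
initial cells N0                          65.0
----------------------------------------------
Lambda (events/h)                        4.487
gamma (1/h)                            0.03312
t_IMT (h)                                20.93
95% CI for t_IMT (h)            [18.93, 22.89]
survival GOF (sup dist)                  0.031
==============================================
```

180 events were observed against an expectation of
`M(40) = 65(e^{0.033·40} − 1) ≈ 178`; 77 interevent gaps fell inside a
single 15-min frame and enter the fit as censored.  The fitted period-
averaged rate Λ = 4.49 events/h yields γ̂ = 0.0331 /h, i.e. an
intermitotic time of 20.9 h with 95% CI [18.9, 22.9] — bracketing the
true 21.0 h.  The goodness-of-fit value is the sup distance between the
empirical and fitted interevent survival curves (small = consistent with
an NHPP, i.e. no synchronization).

The same analysis from Python:

```python
from mitopoisson import GrowthModel, simulate_series, ProliferationModel

series = simulate_series(GrowthModel(n0=65, gamma=0.033), horizon=40, seed=7)
res = ProliferationModel(series, n0=65).fit(seed=1)
print(res.summary())
res.plot_survival(); res.plot_accumulated()
```

Partial cell-cycle synchronization — a time window in which only a
fraction `f` of the population keeps dividing at random — is simulated
by thinning and quantified per window with
`SynchronizationModel(series, n0, windows=[(18, 32)]).fit()`; the
scratch-wound spatial analysis (`mitopoisson spatial`) reports how event
counts grow with circular area around a centre and a CSR deviation
statistic that flags the event-free scratch region.

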