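# Methods

## Scope

`stbrproc` covers the quantitative backbone of short-interval, matrix-free
hPSC suspension expansion in perfused stirred-tank bioreactors: interval
kinetics from daily sampling, seed-train/cryopreservation arithmetic,
aggregate sizing, and a synthetic-data generator that provides ground
truth for all of it. It does not model pH/DO/osmolality control loops,
glutamine/ammonia metabolism, hardware, or any of the biology downstream
of cell counts (expression profiling, flow cytometry, differentiation).

## Interval kinetics

All estimators are two-point formulas between consecutive samples
(t₀, t₁); no smoothing or regression is applied, so every reported value
is attributable to exactly two measurements.

The log-mean X̄ = (X₁ − X₀)/(ln X₁ − ln X₀) is the exact time-average of
X(t) when growth is exponential over the interval, which makes the batch
estimators *exact* under the model's own assumptions: if X(t) = X₀e^{µt}
and dGlc/dt = −q·X with constant q, then ΔGlc/Δt = −q·X̄ identically, and
µ = (ΔX/Δt)/X̄ reduces algebraically to ln(X₁/X₀)/Δt. The test suite
asserts both properties (to 10⁻⁶ and 10⁻¹² relative, respectively) on
independently integrated trajectories.

Under perfusion the estimators add the dilution-rate term, using the
log-mean of the *metabolite* endpoints as a stand-in for its within-
interval time-average. That is an approximation: residual concentration is
not exponential in time, growth may deviate from exponential (the late-
passage µ decline), and the dilution rate is piecewise-constant within a
daily interval. At the generator's default operating point the combined
error is ≤ 2.7% per interval for qGlc/qLac and ≤ 5% for Y (dominated by
the [d3, d4] interval, where µ declines).

Numerical/edge choices:

- **Log-mean fallback.** Fresh medium has ≈0 mM lactate, so the log-mean
  of the first interval's lactate endpoints is undefined. When either
  endpoint is ≤ 10⁻⁹ mM the arithmetic mean is used and flagged
  (`fallback_used`, `fallback_flags`). Equal positive endpoints are the
  continuous limit (value = endpoint), not a fallback. Two nonpositive
  endpoints raise a domain error from `log_mean` itself; the perfusion
  lactate estimator treats the both-zero case as a zero exchange term so
  a passage starting and staying at 0 mM remains computable.
- **Sign convention.** qGlc is positive for net consumption, qLac for net
  production. Rates with the unexpected sign (possible under measurement
  noise) are returned as-is with a warning flag, never clamped.
- **Units.** Storage uses cells/mL and mM; the cells/L and pmol/L
  conversions demanded by the rate formulas (×10³, ×10⁹ — a net factor of
  10⁶) are applied inside the estimators only.
- **Regime bookkeeping.** An interval overlapping any positive-rate
  schedule segment uses the perfusion formulas with the time-weighted mean
  F over the interval (gaps count as 0). Segments with different feed
  glucose inside one interval are rejected with a request to align sample
  times to schedule breakpoints, because a single Glc_f is not defined for
  the interval.

## Seed trains and cryopreservation

Per-passage fold is harvest density over inoculation density. The
"average" per-passage fold of a campaign reported only as a cumulative
fold over n passages is taken as the **geometric mean** (n-th root): it is
the unique per-passage rate that compounds to the observed total, and it
reproduces the published combined-schedule (≈2880-fold) and scale-up
(2.72×10¹¹ cells) figures exactly, which arithmetic averaging of
per-passage densities does not.

`plan_seed_train` projects stage by stage (inoculum = volume × density,
harvest = inoculum × fold) and flags infeasibility (harvest < next
inoculum) in the result instead of raising, so planners can search over
plans. `apply_cryo` scales the first post-thaw passage's fold by the d1
recovery (survivors grow at the unadjusted fold), divides the inoculum by
the post-thaw recovery to get the frozen-cell requirement, and counts
1 mL vials by ceiling at the chosen cryopreservation cell density (CPD),
reporting the surplus.

Post-thaw recovery is implemented as viable-cells-out / cells-frozen —
the direction consistent with the reported 80–100% range (necrosis
losses); day-1 recovery is viable density at 24 h over the target
inoculation density (anoikis losses).

## The synthetic-data generator

The simulator integrates the same mass balances the estimators invert,
so recovered parameters can be compared to known truth:

    dX/dt   = µ(t)·X
    dGlc/dt = −qGlc·X + (F/V)(Glc_f − Glc)
    dLac/dt =  qLac·X − (F/V)·Lac

µ(t) is piecewise: **(1)** an aggregation lag (default: µ = 0 for
t < 1 d). Measured glucose drops from ≈17 to ≈10 mM during d0–d1 at
near-constant viable density, and day-1 "recovery" is a standing concept
even without cryopreservation — both say net growth in the first 24 h is
negligible while single cells re-aggregate. Without the lag, growing at
µ_max from t = 0 would overshoot observed day-4 densities threefold.
**(2)** µ_max (default 1.0 d⁻¹) until t_decline_start (default 3 d).
**(3)** linear decline to µ_min (default 0.76 d⁻¹) at the passage end, a
deterministic-in-time stand-in for the diffusion-limited slowdown of
large aggregates. With defaults, day-4 density is 8.9×10⁶ cells/mL
(observed multi-passage range 6.6–9.7×10⁶) and day-3 density 3.7×10⁶
(observed 3.7–5.2×10⁶).

True metabolic rates default to qGlc = 14 and qLac = 19 pmol/(cell·d),
the midpoints of the observed 9–19 and 11–25 ranges; initial glucose is
17 mM (fresh medium), initial lactate 0.

**Perfusion schedule (calibrated surrogate).** The source process's pump
schedule and feed recipe are not public. The default schedule is off
before d1, then piecewise-constant quarter-day dilution rates ramping
0.172 → 1.783 d⁻¹ with an 80 mM glucose-enriched feed. The rates were
derived once by bisection so that residual glucose follows the observed
pattern — dipping to ≈10 mM at d1 and recovering to a stable ≈16 mM
(inside the reported 14–19 mM operating band) — while the dilution rate
stays below 2 d⁻¹. The quarter-day granularity keeps within-interval
glucose excursions small, which is what keeps the endpoint-log-mean
approximation of the perfusion estimators inside 5%. Every simulated
output flags the schedule as a surrogate in `ground_truth.json`, and any
user schedule can be supplied instead.

**Post-thaw loss** is an instantaneous survival factor at t = 0⁺; with the
d0–d1 lag, the simulated day-1 recovery equals the survival parameter.

**Noise model.** Noise enters only at the daily sampling points (the dense
trajectory stays noiseless ground truth): mean-preserving multiplicative
log-normal noise on densities (CV-parameterised) and additive Gaussian
noise truncated at 0 on metabolites. Viability is cosmetic (97% baseline
with a post-thaw day-1 dip) and feeds no estimator.

**Integration.** Fixed-step classical RK4 (default 0.005 d) — no adaptive
stepping, so identical parameters and seed give bit-identical output.
Schedule breakpoints fall on step boundaries at the default step. Glucose
is floored at 0 with a recorded starvation event, never silently.
Because all cumulative audit terms are integrated with the same RK4
increments as the states, the mass balance closes to round-off whenever
no clamping occurs; the audit (tolerance 0.1%) therefore catches both
starvation-clamp distortion and any bookkeeping inconsistency. Steps
above 0.01 d are accepted for such diagnostics but are not meant for
analysis.

What the generator does *not* emulate: lactate stays realistic only while
exchange rates match the real process — under the ≤ 2 d⁻¹ dilution cap the
surrogate schedule removes less lactate than the (higher-throughput) real
process, so simulated day-4 lactate reaches ≈77 mM versus 21–26.5 mM
observed; growth is not coupled to metabolite levels (no starvation or
lactate inhibition feedback); there is no aggregate-resolved or
cell-level stochastic structure; and passage-to-passage carry-over
effects beyond the survival factor are absent. Passing recovery tests on
this generator therefore validates the estimators under their own model
assumptions, not the biology of any particular run.

## Aggregate sizing

Aggregates are treated as spheres of constant packing density whose cell
number grows exponentially after aggregation completes (day 1), giving
the cube-root law d(t) = d₁·e^{µ(t−1)/3}, anchored at a day-1 mean of
100 µm (midpoint of the observed 80–120 µm). At µ = 1.0 d⁻¹ it predicts
194.8 µm on day 3 and 271.8 µm on day 4 — consistent with the observed
day-3 ranges and below the 300 µm diffusion-limit threshold. Times before
day 1 are out of the model's domain.

Size dispersion is log-normal around the prediction (which is the
median); population means carry the e^{σ²/2} correction with
σ² = ln(1 + CV²), default CV 0.15.

The measurement pipeline is: global threshold (fixed midpoint for
synthetic fixtures, deterministic by construction; Otsu available behind
a flag for imported images), 4-connected components, exclusion of
border-touching objects (avoids truncation bias), equivalent-circle
diameter 2·√(A/π)·scale, and a 30 µm minimum-diameter debris filter
(≈3 cell diameters). It is validated by render→measure round-trips on
synthetic images (counts exact, diameters within 2% at ≥ 30 µm and
1 µm/px); it is **not** a segmenter for real brightfield micrographs with
halos, debris or touching aggregates. Rendered fixtures are dark circles
on a light background, placed by seeded rejection sampling with a
non-overlap margin.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; multi-passage runs
spawn independent per-passage RNG streams from the run seed. The CLI
embeds the seed and a config hash in every output, and a pinned seed
yields byte-identical files across invocations.

Default verification sizes — 4-day passages at 0.005 d steps, 200
replicates for the noise-robustness check, 40–60 objects per synthetic
image — were chosen as the smallest sizes at which the checked statistics
are stable; all are parameters, not constants.
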