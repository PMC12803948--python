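# Methods

## Psychometric model and estimator

The probability that a pulse at intensity `x` (%MSO) evokes an MEP above
the target amplitude is a cumulative Gaussian, `P(x) = Φ((x − t)/σ)`. Only
the threshold `t` is estimated; the spread is a fixed configuration value.
Two spread parameterizations are provided:

* **absolute** (default): `σ` in %MSO, default 3.5. This is the package
  default because it makes the likelihood exactly symmetric under mirroring
  of intensities and outcomes, which gives sharp, testable invariants.
* **relative**: `σ = s·t` with dimensionless `s` (default 0.07), the
  parameterization used in the classical sequential-testing literature.

The per-session estimate is the minimizer of the Bernoulli negative
log-likelihood over a bounded interval (default [1, 150] %MSO — the upper
bound deliberately exceeds the 100 %MSO device maximum so that
"threshold above device range" is representable before the final cap).
Two virtual anchor trials (failure at 0 %MSO, success at 100 %MSO, weight
1.0) enter the likelihood as weighted pseudo-observations rather than hard
constraints; they encode the boundary assumptions and guarantee an interior
minimum from trial 1.

Numerics: the log-probabilities are evaluated with `scipy.special.log_ndtr`
rather than `log(Φ)` so the anchor terms stay finite and smooth where `Φ`
underflows; `response_probability` additionally clips returned
probabilities to `[ε, 1−ε]` (default `ε = 1e−12`). For absolute spread the
NLL is convex in `t` (log-concavity of `Φ`), so the optimizer — a coarse
0.5 %MSO grid to bracket the minimum followed by bounded Brent refinement
(`xatol = 1e−6`) — attains the global minimum; an exhaustive grid search
(`grid_search_oracle`, ties broken toward the lower intensity) serves as
the independent cross-check and as the fallback if the scalar optimizer
ever fails (the estimate is then flagged). One-parameter bounded
minimization was chosen over a damped least-squares iteration because the
contract is the argmin itself, not a particular iteration scheme.

## Session loop

A session = 30 valid trials (configurable). The first intensity is an
integer drawn uniformly from 20–60 %MSO. After every valid trial the
threshold is re-fit on all trials so far and the next tested intensity is
the estimate rounded to the device resolution (1 %MSO) — rounding halves
away from zero, the common stimulator UI behavior, documented so tests can
be exact — and clamped to [1, 100]. No perturbation or step schedule is
added on top of the estimate. Running estimates are stored at full
precision; rounded values are derived where needed for display, and the
convergence metrics operate on the full-precision series by default (a
switch to the rounded/tested-intensity readings exists where the two
interpretations diverge).

Deliveries rejected for pre-stimulus activity are repeated at the same
intensity and recorded in `rejected_repeats`; they do not consume the
trial budget. A cap of 10 consecutive rejections per trial guarantees
termination: exceeding it returns a partial log with `truncated=True`.

The final RMT is the last running estimate rounded to device resolution
and capped at 100 %MSO, with a `capped` flag when the cap was applied.

## EMG rules

MEP amplitude = peak-to-peak (max − min) in the 15–40 ms post-stimulus
window; rejection = peak-to-peak > 0.05 mV in the [−65, 0) ms pre-stimulus
window. Millisecond endpoints are converted to sample indices (5 kHz
default) by rounding to the nearest sample; windows are closed at both
ends, except that the stimulus sample itself is excluded from the
rejection window. "Greater than the target amplitude" is read strictly:
a peak-to-peak exactly equal to the target is a failure (a measure-zero
event on real data; the rule only matters for synthetic fixtures).

## Virtual subject

The generator produces exactly the ingredients the estimator assumes, plus
the nuisance structure reliability analysis needs:

* **Response curve**: success ~ Bernoulli(Φ((x − t_true)/spread)), default
  generator spread 3.5 %MSO.
* **Amplitudes**: lognormal with shape `amp_sigma_log` (default 0.9) and
  intensity-dependent median
  `μ(x) = a_ref · exp(amp_sigma_log · (x − t_true)/spread)`, anchored at the
  reference target `a_ref = 0.05 mV`. This makes
  `P(amplitude > a_ref | x) = Φ((x − t_true)/spread)` exactly, so the
  Bernoulli path, the amplitude-threshold path and the synthetic-trace path
  are distributionally identical — no free calibration. It also induces
  the threshold for any other target in closed form:
  `t(a) = t_true + spread · ln(a/a_ref)/amp_sigma_log`; with the defaults
  the 0.2 mV target sits ≈ 5.4 %MSO above the 0.05 mV threshold.
* **Traces**: 65 ms baseline + 50 ms post-stimulus at 5 kHz; a
  Gaussian-windowed sinusoid planted in the MEP window is rescaled so its
  peak-to-peak equals the drawn amplitude exactly; optional artifact
  injection (0.12 mV p2p at −30 ms) exercises the rejection path.
* **Drift**: session threshold = t_true + day effect + session effect,
  normal with SDs `day_sd` (default 3.0 %MSO) and `session_sd` (default
  1.0 %MSO), drawn once per day / per session and cached, so sessions on
  the same day share their day effect.

Cohort thresholds default to Uniform(35, 65) %MSO. The drift SDs and
amplitude shape are simulation knobs chosen to produce within-day vs
between-day contrasts of the same character as human test–retest data
(high within-day ICC, visibly degraded between-day ICC and wider limits of
agreement); they are not estimates of any cohort. What the generator does
**not** emulate: intensity-dependent MEP variance beyond the lognormal
shape, input–output-curve saturation, facilitation/fatigue trends within a
session, coil-repositioning error structure, or serial correlation between
trials. Passing tests therefore certify the estimator and the analysis
machinery under the stated model, not the physiology of any particular
cohort.

## Metrics conventions

* Precision flag at trial k (k ≥ 3): max − min of estimates {k−2, k−1, k}
  ≤ 2 %MSO, inclusive. Flags are undefined (reported False) at trials 1–2.
* Reference value: arithmetic mean of the **tested intensities** of trials
  25–30 inclusive (six values); the running-estimate-based reference is
  available behind `use_estimates=True`.
* Accuracy flag: |estimate − reference| ≤ 0.05·reference, inclusive; the
  band is relative by default (`relative=False` switches to an absolute
  half-width in %MSO).
* Convergence trial: first index of the maximal trailing run of satisfied
  flags; None if the last flag fails. The pooled 95 % criterion trial is
  the smallest k with ≥ 95 % of sessions converged by k; never-converged
  sessions count against the proportion at every k.
* ICC(2,1) from the two-way ANOVA mean squares
  `(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`; zero total variance
  raises (undefined) rather than returning a default. `Sw = √(Σdᵢ²/2n)`,
  `RC = 1.96·√2·Sw`, `SEM = SD·√(1 − ICC)` with the between-subject SD
  computed from the per-subject means pooled across the two sessions (a
  symmetric choice among the possible readings). Bland–Altman uses the
  sample SD (n−1) of ordered differences, session 1 − session 2 within day
  and session 1 − session 3 between days.

## Study design and problem sizes

A simulated study mirrors the four-session layout: sessions 1–2 on day 1,
3–4 on day 2, the 0.05 mV target hunted before the 0.2 mV target within
each session (order randomization exists but is off by default). Every
subject and session draws from its own seed stream spawned from the master
seed, so any single cell reproduces independently and reruns are
byte-identical.

Default cohort size is 50 subjects (mirroring a typical within-day human
cohort). The test suite and the acceptance script run smaller but still
well-powered configurations chosen as desk-scale study conditions: a
30-subject study (240 sessions) for the convergence-ordering and
reliability-contrast properties, 500 independent sessions for threshold
recovery at trial 18 (|bias| ≤ 1 %MSO, MAE ≤ 2 %MSO), and 250 independent
sessions for the late-trial success-rate check (grand mean over trials
19–30 within 0.45–0.55).

## Known limitations

* The spread is fixed during a session; misspecifying it relative to the
  subject's true slope bias-broadens early estimates (the anchors dominate
  until ~trial 3) though the estimate still converges in location.
* Capped sessions (threshold above device maximum) are represented
  faithfully, but the reliability statistics treat 100 %MSO as a real
  value — the same censoring convention as the human analyses this mirrors.
* ICC confidence intervals and ICC variants other than (2,1) are out of
  scope; `pingouin` provides them if needed.
* The interactive `hunt` mode trusts the operator's success/failure entry;
  it does not re-derive outcomes from EMG in real time (trace
  classification is available for logged data).
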