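# pestmle

Adaptive maximum-likelihood threshold hunting (PEST-MLE) for the
transcranial magnetic stimulation (TMS) **resting motor threshold (RMT)**,
with a virtual-subject simulator and the full test–retest reliability
toolkit (ICC(2,1), Sw, RC, SEM, Bland–Altman, convergence criteria).

## The problem

The RMT is the minimum stimulator intensity (in % of maximum stimulator
output, %MSO) that evokes a motor evoked potential (MEP) larger than a
cutoff amplitude in more than half of trials with the muscle at rest. It is
the reference quantity for dosing almost every TMS protocol. The classical
relative-frequency estimate is slow; adaptive *threshold hunting* gets there
in far fewer pulses.

PEST-MLE models the probability of a supra-cutoff MEP at intensity `x` as a
cumulative Gaussian psychometric function

    P(success | x) = Φ((x − t) / σ)

where `t` is the threshold and `σ` the spread. After each trial the
threshold is re-estimated by maximizing the Bernoulli likelihood

    L(t) = Π_i p_i(t)^{y_i} (1 − p_i(t))^{1−y_i}

over all trials so far, augmented with two virtual *anchor* trials — an
assumed failure at 0 %MSO and an assumed success at 100 %MSO — and the next
tested intensity is the new estimate (rounded to the 1 %MSO device
resolution). A session runs a fixed budget of 30 valid trials, starting
from a random intensity in 20–60 %MSO; deliveries showing >0.05 mV
peak-to-peak EMG activity in the 65 ms before the stimulus are rejected and
repeated. The MEP amplitude is the peak-to-peak value in the 15–40 ms
post-stimulus window; trials are successes when it exceeds the target
amplitude (0.05 mV for the usual RMT, 0.2 mV for threshold-tracking
variants).

The package also implements the evaluation machinery used to validate such
estimators:

* **precision** — the last three running estimates span ≤ 2 %MSO;
* **accuracy** — the estimate lies within ±5 % of the session reference
  (the mean tested intensity over trials 25–30);
* **convergence** — the first trial of the final run of criterion-satisfying
  trials, and the pooled trial at which ≥ 95 % of sessions have converged;
* **reliability** — ICC(2,1) (two-way random effects, absolute agreement,
  single measurement), within-subject SD `Sw = √(Σdᵢ²/2n)`, reproducibility
  coefficient `RC = 1.96·√2·Sw`, standard error of measurement
  `SEM = SD·√(1 − ICC)`, Pearson r, and Bland–Altman limits of agreement
  `mean ± 1.96·SD` of paired differences.

Because no public dataset of single-trial hunting logs exists, a
generative **virtual subject** stands in for the participant: cumulative-
Gaussian response curve, right-skewed (lognormal) MEP amplitudes tied to
that curve in closed form, synthetic 5 kHz EMG traces, and normal day /
session threshold drift. This supports desk-scale replication of the whole
four-session, two-target study design (sessions 1–2 on day one, 3–4 on day
two; within-day reliability from sessions 1 vs 2, between-day from 1 vs 3).

## Worked example

```python
import numpy as np
from pestmle import (SubjectParams, VirtualSubject, SessionConfig,
                     run_session, final_rmt, ConvergenceResult)

subject = VirtualSubject(SubjectParams(true_threshold=54.0), rng=7)
config = SessionConfig(target_amplitude=0.05, rng_seed=11)
log = run_session(subject.responder(mode="bernoulli"), config,
                  np.random.default_rng(11))
```

Printing a few trials of this session:

```
trial  1: x= 25.0  outcome=failure  estimate=62.50
trial  2: x= 63.0  outcome=success  estimate=44.00
trial  3: x= 44.0  outcome=failure  estimate=53.50
trial 10: x= 54.0  outcome=success  estimate=53.38
trial 18: x= 53.0  outcome=failure  estimate=53.59
trial 30: x= 54.0  outcome=failure  estimate=54.12
final RMT: 54 %MSO (capped=False)
reference (mean intensity, trials 25-30): 54.00 %MSO
precision convergence trial: 7
accuracy convergence trial:  5
```

The first intensity is a random draw from 20–60 %MSO; the early estimates
swing while the likelihood is dominated by the anchors, then settle within a
few trials of the subject's true 54 %MSO threshold. `final_rmt` rounds the
last estimate to device resolution and caps it at 100 %MSO (sessions whose
estimate exceeds the device maximum are reported as 100 %MSO with
`capped=True`). `ConvergenceResult.from_session(log)` evaluates the
precision and accuracy criteria per trial: here the estimates are stable
(span ≤ 2 %MSO) from trial 7 on, and within ±5 % of the 54.0 %MSO reference
from trial 5 on.

A full simulated study is one call each:

```python
from pestmle import StudyConfig, simulate_study, analyze_study
report = analyze_study(simulate_study(StudyConfig(n_subjects=30, seed=1)))
report.summary()   # 95 % criterion trials, ICC/RC/SEM/LoA per comparison
```

or from the shell:

```sh
pestmle simulate --seed 1 --subjects 30 --out runs/demo
pestmle analyze --data runs/demo --out runs/demo-report
pestmle report --report-dir runs/demo-report
pestmle hunt --replay runs/demo/subject000_day1_session1_rmt0.05.csv
pestmle hunt --seed 1          # live estimator: type y/n/r after each pulse
```

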