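"""Convergence criteria and test-retest reliability statistics.

Two per-session convergence criteria mirror the standard evaluation of
adaptive threshold hunting:

* **precision** — at trial k (k >= 3), the last three running estimates span
  at most 2 %MSO (max - min <= 2, inclusive);
* **accuracy** — at trial k, the running estimate lies within +/-5 % of the
  session's reference value, defined as the mean tested intensity over
  trials 25-30 (band boundaries inclusive).

Convergence is the first trial of the *final* run of consecutive satisfied
trials extending to the end of the session; a session whose last trial fails
the criterion has not converged.

Reliability between paired sessions is summarized by ICC(2,1) (two-way
random effects, absolute agreement, single measurement), the within-subject
SD Sw = sqrt(sum d_i^2 / 2n), the reproducibility coefficient
RC = 1.96 * sqrt(2) * Sw, the standard error of measurement
SEM = SD * sqrt(1 - ICC), Pearson r, and Bland-Altman limits of agreement
mean +/- 1.96 * SD of the paired differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "ConvergenceResult",
    "BlandAltman",
    "ReliabilityReport",
    "precision_flags",
    "reference_value",
    "accuracy_flags",
    "convergence_trial",
    "criterion_trial_at_95",
    "icc_2_1",
    "within_subject_sd",
    "reproducibility_coefficient",
    "standard_error_of_measurement",
    "limits_of_agreement",
    "bland_altman",
    "per_trial_reliability",
]

PRECISION_SPAN = 2.0  # %MSO, max-min over the last three estimates
ACCURACY_TOL = 0.05  # relative half-width of the accuracy band
REFERENCE_TRIALS = (25, 30)  # 1-based inclusive trial range for the reference
ICC_CONVERGENCE = 0.80  # reliability convergence: first trial with ICC > 0.80


# ---------------------------------------------------------------------------
# convergence criteria


def precision_flags(estimates, span: float = PRECISION_SPAN) -> np.ndarray:
    """Per-trial precision flags for a series of running estimates.

    The flag at (1-based) trial k, for k >= 3, is True iff the estimates at
    trials k-2, k-1, k span at most ``span`` %MSO.  Trials 1-2, where the
    criterion is undefined, are reported False.
    """
    e = np.asarray(estimates, dtype=float)
    flags = np.zeros(e.size, dtype=bool)
    for k in range(2, e.size):
        w = e[k - 2 : k + 1]
        flags[k] = (w.max() - w.min()) <= span
    return flags


def reference_value(log_or_intensities, trial_range: tuple[int, int] = REFERENCE_TRIALS,
                    use_estimates: bool = False) -> float:
    """Session reference threshold: mean tested intensity over trials 25-30.

    Accepts a :class:`~pestmle.hunting.SessionLog` or a plain intensity
    sequence.  ``use_estimates=True`` averages the running ML estimates over
    the same trials instead of the tested intensities.
    """
    lo, hi = trial_range
    if hasattr(log_or_intensities, "intensities"):
        values = (
            np.asarray(log_or_intensities.estimates, dtype=float)
            if use_estimates
            else log_or_intensities.intensities
        )
    else:
        values = np.asarray(log_or_intensities, dtype=float)
    if values.size < hi:
        raise ValueError(f"need at least {hi} trials for the reference value")
    return float(values[lo - 1 : hi].mean())


def accuracy_flags(estimates, reference: float, tol: float = ACCURACY_TOL,
                   relative: bool = True) -> np.ndarray:
    """Per-trial accuracy flags: |estimate_k - reference| <= band (inclusive).

    The band is ``tol * reference`` by default (a 0.05 tolerance level);
    ``relative=False`` reads ``tol`` as an absolute half-width in %MSO.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    e = np.asarray(estimates, dtype=float)
    band = tol * reference if relative else tol
    return np.abs(e - reference) <= band


def convergence_trial(flags) -> int | None:
    """First (1-based) trial of the maximal trailing run of True flags.

    Returns None if the final flag is False (the session never converged for
    the remainder of the session).
    """
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        raise ValueError("flags must be nonempty")
    if not f[-1]:
        return None
    k = f.size - 1
    while k > 0 and f[k - 1]:
        k -= 1
    return k + 1


@dataclass(frozen=True)
class ConvergenceResult:
    """Precision/accuracy evaluation of a single session."""

    precision: np.ndarray
    accuracy: np.ndarray
    precision_trial: int | None
    accuracy_trial: int | None
    reference: float

    @classmethod
    def from_session(cls, log, **kwargs) -> "ConvergenceResult":
        ref = reference_value(log, use_estimates=kwargs.pop("use_estimates", False))
        est = np.asarray(log.estimates, dtype=float)
        p = precision_flags(est, **({"span": kwargs["span"]} if "span" in kwargs else {}))
        a = accuracy_flags(est, ref)
        return cls(p, a, convergence_trial(p), convergence_trial(a), ref)


def criterion_trial_at_95(
    convergence_trials, n_trials: int, level: float = 0.95
) -> tuple[int | None, np.ndarray]:
    """Pooled criterion trial: smallest k with >= ``level`` of sessions
    converged by trial k; also returns the per-trial proportion curve.

    ``convergence_trials`` is a collection of per-session convergence trial
    indices (None = never converged).  The curve is non-decreasing in k by
    construction.
    """
    ct = list(convergence_trials)
    if not ct:
        raise ValueError("need at least one session")
    n = len(ct)
    curve = np.array(
        [sum(1 for c in ct if c is not None and c <= k) / n for k in range(1, n_trials + 1)]
    )
    hits = np.nonzero(curve >= level)[0]
    return (int(hits[0]) + 1 if hits.size else None), curve


# ---------------------------------------------------------------------------
# reliability statistics


def icc_2_1(data) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``data`` is an (n subjects x k sessions) array.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Raises ``ValueError`` when the total variance is zero (undefined ICC) or
    n < 3.
    """
    m = np.asarray(data, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("data must be an (n x k) matrix with k >= 2")
    n, k = m.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if np.isnan(m).any():
        raise ValueError("ICC requires complete data (no missing cells)")
    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("ICC undefined: zero total variance")
    rows = m.mean(axis=1)
    cols = m.mean(axis=0)
    msr = k * ((rows - grand) ** 2).sum() / (n - 1)
    msc = n * ((cols - grand) ** 2).sum() / (k - 1)
    sse = ((m - rows[:, None] - cols[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def within_subject_sd(session1, session2) -> float:
    """Within-subject SD: sqrt of the sum of squared paired differences
    divided by twice the number of subjects."""
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("sessions must be equal-length 1-D arrays")
    d = a - b
    return float(np.sqrt((d**2).sum() / (2 * a.size)))


def reproducibility_coefficient(sw: float) -> float:
    """RC = 1.96 * sqrt(2) * Sw: 95 % bound on a test-retest difference."""
    if sw < 0:
        raise ValueError("Sw must be nonnegative")
    return 1.96 * math.sqrt(2.0) * sw


def standard_error_of_measurement(between_subject_sd: float, icc: float) -> float:
    """SEM = SD * sqrt(1 - ICC), the expected error of a single measurement."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [0, 1]")
    if between_subject_sd < 0:
        raise ValueError("SD must be nonnegative")
    return float(between_subject_sd * math.sqrt(1.0 - icc))


def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """Bland-Altman 95 % limits: mean +/- 1.96 * SD of the differences."""
    half = 1.96 * sd_diff
    return (mean_diff - half, mean_diff + half)


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary of paired measurements (differences = first - second)."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    def round(self, ndigits: int = 2) -> "BlandAltman":
        return BlandAltman(
            round(self.mean_diff, ndigits),
            round(self.sd_diff, ndigits),
            round(self.loa_lower, ndigits),
            round(self.loa_upper, ndigits),
            self.n,
        )


def bland_altman(session1, session2) -> BlandAltman:
    """Bland-Altman analysis of paired sessions (sample SD, n-1 denominator)."""
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = limits_of_agreement(mean, sd)
    return BlandAltman(mean, sd, lo, hi, a.size)


def _between_subject_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Between-subject SD from the per-subject means across the two sessions."""
    means = (a + b) / 2.0
    return float(means.std(ddof=1))


@dataclass
class ReliabilityReport:
    """Per-trial reliability of paired session collections.

    ``table`` has one row per trial index with columns icc, sw, rc, sem,
    pearson_r, mean_diff, sd_diff, loa_lower, loa_upper, n_pairs;
    ``icc_convergence_trial`` is the first trial with ICC > 0.80 (strict),
    or None.
    """

    table: pd.DataFrame
    icc_convergence_trial: int | None
    n_pairs: int = field(default=0)


def per_trial_reliability(
    logs1, logs2, n_trials: int = 30, icc_threshold: float = ICC_CONVERGENCE
) -> ReliabilityReport:
    """Reliability statistics at every trial index using the running estimates
    of two paired session collections (same subjects, same order).

    Differences are taken as session1 - session2.  Requires every log to hold
    at least ``n_trials`` estimates and at least 3 pairs.
    """
    logs1, logs2 = list(logs1), list(logs2)
    if len(logs1) != len(logs2):
        raise ValueError("paired collections must have equal length")
    if len(logs1) < 3:
        raise ValueError("ICC undefined for fewer than 3 pairs")
    for lg in (*logs1, *logs2):
        if len(lg.estimates) < n_trials:
            raise ValueError(f"every log needs >= {n_trials} valid trials")
    e1 = np.asarray([lg.estimates[:n_trials] for lg in logs1])
    e2 = np.asarray([lg.estimates[:n_trials] for lg in logs2])
    rows = []
    for k in range(n_trials):
        a, b = e1[:, k], e2[:, k]
        try:
            icc = icc_2_1(np.column_stack([a, b]))
        except ValueError:
            icc = np.nan
        sw = within_subject_sd(a, b)
        ba = bland_altman(a, b)
        sem = (
            standard_error_of_measurement(_between_subject_sd(a, b), icc)
            if np.isfinite(icc) and 0.0 <= icc <= 1.0
            else np.nan
        )
        r = pearsonr(a, b).statistic if np.std(a) > 0 and np.std(b) > 0 else np.nan
        rows.append(
            {
                "trial": k + 1,
                "icc": icc,
                "sw": sw,
                "rc": reproducibility_coefficient(sw),
                "sem": sem,
                "pearson_r": r,
                "mean_diff": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
                "n_pairs": ba.n,
            }
        )
    table = pd.DataFrame(rows).set_index("trial")
    above = table.index[table["icc"] > icc_threshold]
    conv = int(above[0]) if len(above) else None
    return ReliabilityReport(table=table, icc_convergence_trial=conv, n_pairs=len(logs1))
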