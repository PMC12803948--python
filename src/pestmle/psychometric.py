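"""Cumulative-Gaussian psychometric model and maximum-likelihood threshold fit.

The probability that a TMS pulse at intensity ``x`` (%MSO) evokes a motor
evoked potential above the target amplitude is modelled as

    P(success | x) = Phi((x - t) / sigma)

where ``t`` is the resting motor threshold being estimated, ``sigma``
controls the steepness of the curve, and ``Phi`` is the standard normal CDF.
The threshold is estimated by minimizing the Bernoulli negative
log-likelihood of the observed trials, augmented with two virtual *anchor*
trials encoding the boundary assumptions that 0 %MSO never evokes an MEP and
100 %MSO always does.

Only the threshold is free during a fit; the spread is a fixed configuration
value, either absolute (sigma in %MSO) or relative (sigma = s * t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import log_ndtr, ndtr

__all__ = [
    "TrialRecord",
    "PsychometricModel",
    "AnchorSet",
    "LikelihoodConfig",
    "ThresholdEstimate",
    "response_probability",
    "negative_log_likelihood",
    "fit_threshold_mle",
    "grid_search_oracle",
]

ABSOLUTE = "absolute"
RELATIVE = "relative"


@dataclass(frozen=True)
class TrialRecord:
    """One valid stimulation trial.

    Parameters
    ----------
    intensity : float
        Tested stimulator output in %MSO (device resolution is integer, but
        fractional values are accepted for generality).
    outcome : bool
        True iff the MEP peak-to-peak amplitude exceeded the target amplitude.
    rejected_repeats : int
        Number of artifact-rejected deliveries that preceded this valid trial
        (they were repeated at the same intensity and do not count toward the
        trial budget).
    amplitude_mv : float or None
        MEP peak-to-peak amplitude in mV, when known.
    """

    intensity: float
    outcome: bool
    rejected_repeats: int = 0
    amplitude_mv: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 100.0:
            raise ValueError(f"intensity must be in [0, 100] %MSO, got {self.intensity}")
        if self.rejected_repeats < 0:
            raise ValueError("rejected_repeats must be nonnegative")


@dataclass(frozen=True)
class PsychometricModel:
    """Cumulative-Gaussian response-probability curve.

    ``spread_mode`` selects how ``spread`` is interpreted: ``"absolute"``
    means sigma = spread (%MSO); ``"relative"`` means sigma = spread *
    threshold (dimensionless slope factor, as in the classical sequential
    estimation literature).
    """

    threshold: float
    spread: float
    spread_mode: str = ABSOLUTE

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 200.0:
            raise ValueError(f"threshold must be in (0, 200], got {self.threshold}")
        if self.spread <= 0.0:
            raise ValueError(f"spread must be positive, got {self.spread}")
        if self.spread_mode not in (ABSOLUTE, RELATIVE):
            raise ValueError(f"unknown spread_mode {self.spread_mode!r}")

    @property
    def sigma(self) -> float:
        """Effective standard deviation of the curve in %MSO."""
        if self.spread_mode == ABSOLUTE:
            return self.spread
        return self.spread * self.threshold


@dataclass(frozen=True)
class AnchorSet:
    """Virtual boundary trials: a failure at 0 %MSO and a success at 100 %MSO.

    Included in every likelihood evaluation unless ``enabled`` is False.
    """

    low_intensity: float = 0.0
    high_intensity: float = 100.0
    weight: float = 1.0
    enabled: bool = True


@dataclass(frozen=True)
class LikelihoodConfig:
    """Fixed quantities of a threshold fit (everything except the threshold)."""

    spread: float = 3.5
    spread_mode: str = ABSOLUTE
    anchors: AnchorSet = field(default_factory=AnchorSet)
    eps: float = 1e-12
    search_low: float = 1.0
    search_high: float = 150.0

    def __post_init__(self) -> None:
        if self.spread <= 0.0:
            raise ValueError("spread must be positive")
        if self.spread_mode not in (ABSOLUTE, RELATIVE):
            raise ValueError(f"unknown spread_mode {self.spread_mode!r}")
        if not 0.0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if not 0.0 < self.search_low < self.search_high:
            raise ValueError("require 0 < search_low < search_high")

    def model_at(self, t: float) -> PsychometricModel:
        return PsychometricModel(t, self.spread, self.spread_mode)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Result of a maximum-likelihood threshold fit."""

    value: float
    nll: float
    used_fallback: bool = False

    def __float__(self) -> float:
        return self.value


def response_probability(x, model: PsychometricModel, eps: float = 1e-12):
    """Probability of a supra-target MEP at intensity ``x``.

    Returns Phi((x - t) / sigma) clipped to [eps, 1 - eps] so that log
    terms in the likelihood stay finite even at the anchors.  Accepts scalar
    or array ``x``.
    """
    z = (np.asarray(x, dtype=float) - model.threshold) / model.sigma
    p = np.clip(ndtr(z), eps, 1.0 - eps)
    return float(p) if np.isscalar(x) or np.ndim(x) == 0 else p


def _trial_arrays(
    trials: Iterable[TrialRecord], anchors: AnchorSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack observed trials plus enabled anchors into (x, y, w) arrays."""
    xs = [float(tr.intensity) for tr in trials]
    ys = [1.0 if tr.outcome else 0.0 for tr in trials]
    ws = [1.0] * len(xs)
    if anchors.enabled:
        xs += [anchors.low_intensity, anchors.high_intensity]
        ys += [0.0, 1.0]
        ws += [anchors.weight, anchors.weight]
    return np.asarray(xs), np.asarray(ys), np.asarray(ws)


def _nll_at(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, t, config: LikelihoodConfig
) -> np.ndarray:
    """Vectorized NLL over candidate thresholds ``t`` (scalar or 1-D array)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    sigma = config.spread * t if config.spread_mode == RELATIVE else config.spread
    if x.size == 0:
        return np.zeros(t.shape)
    z = (x[:, None] - t[None, :]) / sigma
    # log-domain Bernoulli terms: log Phi(z) and log Phi(-z) via log_ndtr stay
    # finite and smooth even at the anchors, where Phi underflows to 0/1
    terms = y[:, None] * log_ndtr(z) + (1.0 - y[:, None]) * log_ndtr(-z)
    return -(w[:, None] * terms).sum(axis=0)


def negative_log_likelihood(
    trials: Sequence[TrialRecord], t: float, config: LikelihoodConfig | None = None
) -> float:
    """Bernoulli negative log-likelihood of the trials (plus anchors) at threshold ``t``.

    NLL = -sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)], with the log
    terms evaluated in the log domain (``log_ndtr``) so the extreme anchor
    probabilities never produce log(0).

    Raises ``ValueError`` if ``t`` lies outside the configured search domain.
    """
    config = config or LikelihoodConfig()
    if not config.search_low <= t <= config.search_high:
        raise ValueError(
            f"threshold {t} outside search domain "
            f"[{config.search_low}, {config.search_high}]"
        )
    x, y, w = _trial_arrays(trials, config.anchors)
    return float(_nll_at(x, y, w, t, config)[0])


def _has_informative_data(y: np.ndarray) -> bool:
    return bool(y.size) and bool((y == 1.0).any()) and bool((y == 0.0).any())


def fit_threshold_mle(
    trials: Sequence[TrialRecord], config: LikelihoodConfig | None = None
) -> ThresholdEstimate:
    """Maximum-likelihood threshold: argmin of the NLL over the search interval.

    Strategy: a coarse grid (0.5 %MSO) brackets the global minimum, then
    bounded Brent refinement localizes it; the NLL is convex in the threshold
    for absolute spread, so this matches an exhaustive fine grid.  If the
    scalar optimizer fails, a 0.01 %MSO grid search is used and the estimate
    is flagged via ``used_fallback``.
    """
    config = config or LikelihoodConfig()
    x, y, w = _trial_arrays(trials, config.anchors)
    if not _has_informative_data(y):
        raise ValueError(
            "likelihood has no interior minimum: need anchors enabled or at "
            "least one success and one failure"
        )
    lo, hi = config.search_low, config.search_high
    grid = np.arange(lo, hi + 0.25, 0.5)
    grid[-1] = min(grid[-1], hi)
    nll = _nll_at(x, y, w, grid, config)
    i = int(np.argmin(nll))  # first minimum -> lower intensity on ties
    b_lo = max(lo, grid[i] - 1.0)
    b_hi = min(hi, grid[i] + 1.0)
    try:
        res = minimize_scalar(
            lambda t: float(_nll_at(x, y, w, t, config)[0]),
            bounds=(b_lo, b_hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        ok = bool(res.success)
    except Exception:  # pragma: no cover - scipy failure path
        ok = False
    if not ok:  # pragma: no cover
        est = grid_search_oracle(trials, config, resolution=0.01)
        return ThresholdEstimate(est.value, est.nll, used_fallback=True)
    t_star, f_star = float(res.x), float(res.fun)
    if nll[i] < f_star:  # keep the better point if refinement stalled
        t_star, f_star = float(grid[i]), float(nll[i])
    return ThresholdEstimate(t_star, f_star, used_fallback=False)


def grid_search_oracle(
    trials: Sequence[TrialRecord],
    config: LikelihoodConfig | None = None,
    resolution: float = 0.01,
) -> ThresholdEstimate:
    """Exhaustive NLL minimization on a uniform grid; ties break toward the
    lower intensity.  Serves as an independent check on ``fit_threshold_mle``."""
    config = config or LikelihoodConfig()
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x, y, w = _trial_arrays(trials, config.anchors)
    grid = np.arange(
        config.search_low, config.search_high + resolution / 2.0, resolution
    )
    nll = _nll_at(x, y, w, grid, config)
    i = int(np.argmin(nll))  # np.argmin returns the first (lowest t) minimizer
    return ThresholdEstimate(float(grid[i]), float(nll[i]))


def with_disabled_anchors(config: LikelihoodConfig) -> LikelihoodConfig:
    """Convenience: a copy of ``config`` with the virtual anchors turned off."""
    return replace(config, anchors=replace(config.anchors, enabled=False))
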