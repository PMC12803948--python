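"""The sequential PEST-MLE session loop.

A session delivers a fixed budget of valid trials (30 by default).  The
first intensity is drawn uniformly from 20-60 %MSO; after every valid trial
the threshold is re-fit by maximum likelihood over all trials so far
(anchors included) and the next tested intensity is that estimate rounded to
the stimulator's resolution and clamped to [1, device_max].  Deliveries
rejected for pre-stimulus muscle activity are repeated at the same intensity
and do not consume the trial budget.

The final resting motor threshold is the last running estimate, rounded and
capped at the device maximum (100 %MSO); sessions whose estimate exceeded
the device maximum are reported as 100 %MSO with a ``capped`` flag.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .emg import EmgTrace, Outcome, WindowSpec, classify_trial
from .psychometric import (
    AnchorSet,
    LikelihoodConfig,
    TrialRecord,
    fit_threshold_mle,
)

__all__ = [
    "SessionConfig",
    "SessionLog",
    "FinalRmt",
    "initial_intensity",
    "next_intensity",
    "run_session",
    "final_rmt",
    "round_half_away",
]


def round_half_away(value: float, resolution: float = 1.0) -> float:
    """Round to a multiple of ``resolution``, halves away from zero."""
    q = value / resolution
    return math.copysign(math.floor(abs(q) + 0.5), q) * resolution


@dataclass(frozen=True)
class SessionConfig:
    """Everything that determines one threshold-hunting session."""

    target_amplitude: float = 0.05
    n_trials: int = 30
    init_low: int = 20
    init_high: int = 60
    intensity_resolution: float = 1.0
    device_max: float = 100.0
    rng_seed: int | None = None
    spread: float = 3.5
    spread_mode: str = "absolute"
    anchors_enabled: bool = True
    anchor_weight: float = 1.0
    search_low: float = 1.0
    search_high: float = 150.0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if not self.init_low < self.init_high <= self.device_max:
            raise ValueError("require init_low < init_high <= device_max")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.intensity_resolution <= 0:
            raise ValueError("intensity_resolution must be positive")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")

    def likelihood_config(self) -> LikelihoodConfig:
        return LikelihoodConfig(
            spread=self.spread,
            spread_mode=self.spread_mode,
            anchors=AnchorSet(enabled=self.anchors_enabled, weight=self.anchor_weight),
            search_low=self.search_low,
            search_high=self.search_high,
        )


@dataclass
class SessionLog:
    """Complete, self-describing record of one session.

    ``estimates`` holds the running maximum-likelihood threshold after each
    valid trial, at full precision; display rounding happens downstream.
    """

    trials: list[TrialRecord] = field(default_factory=list)
    estimates: list[float] = field(default_factory=list)
    config: SessionConfig = field(default_factory=SessionConfig)
    seed: int | None = None
    truncated: bool = False

    @property
    def n_valid(self) -> int:
        return len(self.trials)

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([t.intensity for t in self.trials])

    @property
    def outcomes(self) -> np.ndarray:
        return np.asarray([t.outcome for t in self.trials], dtype=bool)

    @property
    def final_estimate(self) -> float:
        if not self.estimates:
            raise ValueError("empty session log")
        return self.estimates[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(1, self.n_valid + 1),
                "intensity_pct_mso": self.intensities,
                "outcome": self.outcomes.astype(int),
                "rejected_repeats": [t.rejected_repeats for t in self.trials],
                "estimate_pct_mso": np.round(self.estimates, 4),
            }
        )
        amps = [t.amplitude_mv for t in self.trials]
        if any(a is not None for a in amps):
            df["amplitude_mv"] = [
                round(a, 6) if a is not None else np.nan for a in amps
            ]
        return df

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write the session-log CSV dialect (config and seed carried in
        ``#`` header comments); lossless round-trip at 4 decimals."""
        header = (
            f"# pestmle-session-log v1\n"
            f"# seed={json.dumps(self.seed)}\n"
            f"# truncated={json.dumps(self.truncated)}\n"
            f"# config={json.dumps(asdict(self.config))}\n"
        )
        body = self.to_frame().to_csv(index=False, float_format="%.4f")
        if isinstance(path, io.TextIOBase):
            path.write(header + body)
        else:
            Path(path).write_text(header + body)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "SessionLog":
        text = path.read() if isinstance(path, io.TextIOBase) else Path(path).read_text()
        meta: dict[str, object] = {}
        body_lines: list[str] = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if val:
                    meta[key.strip()] = json.loads(val)
            elif line.strip():
                body_lines.append(line)
        if not body_lines:
            raise ValueError("session log CSV has no data rows")
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
        required = {
            "trial",
            "intensity_pct_mso",
            "outcome",
            "rejected_repeats",
            "estimate_pct_mso",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"session log CSV missing columns: {sorted(missing)}")
        has_amp = "amplitude_mv" in df.columns
        trials = [
            TrialRecord(
                intensity=float(r.intensity_pct_mso),
                outcome=bool(r.outcome),
                rejected_repeats=int(r.rejected_repeats),
                amplitude_mv=(
                    float(r.amplitude_mv)
                    if has_amp and not pd.isna(r.amplitude_mv)
                    else None
                ),
            )
            for r in df.itertuples()
        ]
        cfg_dict = meta.get("config")
        config = SessionConfig(**cfg_dict) if isinstance(cfg_dict, dict) else SessionConfig()
        return cls(
            trials=trials,
            estimates=[float(v) for v in df["estimate_pct_mso"]],
            config=config,
            seed=meta.get("seed"),
            truncated=bool(meta.get("truncated", False)),
        )


@dataclass(frozen=True)
class FinalRmt:
    """Final session threshold: rounded, device-capped, with a cap flag."""

    value: float
    capped: bool

    def __float__(self) -> float:
        return self.value


def initial_intensity(rng: np.random.Generator, config: SessionConfig) -> int:
    """First tested intensity: uniform integer draw from [init_low, init_high]."""
    return int(rng.integers(config.init_low, config.init_high + 1))


def next_intensity(estimate: float, config: SessionConfig) -> float:
    """Tested intensity for the next trial: the current ML estimate rounded
    to the device resolution (half away from zero), clamped to [1, device_max]."""
    if not math.isfinite(estimate):
        raise ValueError("estimate must be finite")
    x = round_half_away(estimate, config.intensity_resolution)
    return float(min(max(x, 1.0), config.device_max))


def _coerce_outcome(
    response, target_amplitude: float, window: WindowSpec | None
) -> Outcome:
    if isinstance(response, EmgTrace):
        return classify_trial(response, target_amplitude, window)
    if isinstance(response, Outcome):
        return response
    if isinstance(response, (bool, np.bool_)):
        return Outcome.SUCCESS if response else Outcome.FAILURE
    raise TypeError(f"subject returned unsupported response {type(response).__name__}")


def run_session(
    subject,
    config: SessionConfig | None = None,
    rng: np.random.Generator | None = None,
    window: WindowSpec | None = None,
) -> SessionLog:
    """Run one complete PEST-MLE threshold-hunting session.

    ``subject`` is either a callable ``intensity -> response`` or an object
    with a ``respond(intensity)`` method; the response may be an
    :class:`~pestmle.emg.Outcome`, a bool, or a raw
    :class:`~pestmle.emg.EmgTrace` (classified via the EMG rules).  If the
    subject keeps a ``last_amplitude`` attribute it is copied into the trial
    record.

    Rejected deliveries are repeated at the same intensity up to
    ``config.max_retries`` consecutive times; exhausting the retries ends
    the session early with ``truncated=True``.
    """
    config = config or SessionConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    respond: Callable = subject.respond if hasattr(subject, "respond") else subject
    lik = config.likelihood_config()

    log = SessionLog(config=config, seed=config.rng_seed)
    x = float(initial_intensity(rng, config))
    for _ in range(config.n_trials):
        rejected = 0
        outcome = Outcome.REJECTED
        while outcome is Outcome.REJECTED:
            outcome = _coerce_outcome(respond(x), config.target_amplitude, window)
            if outcome is Outcome.REJECTED:
                rejected += 1
                if rejected >= config.max_retries:
                    log.truncated = True
                    return log
        amp = getattr(subject, "last_amplitude", None)
        log.trials.append(
            TrialRecord(
                intensity=x,
                outcome=(outcome is Outcome.SUCCESS),
                rejected_repeats=rejected,
                amplitude_mv=amp,
            )
        )
        est = fit_threshold_mle(log.trials, lik)
        log.estimates.append(est.value)
        x = next_intensity(est.value, config)
    return log


def final_rmt(log: SessionLog) -> FinalRmt:
    """Final RMT of a session: last estimate rounded to the device resolution,
    capped at ``device_max`` (flagged when capping occurred)."""
    last = log.final_estimate  # raises on empty log
    cfg = log.config
    rounded = round_half_away(last, cfg.intensity_resolution)
    if rounded > cfg.device_max:
        return FinalRmt(float(cfg.device_max), capped=True)
    return FinalRmt(float(max(rounded, 1.0)), capped=False)
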