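"""Single-trial EMG handling: MEP amplitude windows and online artifact rejection.

A trial's outcome is derived from its EMG trace with two rules:

* the trial is *rejected* if voluntary background activity in the 65 ms
  before the stimulus exceeds 0.05 mV peak-to-peak (muscle was not at rest);
* otherwise it is a *success* iff the peak-to-peak amplitude within the
  15-40 ms post-stimulus MEP window strictly exceeds the target amplitude.

Windows are closed at both ends at sample resolution, except the rejection
window which is [-65 ms, 0 ms) — the stimulus sample itself is excluded.
Millisecond endpoints are converted to sample indices by rounding to the
nearest sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Outcome",
    "EmgTrace",
    "WindowSpec",
    "peak_to_peak",
    "is_rejected",
    "classify_trial",
    "read_trace_csv",
    "write_trace_csv",
]


class Outcome(enum.Enum):
    """Classification of one stimulus delivery."""

    SUCCESS = "success"
    FAILURE = "failure"
    REJECTED = "rejected"


@dataclass(frozen=True)
class EmgTrace:
    """A single-trial EMG recording.

    ``samples`` are amplitudes in mV; ``stimulus_index`` is the sample at
    which the TMS pulse was delivered. Default sampling rate is 5 kHz.
    """

    samples: np.ndarray
    sampling_rate: float = 5000.0
    stimulus_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.stimulus_index < len(self.samples):
            raise ValueError("stimulus_index must lie within the trace")

    def sample_at_ms(self, t_ms: float) -> int:
        """Index of the sample nearest to time ``t_ms`` relative to the stimulus."""
        return self.stimulus_index + int(round(t_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class WindowSpec:
    """Time windows (ms, relative to stimulus) and the rejection cutoff (mV)."""

    pre_artifact_ms: float = 65.0
    mep_start_ms: float = 15.0
    mep_end_ms: float = 40.0
    artifact_cutoff_mv: float = 0.05

    def __post_init__(self) -> None:
        if not (
            self.pre_artifact_ms > 0
            and 0 < self.mep_start_ms < self.mep_end_ms
            and self.artifact_cutoff_mv > 0
        ):
            raise ValueError("invalid window specification")


def peak_to_peak(trace: EmgTrace, start_ms: float, end_ms: float) -> float:
    """Peak-to-peak amplitude (max - min, mV) in the closed window
    [start_ms, end_ms] relative to the stimulus.

    Raises ``ValueError`` if the window falls outside the recorded trace.
    """
    if start_ms >= end_ms:
        raise ValueError("start_ms must precede end_ms")
    i0 = trace.sample_at_ms(start_ms)
    i1 = trace.sample_at_ms(end_ms)
    if i0 < 0 or i1 >= len(trace.samples):
        raise ValueError(
            f"window [{start_ms}, {end_ms}] ms exceeds the recorded trace"
        )
    seg = trace.samples[i0 : i1 + 1]
    return float(seg.max() - seg.min())


def is_rejected(trace: EmgTrace, spec: WindowSpec | None = None) -> bool:
    """True iff pre-stimulus activity in [-pre_artifact_ms, 0) exceeds the cutoff.

    The comparison is strict (activity must *exceed* 0.05 mV by default) and
    the stimulus sample itself is excluded from the window.
    """
    spec = spec or WindowSpec()
    i0 = trace.sample_at_ms(-spec.pre_artifact_ms)
    i1 = trace.stimulus_index - 1  # [-65 ms, 0 ms): exclude the stimulus sample
    if i0 < 0 or i1 < i0:
        raise ValueError(
            f"trace provides less than {spec.pre_artifact_ms} ms of "
            "pre-stimulus data"
        )
    seg = trace.samples[i0 : i1 + 1]
    return float(seg.max() - seg.min()) > spec.artifact_cutoff_mv


def classify_trial(
    trace: EmgTrace, target_amplitude_mv: float, spec: WindowSpec | None = None
) -> Outcome:
    """Outcome of a delivery: REJECTED on pre-stimulus activity, else SUCCESS
    iff the MEP-window peak-to-peak strictly exceeds the target amplitude.

    A peak-to-peak exactly equal to the target counts as a failure ("greater
    than" is read strictly).
    """
    spec = spec or WindowSpec()
    if target_amplitude_mv <= 0:
        raise ValueError("target_amplitude_mv must be positive")
    if is_rejected(trace, spec):
        return Outcome.REJECTED
    amp = peak_to_peak(trace, spec.mep_start_ms, spec.mep_end_ms)
    return Outcome.SUCCESS if amp > target_amplitude_mv else Outcome.FAILURE


def write_trace_csv(trace: EmgTrace, path: str | Path) -> None:
    """Write a trace as one column of mV samples, with sampling rate and
    stimulus index carried in ``#`` header comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate={trace.sampling_rate:g}\n")
        fh.write(f"# stimulus_index={trace.stimulus_index}\n")
        fh.write("amplitude_mv\n")
        for v in trace.samples:
            fh.write(f"{v:.6f}\n")


def read_trace_csv(path: str | Path) -> EmgTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line != "amplitude_mv":
                values.append(float(line))
    try:
        rate = float(meta["sampling_rate"])
        stim = int(meta["stimulus_index"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing required header comment {exc}") from exc
    return EmgTrace(np.asarray(values), sampling_rate=rate, stimulus_index=stim)
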