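"""Generative virtual TMS subject.

Emulates the three features of real motor-threshold data the rest of the
package needs to be exercised against without hardware:

* a sigmoidal (cumulative-Gaussian) intensity -> response-probability curve,
* right-skewed (lognormal) MEP amplitudes at any fixed intensity, and
* threshold drift between days and between sessions within a day.

The amplitude model is tied to the response curve in closed form: the
lognormal median at intensity x is

    mu(x) = a_ref * exp(amp_sigma_log * (x - threshold) / gen_spread)

so that P(amplitude > a_ref | x) = Phi((x - threshold) / gen_spread)
exactly.  Thresholding an amplitude draw at the reference target and drawing
a Bernoulli outcome directly are therefore distributionally identical, and
the threshold for any other target amplitude ``a`` follows without extra
parameters:

    threshold(a) = threshold + gen_spread * ln(a / a_ref) / amp_sigma_log
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .emg import EmgTrace, Outcome, WindowSpec

__all__ = ["SubjectParams", "VirtualSubject", "SessionResponder"]


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one virtual subject.

    true_threshold : %MSO
        Resting motor threshold at the reference target amplitude.
    gen_spread : %MSO
        Steepness (SD) of the true cumulative-Gaussian response curve.
    amp_sigma_log : dimensionless
        Lognormal shape of single-trial MEP amplitude at fixed intensity.
    day_sd, session_sd : %MSO
        SDs of the between-day and within-day (per-session) threshold drift.
    target_amplitude : mV
        Reference MEP cutoff anchoring the amplitude curve (0.05 mV).
    """

    true_threshold: float
    gen_spread: float = 3.5
    amp_sigma_log: float = 0.9
    day_sd: float = 3.0
    session_sd: float = 1.0
    target_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.true_threshold <= 150.0:
            raise ValueError("true_threshold must be in (0, 150] %MSO")
        if self.gen_spread <= 0:
            raise ValueError("gen_spread must be positive")
        if self.amp_sigma_log <= 0:
            raise ValueError("amp_sigma_log must be positive")
        if self.day_sd < 0 or self.session_sd < 0:
            raise ValueError("drift SDs must be nonnegative")
        if self.target_amplitude <= 0:
            raise ValueError("target_amplitude must be positive")

    def threshold_for_target(self, target_amplitude_mv: float) -> float:
        """Threshold (%MSO) at which P(MEP > target) = 0.5 for this target."""
        shift = (
            self.gen_spread
            * math.log(target_amplitude_mv / self.target_amplitude)
            / self.amp_sigma_log
        )
        return self.true_threshold + shift


class VirtualSubject:
    """A simulated participant answering intensity queries.

    Day and session drift effects are drawn lazily and cached, so sessions 1
    and 2 share the day-1 effect and repeated queries are consistent.
    """

    def __init__(self, params: SubjectParams, rng: np.random.Generator | int | None = None):
        self.params = params
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self._day_effects: dict[int, float] = {}
        self._session_effects: dict[int, float] = {}

    # -- drift ------------------------------------------------------------

    def _day_effect(self, day: int) -> float:
        if day not in self._day_effects:
            self._day_effects[day] = float(self.rng.normal(0.0, self.params.day_sd))
        return self._day_effects[day]

    def _session_effect(self, session: int) -> float:
        if session not in self._session_effects:
            self._session_effects[session] = float(
                self.rng.normal(0.0, self.params.session_sd)
            )
        return self._session_effects[session]

    def realize_session_threshold(self, day: int, session: int) -> float:
        """Effective threshold (%MSO, at the reference target) for one session.

        ``day`` in {1, 2}; ``session`` in {1, ..., 4}; sessions 1-2 belong to
        day 1 and sessions 3-4 to day 2 in the standard design, but any
        consistent labelling works — effects are keyed and cached per label.
        """
        if day not in (1, 2):
            raise ValueError("day must be 1 or 2")
        if session not in (1, 2, 3, 4):
            raise ValueError("session must be in 1..4")
        return (
            self.params.true_threshold
            + self._day_effect(day)
            + self._session_effect(session)
        )

    # -- responses --------------------------------------------------------

    def success_probability(
        self, x: float, threshold: float | None = None, target_amplitude: float | None = None
    ) -> float:
        """P(MEP > target | intensity x) under the generative model."""
        p = self.params
        thr = p.true_threshold if threshold is None else threshold
        if target_amplitude is not None and target_amplitude != p.target_amplitude:
            thr += p.gen_spread * math.log(target_amplitude / p.target_amplitude) / p.amp_sigma_log
        return float(ndtr((x - thr) / p.gen_spread))

    def sample_outcome(
        self, x: float, threshold: float | None = None, target_amplitude: float | None = None
    ) -> bool:
        """Bernoulli draw of trial success at intensity ``x``."""
        return bool(
            self.rng.random() < self.success_probability(x, threshold, target_amplitude)
        )

    def sample_mep_amplitude(self, x: float, threshold: float | None = None) -> float:
        """Lognormal MEP peak-to-peak amplitude (mV) at intensity ``x``.

        Median chosen so that thresholding at the reference target reproduces
        the response sigmoid exactly (see module docstring).
        """
        p = self.params
        thr = p.true_threshold if threshold is None else threshold
        z = (x - thr) / p.gen_spread
        median = p.target_amplitude * math.exp(p.amp_sigma_log * z)
        return float(median * math.exp(p.amp_sigma_log * self.rng.standard_normal()))

    def sample_trace(
        self,
        x: float,
        threshold: float | None = None,
        inject_artifact: bool = False,
        noise_sd: float = 0.0,
        window: WindowSpec | None = None,
        sampling_rate: float = 5000.0,
    ) -> EmgTrace:
        """Synthesize a single-trial EMG trace at intensity ``x``.

        Layout: 65 ms baseline, stimulus, 50 ms post-stimulus.  A
        Gaussian-windowed sinusoid is planted in the MEP window and rescaled
        so its peak-to-peak equals a fresh draw of
        :meth:`sample_mep_amplitude` exactly.  With ``inject_artifact`` a
        0.1 mV burst is placed at -30 ms to trigger online rejection.
        """
        window = window or WindowSpec()
        fs = sampling_rate
        n_pre = int(round(0.065 * fs))
        n_post = int(round(0.050 * fs))
        n = n_pre + 1 + n_post
        stim = n_pre
        samples = (
            self.rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        )
        amp = self.sample_mep_amplitude(x, threshold)
        i0 = stim + int(round(window.mep_start_ms * fs / 1000.0))
        i1 = stim + int(round(window.mep_end_ms * fs / 1000.0))
        tt = np.linspace(-1.0, 1.0, i1 - i0 + 1)
        wave = np.exp(-4.0 * tt**2) * np.sin(2.0 * np.pi * 1.5 * tt)
        wave *= amp / (wave.max() - wave.min())
        samples[i0 : i1 + 1] += wave
        if inject_artifact:
            # 0.12 mV p2p burst at -30 ms: clearly above the 0.05 mV cutoff
            j = stim + int(round(-30.0 * fs / 1000.0))
            samples[j] += 0.06
            samples[j + 3] -= 0.06
        return EmgTrace(samples, sampling_rate=fs, stimulus_index=stim)

    # -- session views ----------------------------------------------------

    def responder(
        self,
        target_amplitude: float | None = None,
        day: int | None = None,
        session: int | None = None,
        mode: str = "bernoulli",
        artifact_prob: float = 0.0,
    ) -> "SessionResponder":
        """Bind this subject to one session and target, yielding an object
        with the ``respond(intensity)`` interface the hunting engine consumes.

        ``mode`` selects the response path: ``"bernoulli"`` (direct outcome
        draw), ``"amplitude"`` (draw an amplitude, threshold it), or
        ``"trace"`` (synthesize EMG, classified downstream).
        """
        if mode not in ("bernoulli", "amplitude", "trace"):
            raise ValueError(f"unknown response mode {mode!r}")
        thr = (
            self.realize_session_threshold(day, session)
            if day is not None and session is not None
            else self.params.true_threshold
        )
        target = target_amplitude if target_amplitude is not None else self.params.target_amplitude
        return SessionResponder(self, thr, target, mode, artifact_prob)


class SessionResponder:
    """One subject x session x target amplitude, answering intensity queries."""

    def __init__(
        self,
        subject: VirtualSubject,
        session_threshold: float,
        target_amplitude: float,
        mode: str = "bernoulli",
        artifact_prob: float = 0.0,
    ):
        self.subject = subject
        self.session_threshold = session_threshold
        self.target_amplitude = target_amplitude
        self.mode = mode
        self.artifact_prob = artifact_prob
        self.last_amplitude: float | None = None

    @property
    def effective_threshold(self) -> float:
        """Session threshold shifted to this responder's target amplitude."""
        p = self.subject.params
        return self.session_threshold + p.gen_spread * math.log(
            self.target_amplitude / p.target_amplitude
        ) / p.amp_sigma_log

    def respond(self, intensity: float):
        """Outcome of one delivery at ``intensity`` (%MSO).

        Returns an :class:`~pestmle.emg.Outcome` in bernoulli/amplitude mode,
        or an :class:`~pestmle.emg.EmgTrace` in trace mode (classification is
        then the engine's job, via ``emg.classify_trial``).
        """
        rng = self.subject.rng
        self.last_amplitude = None
        if self.artifact_prob > 0 and rng.random() < self.artifact_prob:
            if self.mode == "trace":
                return self.subject.sample_trace(
                    intensity, self.session_threshold, inject_artifact=True
                )
            return Outcome.REJECTED
        if self.mode == "bernoulli":
            ok = self.subject.sample_outcome(
                intensity, self.session_threshold, self.target_amplitude
            )
            return Outcome.SUCCESS if ok else Outcome.FAILURE
        if self.mode == "amplitude":
            amp = self.subject.sample_mep_amplitude(intensity, self.session_threshold)
            self.last_amplitude = amp
            return Outcome.SUCCESS if amp > self.target_amplitude else Outcome.FAILURE
        return self.subject.sample_trace(intensity, self.session_threshold)
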