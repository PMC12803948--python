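"""Simulated replication of the four-session, two-target study design.

Each virtual subject is measured four times: twice on day 1 (sessions 1-2)
and twice on day 2 (sessions 3-4), with the low target (RMT0.05) hunted
before the high target (RMT0.2) within every session.  Comparing sessions
1 vs 2 gives within-day reliability; sessions 1 vs 3 give between-day
reliability.  Everything is deterministic under the master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hunting import SessionConfig, SessionLog, final_rmt, run_session
from .metrics import (
    ConvergenceResult,
    bland_altman,
    criterion_trial_at_95,
    per_trial_reliability,
)
from .subject import SubjectParams, VirtualSubject

__all__ = [
    "StudyConfig",
    "StudyDataset",
    "StudyReport",
    "simulate_study",
    "simulate_sessions",
    "analyze_study",
]

SESSION_DAY = {1: 1, 2: 1, 3: 2, 4: 2}  # study layout: sessions 1-2 day 1, 3-4 day 2


@dataclass(frozen=True)
class StudyConfig:
    """Cohort, session plan, and engine configuration of a simulated study."""

    n_subjects: int = 50
    threshold_low: float = 35.0
    threshold_high: float = 65.0
    gen_spread: float = 3.5
    amp_sigma_log: float = 0.9
    day_sd: float = 3.0
    session_sd: float = 1.0
    targets: tuple[float, ...] = (0.05, 0.2)
    sessions: tuple[int, ...] = (1, 2, 3, 4)
    n_trials: int = 30
    seed: int = 0
    response_mode: str = "amplitude"
    artifact_prob: float = 0.0
    session_config: SessionConfig = field(default_factory=SessionConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.threshold_low < self.threshold_high <= 150:
            raise ValueError("require 0 < threshold_low < threshold_high <= 150")
        if self.response_mode not in ("bernoulli", "amplitude", "trace"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")
        if any(s not in SESSION_DAY for s in self.sessions):
            raise ValueError("sessions must be a subset of (1, 2, 3, 4)")
        if not self.targets:
            raise ValueError("at least one target amplitude is required")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "session_config" in d and isinstance(d["session_config"], dict):
            d["session_config"] = SessionConfig(**d["session_config"])
        for key in ("targets", "sessions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load from JSON or YAML (by extension; YAML parses JSON too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = list(self.targets)
        d["sessions"] = list(self.sessions)
        return d


@dataclass
class StudyDataset:
    """All session logs of one simulated study, keyed by
    (subject index, day, session, target amplitude)."""

    logs: dict[tuple[int, int, int, float], SessionLog]
    config: StudyConfig
    true_thresholds: dict[int, float] = field(default_factory=dict)

    def get(self, subject: int, session: int, target: float) -> SessionLog:
        return self.logs[(subject, SESSION_DAY[session], session, target)]

    def session_logs(self, session: int, target: float) -> list[SessionLog]:
        """Logs of one (session, target) cell, ordered by subject index."""
        return [
            self.get(s, session, target) for s in range(self.config.n_subjects)
        ]

    def all_logs(self) -> list[SessionLog]:
        return list(self.logs.values())

    def write(self, outdir: str | Path) -> Path:
        """One CSV per session log plus a manifest JSON; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        for (subj, day, sess, target), log in sorted(self.logs.items()):
            name = f"subject{subj:03d}_day{day}_session{sess}_rmt{target:g}.csv"
            log.to_csv(outdir / name)
            entries.append(
                {"subject": subj, "day": day, "session": sess, "target": target,
                 "file": name}
            )
        manifest = {
            "config": self.config.to_dict(),
            "true_thresholds": {str(k): v for k, v in self.true_thresholds.items()},
            "sessions": entries,
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        return mpath

    @classmethod
    def read(cls, outdir: str | Path) -> "StudyDataset":
        outdir = Path(outdir)
        mpath = outdir / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(f"no manifest.json in {outdir}")
        manifest = json.loads(mpath.read_text())
        config = StudyConfig.from_dict(manifest["config"])
        logs = {
            (e["subject"], e["day"], e["session"], e["target"]): SessionLog.from_csv(
                outdir / e["file"]
            )
            for e in manifest["sessions"]
        }
        thr = {int(k): v for k, v in manifest.get("true_thresholds", {}).items()}
        return cls(logs=logs, config=config, true_thresholds=thr)


def simulate_study(config: StudyConfig | None = None) -> StudyDataset:
    """Simulate the full subject x session x target grid.

    Subject thresholds are drawn uniformly from the configured range; every
    subject and session gets its own seed stream spawned from the master
    seed, so single cells can be reproduced independently.
    """
    config = config or StudyConfig()
    master = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    subj_seeds = master.spawn(config.n_subjects)
    logs: dict[tuple[int, int, int, float], SessionLog] = {}
    true_thresholds: dict[int, float] = {}
    for i in range(config.n_subjects):
        thr = float(cohort_rng.uniform(config.threshold_low, config.threshold_high))
        true_thresholds[i] = thr
        params = SubjectParams(
            true_threshold=thr,
            gen_spread=config.gen_spread,
            amp_sigma_log=config.amp_sigma_log,
            day_sd=config.day_sd,
            session_sd=config.session_sd,
        )
        streams = subj_seeds[i].spawn(len(config.sessions) * len(config.targets) + 1)
        subject = VirtualSubject(params, np.random.default_rng(streams[0]))
        j = 1
        for sess in config.sessions:
            day = SESSION_DAY[sess]
            for target in config.targets:  # low target hunted first each session
                engine_rng = np.random.default_rng(streams[j])
                j += 1
                responder = subject.responder(
                    target_amplitude=target,
                    day=day,
                    session=sess,
                    mode=config.response_mode,
                    artifact_prob=config.artifact_prob,
                )
                scfg = SessionConfig(
                    **{
                        **asdict(config.session_config),
                        "target_amplitude": target,
                        "n_trials": config.n_trials,
                    }
                )
                logs[(i, day, sess, target)] = run_session(responder, scfg, engine_rng)
    return StudyDataset(logs=logs, config=config, true_thresholds=true_thresholds)


def simulate_sessions(
    n_sessions: int,
    seed: int,
    threshold_low: float = 35.0,
    threshold_high: float = 65.0,
    gen_spread: float = 3.5,
    target_amplitude: float = 0.05,
    session_config: SessionConfig | None = None,
    mode: str = "bernoulli",
) -> tuple[list[SessionLog], np.ndarray]:
    """Simulate independent single 30-trial sessions, one fresh subject each.

    Subject thresholds are drawn uniformly from [threshold_low,
    threshold_high]; no day/session drift is applied (each session stands
    alone).  Returns the session logs and the array of true thresholds.
    Used for convergence and parameter-recovery experiments where the
    four-session design is irrelevant.
    """
    base = session_config or SessionConfig(target_amplitude=target_amplitude)
    master = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    streams = master.spawn(n_sessions)
    logs, thresholds = [], np.empty(n_sessions)
    for i in range(n_sessions):
        thr = float(cohort_rng.uniform(threshold_low, threshold_high))
        thresholds[i] = thr
        params = SubjectParams(
            true_threshold=thr,
            gen_spread=gen_spread,
            day_sd=0.0,
            session_sd=0.0,
            target_amplitude=target_amplitude,
        )
        sub_ss, eng_ss = streams[i].spawn(2)
        subject = VirtualSubject(params, np.random.default_rng(sub_ss))
        responder = subject.responder(target_amplitude=target_amplitude, mode=mode)
        logs.append(run_session(responder, base, np.random.default_rng(eng_ss)))
    return logs, thresholds


@dataclass
class StudyReport:
    """Full analysis of a simulated study (convergence, reliability, late trials)."""

    convergence: pd.DataFrame  # per (target, criterion, trial): proportion converged
    criterion_trials: dict  # (target, criterion) -> 95 % criterion trial (or None)
    reliability: dict  # (target, comparison) -> ReliabilityReport
    final_bland_altman: pd.DataFrame  # final-RMT agreement per target/comparison
    late_trials: pd.DataFrame  # per session: success rate and mean MEP, trials 19-30
    n_sessions_analyzed: int = 0

    def summary(self) -> dict:
        rel = {
            f"rmt{target:g}_{comp}": {
                "icc_convergence_trial": rep.icc_convergence_trial,
                "icc_final": float(rep.table["icc"].iloc[-1]),
                "rc_final": float(rep.table["rc"].iloc[-1]),
                "sem_final": float(rep.table["sem"].iloc[-1]),
                "loa_final": [
                    float(rep.table["loa_lower"].iloc[-1]),
                    float(rep.table["loa_upper"].iloc[-1]),
                ],
            }
            for (target, comp), rep in self.reliability.items()
        }
        return {
            "n_sessions_analyzed": self.n_sessions_analyzed,
            "criterion_trials_95": {
                f"rmt{t:g}_{c}": v for (t, c), v in self.criterion_trials.items()
            },
            "late_trial_success_rate_mean": float(
                self.late_trials["success_rate"].mean()
            ),
            "reliability": rel,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.convergence.to_csv(outdir / "convergence_curves.csv", index=False)
        self.late_trials.to_csv(outdir / "late_trials.csv", index=False)
        self.final_bland_altman.to_csv(outdir / "final_bland_altman.csv", index=False)
        rel_rows = []
        for (target, comp), rep in self.reliability.items():
            t = rep.table.reset_index()
            t.insert(0, "target", target)
            t.insert(1, "comparison", comp)
            rel_rows.append(t)
        pd.concat(rel_rows, ignore_index=True).to_csv(
            outdir / "reliability_per_trial.csv", index=False
        )
        (outdir / "summary.json").write_text(json.dumps(self.summary(), indent=2))


LATE_TRIALS = (19, 30)  # 1-based inclusive window for late-phase summaries


def analyze_study(dataset: StudyDataset) -> StudyReport:
    """Reproduce the study's evaluation on a simulated dataset.

    Produces pooled precision/accuracy convergence curves with their 95 %
    criterion trials per target, within-day (sessions 1 vs 2) and between-day
    (1 vs 3) per-trial reliability, final-RMT Bland-Altman agreement, and
    late-trial (19-30) success-rate / mean-amplitude summaries per session.
    """
    cfg = dataset.config
    n_trials = cfg.n_trials

    conv_rows, crit_trials = [], {}
    late_rows = []
    n_analyzed = 0
    for target in cfg.targets:
        prec_trials, acc_trials = [], []
        for key, log in sorted(dataset.logs.items()):
            if key[3] != target:
                continue
            if log.n_valid < n_trials:
                warnings.warn(f"skipping truncated session {key}")
                continue
            n_analyzed += 1
            res = ConvergenceResult.from_session(log)
            prec_trials.append(res.precision_trial)
            acc_trials.append(res.accuracy_trial)
            lo, hi = LATE_TRIALS
            late = log.trials[lo - 1 : hi]
            amps = [t.amplitude_mv for t in late if t.amplitude_mv is not None]
            late_rows.append(
                {
                    "subject": key[0],
                    "session": key[2],
                    "target": target,
                    "success_rate": float(np.mean([t.outcome for t in late])),
                    "mean_amplitude_mv": float(np.mean(amps)) if amps else np.nan,
                }
            )
        for name, trials in (("precision", prec_trials), ("accuracy", acc_trials)):
            k95, curve = criterion_trial_at_95(trials, n_trials)
            crit_trials[(target, name)] = k95
            conv_rows += [
                {"target": target, "criterion": name, "trial": j + 1,
                 "proportion": curve[j]}
                for j in range(n_trials)
            ]

    reliability, ba_rows = {}, []
    comparisons = {"within_day": (1, 2), "between_day": (1, 3)}
    for target in cfg.targets:
        for comp, (s_a, s_b) in comparisons.items():
            if s_a not in cfg.sessions or s_b not in cfg.sessions:
                warnings.warn(f"sessions {s_a}/{s_b} missing; skipping {comp}")
                continue
            logs_a = dataset.session_logs(s_a, target)
            logs_b = dataset.session_logs(s_b, target)
            keep = [
                i
                for i in range(len(logs_a))
                if logs_a[i].n_valid >= n_trials and logs_b[i].n_valid >= n_trials
            ]
            logs_a = [logs_a[i] for i in keep]
            logs_b = [logs_b[i] for i in keep]
            reliability[(target, comp)] = per_trial_reliability(
                logs_a, logs_b, n_trials=n_trials
            )
            fa = np.array([final_rmt(lg).value for lg in logs_a])
            fb = np.array([final_rmt(lg).value for lg in logs_b])
            ba = bland_altman(fa, fb)
            ba_rows.append(
                {"target": target, "comparison": comp, "mean_diff": ba.mean_diff,
                 "sd_diff": ba.sd_diff, "loa_lower": ba.loa_lower,
                 "loa_upper": ba.loa_upper, "n": ba.n}
            )

    return StudyReport(
        convergence=pd.DataFrame(conv_rows),
        criterion_trials=crit_trials,
        reliability=reliability,
        final_bland_altman=pd.DataFrame(ba_rows),
        late_trials=pd.DataFrame(late_rows),
        n_sessions_analyzed=n_analyzed,
    )
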