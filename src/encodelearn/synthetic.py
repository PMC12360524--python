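"""Synthetic observers and full synthetic studies.

Generates trial-level same-different data with the statistical structure
the analysis assumes, so that every pipeline stage — response-time
filtering, sensitivity estimation, curve fitting, inference — can be
exercised and validated by parameter recovery without any external data.

A synthetic study mirrors the 11-session design: six training sessions
(2, 3, 5, 6, 8, 9) of 360 trials at a fixed 100 ms encoding duration, four
evaluation sessions (1, 4, 7, 10) of 480 trials (60 per duration at
17-1000 ms, half same / half different pairs), and a generalization
session (11) run on a subset of participants with the session-10
parameters minus an optional asymptote decrement.

Generating model per observer and session:

* evaluation sensitivity follows a shifted-exponential encoding curve
  d'(t) = A(1 - exp(-R(t - I))) with per-participant parameters drawn from
  truncated normal distributions around session-dependent population means;
* training sensitivity at 100 ms follows a saturating learning trajectory
  across training sessions;
* responses are Bernoulli draws from the forward same-different decision
  model (independent-observation by default) at criterion k = d'/2 + bias;
  with probability ``lapse_rate`` the response is replaced by a fair coin;
* response times are lognormal, with a configurable probability mass
  placed outside the [0.2, 5.0] s analysis window so filter code paths are
  always exercised.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import truncnorm

from .encoding_model import DEFAULT_BOUNDS, ShiftedExponentialParams, predict
from .sdt import forward_differencing, forward_independent
from .trial_data import (
    COLUMNS,
    EVALUATION_DURATIONS_MS,
    EVALUATION_SESSIONS,
    GENERALIZATION_SESSIONS,
    TRAINING_DURATION_MS,
    TRAINING_SESSIONS,
    SessionSpec,
    TrialTable,
    write_trials,
)

__all__ = [
    "LearningTrajectory",
    "SimulationConfig",
    "ObserverParams",
    "StudyBundle",
    "sample_population",
    "simulate_evaluation_session",
    "simulate_training_course",
    "simulate_study",
]

#: Default population encoding-curve means per evaluation session
#: (A in d', R per ms, I in ms), shaped like the published fits: asymptote,
#: rate and onset all improve with training.
DEFAULT_POPULATION_CURVES: Mapping[int, tuple[float, float, float]] = {
    1: (2.88, 0.00708, 14.7),
    4: (3.37, 0.01162, 0.3),
    7: (3.53, 0.01474, 2.8),
    10: (3.60, 0.01497, 1e-7),
}


@dataclass(frozen=True)
class LearningTrajectory:
    """Saturating exponential d' trajectory over the six training sessions.

    d'_j = end - (end - start) * exp(-rate * (j - 1)) for training session
    ordinal j = 1..6 (sessions 2, 3, 5, 6, 8, 9).  ``start`` and ``end``
    are on the d' scale at the 100 ms training duration.
    """

    start: float = 1.0
    end: float = 2.1
    rate: float = 0.45

    def dprime(self, ordinal: int) -> float:
        return self.end - (self.end - self.start) * np.exp(-self.rate * (ordinal - 1))


@dataclass
class SimulationConfig:
    """Design and generating-model parameters of a synthetic study."""

    seed: int
    n_participants: int = 27
    n_generalization: int = 16
    durations_ms: Sequence[float] = EVALUATION_DURATIONS_MS
    trials_per_duration: int = 60          # 30 same / 30 different
    training_trials: int = 360
    sdt_model: str = "independent_observation"
    population_curves: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_CURVES))
    sd_A: float = 0.5
    sd_R_rel: float = 0.25                 # between-subject SD of R, relative
    sd_I_ms: float = 5.0
    trajectory: LearningTrajectory = field(default_factory=LearningTrajectory)
    sd_training: float = 0.5               # between-subject SD of training d'
    generalization_decrement_A: float = 0.1
    criterion_bias: float = 0.0            # offset from the unbiased criterion
    lapse_rate: float = 0.01
    rt_median_s: float = 0.7
    rt_sigma: float = 0.35
    rt_outlier_prob: float = 0.02          # mass outside [0.2, 5.0] s
    omission_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_duration < 2:
            raise ValueError("counts must be positive")
        if self.trials_per_duration % 2:
            raise ValueError("trials_per_duration must be even")
        if not all(np.diff(self.durations_ms) > 0):
            raise ValueError("durations must be sorted increasing")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        (alo, ahi), (rlo, rhi), (ilo, ihi) = DEFAULT_BOUNDS
        for s, (A, R, I) in self.population_curves.items():
            if not (alo <= A <= ahi and rlo <= R <= rhi and ilo <= I <= ihi):
                raise ValueError(f"session {s} population means outside bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["durations_ms"] = list(self.durations_ms)
        d["population_curves"] = {str(k): list(v)
                                  for k, v in self.population_curves.items()}
        return d


@dataclass
class ObserverParams:
    """Generating parameters of one synthetic observer."""

    participant_id: str
    curves: dict            # session_index -> ShiftedExponentialParams
    training_dprime: dict   # session_index -> d' at 100 ms
    criterion_bias: float
    lapse_rate: float
    rt_median_s: float
    rt_sigma: float

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "curves": {str(s): [p.A, p.R, p.I] for s, p in self.curves.items()},
            "training_dprime": {str(s): v for s, v in self.training_dprime.items()},
            "criterion_bias": self.criterion_bias,
            "lapse_rate": self.lapse_rate,
            "rt_median_s": self.rt_median_s,
            "rt_sigma": self.rt_sigma,
        }


def _trunc_ppf(u: float, mean: float, sd: float, lo: float, hi: float) -> float:
    """Quantile of a normal truncated to [lo, hi]; degenerate sd -> mean."""
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def sample_population(config: SimulationConfig) -> list[ObserverParams]:
    """Draw per-participant parameters around the population means.

    Each participant gets one latent quantile per parameter family, shared
    across sessions, so that a participant who is above average with no
    training stays above average with training (stable individual
    differences).  Draws are truncated to the model's parameter bounds and
    fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    (alo, ahi), (rlo, rhi), (ilo, ihi) = DEFAULT_BOUNDS
    observers = []
    for i in range(config.n_participants):
        u_A, u_R, u_I, u_T = rng.random(4)
        curves = {}
        for session, (A, R, I) in config.population_curves.items():
            curves[session] = ShiftedExponentialParams(
                A=_trunc_ppf(u_A, A, config.sd_A, alo, ahi),
                R=_trunc_ppf(u_R, R, config.sd_R_rel * R, rlo, rhi),
                I=_trunc_ppf(u_I, I, config.sd_I_ms, ilo, ihi),
            )
        if GENERALIZATION_SESSIONS[0] not in curves and \
                EVALUATION_SESSIONS[-1] in curves:
            last = curves[EVALUATION_SESSIONS[-1]]
            curves[GENERALIZATION_SESSIONS[0]] = ShiftedExponentialParams(
                A=max(alo, last.A - config.generalization_decrement_A),
                R=last.R, I=last.I)
        training = {}
        for j, session in enumerate(TRAINING_SESSIONS, start=1):
            mean_d = config.trajectory.dprime(j)
            training[session] = _trunc_ppf(u_T, mean_d, config.sd_training,
                                           0.0, 8.0)
        observers.append(ObserverParams(
            participant_id=f"p{i + 1:02d}", curves=curves,
            training_dprime=training, criterion_bias=config.criterion_bias,
            lapse_rate=config.lapse_rate, rt_median_s=config.rt_median_s,
            rt_sigma=config.rt_sigma))
    return observers


def _diff_criterion(dprime: float) -> float:
    """Accuracy-maximizing criterion of the differencing rule at d'."""
    if dprime <= 0:
        return 1.0

    def neg_pc(k):
        h, f = forward_differencing(dprime, k)
        return -(h + 1.0 - f) / 2.0

    res = minimize_scalar(neg_pc, bounds=(1e-6, 12.0), method="bounded")
    return float(res.x)


def _response_probs(model: str, dprime: float, bias: float
                    ) -> tuple[float, float]:
    """(P(respond different | different), P(respond different | same))."""
    if model == "independent_observation":
        k = dprime / 2.0 + bias
        return forward_independent(dprime, k)
    if model == "differencing":
        k = _diff_criterion(dprime) + bias
        return forward_differencing(dprime, k)
    raise ValueError(f"no response generator for model {model!r}")


def _draw_rts(rng: np.random.Generator, n: int, median: float, sigma: float,
              outlier_prob: float) -> np.ndarray:
    rt = np.exp(rng.normal(np.log(median), sigma, size=n))
    rt = np.clip(rt, 0.2, 5.0)
    out = rng.random(n) < outlier_prob
    n_out = int(out.sum())
    if n_out:
        low = rng.random(n_out) < 0.5
        vals = np.where(low, rng.uniform(0.05, 0.195, n_out),
                        rng.uniform(5.005, 6.5, n_out))
        rt[out] = vals
    return np.round(rt, 4)


def _simulate_cells(rng: np.random.Generator, observer: ObserverParams,
                    session: int, phase: str, durations: Sequence[float],
                    dprimes: Sequence[float], per_duration: int,
                    model: str, rt_outlier_prob: float,
                    omission_prob: float) -> TrialTable:
    half = per_duration // 2
    rows = []
    for t_ms, d in zip(durations, dprimes):
        h, f = _response_probs(model, max(d, 0.0), observer.criterion_bias)
        lam = observer.lapse_rate
        p_diff = {"different": (1 - lam) * h + lam / 2,
                  "same": (1 - lam) * f + lam / 2}
        for pair in ("same", "different"):
            r = rng.random(half) < p_diff[pair]
            resp = np.where(r, "different", "same")
            if omission_prob > 0:
                omit = rng.random(half) < omission_prob
                resp = np.where(omit, "none", resp)
            rts = _draw_rts(rng, half, observer.rt_median_s,
                            observer.rt_sigma, rt_outlier_prob)
            for j in range(half):
                rows.append((observer.participant_id, session, phase, 0,
                             float(t_ms), pair, resp[j], float(rts[j])))
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame = frame.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2 ** 31 - 1))).reset_index(drop=True)
    frame["trial_index"] = np.arange(1, len(frame) + 1)
    return TrialTable(frame)


def simulate_evaluation_session(observer: ObserverParams, session_index: int,
                                spec: SessionSpec, seed: int,
                                model: str = "independent_observation",
                                rt_outlier_prob: float = 0.02,
                                omission_prob: float = 0.0) -> TrialTable:
    """One evaluation (or generalization) session for one observer.

    True d' per duration comes from the observer's encoding curve for that
    session; trial counts match ``spec`` exactly and trial order is
    randomized.
    """
    if session_index not in observer.curves:
        raise KeyError(f"observer has no curve for session {session_index}")
    curve = observer.curves[session_index]
    dprimes = [float(predict(curve, t)) for t in spec.durations_ms]
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed, session_index, _pid_int(observer.participant_id)]))
    table = _simulate_cells(rng, observer, session_index, spec.phase,
                            spec.durations_ms, dprimes,
                            spec.trials_per_duration, model,
                            rt_outlier_prob, omission_prob)
    table.meta["seed"] = seed
    return table


def _pid_int(pid: str) -> int:
    return abs(hash(pid)) % (2 ** 31) if not pid[1:].isdigit() else int(pid[1:])


def simulate_training_course(config: SimulationConfig,
                             observers: list[ObserverParams] | None = None
                             ) -> tuple[dict, pd.DataFrame]:
    """All six training sessions for every observer.

    Returns ``(tables, trajectory)`` where ``tables`` maps session index to
    a combined :class:`TrialTable` and ``trajectory`` holds each observer's
    true d' at 100 ms per training session.
    """
    if observers is None:
        observers = sample_population(config)
    spec = SessionSpec("training", [TRAINING_DURATION_MS],
                       config.training_trials)
    tables: dict[int, TrialTable] = {}
    truth_rows = []
    for session in TRAINING_SESSIONS:
        frames = []
        for obs in observers:
            d = obs.training_dprime[session]
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.seed, session, _pid_int(obs.participant_id)]))
            tab = _simulate_cells(rng, obs, session, "training",
                                  spec.durations_ms, [d],
                                  spec.trials_per_duration, config.sdt_model,
                                  config.rt_outlier_prob, config.omission_prob)
            frames.append(tab.frame)
            truth_rows.append({"participant_id": obs.participant_id,
                               "session_index": session, "true_dprime": d})
        tables[session] = TrialTable(pd.concat(frames, ignore_index=True),
                                     meta={"seed": config.seed})
    return tables, pd.DataFrame(truth_rows)


@dataclass
class StudyBundle:
    """A complete synthetic study: trials plus the generating manifest."""

    trials: TrialTable                  # all sessions, all participants
    observers: list
    config: SimulationConfig
    training_truth: pd.DataFrame

    @property
    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "observers": [o.to_dict() for o in self.observers],
        }

    def session_table(self, session: int) -> TrialTable:
        mask = self.trials.frame["session_index"] == session
        return self.trials.subset(mask, f"session=={session}")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for session in sorted(self.trials.frame["session_index"].unique()):
            write_trials(self.session_table(int(session)),
                         outdir / f"session_{int(session):02d}.csv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2))


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Full 11-session synthetic study under the default schedule.

    Training, evaluation and generalization sessions are assembled per the
    interleaved schedule; the generalization session includes only the
    first ``config.n_generalization`` participants.  The manifest records
    every generating parameter for parameter-recovery scoring.
    """
    observers = sample_population(config)
    eval_spec = SessionSpec("evaluation", list(config.durations_ms),
                            config.trials_per_duration)
    gen_spec = SessionSpec("generalization", list(config.durations_ms),
                           config.trials_per_duration)
    frames = []
    training_tables, truth = simulate_training_course(config, observers)
    for session in TRAINING_SESSIONS:
        frames.append(training_tables[session].frame)
    for session in EVALUATION_SESSIONS:
        for obs in observers:
            frames.append(simulate_evaluation_session(
                obs, session, eval_spec, config.seed, config.sdt_model,
                config.rt_outlier_prob, config.omission_prob).frame)
    gen_session = GENERALIZATION_SESSIONS[0]
    for obs in observers[:config.n_generalization]:
        frames.append(simulate_evaluation_session(
            obs, gen_session, gen_spec, config.seed, config.sdt_model,
            config.rt_outlier_prob, config.omission_prob).frame)
    combined = pd.concat(frames, ignore_index=True)
    combined = combined.sort_values(
        ["session_index", "participant_id", "trial_index"],
        kind="stable").reset_index(drop=True)
    trials = TrialTable(combined, meta={"seed": config.seed,
                                        "generator": "simulate_study"})
    return StudyBundle(trials, observers, config, truth)
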