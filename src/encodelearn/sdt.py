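"""Signal-detection sensitivity for same-different discrimination data.

Three decision models are provided for converting a (hit rate, false-alarm
rate) pair into a sensitivity index d':

``yesno``
    The plain yes-no index z(H) - z(FA).  This treats each trial as a
    single-observation detection decision; it underestimates the underlying
    stimulus separation in a two-observation same-different design but is
    what several published analysis scripts compute.

``differencing``
    The observer responds "different" when |x1 - x2| exceeds a criterion k.
    Forward equations: FA = 2 Phi(-k/sqrt(2)),
    H = Phi((d'-k)/sqrt(2)) + Phi((-d'-k)/sqrt(2)).

``independent_observation``
    The observer categorizes each of the two observations independently
    against a fixed criterion k and responds "different" when the two
    categorizations disagree.  With a = Phi(-k) and b = Phi(d'-k):

        H  = a(1-b) + (1-a)b          (different pairs)
        FA = a(1-a) + b(1-b)          (same pairs, equal mixture)

    At the unbiased criterion k = d'/2 this attains the familiar optimum
    pc_max = Phi(d'/2)^2 + Phi(-d'/2)^2.  Inversion from (H, FA) to
    (d', k) is closed-form: with s = a + b and p = a b,
    H = s - 2p and FA = s - (s^2 - 2p), hence s^2 - 2s + (H + FA) = 0,
    so s = 1 -/+ sqrt(1 - H - FA), p = (s - H)/2, and a, b are the roots of
    x^2 - s x + p.  Then d' = z(b) - z(a) (identical for both s branches)
    and k = -z(a).

Hit/false-alarm rates of exactly 0 or 1 make d' infinite; two standard
corrections are provided (half-count 1/(2N) replacement, and the log-linear
(count + 0.5)/(N + 1) rule applied to every cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_data import TrialTable, summarize_counts

__all__ = [
    "MODELS",
    "CORRECTIONS",
    "RateEstimate",
    "SensitivityEstimate",
    "DegenerateRateError",
    "ModelRangeError",
    "correct_rates",
    "dprime_yesno",
    "dprime_samediff_differencing",
    "dprime_samediff_independent",
    "forward_differencing",
    "forward_independent",
    "unbiased_criterion",
    "pc_max_independent",
    "sensitivity_table",
    "write_sensitivity_tsv",
]

MODELS = ("yesno", "differencing", "independent_observation")
CORRECTIONS = ("none", "half_count", "log_linear")

#: Upper end of the bracket searched when solving a forward model for d'.
DPRIME_MAX = 10.0
_TOL = 1e-9


class DegenerateRateError(ValueError):
    """A rate of exactly 0 or 1 reached a computation that needs (0, 1)."""


class ModelRangeError(ValueError):
    """No (d', k) within the model's range reproduces the observed rates."""


@dataclass(frozen=True)
class RateEstimate:
    """Hit / false-alarm proportions with their correction provenance."""

    h: float
    f: float
    correction: str
    n_hit: int
    n_fa: int
    n_different_trials: int
    n_same_trials: int

    @property
    def degenerate(self) -> bool:
        return self.h in (0.0, 1.0) or self.f in (0.0, 1.0)


@dataclass(frozen=True)
class SensitivityEstimate:
    """A d' value with the decision model and criterion that produced it."""

    dprime: float
    criterion: float
    model: str
    cell: tuple = ()


def correct_rates(n_hit: int, n_fa: int, n_different_trials: int,
                  n_same_trials: int, method: str = "half_count") -> RateEstimate:
    """Convert counts to hit/false-alarm rates, guarding 0 and 1.

    ``none`` returns raw proportions (possibly degenerate); ``half_count``
    replaces 0 with 1/(2N) and 1 with 1 - 1/(2N) using each cell's own N;
    ``log_linear`` applies (count + 0.5)/(N + 1) to every cell.
    """
    if method not in CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}")
    if n_different_trials < 1 or n_same_trials < 1:
        raise ValueError("need at least one same and one different trial")
    if not (0 <= n_hit <= n_different_trials and 0 <= n_fa <= n_same_trials):
        raise ValueError("counts exceed trial totals")
    if method == "log_linear":
        h = (n_hit + 0.5) / (n_different_trials + 1)
        f = (n_fa + 0.5) / (n_same_trials + 1)
    else:
        h = n_hit / n_different_trials
        f = n_fa / n_same_trials
        if method == "half_count":
            h = min(max(h, 1 / (2 * n_different_trials)),
                    1 - 1 / (2 * n_different_trials))
            f = min(max(f, 1 / (2 * n_same_trials)),
                    1 - 1 / (2 * n_same_trials))
    return RateEstimate(h, f, method, n_hit, n_fa,
                        n_different_trials, n_same_trials)


def _check_open_unit(h: float, f: float) -> None:
    if not (0.0 < h < 1.0 and 0.0 < f < 1.0):
        raise DegenerateRateError(
            "rates must lie strictly in (0, 1); apply a correction "
            "(half_count or log_linear) first")


def dprime_yesno(h: float, f: float, cell: tuple = ()) -> SensitivityEstimate:
    """Yes-no sensitivity d' = z(h) - z(f) with criterion c = -(z(h)+z(f))/2."""
    _check_open_unit(h, f)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return SensitivityEstimate(zh - zf, -(zh + zf) / 2, "yesno", cell)


# -- differencing rule -------------------------------------------------------

def forward_differencing(dprime: float, k: float) -> tuple[float, float]:
    """(H, FA) produced by the |x1 - x2| > k rule at separation d'."""
    s2 = math.sqrt(2.0)
    fa = 2 * norm.cdf(-k / s2)
    h = norm.cdf((dprime - k) / s2) + norm.cdf((-dprime - k) / s2)
    return h, fa


def dprime_samediff_differencing(h: float, f: float, cell: tuple = (),
                                 signed: bool = False) -> SensitivityEstimate:
    """Invert the differencing rule.

    By convention h <= f maps to d' = 0; with ``signed=True`` the mirrored
    problem (f, h) is solved and its d' negated, which makes the estimator
    point-symmetric around zero (useful when averaging noisy estimates of
    near-zero sensitivity).
    """
    _check_open_unit(h, f)
    if h < f and signed:
        est = dprime_samediff_differencing(f, h, cell)
        return SensitivityEstimate(-est.dprime, est.criterion,
                                   "differencing", cell)
    if h <= f:
        k = -math.sqrt(2.0) * norm.ppf(f / 2)
        return SensitivityEstimate(0.0, k, "differencing", cell)
    k = -math.sqrt(2.0) * norm.ppf(f / 2)

    def gap(d: float) -> float:
        return forward_differencing(d, k)[0] - h

    lo, hi = 0.0, DPRIME_MAX
    if gap(hi) < 0:
        raise ModelRangeError(f"no d' in [0, {DPRIME_MAX}] reaches h={h}")
    from scipy.optimize import brentq
    d = brentq(gap, lo, hi, xtol=_TOL, rtol=4 * np.finfo(float).eps)
    return SensitivityEstimate(float(d), k, "differencing", cell)


# -- independent-observation rule --------------------------------------------

def forward_independent(dprime: float, k: float) -> tuple[float, float]:
    """(H, FA) for independent categorization of the two observations."""
    a = norm.cdf(-k)            # P("category 2" | first stimulus class)
    b = norm.cdf(dprime - k)    # P("category 2" | second stimulus class)
    h = a * (1 - b) + (1 - a) * b
    fa = a * (1 - a) + b * (1 - b)
    return h, fa


def unbiased_criterion(dprime: float) -> float:
    """Criterion maximizing accuracy under the independent-observation rule."""
    return dprime / 2.0


def pc_max_independent(dprime: float) -> float:
    """Maximum proportion correct: Phi(d'/2)^2 + Phi(-d'/2)^2."""
    p = norm.cdf(dprime / 2.0)
    return p * p + (1 - p) * (1 - p)


def dprime_samediff_independent(h: float, f: float, cell: tuple = (),
                                signed: bool = False) -> SensitivityEstimate:
    """Closed-form inversion of the independent-observation rule.

    Returns d' = 0 for h <= f (``signed=True`` instead negates the solution
    of the mirrored problem (f, h), making the estimator point-symmetric
    around zero).  The exact inverse is accepted only if forward-evaluating
    it reproduces (h, f) to within 1e-7.  Not every (h, f) pair is
    reachable by the model — the manifold excludes h + f > 1 entirely and
    folds over a region of conservative rate pairs — and an off-manifold
    pair is resolved on the unbiased boundary: d' from proportion correct
    pc = (h + 1 - f)/2 via pc_max, i.e. d' = 2 z((1 + sqrt(2 pc - 1))/2),
    with criterion reported at d'/2.  This boundary estimate is continuous
    with the exact inverse at h + f = 1.
    """
    _check_open_unit(h, f)
    if h < f and signed:
        est = dprime_samediff_independent(f, h, cell)
        return SensitivityEstimate(-est.dprime, est.criterion,
                                   "independent_observation", cell)
    if h <= f:
        return SensitivityEstimate(0.0, 0.0, "independent_observation", cell)
    d = k = None
    under = 1.0 - h - f
    if under >= 0.0:
        s = 1.0 - math.sqrt(under)
        p = (s - h) / 2.0
        disc = s * s - 4.0 * p
        if disc >= 0.0:
            root = math.sqrt(disc)
            a = (s - root) / 2.0
            b = (s + root) / 2.0
            if 0.0 < a < 1.0 and 0.0 < b < 1.0:
                d_try = float(norm.ppf(b) - norm.ppf(a))
                k_try = float(-norm.ppf(a))  # conservative branch, k >= d'/2
                h2, f2 = forward_independent(d_try, k_try)
                if abs(h2 - h) < 1e-7 and abs(f2 - f) < 1e-7:
                    d, k = d_try, k_try
    if d is None:
        # off-manifold: boundary solution at the unbiased criterion
        pc = (h + 1.0 - f) / 2.0
        g = (1.0 + math.sqrt(2.0 * pc - 1.0)) / 2.0
        d = float(2.0 * norm.ppf(g))
        k = d / 2.0
    if d > DPRIME_MAX:
        raise ModelRangeError(f"solution d'={d:.2f} outside [0, {DPRIME_MAX}]")
    return SensitivityEstimate(d, k, "independent_observation", cell)


_ESTIMATORS = {
    "yesno": dprime_yesno,
    "differencing": dprime_samediff_differencing,
    "independent_observation": dprime_samediff_independent,
}


def sensitivity_table(
    table: TrialTable,
    model: str = "independent_observation",
    correction: str = "half_count",
    grouping: Sequence[str] = ("participant_id", "session_index",
                               "encoding_duration_ms"),
    min_trials: int = 10,
    signed: bool = True,
) -> pd.DataFrame:
    """One sensitivity estimate per non-empty analysis cell.

    The input should already be response-time filtered.  Cells with fewer
    than ``min_trials`` responded trials are kept but flagged
    (``low_n = True``); cells whose rates fall outside the chosen model's
    range get ``dprime = NaN`` and ``error`` text rather than a fabricated
    value.  With ``signed=True`` (default) cells with h < f get the negated
    mirrored estimate instead of a hard 0, so that noise around zero true
    sensitivity averages out in group means.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    counts = summarize_counts(table, grouping)
    rows = []
    for tup in counts.itertuples(index=False):
        rec = tup._asdict()
        n_resp = rec["n_different_trials"] + rec["n_same_trials"]
        row = {g: rec[g] for g in grouping}
        row.update(n_trials=n_resp, n_omit=rec["n_omit"],
                   low_n=n_resp < min_trials, model=model,
                   correction=correction, error="")
        if rec["n_different_trials"] < 1 or rec["n_same_trials"] < 1:
            row.update(h=np.nan, f=np.nan, dprime=np.nan, criterion=np.nan,
                       error="missing same or different trials")
            rows.append(row)
            continue
        rate = correct_rates(rec["n_hit"], rec["n_fa"],
                             rec["n_different_trials"], rec["n_same_trials"],
                             correction)
        row.update(h=rate.h, f=rate.f)
        try:
            kw = {} if model == "yesno" else {"signed": signed}
            est = _ESTIMATORS[model](rate.h, rate.f,
                                     cell=tuple(rec[g] for g in grouping), **kw)
            row.update(dprime=est.dprime, criterion=est.criterion)
        except (DegenerateRateError, ModelRangeError) as exc:
            row.update(dprime=np.nan, criterion=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def write_sensitivity_tsv(sens: pd.DataFrame, path: str | Path) -> None:
    """Serialize a sensitivity table in the canonical TSV column order."""
    lead = [c for c in ("participant_id", "session_index",
                        "encoding_duration_ms") if c in sens.columns]
    cols = lead + ["n_trials", "h", "f", "dprime", "model", "correction"]
    extra = [c for c in sens.columns if c not in cols]
    sens[cols + extra].to_csv(path, sep="\t", index=False)


def pooled_dprime_by_session(table: TrialTable, model: str = "independent_observation",
                             correction: str = "half_count"
                             ) -> Mapping[str, Mapping[int, float]]:
    """Per-participant map session -> pooled d' (all durations combined).

    This is the quantity the inclusion criterion compares between the
    baseline and criterion sessions.
    """
    sens = sensitivity_table(table, model=model, correction=correction,
                             grouping=("participant_id", "session_index"))
    out: dict[str, dict[int, float]] = {}
    for row in sens.itertuples(index=False):
        if np.isnan(row.dprime):
            continue
        out.setdefault(str(row.participant_id), {})[int(row.session_index)] = \
            float(row.dprime)
    return out
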