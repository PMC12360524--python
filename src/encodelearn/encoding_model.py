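"""Shifted-exponential model of sensitivity versus encoding duration.

The encoding curve

    d'(t) = A * (1 - exp(-R * (t - I)))   for t > I,   else 0

summarizes how discrimination sensitivity grows with the time t (ms) a
stimulus is available before a backward mask: ``I`` is the onset of
information availability (ms), ``R`` the rate of information extraction
(fitted per ms, conventionally reported multiplied by 1000 as d'/s), and
``A`` the asymptotic sensitivity (d' units).

Fitting follows the usual nonlinear least-squares practice for this model:
the *smooth* expression A(1-exp(-R(t-I))) is the least-squares objective —
a Levenberg-Marquardt-style solver needs a differentiable residual, and at
every practical optimum all design durations exceed I, where the smooth and
piecewise forms coincide.  ``predict`` on a fitted result exposes the
piecewise curve (exactly 0 at and below the onset).  The optimum is
searched from many Latin-hypercube starting points over the parameter box

    A in [1, 10],   R in [1e-4, 10] per ms,   I in [1e-7, 500] ms,

and the lowest-SSE converged solution wins (ties broken by smallest I).
Goodness of fit is R^2 = 1 - SSE / SST with SST about the mean of the
observed values; parameter uncertainty is the linearized covariance
s^2 (J'J)^-1 at the optimum with s^2 = SSE/(n - 3).

The module follows the statsmodels idiom: build an
:class:`EncodingCurveModel` from data, call :meth:`~EncodingCurveModel.fit`,
and work with the returned :class:`EncodingCurveResults` (``params``,
``bse``, ``rsquared``, ``summary()``, ``predict``, ``invert_duration``,
``plot``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, qmc

__all__ = [
    "DEFAULT_BOUNDS",
    "ShiftedExponentialParams",
    "EncodingCurveModel",
    "EncodingCurveResults",
    "predict",
    "fit_encoding_curve",
    "r_squared",
    "invert_duration",
    "dprime_pc_conversion",
    "pc_from_dprime",
]

#: Parameter box (lower, upper) for (A, R per ms, I ms).
DEFAULT_BOUNDS = ((1.0, 10.0), (1e-4, 10.0), (1e-7, 500.0))

_SSE_TIE = 1e-10


@dataclass(frozen=True)
class ShiftedExponentialParams:
    """Asymptote (d'), rate (per ms) and onset (ms) of an encoding curve."""

    A: float
    R: float  # per ms
    I: float  # ms

    @property
    def rate_per_s(self) -> float:
        """Rate in the conventional reporting unit d'/s (= 1000 R)."""
        return 1000.0 * self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.R, self.I])


def predict(params: ShiftedExponentialParams, t) -> np.ndarray | float:
    """Piecewise encoding curve: A(1-exp(-R(t-I))) for t > I, else exactly 0."""
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        val = params.A * (1.0 - np.exp(-params.R * (t_arr - params.I)))
    out = np.where(t_arr > params.I, val, 0.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _smooth(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, R, I = theta
    with np.errstate(over="ignore"):
        return A * (1.0 - np.exp(-R * (t - I)))


def _jacobian(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, R, I = theta
    with np.errstate(over="ignore"):
        e = np.exp(-R * (t - I))
    return np.column_stack([1.0 - e, A * (t - I) * e, -A * R * e])


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """R^2 = 1 - sum((obs-pred)^2) / sum((obs-mean(obs))^2)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("degenerate observations: zero total sum of squares")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def invert_duration(params: ShiftedExponentialParams, target_dprime: float) -> float:
    """Encoding duration at which the curve reaches ``target_dprime``.

    t = I - ln(1 - target/A) / R; requires 0 <= target < A.
    """
    if not 0.0 <= target_dprime < params.A:
        raise ValueError(f"target d' must lie in [0, A={params.A:g})")
    return params.I - math.log(1.0 - target_dprime / params.A) / params.R


def dprime_pc_conversion(pc: float) -> float:
    """Unbiased equal-variance correspondence d' = 2 z(pc), for pc in (0.5, 1)."""
    if not 0.5 < pc < 1.0:
        raise ValueError("proportion correct must lie in (0.5, 1)")
    return float(2.0 * norm.ppf(pc))


def pc_from_dprime(dprime: float) -> float:
    """Inverse of :func:`dprime_pc_conversion`: pc = Phi(d'/2)."""
    if dprime <= 0:
        raise ValueError("d' must be positive")
    return float(norm.cdf(dprime / 2.0))


class EncodingCurveModel:
    """Shifted-exponential growth model for (duration, mean d') data.

    Parameters
    ----------
    dprime : sequence of float
        Observed sensitivities (typically group means), one per duration.
    durations_ms : sequence of float
        Strictly increasing encoding durations in ms.
    """

    def __init__(self, dprime: Sequence[float], durations_ms: Sequence[float]) -> None:
        t = np.asarray(durations_ms, dtype=float)
        y = np.asarray(dprime, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("dprime and durations_ms must be equal-length 1-D")
        if t.size < 4:
            raise ValueError("need at least 4 points to fit 3 parameters")
        if not np.all(np.diff(t) > 0):
            raise ValueError("durations must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("dprime values must be finite")
        self.durations_ms = t
        self.dprime = y

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       duration_col: str = "encoding_duration_ms",
                       dprime_col: str = "dprime") -> "EncodingCurveModel":
        frame = frame.sort_values(duration_col)
        return cls(frame[dprime_col].to_numpy(), frame[duration_col].to_numpy())

    def fit(self, bounds=DEFAULT_BOUNDS, n_starts: int = 64, seed: int = 0,
            bounded: bool = True) -> "EncodingCurveResults":
        """Multi-start bounded Levenberg-Marquardt least squares.

        Starting points are a Latin-hypercube sample over the bound box
        (the rate dimension sampled log-uniformly); with ``bounded=False``
        the box only constrains the starting points and the parameters
        themselves are unrestricted (plain LM).
        """
        t, y = self.durations_ms, self.dprime
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        sampler = qmc.LatinHypercube(d=3, seed=seed)
        u = sampler.random(n_starts)
        starts = np.empty_like(u)
        starts[:, 0] = lo[0] + u[:, 0] * (hi[0] - lo[0])
        starts[:, 1] = 10 ** (np.log10(lo[1]) + u[:, 1]
                              * (np.log10(hi[1]) - np.log10(lo[1])))
        starts[:, 2] = lo[2] + u[:, 2] * (hi[2] - lo[2])

        def resid(theta):
            return _smooth(theta, t) - y

        best, n_used = None, 0
        with np.errstate(over="ignore", invalid="ignore"):
            best, n_used = self._multistart(resid, starts, lo, hi, t, bounded)

        if best is None:
            return EncodingCurveResults(
                self, ShiftedExponentialParams(np.nan, np.nan, np.nan),
                bse=(np.nan,) * 3, sse=np.nan, converged=False,
                n_starts_used=n_used, bounds=bounds, at_bound=(False,) * 3)

        theta = best.x
        sse = float(np.sum(best.fun ** 2))
        at_bound = tuple(bool(np.isclose(theta[i], lo[i], rtol=0, atol=1e-10)
                              or np.isclose(theta[i], hi[i], rtol=0, atol=1e-10))
                         for i in range(3)) if bounded else (False,) * 3
        bse = _standard_errors(theta, t, sse)
        return EncodingCurveResults(
            self, ShiftedExponentialParams(*theta), bse=bse, sse=sse,
            converged=True, n_starts_used=n_used, bounds=bounds,
            at_bound=at_bound)

    @staticmethod
    def _multistart(resid, starts, lo, hi, t, bounded):
        best, n_used = None, 0
        for theta0 in starts:
            try:
                if bounded:
                    sol = least_squares(resid, theta0, jac=lambda th: _jacobian(th, t),
                                        bounds=(lo, hi), method="trf",
                                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
                else:
                    sol = least_squares(resid, theta0, jac=lambda th: _jacobian(th, t),
                                        method="lm", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if not (sol.success and np.all(np.isfinite(sol.fun))):
                continue
            n_used += 1
            if (best is None or sol.cost < best.cost - _SSE_TIE / 2
                    or (abs(sol.cost - best.cost) < _SSE_TIE / 2
                        and sol.x[2] < best.x[2])):
                best = sol
        return best, n_used


def _standard_errors(theta: np.ndarray, t: np.ndarray, sse: float
                     ) -> tuple[float, float, float]:
    """Linearized SEs: sqrt(diag(s^2 (J'J)^-1)), s^2 = SSE/(n-3)."""
    n = t.size
    if n <= 3:
        return (np.nan,) * 3
    J = _jacobian(theta, t)
    JtJ = J.T @ J
    s2 = sse / (n - 3)
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        return (np.nan,) * 3
    diag = np.diag(cov)
    if np.any(diag < 0) or not np.all(np.isfinite(diag)):
        return (np.nan,) * 3
    return tuple(float(x) for x in np.sqrt(diag))


class EncodingCurveResults:
    """Fit of a shifted-exponential encoding curve.

    Attributes
    ----------
    params : ShiftedExponentialParams
        (A, R per ms, I ms) at the optimum.
    bse : tuple
        Linearized standard errors of (A, R, I), same units as the
        parameters (``se_rate_per_s`` gives the rate SE in d'/s).
    sse, rsquared, nobs, converged, n_starts_used, at_bound
    """

    def __init__(self, model: EncodingCurveModel, params: ShiftedExponentialParams,
                 bse, sse, converged, n_starts_used, bounds, at_bound) -> None:
        self.model = model
        self.params = params
        self.bse = tuple(bse)
        self.sse = sse
        self.converged = converged
        self.n_starts_used = n_starts_used
        self.bounds = bounds
        self.at_bound = at_bound

    # -- derived quantities --------------------------------------------------

    @property
    def nobs(self) -> int:
        return int(self.model.durations_ms.size)

    @property
    def rsquared(self) -> float:
        if not self.converged:
            return np.nan
        return r_squared(self.model.dprime,
                         _smooth(self.params.as_array(), self.model.durations_ms))

    @property
    def rate_per_s(self) -> float:
        return self.params.rate_per_s

    @property
    def se_rate_per_s(self) -> float:
        return 1000.0 * self.bse[1]

    def predict(self, t) -> np.ndarray | float:
        """Fitted piecewise curve evaluated at duration(s) ``t`` (ms)."""
        return predict(self.params, t)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.durations_ms)

    @property
    def resid(self) -> np.ndarray:
        return self.model.dprime - _smooth(self.params.as_array(),
                                           self.model.durations_ms)

    def invert_duration(self, target_dprime: float) -> float:
        """Duration (ms) at which the fitted curve reaches ``target_dprime``."""
        return invert_duration(self.params, target_dprime)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Shifted-exponential encoding curve",
            "=" * 50,
            f"n points: {self.nobs:>3d}    converged: {self.converged}"
            f"    starts used: {self.n_starts_used}",
            f"SSE: {self.sse:.6g}    R^2: {self.rsquared:.4f}",
            "-" * 50,
            f"{'parameter':<22}{'estimate':>12}{'SE':>12}",
            f"{'asymptote A (d-prime)':<22}{p.A:>12.4f}{se[0]:>12.4f}",
            f"{'rate R (d-prime/s)':<22}{p.rate_per_s:>12.4f}{1000 * se[1]:>12.4f}",
            f"{'onset I (ms)':<22}{p.I:>12.4f}{se[2]:>12.4f}",
        ]
        if any(self.at_bound):
            which = [n for n, f in zip("ARI", self.at_bound) if f]
            lines.append(f"note: parameter(s) at bound: {', '.join(which)}")
        return "\n".join(lines)

    def to_dict(self, session=None) -> dict:
        d = {
            "A": self.params.A, "R_per_s": self.rate_per_s,
            "I_ms": self.params.I, "se_A": self.bse[0],
            "se_R_per_s": self.se_rate_per_s, "se_I_ms": self.bse[2],
            "r_squared": self.rsquared, "sse": self.sse,
            "n_points": self.nobs, "converged": self.converged,
            "at_bound": {"A": self.at_bound[0], "R": self.at_bound[1],
                         "I": self.at_bound[2]},
        }
        if session is not None:
            d = {"session": session, **d}
        return d

    def to_json(self, session=None) -> str:
        return json.dumps(self.to_dict(session), indent=2)

    def plot(self, ax=None):
        """Data points and fitted curve on a log-duration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.durations_ms
        grid = np.linspace(0, t.max(), 500)
        ax.plot(t, self.model.dprime, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="fitted")
        ax.set_xlabel("encoding duration (ms)")
        ax.set_ylabel("sensitivity (d')")
        ax.legend()
        return ax


def fit_encoding_curve(durations: Sequence[float], mean_dprime: Sequence[float],
                       bounds=DEFAULT_BOUNDS, n_starts: int = 64, seed: int = 0,
                       bounded: bool = True) -> EncodingCurveResults:
    """Functional wrapper: fit the curve to (durations, mean d') data."""
    return EncodingCurveModel(mean_dprime, durations).fit(
        bounds=bounds, n_starts=n_starts, seed=seed, bounded=bounded)
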