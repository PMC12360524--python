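"""Inferential statistics for within-subject designs.

Covers the inference layer of the analysis: repeated-measures ANOVA with
one or two within-subject factors (Greenhouse-Geisser sphericity
correction and Mauchly's test per effect), paired and one-sample t-tests
with Cohen's d and 95% CIs, Benjamini-Hochberg false-discovery-rate
control, and Shapiro-Wilk normality checks.

The ANOVA is the textbook univariate decomposition for complete, balanced
data: each within-subject effect is tested against its own
effect-by-subject interaction.  Greenhouse-Geisser epsilon for an effect
with q = df numerator degrees of freedom is computed from the sample
covariance of the orthonormally contrasted scores M = C S C':

    epsilon = tr(M)^2 / (q * tr(M^2)),        1/q <= epsilon <= 1,

and Mauchly's W = det(M) / (tr(M)/q)^q with the standard chi-square
approximation.  Corrected p-values use F with both degrees of freedom
multiplied by epsilon; both corrected and uncorrected p are always
reported (the correction is conventionally *applied* when Mauchly's
p < .05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "EffectResult",
    "AnovaResult",
    "TTestResult",
    "BHResult",
    "rm_anova",
    "paired_t",
    "one_sample_t",
    "bh_adjust",
    "shapiro_wilk",
]


@dataclass
class EffectResult:
    """One within-subject effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    gg_epsilon: float
    p_gg: float
    partial_eta_sq: float
    mauchly_W: float
    mauchly_p: float
    ss_effect: float
    ss_error: float

    @property
    def df_num_gg(self) -> float:
        return self.gg_epsilon * self.df_num

    @property
    def df_den_gg(self) -> float:
        return self.gg_epsilon * self.df_den


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA table, one :class:`EffectResult` per effect."""

    effects: dict = field(default_factory=dict)
    n_subjects: int = 0

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append({
                "effect": e.effect, "F": e.F, "df_num": e.df_num,
                "df_den": e.df_den, "p": e.p_uncorrected,
                "gg_epsilon": e.gg_epsilon, "df_num_gg": e.df_num_gg,
                "df_den_gg": e.df_den_gg, "p_gg": e.p_gg,
                "partial_eta_sq": e.partial_eta_sq,
                "mauchly_W": e.mauchly_W, "mauchly_p": e.mauchly_p,
            })
        return pd.DataFrame(rows)


def _eps_mauchly_from_contrasts(Z: np.ndarray) -> tuple[float, float, float]:
    """(GG epsilon, Mauchly W, Mauchly p) from contrasted scores.

    ``Z`` is an n_subjects x q matrix of orthonormally contrasted cell
    scores for one effect.  Mauchly's p uses the standard chi-square
    approximation with the second-order (Anderson) correction term.
    """
    n, q = Z.shape
    if q == 1:
        return 1.0, 1.0, 1.0
    M = np.cov(Z.T, ddof=1)
    tr = np.trace(M)
    eps = tr ** 2 / (q * np.trace(M @ M))
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    detM = np.linalg.det(M)
    if detM <= 0 or n - 1 < q:
        return eps, np.nan, np.nan
    W = float(detM / (tr / q) ** q)
    f = 1.0 - (2 * q ** 2 + q + 2) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = q * (q + 1) / 2 - 1
    w2 = ((q + 2) * (q - 1) * (q - 2) * (2 * q ** 3 + 6 * q ** 2 + 3 * q + 2)
          / (288.0 * ((n - 1) * q * f) ** 2))
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return eps, W, p


def _epsilon_mauchly(scores: np.ndarray) -> tuple[float, float, float]:
    """As above, from raw n x k cell scores (contrast applied here)."""
    n, k = scores.shape
    if k - 1 == 1:
        return 1.0, 1.0, 1.0
    C = helmert(k, full=False)  # (k-1) x k, orthonormal, orthogonal to 1
    return _eps_mauchly_from_contrasts(scores @ C.T)


def _effect(name: str, ss_eff: float, df_eff: float, ss_err: float,
            df_err: float, scores: np.ndarray) -> EffectResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
    p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    eps, W, mp = _epsilon_mauchly(scores)
    p_gg = float(sps.f.sf(F, eps * df_eff, eps * df_err)) if np.isfinite(F) else 0.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return EffectResult(name, float(F), float(df_eff), float(df_err), p,
                        eps, p_gg, float(eta), W, mp,
                        float(ss_eff), float(ss_err))


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str) -> AnovaResult:
    """Repeated-measures ANOVA with one or two within-subject factors.

    ``data`` is long format; the design must be complete and balanced
    (every subject observed once in every cell).  Returns one effect per
    factor plus, for two factors, their interaction.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("within must name 1 or 2 factors")
    for col in [dv, subject, *within]:
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")

    cell = data.groupby([subject, *within], sort=True)[dv]
    sizes = cell.size()
    if (sizes != 1).any():
        bad = sizes[sizes != 1].index[0]
        raise ValueError(f"design not complete/balanced at cell {bad}")
    wide = cell.mean().unstack(within)  # subjects x cells, level-sorted
    subjects = wide.index
    n = len(subjects)
    if wide.isna().any().any():
        missing = wide.stack(list(range(wide.columns.nlevels)), future_stack=True)
        missing = missing[missing.isna()].index[0]
        raise ValueError(f"missing cell for {missing}")

    if len(within) == 1:
        Y = wide.to_numpy()  # n x k
        k = Y.shape[1]
        if k < 2:
            raise ValueError("factor needs at least 2 levels")
        grand = Y.mean()
        cond = Y.mean(axis=0)
        subj = Y.mean(axis=1)
        ss_cond = n * np.sum((cond - grand) ** 2)
        ss_err = np.sum((Y - cond[None, :] - subj[:, None] + grand) ** 2)
        res = AnovaResult(n_subjects=n)
        res.effects[within[0]] = _effect(within[0], ss_cond, k - 1, ss_err,
                                         (n - 1) * (k - 1), Y)
        return res

    # two factors
    a_levels = wide.columns.levels[0] if wide.columns.nlevels == 2 else None
    Y = wide.to_numpy()
    a = len(wide.columns.levels[0])
    b = len(wide.columns.levels[1])
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")
    Y = Y.reshape(n, a, b)
    grand = Y.mean()
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_s = Y.mean(axis=(1, 2))
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    resid = (Y - m_ab[None] - m_as[:, :, None] - m_bs[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = np.sum(resid ** 2)

    res = AnovaResult(n_subjects=n)
    res.effects[within[0]] = _effect(
        within[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_as)
    res.effects[within[1]] = _effect(
        within[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_bs)
    # interaction epsilon/Mauchly from the doubly-contrasted cell scores
    Ca = helmert(a, full=False)
    Cb = helmert(b, full=False)
    inter_scores = np.einsum("pa,nab,qb->npq", Ca, Y, Cb).reshape(n, -1)
    q_ab = (a - 1) * (b - 1)
    ms_ab = ss_ab / q_ab
    ms_abs = ss_abs / (q_ab * (n - 1))
    F = ms_ab / ms_abs if ms_abs > 0 else (0.0 if ms_ab == 0 else np.inf)
    p = float(sps.f.sf(F, q_ab, q_ab * (n - 1))) if np.isfinite(F) else 0.0
    eps, W, mp = _eps_mauchly_from_contrasts(inter_scores)
    p_gg = float(sps.f.sf(F, eps * q_ab, eps * q_ab * (n - 1))) \
        if np.isfinite(F) else 0.0
    name = f"{within[0]}*{within[1]}"
    res.effects[name] = EffectResult(
        name, float(F), float(q_ab), float(q_ab * (n - 1)), p, eps, p_gg,
        float(ss_ab / (ss_ab + ss_abs)) if ss_ab + ss_abs > 0 else 0.0,
        W, mp, float(ss_ab), float(ss_abs))
    return res


@dataclass
class TTestResult:
    """t statistic with two-tailed p, 95% CI of the mean (difference), and d."""

    t: float
    df: int
    p_two_tailed: float
    ci_low: float
    ci_high: float
    cohens_d: float
    kind: str
    mean: float
    sd: float
    n: int


def _t_from_summary(mean: float, sd: float, n: int, kind: str) -> TTestResult:
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0 or (sd == 0 and mean != 0):
        raise ValueError("degenerate: zero variance with nonzero mean")
    if sd == 0:
        # identical scores: t = 0, p = 1, d = 0 by convention
        return TTestResult(0.0, n - 1, 1.0, 0.0, 0.0, 0.0, kind, 0.0, 0.0, n)
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return TTestResult(float(t), df, p, float(mean - tcrit * se),
                       float(mean + tcrit * se), float(mean / sd), kind,
                       float(mean), float(sd), n)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed paired t-test; Cohen's d = mean(diff) / sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D vectors")
    d = x - y
    return _t_from_summary(float(d.mean()), float(d.std(ddof=1)), d.size,
                           "paired")


def one_sample_t(x=None, mu0: float = 0.0, *, mean: float | None = None,
                 sd: float | None = None, n: int | None = None) -> TTestResult:
    """Two-tailed one-sample t-test against ``mu0``.

    Accepts either a data vector ``x`` or printed summary statistics
    (``mean``, ``sd``, ``n``) — the latter is what published tables
    provide.  The CI is for the mean minus ``mu0``.
    """
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("x must be a 1-D vector with n >= 2")
        mean, sd, n = float(x.mean()), float(x.std(ddof=1)), x.size
    if mean is None or sd is None or n is None:
        raise ValueError("provide x or all of (mean, sd, n)")
    return _t_from_summary(mean - mu0, sd, int(n), "one_sample")


@dataclass
class BHResult:
    """Benjamini-Hochberg step-up decision at false-discovery level q."""

    p_raw: np.ndarray        # original order
    order: np.ndarray        # indices sorting p ascending
    thresholds: np.ndarray   # (i/m) q for rank i, in sorted order
    rejected: np.ndarray     # original order
    p_adjusted: np.ndarray   # original order, monotone-enforced
    q: float


def bh_adjust(p_values: Sequence[float], q: float = 0.05) -> BHResult:
    """Benjamini-Hochberg FDR control.

    Sort p ascending; find the largest rank i with p_(i) <= (i/m) q and
    reject every hypothesis with p at or below p_(i).  Also returns
    adjusted p-values p_adj_(i) = min_{j>=i} m p_(j)/j (capped at 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return BHResult(p, np.array([], int), p.copy(), np.array([], bool),
                        p.copy(), q)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    thresholds = ranks / m * q
    sorted_p = p[order]
    passing = sorted_p <= thresholds
    rejected_sorted = np.zeros(m, dtype=bool)
    if passing.any():
        i_star = int(np.max(np.flatnonzero(passing)))
        rejected_sorted[:i_star + 1] = True
    adj_sorted = np.minimum.accumulate((m / ranks * sorted_p)[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    rejected = np.empty(m, dtype=bool)
    rejected[order] = rejected_sorted
    p_adjusted = np.empty(m, dtype=float)
    p_adjusted[order] = adj_sorted
    return BHResult(p, order, thresholds, rejected, p_adjusted, q)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and approximate p for 3 <= n <= 5000 samples."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValueError("need a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: all values identical")
    w, p = sps.shapiro(x)
    return float(w), float(p)
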