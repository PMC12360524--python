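"""End-to-end analysis of a same-different discrimination study.

``run_analysis`` executes the stages of the behavioral analysis in order —
response-time filter, participant inclusion, per-cell sensitivity, group
aggregation, encoding-curve fits, inferential statistics, curve inversion —
and collects everything in an :class:`AnalysisReport`.  Partial inputs
(e.g. a single evaluation session, or published group means via
:func:`fit_report_from_table`) produce a partial report with the missing
pieces listed in ``report.gaps`` rather than an error.

Multiple-comparison families follow the study's comparison structure:
successive training sessions, successive sessions per duration, successive
durations per session, and generalization-vs-baseline contrasts, each
family corrected with Benjamini-Hochberg at the configured q.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sdt, stats
from .encoding_model import EncodingCurveResults, fit_encoding_curve
from .trial_data import (
    DEFAULT_SESSION_SCHEDULE,
    TrialTable,
    apply_inclusion_criterion,
    filter_by_rt,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "PipelineError",
    "run_analysis",
    "tabulate_group_sensitivity",
    "fit_report_from_table",
]

log = logging.getLogger("encodelearn.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """All knobs of the end-to-end analysis, serializable to YAML/JSON."""

    rt_lo_s: float = 0.2
    rt_hi_s: float = 5.0
    model: str = "independent_observation"
    correction: str = "half_count"
    inclusion_delta_min: float = 0.4
    inclusion_baseline_session: int = 1
    inclusion_criterion_session: int = 8
    apply_inclusion: bool = True
    session_schedule: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_SCHEDULE))
    fit_n_starts: int = 64
    fit_seed: int = 0
    bh_q: float = 0.05
    min_trials: int = 10
    target_dprime: Sequence[float] = (1.68,)

    def __post_init__(self) -> None:
        if not 0 < self.bh_q < 1:
            raise ValueError("bh_q must lie in (0, 1)")
        for s in (self.inclusion_baseline_session,
                  self.inclusion_criterion_session):
            if self.apply_inclusion and s not in self.session_schedule:
                raise ValueError(f"inclusion session {s} not in schedule")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "session_schedule" in d:
            d["session_schedule"] = {int(k): v
                                     for k, v in d["session_schedule"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_dprime"] = list(self.target_dprime)
        return d


@dataclass
class AnalysisReport:
    """Everything :func:`run_analysis` computes, with provenance."""

    config: dict
    filter_report: object = None
    inclusion: object = None
    sensitivity: pd.DataFrame | None = None
    group_table: pd.DataFrame | None = None
    fits: dict = field(default_factory=dict)
    training_anova: object = None
    session_by_duration_anova: object = None
    contrasts: dict = field(default_factory=dict)
    one_sample: pd.DataFrame | None = None
    inversions: pd.DataFrame | None = None
    gaps: list = field(default_factory=list)
    log_records: list = field(default_factory=list)

    def _note(self, msg: str) -> None:
        self.log_records.append(msg)
        log.info(msg)

    def fit_summary(self) -> dict:
        return {str(s): r.to_dict(session=s) for s, r in self.fits.items()}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.sensitivity is not None:
            sdt.write_sensitivity_tsv(self.sensitivity,
                                      outdir / "sensitivity.tsv")
        if self.group_table is not None:
            self.group_table.to_csv(outdir / "group_sensitivity.tsv",
                                    sep="\t", index=False)
        if self.fits:
            (outdir / "fits.json").write_text(
                json.dumps(self.fit_summary(), indent=2))
        for name, frame in self.contrasts.items():
            frame.to_csv(outdir / f"contrasts_{name}.tsv", sep="\t",
                         index=False)
        if self.one_sample is not None:
            self.one_sample.to_csv(outdir / "one_sample.tsv", sep="\t",
                                   index=False)
        if self.inversions is not None:
            self.inversions.to_csv(outdir / "inversions.tsv", sep="\t",
                                   index=False)
        for name, res in (("training_anova", self.training_anova),
                          ("session_by_duration_anova",
                           self.session_by_duration_anova)):
            if res is not None:
                res.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t",
                                      index=False)
        if self.inclusion is not None:
            (outdir / "inclusion.json").write_text(self.inclusion.to_json())
        (outdir / "run.log").write_text("\n".join(self.log_records) + "\n")
        (outdir / "config.json").write_text(json.dumps(self.config, indent=2))


def tabulate_group_sensitivity(sens: pd.DataFrame) -> pd.DataFrame:
    """Group mean / SD / SEM of d' per session x duration.

    Cells with a single participant keep their mean but have SD and SEM
    set to NaN (flagged, not fabricated).
    """
    valid = sens.dropna(subset=["dprime"])
    keys = [k for k in ("session_index", "encoding_duration_ms")
            if k in valid.columns]
    g = valid.groupby(keys, sort=True)["dprime"]
    out = g.agg(n="count", mean_dprime="mean",
                sd_dprime=lambda s: s.std(ddof=1)).reset_index()
    out["sem_dprime"] = out["sd_dprime"] / np.sqrt(out["n"])
    return out


def fit_report_from_table(summary: pd.DataFrame,
                          duration_col: str = "encoding_duration_ms",
                          n_starts: int = 64, seed: int = 0
                          ) -> dict[object, EncodingCurveResults]:
    """Fit the encoding curve to each session column of a group-mean table.

    ``summary`` has one duration column plus one column of mean d' per
    session (column name = session label).  This is the entry point that
    makes published group-mean tables directly reproducible.
    """
    if duration_col in summary.columns:
        durations = summary[duration_col].to_numpy(float)
        value_cols = [c for c in summary.columns if c != duration_col]
    else:
        durations = summary.index.to_numpy(float)
        value_cols = list(summary.columns)
    fits = {}
    for col in value_cols:
        y = pd.to_numeric(summary[col], errors="coerce")
        ok = y.notna().to_numpy()
        if ok.sum() < 4:
            continue
        fits[col] = fit_encoding_curve(durations[ok], y.to_numpy()[ok],
                                       n_starts=n_starts, seed=seed)
    return fits


def _successive_pairs(values: Sequence) -> list[tuple]:
    return list(zip(values[:-1], values[1:]))


def _paired_family(wide: pd.DataFrame, pairs: list[tuple], q: float,
                   label_cols: tuple[str, str]) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            continue
        sub = wide[[a, b]].dropna()
        if len(sub) < 2:
            continue
        r = stats.paired_t(sub[a].to_numpy(), sub[b].to_numpy())
        rows.append({label_cols[0]: a, label_cols[1]: b, "n": r.n, "t": r.t,
                     "df": r.df, "p": r.p_two_tailed, "cohens_d": r.cohens_d,
                     "ci_low": r.ci_low, "ci_high": r.ci_high})
    frame = pd.DataFrame(rows)
    if len(frame):
        bh = stats.bh_adjust(frame["p"].to_numpy(), q=q)
        frame["p_bh_adjusted"] = bh.p_adjusted
        frame["significant_bh"] = bh.rejected
    return frame


def run_analysis(trials: TrialTable, config: AnalysisConfig | None = None
                 ) -> AnalysisReport:
    """Run the full analysis on a (possibly partial) trial table."""
    config = config or AnalysisConfig()
    report = AnalysisReport(config=config.to_dict())

    # stage 1: response-time filter ----------------------------------------
    filtered, frep = filter_by_rt(trials, config.rt_lo_s, config.rt_hi_s)
    report.filter_report = frep
    report._note(f"rt_filter: kept {frep.n_kept} removed {frep.n_removed} "
                 f"of {len(trials)}")
    if len(filtered) == 0:
        raise PipelineError("stage rt_filter: window "
                            f"[{config.rt_lo_s}, {config.rt_hi_s}] s removed "
                            "all trials")
    schedule = config.session_schedule
    sessions_present = sorted(int(s)
                              for s in filtered.frame["session_index"].unique())
    eval_sessions = [s for s in sessions_present
                     if schedule.get(s) in ("evaluation", "generalization")]
    train_sessions = [s for s in sessions_present
                      if schedule.get(s) == "training"]
    if not eval_sessions:
        raise PipelineError("stage inputs: no evaluation session present")

    # stage 2: participant inclusion ---------------------------------------
    if config.apply_inclusion:
        pooled = sdt.pooled_dprime_by_session(filtered, config.model,
                                              config.correction)
        inc = apply_inclusion_criterion(
            pooled, config.inclusion_delta_min,
            config.inclusion_baseline_session,
            config.inclusion_criterion_session)
        report.inclusion = inc
        if inc.included:
            keep = filtered.frame["participant_id"].isin(inc.included)
            filtered = filtered.subset(keep, "inclusion_criterion")
            report._note(f"inclusion: {len(inc.included)} included, "
                         f"{len(inc.excluded)} excluded, "
                         f"{len(inc.undetermined)} undetermined")
        elif inc.excluded:
            raise PipelineError(
                "stage inclusion: no participant passed; deltas="
                + json.dumps(inc.deltas))
        else:
            report.gaps.append("inclusion undetermined: baseline or "
                               "criterion session absent")
            report._note("inclusion skipped: sessions absent")

    # stage 3: sensitivity --------------------------------------------------
    eval_mask = filtered.frame["session_index"].isin(eval_sessions)
    eval_trials = filtered.subset(eval_mask, "evaluation_sessions")
    sens = sdt.sensitivity_table(
        eval_trials, model=config.model, correction=config.correction,
        min_trials=config.min_trials)
    report.sensitivity = sens
    report._note(f"sensitivity: {len(sens)} cells, "
                 f"{int(sens['dprime'].isna().sum())} flagged")

    # stage 4: group aggregation --------------------------------------------
    group = tabulate_group_sensitivity(sens)
    report.group_table = group

    # stage 5: encoding-curve fits ------------------------------------------
    for session in eval_sessions:
        sub = group[group["session_index"] == session]
        if len(sub) < 4:
            report.gaps.append(f"fit session {session}: fewer than 4 durations")
            continue
        fit = fit_encoding_curve(sub["encoding_duration_ms"].to_numpy(),
                                 sub["mean_dprime"].to_numpy(),
                                 n_starts=config.fit_n_starts,
                                 seed=config.fit_seed)
        report.fits[session] = fit
        report._note(f"fit session {session}: A={fit.params.A:.3f} "
                     f"R={fit.rate_per_s:.2f}/s I={fit.params.I:.2f}ms "
                     f"R2={fit.rsquared:.4f}")

    # stage 6: inferential statistics ---------------------------------------
    _run_stats(report, filtered, sens, train_sessions, eval_sessions, config)

    # stage 7: curve inversion ----------------------------------------------
    inv_rows = []
    for session, fit in report.fits.items():
        for target in config.target_dprime:
            if not fit.converged or not 0 <= target < fit.params.A:
                inv_rows.append({"session_index": session,
                                 "target_dprime": target,
                                 "duration_ms": np.nan})
                continue
            inv_rows.append({"session_index": session,
                             "target_dprime": target,
                             "duration_ms": fit.invert_duration(target)})
    report.inversions = pd.DataFrame(inv_rows)
    report._note("done")
    return report


def _run_stats(report: AnalysisReport, filtered: TrialTable,
               sens: pd.DataFrame, train_sessions: list, eval_sessions: list,
               config: AnalysisConfig) -> None:
    # learning curve over training sessions at the fixed training duration
    if len(train_sessions) >= 2:
        tmask = filtered.frame["session_index"].isin(train_sessions)
        tsens = sdt.sensitivity_table(
            filtered.subset(tmask, "training_sessions"),
            model=config.model, correction=config.correction,
            grouping=("participant_id", "session_index"),
            min_trials=config.min_trials)
        complete = tsens.dropna(subset=["dprime"])
        counts = complete.groupby("participant_id")["session_index"].nunique()
        full = counts[counts == len(train_sessions)].index
        complete = complete[complete["participant_id"].isin(full)]
        if complete["participant_id"].nunique() >= 3:
            report.training_anova = stats.rm_anova(
                complete, dv="dprime", within=["session_index"],
                subject="participant_id")
            wide = complete.pivot(index="participant_id",
                                  columns="session_index", values="dprime")
            report.contrasts["training_successive"] = _paired_family(
                wide, _successive_pairs(sorted(wide.columns)), config.bh_q,
                ("session_a", "session_b"))
        else:
            report.gaps.append("training stats: too few complete participants")
    else:
        report.gaps.append("training stats: fewer than 2 training sessions")

    valid = sens.dropna(subset=["dprime"])
    strict_eval = [s for s in eval_sessions
                   if config.session_schedule.get(s) == "evaluation"]
    # session x duration ANOVA on participants complete in all cells
    if len(strict_eval) >= 2:
        ev = valid[valid["session_index"].isin(strict_eval)]
        n_cells = ev.groupby("participant_id").size()
        n_dur = ev["encoding_duration_ms"].nunique()
        full = n_cells[n_cells == len(strict_eval) * n_dur].index
        ev_full = ev[ev["participant_id"].isin(full)]
        if ev_full["participant_id"].nunique() >= 3 and n_dur >= 2:
            report.session_by_duration_anova = stats.rm_anova(
                ev_full, dv="dprime",
                within=["session_index", "encoding_duration_ms"],
                subject="participant_id")
        else:
            report.gaps.append("session x duration ANOVA: incomplete data")

        # successive sessions per duration (one BH family per session pair)
        for a, b in _successive_pairs(strict_eval):
            frames = []
            for dur in sorted(ev["encoding_duration_ms"].unique()):
                sub = ev[ev["encoding_duration_ms"] == dur]
                wide = sub.pivot(index="participant_id",
                                 columns="session_index", values="dprime")
                fam = _paired_family(wide, [(a, b)], config.bh_q,
                                     ("session_a", "session_b"))
                if len(fam):
                    fam.insert(0, "encoding_duration_ms", dur)
                    frames.append(fam)
            if frames:
                fam = pd.concat(frames, ignore_index=True).drop(
                    columns=["p_bh_adjusted", "significant_bh"])
                bh = stats.bh_adjust(fam["p"].to_numpy(), q=config.bh_q)
                fam["p_bh_adjusted"] = bh.p_adjusted
                fam["significant_bh"] = bh.rejected
                report.contrasts[f"sessions_{a}_vs_{b}_by_duration"] = fam

    # successive durations per session (one BH family per session)
    for session in eval_sessions:
        sub = valid[valid["session_index"] == session]
        wide = sub.pivot(index="participant_id",
                         columns="encoding_duration_ms", values="dprime")
        fam = _paired_family(wide, _successive_pairs(sorted(wide.columns)),
                             config.bh_q, ("duration_a", "duration_b"))
        if len(fam):
            report.contrasts[f"durations_session_{session}"] = fam

    # generalization contrasts: session 11 vs 1 and vs 10, per duration
    gen = [s for s in eval_sessions
           if config.session_schedule.get(s) == "generalization"]
    for g in gen:
        for ref in (strict_eval[0], strict_eval[-1]) if strict_eval else ():
            frames = []
            for dur in sorted(valid["encoding_duration_ms"].unique()):
                sub = valid[valid["encoding_duration_ms"] == dur]
                wide = sub.pivot(index="participant_id",
                                 columns="session_index", values="dprime")
                fam = _paired_family(wide, [(ref, g)], config.bh_q,
                                     ("session_a", "session_b"))
                if len(fam):
                    fam.insert(0, "encoding_duration_ms", dur)
                    frames.append(fam)
            if frames:
                fam = pd.concat(frames, ignore_index=True).drop(
                    columns=["p_bh_adjusted", "significant_bh"])
                bh = stats.bh_adjust(fam["p"].to_numpy(), q=config.bh_q)
                fam["p_bh_adjusted"] = bh.p_adjusted
                fam["significant_bh"] = bh.rejected
                report.contrasts[f"generalization_{g}_vs_{ref}"] = fam

    # chance-level test at the shortest duration, per session
    rows = []
    shortest = valid["encoding_duration_ms"].min() if len(valid) else None
    for session in eval_sessions:
        x = valid[(valid["session_index"] == session)
                  & (valid["encoding_duration_ms"] == shortest)]["dprime"]
        if len(x) < 2:
            continue
        r = stats.one_sample_t(x.to_numpy(), mu0=0.0)
        rows.append({"session_index": session,
                     "encoding_duration_ms": shortest, "n": r.n, "t": r.t,
                     "df": r.df, "p": r.p_two_tailed, "cohens_d": r.cohens_d,
                     "ci_low": r.ci_low, "ci_high": r.ci_high})
    report.one_sample = pd.DataFrame(rows)
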