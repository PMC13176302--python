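"""End-to-end orchestration: QC -> circadian metrics -> windows -> models.

The in-memory entry points are :func:`analyze_cohort` (tidy per-day and
per-week metric tables plus QC accounting) and :func:`fit_all_models`
(Tables of fixed-effect estimates for the three model families).
:func:`run_pipeline` wraps them as a reproducible run directory with the
configuration serialized alongside every output table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, models, qc, wake, windows
from .errors import ModelError
from .io import DiarySet, EpochSeries, ParticipantManifest
from .simulate import Cohort, CohortSpec, figure1_preset, generate_cohort

logger = logging.getLogger(__name__)

MODEL_VARIABLES = ("IS", "IV", "M10", "L5", "RA", "wake_time")
#: the logistic family follows the convention of reporting wake time in hours
LOGISTIC_VARIABLES = ("IS", "IV", "M10", "L5", "RA", "wake_hours")


@dataclass
class AnalysisResult:
    flow: qc.CohortFlow
    qc_report: pd.DataFrame
    assignments: dict[str, windows.RelapseAssignment]
    daily: pd.DataFrame
    weekly: pd.DataFrame
    inpatient_subset: list[str]


def analyze_cohort(
    series: dict[str, EpochSeries],
    diaries: dict[str, DiarySet],
    manifest: dict[str, ParticipantManifest],
    wake_params: wake.WakeParams = wake.DEFAULT_WAKE_PARAMS,
    detect_wake: bool = True,
) -> AnalysisResult:
    """Filter a cohort and compute every per-day and per-week circadian metric.

    ``detect_wake=False`` skips the (comparatively expensive) wake-time stage
    and leaves the daily ``wake_time`` column absent, for runs that only need
    the weekly statistics.
    """
    cohort = {pid: (series[pid], diaries.get(pid)) for pid in series}
    retained, flow, report = qc.apply_cohort_filters(cohort)

    assignments: dict[str, windows.RelapseAssignment] = {}
    labeled: dict[str, pd.DataFrame] = {}
    daily_rows = []
    weekly_rows = []
    for pid in sorted(retained):
        part = retained[pid]
        mani = manifest[pid]
        assignment = windows.assign_relapse(part.diary, mani)
        assignments[pid] = assignment
        labels = windows.label_days(part, assignment, mani)
        labeled[pid] = labels
        if labels.empty:
            continue

        dates, counts, valid = part.series.day_matrix()
        row_of = {d: i for i, d in enumerate(dates)}
        dm = metrics.daily_metrics_matrix(counts, valid)
        estimates = {}
        if detect_wake:
            estimates = {
                e.date: e.wake_time
                for e in wake.detect_wake_times(
                    part.series, wake_params, valid_dates=list(labels["date"])
                )
            }
        for _, lab in labels.iterrows():
            i = row_of[lab["date"]]
            daily_rows.append(
                {
                    "participant": pid,
                    "date": lab["date"],
                    "setting": lab["setting"],
                    "phase": lab["phase"],
                    "week": lab["week"],
                    "M10": dm[i, 0],
                    "L5": dm[i, 1],
                    "RA": dm[i, 2],
                    "wake_time": estimates.get(lab["date"], np.nan),
                }
            )
        for week, setting, group_dates in windows.weekly_groups(labels):
            weekly_rows.append(
                _weekly_row(
                    pid, "relapse", f"w{week}:{setting}", week, setting,
                    group_dates, labels, counts, valid, row_of,
                )
            )
        dgroups = windows.discharge_groups(labels, mani)
        if dgroups is not None:
            for unit, setting, group_dates in dgroups:
                weekly_rows.append(
                    _weekly_row(
                        pid, "discharge", unit, np.nan, setting,
                        group_dates, labels, counts, valid, row_of,
                    )
                )

    daily = pd.DataFrame(
        daily_rows,
        columns=["participant", "date", "setting", "phase", "week",
                 "M10", "L5", "RA", "wake_time"],
    )
    weekly = pd.DataFrame(
        weekly_rows,
        columns=["participant", "scheme", "unit", "week", "setting", "phase",
                 "IS", "IV", "n_days"],
    )
    subset = windows.inpatient_subset(labeled)
    if not daily.empty:
        first_out_end = {
            pid: manifest[pid].discharge_date + dt.timedelta(days=6) for pid in retained
        }
        daily["in_discharge_window"] = [
            row["participant"] in subset
            and (
                row["setting"] == "inpatient"
                or row["date"] <= first_out_end[row["participant"]]
            )
            for _, row in daily.iterrows()
        ]
    else:
        daily["in_discharge_window"] = pd.Series(dtype=bool)
    return AnalysisResult(
        flow=flow,
        qc_report=report,
        assignments=assignments,
        daily=daily,
        weekly=weekly,
        inpatient_subset=subset,
    )


def _weekly_row(pid, scheme, unit, week, setting, group_dates, labels, counts, valid, row_of):
    idx = [row_of[d] for d in group_dates]
    h = metrics.hourly_summaries(
        np.array(group_dates), counts[idx], valid[idx], key=(pid, unit)
    )
    phases = labels.loc[labels["date"].isin(group_dates), "phase"].unique()
    phase = phases[0] if len(phases) == 1 and scheme == "relapse" else "none"
    return {
        "participant": pid,
        "scheme": scheme,
        "unit": unit,
        "week": week,
        "setting": setting,
        "phase": phase,
        "IS": metrics.interdaily_stability(h),
        "IV": metrics.intradaily_variability(h),
        "n_days": len(group_dates),
    }


def lmm_diagnostics(result: AnalysisResult) -> pd.DataFrame:
    """Residual diagnostics (Q-Q agreement, residual-vs-fitted correlations)
    for every linear mixed model of the discharge and relapse-effect families."""
    rows = []
    for family, fitter in [
        ("discharge", models.fit_discharge_lmm),
        ("relapse_effect", models.fit_relapse_effect_lmm),
    ]:
        for variable in MODEL_VARIABLES:
            obs = windows.build_observation_rows(
                result.daily, result.weekly, result.assignments, variable, family
            )
            try:
                _, fitted = fitter(obs, variable)
                report = models.assumption_checks(fitted)
            except (ModelError, ValueError, np.linalg.LinAlgError):
                # degenerate fits on tiny cohorts have no residual structure
                continue
            rows.append(
                {"family": family, "variable": variable,
                 "qq_correlation": report.qq_correlation,
                 "resid_fitted_correlation": report.resid_fitted_correlation,
                 "spread_fitted_correlation": report.spread_fitted_correlation,
                 "tail_flag": report.tail_flag, "n_residuals": report.n_residuals}
            )
    return pd.DataFrame(rows)


def fit_all_models(
    result: AnalysisResult,
    families: tuple[str, ...] = ("discharge", "relapse_probability", "relapse_effect"),
) -> pd.DataFrame:
    """Fit every requested model family for every circadian variable."""
    rows = []
    for family in families:
        variables = LOGISTIC_VARIABLES if family == "relapse_probability" else MODEL_VARIABLES
        for variable in variables:
            obs = windows.build_observation_rows(
                result.daily, result.weekly, result.assignments, variable, family
            )
            try:
                if family == "discharge":
                    est, _ = models.fit_discharge_lmm(obs, variable)
                elif family == "relapse_effect":
                    est, _ = models.fit_relapse_effect_lmm(obs, variable)
                else:
                    est = models.fit_relapse_logistic(obs, variable)
            except ModelError as exc:
                logger.warning("%s/%s: %s", family, variable, exc)
                rows.append(
                    {"family": family, "variable": variable, "beta": np.nan,
                     "se": np.nan, "df": 0, "statistic": np.nan, "p_value": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "odds_ratio": np.nan,
                     "n_obs": len(obs), "converged": False, "diagnostics": str(exc)}
                )
                continue
            rows.append(
                {"family": family, "variable": variable, "beta": est.beta,
                 "se": est.se, "df": est.df, "statistic": est.statistic,
                 "p_value": est.p_value, "ci_low": est.ci95[0],
                 "ci_high": est.ci95[1], "odds_ratio": est.odds_ratio,
                 "n_obs": len(obs), "converged": est.converged,
                 "diagnostics": est.diagnostics}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run directory


@dataclass
class RunConfig:
    """One reproducible run: either a simulation spec or an input directory."""

    output_dir: str
    simulation: CohortSpec | None = None
    preset: str | None = None  # "figure1"
    input_dir: str | None = None
    wake_params: wake.WakeParams = field(default_factory=wake.WakeParams)
    families: tuple[str, ...] = ("discharge", "relapse_probability", "relapse_effect")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
            out["simulation"]["start_date"] = self.simulation.start_date.isoformat()
        return out


def load_cohort(config: RunConfig) -> Cohort | tuple:
    from . import io as io_mod

    if config.preset == "figure1":
        seed = config.simulation.seed if config.simulation else 0
        return figure1_preset(seed)
    if config.simulation is not None:
        return generate_cohort(config.simulation)
    if config.input_dir is None:
        raise ValueError("config needs a simulation spec, preset, or input directory")
    root = Path(config.input_dir)
    manifest = io_mod.read_manifest(root / "manifest.csv")
    diaries = io_mod.read_diaries(root / "diaries.csv")
    series = {
        pid: io_mod.read_epoch_file(root / "epochs" / f"{pid}.csv", participant_id=pid)
        for pid in manifest
    }
    return Cohort(spec=None, series=series, diaries=diaries, manifest=manifest, truth=pd.DataFrame())


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write a run directory; deterministic per config."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    cohort = load_cohort(config)
    result = analyze_cohort(cohort.series, cohort.diaries, cohort.manifest, config.wake_params)

    result.qc_report.to_csv(out / "qc_report.csv", index=False)
    flow = result.flow
    (out / "cohort_flow.txt").write_text(
        f"input\t{flow.n_input}\nexcluded_no_diary\t{flow.n_excluded_no_diary}\n"
        f"excluded_weartime\t{flow.n_excluded_weartime}\nretained\t{flow.n_retained}\n"
    )
    result.daily.to_csv(out / "daily_metrics.csv", index=False)
    result.weekly.to_csv(out / "weekly_metrics.csv", index=False)
    pd.DataFrame([vars(a) for a in result.assignments.values()]).to_csv(
        out / "relapse_assignments.csv", index=False
    )
    comparison = models.compare_groups(result.daily, result.weekly, result.assignments)
    comparison.to_csv(out / "group_comparison.csv", index=False)
    effects = fit_all_models(result, config.families)
    effects.to_csv(out / "model_effects.csv", index=False)
    lmm_diagnostics(result).to_csv(out / "model_diagnostics.csv", index=False)
    for family, name in [
        ("discharge", "table_discharge_effects.csv"),
        ("relapse_probability", "table_relapse_probability.csv"),
        ("relapse_effect", "table_relapse_effects.csv"),
    ]:
        if family in config.families:
            effects[effects["family"] == family].to_csv(out / name, index=False)
    _write_summary(out, flow, comparison, effects)
    logger.info("run complete: %s", out)
    return out


def _write_summary(out: Path, flow, comparison, effects) -> None:
    lines = [
        "circact run summary",
        "===================",
        f"cohort: {flow.n_input} in, {flow.n_excluded_no_diary} no-diary, "
        f"{flow.n_excluded_weartime} wear-time, {flow.n_retained} retained",
        "",
        "group comparison (study-period means, relapse vs non-relapse):",
        comparison.to_string(index=False),
        "",
        "model effects:",
        effects.to_string(index=False),
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
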