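"""Random-intercept mixed models and group-comparison statistics.

Three model families mirror the study's analyses:

* discharge effect — linear mixed model ``value ~ outpatient`` with a
  participant random intercept, on the inpatient subset;
* relapse probability — logistic mixed model ``relapsed ~ value`` with a
  participant random intercept, on pre-relapse rows only;
* relapse effect — linear mixed model ``value ~ post_relapse + outpatient``
  (adjusted for discharge) with a participant random intercept.

Fixed effects are tested with Wald statistics; the reported degrees of
freedom are residual (observations minus participants minus fixed-effect
columns), matching the residual-counting convention of the tables this
module reproduces.  The logistic family reports exp(beta) as an odds ratio
per unit of the circadian variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ModelError
from .wake import wake_seconds_to_clock
from .windows import RelapseAssignment


@dataclass
class EffectEstimate:
    family: str
    variable: str
    beta: float
    se: float
    df: int
    statistic: float
    p_value: float
    ci95: tuple[float, float]
    odds_ratio: float | None = None
    converged: bool = True
    diagnostics: str = ""


@dataclass
class GroupComparison:
    variable: str
    mean_nonrelapse: float
    sd_nonrelapse: float
    mean_relapse: float
    sd_relapse: float
    n_nonrelapse: int
    n_relapse: int
    p_value: float
    smd: float


@dataclass
class AssumptionReport:
    qq_correlation: float
    resid_fitted_correlation: float
    spread_fitted_correlation: float
    tail_flag: bool
    n_residuals: int
    notes: list[str] = field(default_factory=list)


def _wald(family, variable, beta, se, df) -> EffectEstimate:
    statistic = beta / se
    p = 2 * stats.t.sf(abs(statistic), df) if df > 0 else float("nan")
    return EffectEstimate(
        family=family,
        variable=variable,
        beta=float(beta),
        se=float(se),
        df=int(df),
        statistic=float(statistic),
        p_value=float(p),
        ci95=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
    )


def _check_lmm_rows(rows: pd.DataFrame, indicator: str) -> None:
    if rows["participant"].nunique() < 2:
        raise ModelError("need at least 2 participants")
    if rows[indicator].nunique() < 2:
        raise ModelError(f"both levels of {indicator} must be represented")
    if rows["value"].nunique() < 2:
        raise ModelError("degenerate fit: response is constant")


def _fit_lmm(rows: pd.DataFrame, formula: str, family: str, variable: str, term: str):
    # fit on a standardized response for numerical conditioning (the circadian
    # variables span 5 orders of magnitude), then map estimates back
    scale = float(rows["value"].std(ddof=1))
    data = rows.copy()
    data["value"] = data["value"] / scale
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=data, groups=data["participant"])
        result = None
        errors = []
        for method in ("lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=True, method=[method])
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
        if result is None:
            raise ModelError("mixed model fit failed: " + "; ".join(errors))
    k_fe = len(result.fe_params)
    df = int(result.nobs) - rows["participant"].nunique() - k_fe
    est = _wald(
        family, variable, result.fe_params[term] * scale, result.bse_fe[term] * scale, df
    )
    if not result.converged:
        est.converged = False
        est.diagnostics = "optimizer did not converge"
    notes = [str(w.message) for w in caught if "converge" in str(w.message).lower()]
    if notes:
        est.converged = False
        est.diagnostics = (est.diagnostics + "; " + "; ".join(notes)).strip("; ")
    return est, result


def fit_discharge_lmm(rows: pd.DataFrame, variable: str = "value"):
    """Effect of discharge: ``value ~ outpatient`` + participant random intercept."""
    _check_lmm_rows(rows, "outpatient")
    return _fit_lmm(rows, "value ~ outpatient", "discharge", variable, "outpatient")


def fit_relapse_effect_lmm(rows: pd.DataFrame, variable: str = "value"):
    """Effect of relapse, adjusted for discharge:
    ``value ~ post_relapse + outpatient`` + participant random intercept."""
    _check_lmm_rows(rows, "post_relapse")
    return _fit_lmm(
        rows, "value ~ post_relapse + outpatient", "relapse_effect", variable, "post_relapse"
    )


def fit_relapse_logistic(
    rows: pd.DataFrame, variable: str = "value", engine: str = "gee"
) -> EffectEstimate:
    """Probability of relapse from a pre-relapse circadian variable.

    The target model is a within-participant-correlated logistic regression
    of the binary relapse outcome on the circadian variable.  Because the
    outcome is constant within participant, the subject-specific
    random-intercept likelihood is unidentified (the intercept variance
    diverges and Wald SEs explode), so the default engine estimates the
    marginal model by GEE with an independence working correlation and
    cluster-robust (sandwich) standard errors.  The independence working
    correlation matters: relapsers contribute systematically fewer
    (pre-relapse) rows than non-relapsers, and with such informative cluster
    sizes an exchangeable working correlation — whose estimate degenerates
    toward 1 because the outcome is cluster-constant — yields badly
    anti-conservative tests, while the independence estimating equations
    with a sandwich variance stay calibrated.  ``engine="glmm_vb"`` fits the
    literal random-intercept model by the variational Gaussian approximation
    instead; its z-statistics come from the approximate posterior and are
    *not* calibrated here.

    Outcome separation yields a flagged (non-converged) estimate, not a crash.
    """
    outcomes = rows.groupby("participant")["relapsed"].first()
    if outcomes.nunique() < 2:
        raise ModelError("both relapse outcomes must be present")
    if rows["value"].nunique() < 2:
        raise ModelError("degenerate fit: predictor is constant")
    data = rows.copy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if engine == "gee":
                model = sm.GEE.from_formula(
                    "relapsed ~ value",
                    groups="participant",
                    data=data,
                    family=sm.families.Binomial(),
                    cov_struct=sm.cov_struct.Independence(),
                )
                # bias-reduced (Mancl-DeRouen) sandwich: the plain robust
                # covariance is slightly anti-conservative at ~100 clusters
                result = model.fit(cov_type="bias_reduced")
                beta = float(result.params["value"])
                se = float(result.bse["value"])
            elif engine == "glmm_vb":
                model = sm.BinomialBayesMixedGLM.from_formula(
                    "relapsed ~ value", {"participant": "0 + C(participant)"}, data
                )
                result = model.fit_vb()
                beta = float(result.fe_mean[1])
                se = float(result.fe_sd[1])
            else:
                raise ValueError(f"unknown engine {engine!r}")
        flagged = not np.isfinite(beta) or not np.isfinite(se) or se == 0
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as exc:
        if isinstance(exc, ValueError) and "unknown engine" in str(exc):
            raise
        return EffectEstimate(
            family="relapse_probability",
            variable=variable,
            beta=float("nan"),
            se=float("nan"),
            df=0,
            statistic=float("nan"),
            p_value=float("nan"),
            ci95=(float("nan"), float("nan")),
            converged=False,
            diagnostics=f"fit failed: {exc}",
        )
    z = beta / se
    # reference the Wald statistic against t with cluster-level df
    df_cluster = int(rows["participant"].nunique() - 2)
    est = EffectEstimate(
        family="relapse_probability",
        variable=variable,
        beta=beta,
        se=se,
        df=df_cluster,
        statistic=float(z),
        p_value=float(2 * stats.t.sf(abs(z), df_cluster)) if df_cluster > 0 else float("nan"),
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        odds_ratio=float(np.exp(beta)),
        converged=not flagged,
        diagnostics="" if not flagged else "separation or degenerate posterior",
    )
    return est


def assumption_checks(result, tail_bound: float = 0.98) -> AssumptionReport:
    """Residual diagnostics for a fitted linear mixed model.

    Summarizes the residual-vs-fitted relation (correlations of the residuals
    and their magnitudes with the fitted values) and the normal Q-Q agreement
    (correlation of ordered residuals with normal quantiles); the tail flag is
    raised when the Q-Q correlation falls below ``tail_bound``.
    """
    resid = np.asarray(result.resid, dtype=float)
    fitted = np.asarray(result.fittedvalues, dtype=float)
    n = resid.size
    notes = []
    if np.std(resid) == 0:
        return AssumptionReport(1.0, 0.0, 0.0, False, n, ["zero residual spread"])
    order = np.sort((resid - resid.mean()) / resid.std())
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq = float(np.corrcoef(order, theo)[0, 1])
    rf = float(np.corrcoef(resid, fitted)[0, 1]) if np.std(fitted) > 0 else 0.0
    sf_ = float(np.corrcoef(np.abs(resid), fitted)[0, 1]) if np.std(fitted) > 0 else 0.0
    flag = qq < tail_bound
    if flag:
        notes.append(f"Q-Q correlation {qq:.4f} below {tail_bound}")
    return AssumptionReport(qq, rf, sf_, flag, n, notes)


def _participant_means(table: pd.DataFrame, variable: str) -> pd.Series:
    return table.groupby("participant")[variable].mean()


def compare_groups(
    daily: pd.DataFrame,
    weekly: pd.DataFrame,
    assignments: dict[str, RelapseAssignment],
) -> pd.DataFrame:
    """Relapse vs non-relapse comparison of study-period circadian parameters.

    Each participant contributes one value per variable (their study-period
    mean), compared across groups with a two-tailed t-test and an absolute
    pooled-SD standardized mean difference (Cohen's d with unequal-n pooling).
    """
    weekly_r = weekly[weekly["scheme"] == "relapse"]
    rows = []
    for variable, table in [
        ("IV", weekly_r),
        ("IS", weekly_r),
        ("L5", daily),
        ("M10", daily),
        ("RA", daily),
        ("wake_time", daily),
    ]:
        means = _participant_means(table, variable).dropna()
        grp = {
            flag: means[[p for p in means.index if assignments[p].relapsed == flag]]
            for flag in (False, True)
        }
        n0, n1 = len(grp[False]), len(grp[True])
        if min(n0, n1) >= 2:
            _, p = stats.ttest_ind(grp[False], grp[True], equal_var=True)
            pooled = np.sqrt(
                ((n0 - 1) * grp[False].var(ddof=1) + (n1 - 1) * grp[True].var(ddof=1))
                / (n0 + n1 - 2)
            )
            smd = abs(grp[False].mean() - grp[True].mean()) / pooled if pooled > 0 else 0.0
        else:
            p, smd = float("nan"), float("nan")
        rows.append(
            GroupComparison(
                variable=variable,
                mean_nonrelapse=float(grp[False].mean()) if n0 else float("nan"),
                sd_nonrelapse=float(grp[False].std(ddof=1)) if n0 > 1 else float("nan"),
                mean_relapse=float(grp[True].mean()) if n1 else float("nan"),
                sd_relapse=float(grp[True].std(ddof=1)) if n1 > 1 else float("nan"),
                n_nonrelapse=n0,
                n_relapse=n1,
                p_value=float(p),
                smd=float(smd),
            )
        )
    frame = pd.DataFrame([vars(c) for c in rows])
    clock = []
    for _, row in frame.iterrows():
        if row["variable"] == "wake_time" and np.isfinite(row["mean_nonrelapse"]):
            clock.append(
                f"{wake_seconds_to_clock(row['mean_nonrelapse'])} vs "
                f"{wake_seconds_to_clock(row['mean_relapse'])}"
            )
        else:
            clock.append("")
    frame["clock_rendering"] = clock
    return frame
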