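"""Per-trial IFR regressions and mixed-effect contrasts of SEE vs CTRL.

Two statistical stages sit on top of the feature tables:

1. **Per-trial ordinary least squares** of per-spike IFR on a mechanical
   predictor (MTU/fascicle displacement or velocity, MTU force) linearly
   interpolated to the spike times. Regression windows follow the stretch
   type: cycles 2..end for sinusoids, stretches 2–3 for triangles, and the
   hold phase only for ramps — force and length are not expected to predict
   the more dynamic firing components.

2. **Linear mixed models** contrasting SEE against CTRL with a random
   intercept per grouping unit: animals for stiffness/RFD responses,
   afferents for firing responses. Fits use REML; p-values are Wald z on
   the SEE coefficient. A singular fit (zero group variance) falls back to
   pooled OLS with a warning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .conditioning import IFRSeries
from .features import PhaseSegmentation
from .records import ConditionedTrial

logger = logging.getLogger(__name__)

PREDICTOR_UNITS = {
    "mtu_displacement": "pps/mm",
    "mtu_velocity": "pps/(mm/s)",
    "fascicle_displacement": "pps/mm",
    "fascicle_velocity": "pps/(mm/s)",
    "mtu_force": "pps/N",
}


@dataclass
class RegressionResult:
    """OLS fit of per-spike IFR on one mechanical predictor."""

    trial_id: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n_spikes: int
    window: tuple[float, float]
    units: str = ""
    ok: bool = True
    flags: list = field(default_factory=list)


@dataclass
class EffectEstimate:
    """Fixed effect of SEE on one response, from a random-intercept model."""

    response: str
    effect: float          # units of the response (SEE minus CTRL)
    se: float
    p_value: float
    grouping: str          # "animal" or "afferent"
    n_trials: int
    n_groups: int
    control_mean: float = math.nan
    method: str = "mixedlm-reml"

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("a contrast needs at least 2 groups")
        if not self.se > 0:
            raise ValueError("standard error must be > 0")


def regression_window(seg: PhaseSegmentation) -> tuple[float, float]:
    """The analysis window the per-trial regressions use, per stretch type."""
    if seg.kind == "sinusoid":
        return seg.stretches[1].onset, seg.stretches[-1].release_end
    if seg.kind == "triangle":
        return seg.stretches[1].onset, seg.stretches[-1].release_end
    # ramp: hold phase only (the static response)
    p = seg.stretches[0]
    return p.hold_start, p.hold_end


def regress_ifr(
    trial: ConditionedTrial,
    ifr: IFRSeries,
    predictor: str,
    window: Optional[tuple[float, float]] = None,
    seg: Optional[PhaseSegmentation] = None,
) -> RegressionResult:
    """OLS of per-spike IFR on a predictor sampled at spike times.

    The predictor channel is linearly interpolated to the anchor spike
    times within the window. Fewer than 3 spikes, or a constant predictor,
    yields a flagged, not-ok result rather than an error.
    """
    if window is None:
        from .features import segment_phases
        if seg is None:
            seg = segment_phases(trial)
        window = regression_window(seg)
    w = ifr.in_window(*window)
    units = PREDICTOR_UNITS.get(predictor, "")
    base = dict(trial_id=trial.trial_id, predictor=predictor, units=units,
                window=(float(window[0]), float(window[1])))
    if len(w) < 2:  # fewer than 3 spikes -> fewer than 2 IFR points
        return RegressionResult(slope=math.nan, intercept=math.nan,
                                r_squared=math.nan, n_spikes=len(w), ok=False,
                                flags=["fewer than 3 spikes in window"], **base)
    x = np.interp(w.times, trial.time, trial.predictor(predictor))
    if np.ptp(x) == 0.0:
        return RegressionResult(slope=math.nan, intercept=math.nan,
                                r_squared=math.nan, n_spikes=len(w), ok=False,
                                flags=["predictor constant in window"], **base)
    fit = sps.linregress(x, w.ifr)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            n_spikes=len(w), **base)


def mixed_effect_contrast(
    table: pd.DataFrame,
    response: str,
    grouping: str,
    condition_col: str = "condition",
) -> EffectEstimate:
    """Random-intercept mixed-model contrast of SEE vs CTRL.

    Fits ``response ~ see + (1 | group)`` by REML, where ``see`` codes the
    SEE condition as 1 and CTRL as 0, and returns the SEE coefficient with
    its Wald standard error and z-test p-value. Rows with missing response
    values are dropped. When the random-intercept variance collapses to
    zero (singular fit) the contrast falls back to pooled OLS, with a
    warning and ``method = "ols-fallback"``.
    """
    for col in (response, grouping, condition_col):
        if col not in table.columns:
            raise ValueError(f"table is missing column {col!r}")
    df = table[[response, grouping, condition_col]].dropna().copy()
    conds = set(df[condition_col].unique())
    if conds != {"CTRL", "SEE"}:
        raise ValueError(
            f"contrast needs both CTRL and SEE trials, got {sorted(conds)}")
    df["see"] = (df[condition_col] == "SEE").astype(float)
    df = df.rename(columns={response: "y", grouping: "grp"})
    n_groups = df["grp"].nunique()
    if n_groups < 2:
        raise ValueError(f"contrast needs >= 2 groups, got {n_groups}")
    control_mean = float(df.loc[df["see"] == 0.0, "y"].mean())
    if float(df["y"].var()) == 0.0:
        # fully degenerate response: no variance anywhere
        return EffectEstimate(response=response, effect=0.0,
                              se=np.finfo(float).tiny, p_value=1.0,
                              grouping=grouping, n_trials=len(df),
                              n_groups=n_groups, control_mean=control_mean,
                              method="degenerate")

    effect = se = p = None
    method = "mixedlm-reml"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm("y ~ see", df, groups=df["grp"])
            res = model.fit(reml=True)
            singular = (not res.converged or
                        float(res.cov_re.iloc[0, 0]) < 1e-10 or
                        not np.isfinite(res.bse["see"]))
            if not singular:
                effect = float(res.params["see"])
                se = float(res.bse["see"])
                p = float(res.pvalues["see"])
        except Exception as exc:  # numerical failure -> pooled OLS
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
    if effect is None or se is None or not np.isfinite(se) or se <= 0:
        warnings.warn(
            f"singular mixed-model fit for {response!r}; falling back to "
            "pooled OLS", stacklevel=2)
        ols = smf.ols("y ~ see", df).fit()
        effect = float(ols.params["see"])
        se = float(ols.bse["see"])
        p = float(ols.pvalues["see"])
        method = "ols-fallback"
        if se == 0.0 or not np.isfinite(se):
            # fully degenerate: zero residual variance
            se = np.finfo(float).tiny
            p = 1.0 if effect == 0.0 else 0.0
    return EffectEstimate(response=response, effect=effect, se=se, p_value=p,
                          grouping="animal" if grouping == "animal_id"
                          else "afferent" if grouping == "afferent_id"
                          else grouping,
                          n_trials=len(df), n_groups=n_groups,
                          control_mean=control_mean, method=method)


def build_report(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy summary table: one row per metric.

    Columns: metric, control_mean, see_change, se, p, n_trials, n_groups,
    grouping, method. An empty input yields an empty table with the header.
    """
    cols = ["metric", "control_mean", "see_change", "se", "p",
            "n_trials", "n_groups", "grouping", "method"]
    rows = [{"metric": e.response, "control_mean": e.control_mean,
             "see_change": e.effect, "se": e.se, "p": e.p_value,
             "n_trials": e.n_trials, "n_groups": e.n_groups,
             "grouping": e.grouping, "method": e.method}
            for e in estimates]
    return pd.DataFrame(rows, columns=cols)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the tidy report table."""
    if report.empty:
        return "metric  control_mean  see_change  se  p  n_trials  n_groups\n"
    lines = [f"{'metric':<34}{'ctrl mean':>10}{'SEE change':>12}"
             f"{'SE':>9}{'p':>12}{'n':>6}{'groups':>8}"]
    for _, r in report.iterrows():
        lines.append(
            f"{r['metric']:<34}{r['control_mean']:>10.3f}"
            f"{r['see_change']:>12.3f}{r['se']:>9.3f}{r['p']:>12.3g}"
            f"{int(r['n_trials']):>6}{int(r['n_groups']):>8}")
    return "\n".join(lines) + "\n"
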