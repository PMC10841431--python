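"""Study-level model/results surface tying the pipeline stages together.

:class:`StretchStudy` is built from a collection of trials (synthetic or
loaded from disk); :meth:`StretchStudy.fit` runs conditioning, exclusion,
stiffness/RFD estimation, firing-feature extraction, per-trial regressions
and the mixed-model SEE contrasts, and returns a :class:`StudyResults`
carrying the per-trial tables, the effect estimates with their standard
errors and p-values, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import mechanics as mech
from .conditioning import (SignalConfig, condition_channels, exclude_trials,
                           spikes_to_ifr)
from .features import FeatureConfig, extract_features, segment_phases
from .generator import GeneratorParams, generate_dataset
from .records import ConditionedTrial, TrialRecord
from .stats import (EffectEstimate, RegressionResult, build_report,
                    mixed_effect_contrast, regress_ifr, render_report)

logger = logging.getLogger(__name__)

#: metric name -> (table column, grouping column); stiffness responses are
#: grouped by animal, firing responses by afferent.
STUDY_METRICS: dict[str, tuple[str, str]] = {
    "rfd": ("rfd", "animal_id"),
    "k_mtu": ("k_mtu", "animal_id"),
    "k_fas": ("k_fas", "animal_id"),
    "sinusoid_peak_ifr": ("peak_ifr", "afferent_id"),
    "sinusoid_mean_ifr": ("mean_ifr", "afferent_id"),
    "ramp_initial_burst": ("initial_burst", "afferent_id"),
    "ramp_dynamic_response": ("dynamic_response", "afferent_id"),
    "ramp_static_response": ("static_response", "afferent_id"),
    "ramp_dynamic_index": ("dynamic_index", "afferent_id"),
    "triangle_initial_burst": ("initial_burst", "afferent_id"),
    "triangle_mean_ifr_stretch1": ("mean_ifr", "afferent_id"),
    "triangle_spike_count_stretch1": ("spike_count", "afferent_id"),
    "triangle_hd_mean_ifr": ("history_dependence_mean_ifr", "afferent_id"),
    "triangle_hd_spike_count": ("history_dependence_spike_count",
                                "afferent_id"),
}


class StretchStudy:
    """A stretch study: trials under CTRL and SEE awaiting analysis.

    Parameters
    ----------
    trials : iterable of TrialRecord
    signal_config : SignalConfig, optional
        Conditioning parameters (decimation, filters, calibration).
    feature_config : FeatureConfig, optional
        Firing-metric windowing conventions.
    predictors : sequence of str, optional
        Mechanical channels regressed against IFR per trial.
    """

    def __init__(
        self,
        trials: Iterable[TrialRecord],
        signal_config: Optional[SignalConfig] = None,
        feature_config: Optional[FeatureConfig] = None,
        predictors: Sequence[str] = ConditionedTrial.PREDICTORS,
    ) -> None:
        self.trials = list(trials)
        if not self.trials:
            raise ValueError("study needs at least one trial")
        self.signal_config = signal_config or SignalConfig()
        self.feature_config = feature_config or FeatureConfig()
        self.predictors = tuple(predictors)

    @classmethod
    def simulate(
        cls,
        protocols: Sequence[str] = ("sinusoid", "ramp_hold", "triangle"),
        params: GeneratorParams = GeneratorParams(),
        n_animals: int = 5,
        afferents_per_animal: int = 2,
        trials_per_condition: int = 2,
        seed: int = 0,
        **kw,
    ) -> "StretchStudy":
        """Build a study from the synthetic generator (known ground truth)."""
        trials = generate_dataset(
            protocols=protocols, params=params, n_animals=n_animals,
            afferents_per_animal=afferents_per_animal,
            trials_per_condition=trials_per_condition, seed=seed)
        return cls(trials, **kw)

    @classmethod
    def from_manifest(cls, path, **kw) -> "StretchStudy":
        """Load all trials listed in a dataset manifest file."""
        from .io import load_manifest
        return cls(load_manifest(path), **kw)

    # ----------------------------------------------------------------- #

    def fit(self, require_both_conditions: bool = True) -> "StudyResults":
        """Run the full pipeline and contrast SEE against CTRL."""
        kept, excluded = exclude_trials(self.trials)
        if not kept:
            raise ValueError("no trials survive the exclusion rules")
        conds = {t.condition for t in kept}
        if require_both_conditions and conds != {"CTRL", "SEE"}:
            raise ValueError(
                "the SEE contrast needs trials in both CTRL and SEE "
                f"conditions; this dataset has only {sorted(conds)}")

        rows: list[dict] = []
        regressions: list[RegressionResult] = []
        skipped_fits: list[tuple[str, str]] = []
        for rec in kept:
            cond = condition_channels(rec, self.signal_config)
            seg = segment_phases(cond)
            row = {"trial_id": rec.trial_id, "animal_id": rec.animal_id,
                   "afferent_id": rec.afferent_id, "condition": rec.condition,
                   "protocol": rec.protocol.kind}
            try:
                st = mech.stiffness_and_rfd(cond, seg)
                row.update(rfd=st.rfd, k_mtu=st.k_mtu, k_fas=st.k_fas)
            except (mech.ThresholdNotReached, ValueError) as exc:
                skipped_fits.append((rec.trial_id, str(exc)))
                logger.info("stiffness fit skipped for %s: %s",
                            rec.trial_id, exc)
                row.update(rfd=math.nan, k_mtu=math.nan, k_fas=math.nan)
            fs = extract_features(cond, seg, self.feature_config)
            row.update({k: v for k, v in fs.to_dict().items()
                        if isinstance(v, (int, float))})
            rows.append(row)
            ifr = spikes_to_ifr(rec.spike_times)
            for pred in self.predictors:
                regressions.append(regress_ifr(cond, ifr, pred, seg=seg))

        table = pd.DataFrame(rows)
        effects: list[EffectEstimate] = []
        for metric, (col, grouping) in STUDY_METRICS.items():
            sub = table
            if metric.startswith(("sinusoid", "ramp", "triangle")):
                proto = ("ramp_hold" if metric.startswith("ramp")
                         else metric.split("_")[0])
                sub = table[table["protocol"] == proto]
            if sub.empty or col not in sub.columns:
                continue
            if sub[col].dropna().empty:
                continue
            try:
                est = mixed_effect_contrast(sub, col, grouping)
                est.response = metric
                effects.append(est)
            except ValueError as exc:
                logger.info("contrast for %s skipped: %s", metric, exc)
        return StudyResults(
            study=self, trial_table=table, effects=effects,
            regressions=regressions, exclusions=excluded,
            skipped_fits=skipped_fits)

    def contrast_regression(
        self, predictor: str, protocol: str,
        results: "StudyResults", quantity: str = "slope",
    ) -> EffectEstimate:
        """SEE contrast on a per-trial regression quantity (slope, r_squared)."""
        reg = results.regression_table
        meta = results.trial_table[["trial_id", "afferent_id", "condition",
                                    "protocol"]]
        df = reg.merge(meta, on="trial_id")
        df = df[(df["predictor"] == predictor) & (df["protocol"] == protocol)
                & df["ok"]]
        est = mixed_effect_contrast(df, quantity, "afferent_id")
        est.response = f"{protocol}_{predictor}_{quantity}"
        return est


@dataclass
class StudyResults:
    """Fitted study: per-trial tables, effect estimates, diagnostics."""

    study: StretchStudy
    trial_table: pd.DataFrame
    effects: list[EffectEstimate]
    regressions: list[RegressionResult]
    exclusions: list = field(default_factory=list)
    skipped_fits: list = field(default_factory=list)

    @property
    def report(self) -> pd.DataFrame:
        return build_report(self.effects)

    @property
    def regression_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.regressions])

    def effect(self, metric: str) -> EffectEstimate:
        for e in self.effects:
            if e.response == metric:
                return e
        raise KeyError(f"no effect estimate for metric {metric!r}")

    def summary(self) -> str:
        """Human-readable study summary."""
        n = len(self.trial_table)
        header = (
            "Series-compliance stretch study\n"
            f"  trials analysed: {n} "
            f"({len(self.exclusions)} excluded, "
            f"{len(self.skipped_fits)} stiffness fits skipped)\n"
            f"  animals: {self.trial_table['animal_id'].nunique()}, "
            f"afferents: {self.trial_table['afferent_id'].nunique()}\n"
            "  SEE fixed effect per metric "
            "(random intercept per animal/afferent):\n\n")
        return header + render_report(self.report)

    def save(self, outdir) -> None:
        """Write the tidy report, trial table and regression table as CSV."""
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(outdir / "effects.csv", index=False)
        self.trial_table.to_csv(outdir / "trial_features.csv", index=False)
        self.regression_table.to_csv(outdir / "regressions.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary())

    def plot_effects(self, ax=None):
        """Bar plot of the SEE effects with ±1 SE error bars."""
        import matplotlib.pyplot as plt
        rep = self.report
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.bar(rep["metric"], rep["see_change"], yerr=rep["se"],
               color="#4878a8", capsize=3)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_ylabel("SEE − CTRL")
        ax.set_xticklabels(rep["metric"], rotation=60, ha="right",
                           fontsize=7)
        ax.figure.tight_layout()
        return ax
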