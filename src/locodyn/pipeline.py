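"""Cohort-level pipeline: per-individual analyses plus group tables.

A cohort is a manifest of individuals — each an ActivitySeries (or a path to
a two-column series file) with an id and a group label.  ``run_spectrum``
produces per-individual rhythm summaries and a group mean±SEM table with a
one-way ANOVA and Dunnett-vs-control comparison per column; ``run_behavior``
does the same for bout-statistics parameters and optionally the full
threshold sweep.  Group hypothesis testing is delegated to scipy.stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, wavelet
from .io import read_series
from .preprocess import ActivitySeries, normalize_series

__all__ = ["CohortMember", "run_spectrum", "run_behavior", "group_table"]

logger = logging.getLogger("locodyn")


@dataclass(frozen=True)
class CohortMember:
    """One individual in a cohort manifest."""

    id: str
    series: ActivitySeries | str | Path
    group: str = "default"

    def load(self, normalize: bool = False) -> ActivitySeries:
        s = self.series
        if not isinstance(s, ActivitySeries):
            s = read_series(s)
        if normalize and not s.normalized:
            s = normalize_series(s)
        return s


def _group_stats(df: pd.DataFrame, columns: Sequence[str], control: str) -> pd.DataFrame:
    """Mean ± SEM per group and column, with one-way ANOVA p and Dunnett p
    (vs the control group) where at least two groups have n >= 2."""
    rows = []
    groups = list(dict.fromkeys(df["group"]))
    for col in columns:
        sub = df[["group", col]].dropna()
        per_group = {g: sub.loc[sub["group"] == g, col].to_numpy() for g in groups}
        per_group = {g: v for g, v in per_group.items() if v.size > 0}
        anova_p = np.nan
        arrays = [v for v in per_group.values() if v.size >= 2]
        if len(arrays) >= 2:
            try:
                anova_p = float(stats.f_oneway(*arrays).pvalue)
            except ValueError:
                pass
        dunnett_p: dict[str, float] = {}
        treat = [g for g in per_group if g != control]
        if (
            control in per_group
            and per_group[control].size >= 2
            and treat
            and all(per_group[g].size >= 2 for g in treat)
        ):
            try:
                res = stats.dunnett(
                    *[per_group[g] for g in treat], control=per_group[control]
                )
                dunnett_p = dict(zip(treat, map(float, res.pvalue)))
            except ValueError:
                pass
        for g, v in per_group.items():
            rows.append(
                {
                    "parameter": col,
                    "group": g,
                    "n": int(v.size),
                    "mean": float(np.mean(v)),
                    "sem": float(stats.sem(v)) if v.size >= 2 else np.nan,
                    "anova_p": anova_p,
                    "dunnett_p_vs_control": dunnett_p.get(g, np.nan),
                }
            )
    return pd.DataFrame(rows)


def group_table(df: pd.DataFrame, columns: Sequence[str], control: str | None = None) -> pd.DataFrame:
    """Public wrapper building the mean±SEM/ANOVA/Dunnett table from a
    per-individual DataFrame with a ``group`` column."""
    if control is None:
        control = df["group"].iloc[0]
    return _group_stats(df, columns, control)


def run_spectrum(
    cohort: Sequence[CohortMember],
    params: wavelet.WaveletParams = wavelet.WaveletParams(),
    normalize: bool = True,
    control: str | None = None,
) -> dict:
    """Wavelet rhythm analysis of every individual plus a group table.

    Individuals whose record yields no circadian peak contribute NaN to the
    T_cir column and are therefore excluded from that comparison (but not
    from the band areas).  Per-individual failures are logged and skipped.
    """
    rows = []
    spectra: dict[str, wavelet.SpectrumDensity] = {}
    for member in cohort:
        try:
            series = member.load(normalize=normalize)
            mod = wavelet.cwt_modulus(series, params.clipped_to_nyquist(series.dt))
            spec = wavelet.normalized_spectrum(mod)
            summary = wavelet.band_areas(spec)
            spectra[member.id] = spec
            rows.append(
                {
                    "id": member.id,
                    "group": member.group,
                    "T_cir_h": np.nan if summary.T_cir_h is None else summary.T_cir_h,
                    "A_cir": summary.A_cir,
                    "A_ult": summary.A_ult,
                    "R": np.nan if summary.R is None else summary.R,
                }
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("spectrum failed for %s: %s", member.id, exc)
    if not rows:
        raise ValueError("no individual succeeded")
    individuals = pd.DataFrame(rows)
    control = control if control is not None else individuals["group"].iloc[0]
    table = _group_stats(individuals, ["T_cir_h", "A_cir", "A_ult", "R"], control)
    logger.info("spectrum: %d individuals analyzed", len(individuals))
    return {"individuals": individuals, "group_table": table, "spectra": spectra}


def run_behavior(
    cohort: Sequence[CohortMember],
    multiplier: float = 1.0,
    sweep: bool = False,
    multipliers: tuple[float, ...] = behavior.SWEEP_MULTIPLIERS,
    rest_range: tuple[float, float] = behavior.REST_FIT_RANGE,
    act_range: tuple[float, float] = behavior.ACTIVE_FIT_RANGE,
    control: str | None = None,
) -> dict:
    """Bout-statistics analysis of every individual plus group tables.

    Returns per-individual (mean_rest_s, mean_act_s, gamma, beta), the group
    mean±SEM table, the per-individual rescaled distributions, and — when
    ``sweep`` is set — a long-format table of fitted parameters per threshold
    multiplier per individual.
    """
    rows = []
    dists: dict[str, dict[str, behavior.CumulativeDistribution]] = {}
    sweep_frames = []
    for member in cohort:
        try:
            series = member.load()
            sample = behavior.extract_durations(
                series, behavior.ThresholdSpec(multiplier=multiplier)
            )
            rest = behavior.rescaled_cumulative(sample.resting, dt=series.dt)
            act = behavior.rescaled_cumulative(sample.active, dt=series.dt)
            pl = behavior.fit_power_law(rest, rest_range)
            se = behavior.fit_stretched_exponential(act, act_range)
            dists[member.id] = {"resting": rest, "active": act}
            rows.append(
                {
                    "id": member.id,
                    "group": member.group,
                    "mean_rest_s": sample.mean_rest,
                    "mean_act_s": sample.mean_act,
                    "gamma": pl.gamma,
                    "beta": se.beta,
                    "n_rest": len(sample.resting),
                    "n_act": len(sample.active),
                }
            )
            if sweep:
                sw = behavior.threshold_sweep(series, multipliers, rest_range, act_range)
                sw.insert(0, "id", member.id)
                sw.insert(1, "group", member.group)
                sweep_frames.append(sw)
        except (ValueError, RuntimeError) as exc:
            logger.warning("behavior failed for %s: %s", member.id, exc)
    if not rows:
        raise ValueError("no individual succeeded")
    individuals = pd.DataFrame(rows)
    control = control if control is not None else individuals["group"].iloc[0]
    table = _group_stats(
        individuals, ["mean_rest_s", "mean_act_s", "gamma", "beta"], control
    )
    out = {"individuals": individuals, "group_table": table, "distributions": dists}
    if sweep:
        out["sweep"] = pd.concat(sweep_frames, ignore_index=True)
    logger.info("behavior: %d individuals analyzed", len(individuals))
    return out
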