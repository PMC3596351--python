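"""Statistical laws of behavioral organization.

An activity record is dichotomized at a threshold proportional to the mean of
its non-zero values: samples strictly above the threshold are *active*, the
rest are *resting*.  Maximal runs of each state become bout durations.  Their
mean-rescaled cumulative distributions P(>=x) follow, empirically, a
power law for resting bouts,

    P(>= x) ~ A * x**(-gamma),

and a stretched exponential (Weibull-type survival) for active bouts,

    P(>= x) = exp(-(x / x0)**beta).

A smaller gamma means a fatter resting tail — more intermittent behavior.
Both laws are fitted by orthogonal distance regression (errors in both
coordinates) with Levenberg-Marquardt refinement and multi-start
local-minimum selection on the chi-square statistic, the resting law on
log10 P vs log10 x over x in [0.2, 20], the active law on ln P vs x over
x in [0.1, 10].  A threshold sweep (0.6x to 1.8x the non-zero mean) probes
robustness of the fitted exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import odr

from .preprocess import ActivitySeries, mean_nonzero

__all__ = [
    "ThresholdSpec",
    "DurationSample",
    "CumulativeDistribution",
    "PowerLawFit",
    "StretchedExpFit",
    "GroupDistribution",
    "DEFAULT_GRID",
    "REST_FIT_RANGE",
    "ACTIVE_FIT_RANGE",
    "SWEEP_MULTIPLIERS",
    "extract_durations",
    "rescaled_cumulative",
    "fit_power_law",
    "fit_stretched_exponential",
    "threshold_sweep",
    "group_average",
]

REST_FIT_RANGE: tuple[float, float] = (0.2, 20.0)
ACTIVE_FIT_RANGE: tuple[float, float] = (0.1, 10.0)
SWEEP_MULTIPLIERS: tuple[float, ...] = tuple(np.round(np.arange(0.6, 1.81, 0.1), 1))

#: Shared evaluation grid for rescaled cumulative distributions:
#: 20 points per decade over 4 decades around the (unit) mean.
DEFAULT_GRID: np.ndarray = 10.0 ** (np.arange(-2 * 20, 2 * 20 + 1) / 20.0)


@dataclass(frozen=True)
class ThresholdSpec:
    """Rest/activity threshold: ``multiplier`` times the series' non-zero mean.

    An explicit ``theta`` overrides the multiplier (used e.g. when ground
    truth places the threshold between baseline and burst levels).
    """

    multiplier: float = 1.0
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("threshold multiplier must be positive")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("explicit theta must be positive")

    def resolve(self, series: ActivitySeries) -> float:
        if self.theta is not None:
            return self.theta
        return self.multiplier * mean_nonzero(series)


@dataclass(frozen=True)
class DurationSample:
    """Interior resting/active bout durations of one record (seconds)."""

    resting: np.ndarray
    active: np.ndarray
    dt: float
    theta: float
    threshold: ThresholdSpec

    @property
    def mean_rest(self) -> float:
        return float(np.mean(self.resting))

    @property
    def mean_act(self) -> float:
        return float(np.mean(self.active))


@dataclass(frozen=True)
class CumulativeDistribution:
    """P(>= x) tabulated on a grid; non-increasing, starts at 1."""

    x: np.ndarray
    P: np.ndarray
    bin_width: float
    n: int = 0
    low_confidence: bool = False


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    amplitude: float
    fit_range: tuple[float, float]
    chi2: float
    n_points: int


@dataclass(frozen=True)
class StretchedExpFit:
    beta: float
    x0: float
    fit_range: tuple[float, float]
    chi2: float
    n_points: int


@dataclass(frozen=True)
class GroupDistribution:
    x: np.ndarray
    mean_P: np.ndarray
    sem: np.ndarray
    n: int


# -- bout extraction ----------------------------------------------------------

def _run_lengths(active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean series -> (lengths, states)."""
    change = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [len(active)]))
    lengths = np.diff(bounds)
    states = active[bounds[:-1]]
    return lengths, states


def extract_durations(
    series: ActivitySeries, thr: ThresholdSpec = ThresholdSpec()
) -> DurationSample:
    """Classify samples at the threshold and collect interior bout durations.

    value > theta is active, value <= theta resting.  The first and last
    runs are truncated by the recording boundaries (their true length is
    unknowable) and are discarded.
    """
    theta = thr.resolve(series)
    is_act = series.values > theta
    lengths, states = _run_lengths(is_act)
    if len(lengths) < 3:
        raise ValueError(
            f"only {len(lengths)} runs at theta={theta:g}; no interior bouts"
        )
    lengths, states = lengths[1:-1], states[1:-1]
    durations = lengths * series.dt
    return DurationSample(
        resting=durations[~states],
        active=durations[states],
        dt=series.dt,
        theta=theta,
        threshold=thr,
    )


# -- rescaled cumulative distributions ---------------------------------------

def rescaled_cumulative(
    durations: np.ndarray,
    mean: float | None = None,
    dt: float = 0.1,
    grid: np.ndarray | None = None,
    min_count: int = 50,
) -> CumulativeDistribution:
    """Mean-rescale durations and tabulate P(>= x) on the shared log grid.

    Durations are divided by ``mean`` (default: their own arithmetic mean).
    The density is accumulated on bins of the rescaled sampling width
    ``dt / mean`` and cumulated from above, so P equals the exact empirical
    survival fraction at each grid point and P at the smallest populated
    grid point is 1.

    Samples smaller than ``min_count`` are flagged low-confidence, not
    rejected.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("empty duration sample")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if mean is None:
        mean = float(np.mean(durations))
    if mean <= 0:
        raise ValueError("mean must be positive")
    r = np.sort(durations / mean)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    # survival at x: fraction of rescaled durations >= x
    p = 1.0 - np.searchsorted(r, grid, side="left") / r.size
    return CumulativeDistribution(
        x=grid,
        P=p,
        bin_width=dt / mean,
        n=int(r.size),
        low_confidence=r.size < min_count,
    )


# -- chi-square ODR fits ------------------------------------------------------

def _odr_multistart(model, x, y, starts, maxit: int = 200):
    """Run scipy.odr from several starts; return the converged output with
    the smallest chi-square (sum of squared orthogonal residuals)."""
    best = None
    data = odr.Data(x, y)
    for b0 in starts:
        out = odr.ODR(data, model, beta0=list(b0), maxit=maxit).run()
        if out.info >= 4:  # no convergence
            continue
        if best is None or out.sum_square < best.sum_square:
            best = out
    if best is None:
        raise RuntimeError("ODR failed to converge from every start")
    return best


def fit_power_law(
    dist: CumulativeDistribution,
    fit_range: tuple[float, float] = REST_FIT_RANGE,
    min_points: int = 10,
) -> PowerLawFit:
    """Fit P(>=x) = A * x**-gamma on log10-log10 coordinates by multi-start ODR."""
    lo, hi = fit_range
    mask = (dist.x >= lo) & (dist.x <= hi) & (dist.P > 0)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} usable grid points in [{lo}, {hi}]"
        )
    lx = np.log10(dist.x[mask])
    ly = np.log10(dist.P[mask])
    model = odr.Model(lambda b, x: b[0] - b[1] * x)
    # crude slope seed from the endpoints, plus spread-out alternatives
    slope0 = -(ly[-1] - ly[0]) / (lx[-1] - lx[0]) if lx[-1] > lx[0] else 1.0
    starts = [(ly[0] + slope0 * lx[0], slope0)] + [
        (0.0, g) for g in (0.3, 0.6, 1.0, 1.5)
    ]
    out = _odr_multistart(model, lx, ly, starts)
    return PowerLawFit(
        gamma=float(out.beta[1]),
        amplitude=float(10.0 ** out.beta[0]),
        fit_range=fit_range,
        chi2=float(out.sum_square),
        n_points=int(mask.sum()),
    )


def fit_stretched_exponential(
    dist: CumulativeDistribution,
    fit_range: tuple[float, float] = ACTIVE_FIT_RANGE,
    min_points: int = 10,
) -> StretchedExpFit:
    """Fit P(>=x) = exp(-(x/x0)**beta) on (x, ln P) by multi-start ODR."""
    lo, hi = fit_range
    mask = (dist.x >= lo) & (dist.x <= hi) & (dist.P > 0)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} usable grid points in [{lo}, {hi}]"
        )
    x = dist.x[mask]
    ly = np.log(dist.P[mask])

    def f(b, xx):
        beta, x0 = b
        return -np.power(np.abs(xx) / np.abs(x0), beta)

    # x0 seed: x where ln P crosses -1
    i0 = int(np.argmin(np.abs(ly + 1.0)))
    x0_seed = float(x[i0]) if ly[i0] < -1e-3 else 1.0
    starts = [(b, x0_seed) for b in (0.3, 0.5, 0.8, 1.0, 1.5)]
    out = _odr_multistart(odr.Model(f), x, ly, starts)
    beta, x0 = float(out.beta[0]), float(abs(out.beta[1]))
    if beta <= 0 or x0 <= 0:
        raise RuntimeError(f"stretched-exponential fit degenerate: beta={beta}, x0={x0}")
    return StretchedExpFit(
        beta=beta,
        x0=x0,
        fit_range=fit_range,
        chi2=float(out.sum_square),
        n_points=int(mask.sum()),
    )


# -- threshold sweep and group curves ----------------------------------------

def threshold_sweep(
    series: ActivitySeries,
    multipliers: tuple[float, ...] = SWEEP_MULTIPLIERS,
    rest_range: tuple[float, float] = REST_FIT_RANGE,
    act_range: tuple[float, float] = ACTIVE_FIT_RANGE,
) -> pd.DataFrame:
    """Full extraction + rescaling + both fits at each threshold multiplier.

    Returns one row per multiplier with columns (m, theta, gamma, beta,
    mean_rest_s, mean_act_s, n_rest, n_act, error).  A failing multiplier
    yields a row with the error message; the sweep continues.
    """
    rows = []
    for m in multipliers:
        row: dict = {"m": float(m)}
        try:
            sample = extract_durations(series, ThresholdSpec(multiplier=float(m)))
            rest = rescaled_cumulative(sample.resting, dt=series.dt)
            act = rescaled_cumulative(sample.active, dt=series.dt)
            pl = fit_power_law(rest, rest_range)
            se = fit_stretched_exponential(act, act_range)
            row.update(
                theta=sample.theta,
                gamma=pl.gamma,
                beta=se.beta,
                mean_rest_s=sample.mean_rest,
                mean_act_s=sample.mean_act,
                n_rest=len(sample.resting),
                n_act=len(sample.active),
                error=None,
            )
        except (ValueError, RuntimeError) as exc:
            row.update(
                theta=np.nan,
                gamma=np.nan,
                beta=np.nan,
                mean_rest_s=np.nan,
                mean_act_s=np.nan,
                n_rest=0,
                n_act=0,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def group_average(
    dists: list[CumulativeDistribution],
    align_at: float | None = None,
) -> GroupDistribution:
    """Pointwise mean and SEM of individual cumulative distributions.

    All distributions must share the same grid.  ``align_at`` optionally
    rescales each curve vertically so all take the same (geometric-mean)
    value at that x — a display convention for overlaying log-log curves;
    never use the aligned curves for fitting.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 individuals")
    x = dists[0].x
    for d in dists[1:]:
        if len(d.x) != len(x) or not np.allclose(d.x, x):
            raise ValueError("distributions are on mismatched grids")
    P = np.vstack([d.P for d in dists])
    if align_at is not None:
        i = int(np.argmin(np.abs(x - align_at)))
        ref = P[:, i]
        if np.any(ref <= 0):
            raise ValueError(f"some curves vanish at alignment point x={align_at}")
        target = np.exp(np.mean(np.log(ref)))
        P = P * (target / ref)[:, None]
    mean = P.mean(axis=0)
    sem = P.std(axis=0, ddof=1) / np.sqrt(P.shape[0])
    return GroupDistribution(x=x, mean_P=mean, sem=sem, n=P.shape[0])
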