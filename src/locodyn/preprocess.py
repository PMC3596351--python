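"""Raw sensor signal -> local-variance activity series.

A piezo-type locomotor sensor produces a zero-mean voltage trace sampled at
high rate (e.g. 100 Hz).  Activity is quantified as the *local variance*: the
trace is cut into consecutive non-overlapping windows, a straight line is
fitted and subtracted within each window (removing slow drift), and the
population variance of the residuals becomes one activity sample per window.
Normalizing the resulting series by its record mean gives the dimensionless
"nVar" units in which records of animals with different body mass are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RawSignal",
    "ActivitySeries",
    "compute_local_variance",
    "normalize_series",
    "mean_nonzero",
    "coarsen",
]


@dataclass(frozen=True)
class RawSignal:
    """Uniformly sampled sensor trace.

    Parameters
    ----------
    dt_raw : float
        Sampling interval in seconds (0.01 for a 100 Hz acquisition).
    values : numpy.ndarray
        Sensor samples in arbitrary (voltage) units.
    t0 : float
        Time of the first sample, seconds.
    """

    dt_raw: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt_raw <= 0:
            raise ValueError("dt_raw must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raw signal contains non-finite samples")


@dataclass(frozen=True)
class ActivitySeries:
    """Uniformly sampled nonnegative activity series (local variances).

    ``dt`` is the window size the series was computed at (seconds); values are
    per-window variances, optionally normalized so their record mean is 1.
    """

    dt: float
    values: np.ndarray
    normalized: bool = False
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1:
            raise ValueError("activity series must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("activity values must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (left edge of each window)."""
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.dt * len(self.values)

    def mean_nonzero(self) -> float:
        return mean_nonzero(self)


def compute_local_variance(raw: RawSignal, window: float) -> ActivitySeries:
    """Windowed linear detrending followed by per-window population variance.

    The raw trace is partitioned into consecutive non-overlapping windows of
    ``window`` seconds.  Within each window an ordinary least-squares line is
    fitted and subtracted; the output value for that window is the population
    variance (divide by n) of the residuals.  A trailing partial window is
    discarded.

    Parameters
    ----------
    raw : RawSignal
    window : float
        Window length in seconds; must be an integer multiple of
        ``raw.dt_raw`` and span at least 2 raw samples.

    Returns
    -------
    ActivitySeries
        One value per full window, ``dt == window``, not normalized.
    """
    ratio = window / raw.dt_raw
    n = int(round(ratio))
    if not np.isclose(ratio, n, rtol=0, atol=1e-9 * max(1.0, ratio)):
        raise ValueError(
            f"window ({window} s) must be an integer multiple of the raw "
            f"sampling interval ({raw.dt_raw} s)"
        )
    if n < 2:
        raise ValueError("window must span at least 2 raw samples")
    n_win = len(raw.values) // n
    if n_win < 1:
        raise ValueError("signal shorter than one window")

    y = raw.values[: n_win * n].reshape(n_win, n)
    # Shared regressor: window-local time, centered.  Residual variance of an
    # OLS line fit is var(y) - cov(t, y)^2 / var(t), all population moments.
    tc = np.arange(n, dtype=float) - (n - 1) / 2.0
    stt = np.mean(tc * tc)
    yc = y - y.mean(axis=1, keepdims=True)
    sty = yc @ tc / n
    var = np.mean(yc * yc, axis=1) - sty * sty / stt
    np.clip(var, 0.0, None, out=var)  # guard round-off below zero
    return ActivitySeries(dt=window, values=var, normalized=False, t0=raw.t0)


def normalize_series(series: ActivitySeries) -> ActivitySeries:
    """Divide every value by the record mean so the output mean is 1."""
    m = float(np.mean(series.values))
    if m <= 0:
        raise ValueError("cannot normalize an all-zero activity series")
    return replace(series, values=series.values / m, normalized=True)


def coarsen(series: ActivitySeries, window: float) -> ActivitySeries:
    """Aggregate an activity series into coarser windows by averaging.

    Used to derive the minute-scale series for spectral work from the
    fine-scale series: each output sample is the mean activity over a
    ``window``-second block (a trailing partial block is discarded).  The
    normalized flag is dropped — the coarse series has its own mean.
    """
    ratio = window / series.dt
    n = int(round(ratio))
    if not np.isclose(ratio, n, rtol=0, atol=1e-9 * max(1.0, ratio)) or n < 1:
        raise ValueError("window must be a positive integer multiple of series dt")
    n_win = len(series.values) // n
    if n_win < 1:
        raise ValueError("series shorter than one window")
    v = series.values[: n_win * n].reshape(n_win, n).mean(axis=1)
    return ActivitySeries(dt=window, values=v, normalized=False, t0=series.t0)


def mean_nonzero(series: ActivitySeries) -> float:
    """Arithmetic mean of the strictly positive activity values.

    This is the basis of the rest/activity threshold: the threshold is a
    multiplier times this quantity.
    """
    pos = series.values[series.values > 0]
    if pos.size == 0:
        raise ValueError("series has no positive values")
    return float(np.mean(pos))
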