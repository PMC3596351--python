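"""Morlet continuous-wavelet spectral analysis of activity series.

The circadian/ultradian content of an activity record x(t) is quantified with
the continuous wavelet transform (CWT) using the complex Morlet mother wavelet

    psi(eta) = pi^(-1/4) * exp(i*omega0*eta) * exp(-eta^2 / 2),

with non-dimensional center frequency ``omega0`` (default 6).  The
Fourier-equivalent frequency of scale ``s`` is

    f = (omega0 + sqrt(2 + omega0^2)) / (4 * pi * s),

so a logarithmic frequency grid translates directly into a scale grid.  The
transform is evaluated by frequency-domain convolution over the zero-padded
series with L2 (energy-preserving) normalization, following the standard
geophysical-wavelet convention.

The *normalized spectrum* is the time integral of |W(s, t)| per scale, divided
by its own trapezoidal integral over frequency on [1e-5, 1e-2] Hz, so every
record's spectrum has unit area and records can be averaged and compared.
Rhythms are then summarized by:

* ``T_cir`` — period (hours) of the most dominant spectral peak in the
  circadian band 1.0e-5 to 2.0e-5 Hz (roughly 14 to 28 h), or None when the
  band contains no significant local maximum (arrhythmic record);
* ``A_cir`` / ``A_ult`` — spectral area of the circadian band and of the
  ultradian band 2.0e-5 to 1.1e-4 Hz (roughly 2.5 to 14 h);
* ``R = A_ult / A_cir`` — relative weight of ultradian rhythmicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .preprocess import ActivitySeries

__all__ = [
    "WaveletParams",
    "WaveletModulus",
    "SpectrumDensity",
    "RhythmSummary",
    "CIRCADIAN_BAND",
    "ULTRADIAN_BAND",
    "fourier_factor",
    "scale_to_frequency",
    "frequency_to_scale",
    "frequency_grid",
    "cwt_modulus",
    "cwt_modulus_direct",
    "normalized_spectrum",
    "spectral_peaks",
    "circadian_period",
    "band_areas",
    "frequency_to_period",
]

CIRCADIAN_BAND: tuple[float, float] = (1.0e-5, 2.0e-5)  # Hz
ULTRADIAN_BAND: tuple[float, float] = (2.0e-5, 1.1e-4)  # Hz


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT configuration.

    omega0 : non-dimensional center frequency of the Morlet wavelet.
    f_min, f_max : analyzed frequency band in Hz.
    voices_per_octave : scale-grid density; 16 resolves a ~5% period shift
        (one grid step is 2**(1/16) ≈ 4.4%).
    """

    omega0: float = 6.0
    f_min: float = 1.0e-5
    f_max: float = 1.0e-2
    voices_per_octave: int = 16

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    def clipped_to_nyquist(self, dt: float) -> "WaveletParams":
        """Copy of these parameters with ``f_max`` limited to the Nyquist
        frequency of a series sampled every ``dt`` seconds.

        The nominal upper band edge (1e-2 Hz, a 100 s period) lies above the
        Nyquist frequency of a 60 s-sampled record; clipping keeps the
        analyzed band physically meaningful without touching the circadian
        and ultradian bands, which sit far below.
        """
        nyq = 0.5 / dt
        if self.f_max <= nyq:
            return self
        if self.f_min >= nyq:
            raise ValueError(f"f_min={self.f_min} Hz at or above Nyquist {nyq} Hz")
        return WaveletParams(
            omega0=self.omega0,
            f_min=self.f_min,
            f_max=nyq,
            voices_per_octave=self.voices_per_octave,
        )


@dataclass(frozen=True)
class WaveletModulus:
    """|W(s, t)| on a (frequency, time) grid, plus edge-effect metadata."""

    freqs: np.ndarray  # Hz, ascending
    times: np.ndarray  # seconds
    modulus: np.ndarray  # shape (len(freqs), len(times)), >= 0
    params: WaveletParams
    dt: float
    coi: np.ndarray | None = None  # cone-of-influence frequency floor per time
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpectrumDensity:
    """Normalized wavelet spectrum: unit trapezoidal area over the grid."""

    freqs: np.ndarray
    density: np.ndarray

    def integral(self, lo: float | None = None, hi: float | None = None) -> float:
        """Trapezoidal integral of the density over [lo, hi] (defaults: full grid)."""
        lo = self.freqs[0] if lo is None else lo
        hi = self.freqs[-1] if hi is None else hi
        return _band_integral(self.freqs, self.density, lo, hi)


@dataclass(frozen=True)
class RhythmSummary:
    """Circadian/ultradian summary of one record."""

    T_cir_h: float | None
    A_cir: float
    A_ult: float
    R: float | None

    def as_dict(self) -> dict:
        return {
            "T_cir_h": self.T_cir_h,
            "A_cir": self.A_cir,
            "A_ult": self.A_ult,
            "R": self.R,
        }


# -- scale <-> frequency ------------------------------------------------------

def fourier_factor(omega0: float = 6.0) -> float:
    """Product f*s for the Morlet wavelet: (omega0 + sqrt(2 + omega0^2)) / 4pi."""
    return (omega0 + math.sqrt(2.0 + omega0**2)) / (4.0 * math.pi)


def scale_to_frequency(s, params: WaveletParams = WaveletParams()):
    """Fourier-equivalent frequency (Hz) of wavelet scale ``s`` (seconds)."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scale must be positive")
    out = fourier_factor(params.omega0) / s
    return float(out) if out.ndim == 0 else out


def frequency_to_scale(f, params: WaveletParams = WaveletParams()):
    """Inverse of :func:`scale_to_frequency`."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = fourier_factor(params.omega0) / f
    return float(out) if out.ndim == 0 else out


def frequency_grid(params: WaveletParams = WaveletParams()) -> np.ndarray:
    """Log-spaced frequency grid, ``voices_per_octave`` points per octave,
    spanning [f_min, f_max] inclusive (ascending)."""
    n_oct = math.log2(params.f_max / params.f_min)
    k = np.arange(math.floor(n_oct * params.voices_per_octave) + 1)
    freqs = params.f_min * 2.0 ** (k / params.voices_per_octave)
    if freqs[-1] < params.f_max * (1 - 1e-12):
        freqs = np.append(freqs, params.f_max)
    return freqs


# -- the transform ------------------------------------------------------------

def cwt_modulus(
    series: ActivitySeries, params: WaveletParams = WaveletParams(), demean: bool = True
) -> WaveletModulus:
    """Morlet CWT modulus by FFT convolution over the zero-padded series.

    For each scale on the logarithmic grid the transform is computed as

        W(s, t_n) = IFFT[ FFT(x) * Psi_hat(s * omega) ],

    with the L2-normalized analytic Morlet kernel
    ``Psi_hat(s*w) = sqrt(2*pi*s/dt) * pi^(-1/4) * exp(-(s*w - omega0)^2 / 2)``
    supported on positive frequencies only.  The record mean is subtracted
    first (``demean``): the offset carries no rhythm information, and against
    the zero padding it would masquerade as a low-frequency edge response
    that biases the circadian peak.  The series is zero-padded to a power of
    two at least twice its length (keeping wraparound negligible at the
    largest scales); padding is removed before the modulus is returned.

    Raises if ``f_max`` exceeds the series Nyquist frequency.  A record
    shorter than one oscillation at ``f_min`` is analyzed anyway, with a
    warning recorded on the result.
    """
    x = series.values
    if demean:
        x = x - x.mean()
    dt = series.dt
    nyq = 0.5 / dt
    if params.f_max > nyq * (1 + 1e-12):
        raise ValueError(
            f"f_max={params.f_max} Hz above the Nyquist frequency {nyq} Hz"
        )
    n = len(x)
    warnings: list[str] = []
    if n * dt < 1.0 / params.f_min:
        warnings.append(
            f"record ({n * dt:.0f} s) shorter than one oscillation at "
            f"f_min={params.f_min} Hz"
        )

    nfft = 1 << max(1, (2 * n - 1).bit_length())
    xhat = np.fft.fft(x, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=dt)

    freqs = frequency_grid(params)
    scales = frequency_to_scale(freqs, params)
    # kernel matrix (n_scales, nfft); analytic wavelet -> positive freqs only
    arg = scales[:, None] * omega[None, :]
    kernel = np.where(
        omega[None, :] > 0,
        np.exp(-0.5 * (arg - params.omega0) ** 2),
        0.0,
    )
    kernel *= (np.pi**-0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    w = np.fft.ifft(xhat[None, :] * kernel, axis=1)[:, :n]
    modulus = np.abs(w)

    # cone of influence: e-folding time sqrt(2)*s -> lowest trustworthy
    # frequency at distance tau from the nearer edge (metadata only)
    t = series.times - series.t0
    edge = np.minimum(t, (n - 1) * dt - t)
    with np.errstate(divide="ignore"):
        coi = fourier_factor(params.omega0) / (math.sqrt(2.0) * np.maximum(edge, dt))
    return WaveletModulus(
        freqs=freqs,
        times=series.times,
        modulus=modulus,
        params=params,
        dt=dt,
        coi=coi,
        warnings=tuple(warnings),
    )


def cwt_modulus_direct(
    series: ActivitySeries, params: WaveletParams = WaveletParams(), demean: bool = True
) -> WaveletModulus:
    """Direct time-domain Morlet CWT (O(n^2) per scale).

    Reference implementation for validating the FFT path on short series:
    identical convention and normalization, truncated (not circular)
    convolution.  The time-domain kernel is the *exact* analytic Morlet —
    the inverse transform of the positive-frequency Gaussian — evaluated in
    closed form, psi0(eta) = pi**-0.25 / 2 * exp(-omega0**2/2)
    * erfcx((-omega0 - i*eta)/sqrt(2)), which reduces to the familiar
    pi**-0.25 * exp(i*omega0*eta - eta**2/2) up to terms of order
    exp(-omega0**2/2).
    """
    from scipy.special import erfcx

    x = series.values
    if demean:
        x = x - x.mean()
    dt = series.dt
    n = len(x)
    freqs = frequency_grid(params)
    scales = frequency_to_scale(freqs, params)
    t = dt * np.arange(n)
    om = params.omega0
    c0 = (np.pi**-0.25) * 0.5 * math.exp(-0.5 * om * om)
    modulus = np.empty((len(scales), n))
    for i, s in enumerate(scales):
        eta = (t[None, :] - t[:, None]) / s  # (b, t')
        psi = c0 * erfcx((-om - 1j * eta) / math.sqrt(2.0))
        w = (psi.conj() @ x) * math.sqrt(dt / s)
        modulus[i] = np.abs(w)
    return WaveletModulus(
        freqs=freqs, times=series.times, modulus=modulus, params=params, dt=dt
    )


# -- spectrum and summaries ---------------------------------------------------

def normalized_spectrum(mod: WaveletModulus) -> SpectrumDensity:
    """Time-integrated modulus per frequency, normalized to unit area.

    The per-frequency time integral of |W| is divided by its trapezoidal
    integral over the frequency grid, so the result integrates to 1.
    """
    raw = mod.modulus.sum(axis=1) * mod.dt
    area = np.trapezoid(raw, mod.freqs)
    if area <= 0:
        raise ValueError("all-zero modulus: spectrum normalization undefined")
    return SpectrumDensity(freqs=mod.freqs, density=raw / area)


def spectral_peaks(
    spec: SpectrumDensity, min_prominence_frac: float = 0.05
) -> np.ndarray:
    """Indices of significant local maxima of the density.

    A peak is significant when its prominence is at least
    ``min_prominence_frac`` of the global density maximum.  Maxima sitting on
    the first or last grid point count as peaks (sentinel padding): a rhythm
    whose period falls at the edge of the analyzed range still produces one.
    """
    prominence = min_prominence_frac * float(np.max(spec.density))
    padded = np.concatenate(([-np.inf], spec.density, [-np.inf]))
    idx, _ = find_peaks(padded, prominence=(prominence, None))
    return idx - 1


def circadian_period(
    spec: SpectrumDensity,
    band: tuple[float, float] = CIRCADIAN_BAND,
    min_prominence_frac: float = 0.05,
) -> float | None:
    """Period (hours) of the dominant circadian-band peak, or None.

    Among significant local maxima of the density with frequency inside
    ``band``, the one with the greatest density wins; its period is 1/f in
    hours.  Returns None when the band holds no significant local maximum —
    the spectral signature of an arrhythmic record.
    """
    idx = spectral_peaks(spec, min_prominence_frac)
    lo, hi = band
    in_band = idx[(spec.freqs[idx] >= lo) & (spec.freqs[idx] <= hi)]
    if in_band.size == 0:
        return None
    best = in_band[np.argmax(spec.density[in_band])]
    return frequency_to_period(float(spec.freqs[best]), unit="hours")


def band_areas(
    spec: SpectrumDensity,
    circadian_band: tuple[float, float] = CIRCADIAN_BAND,
    ultradian_band: tuple[float, float] = ULTRADIAN_BAND,
    min_prominence_frac: float = 0.05,
) -> RhythmSummary:
    """Circadian/ultradian band areas, their ratio, and the circadian period."""
    a_cir = _band_integral(spec.freqs, spec.density, *circadian_band)
    a_ult = _band_integral(spec.freqs, spec.density, *ultradian_band)
    r = a_ult / a_cir if a_cir > 0 else None
    t_cir = circadian_period(spec, circadian_band, min_prominence_frac)
    return RhythmSummary(T_cir_h=t_cir, A_cir=a_cir, A_ult=a_ult, R=r)


def frequency_to_period(
    f: float, unit: str = "hours", ndigits: int | None = None
) -> float:
    """Reciprocal period 1/f in the requested unit ('seconds' or 'hours')."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    period_s = 1.0 / f
    if unit == "seconds":
        out = period_s
    elif unit == "hours":
        out = period_s / 3600.0
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return round(out, ndigits) if ndigits is not None else out


def _band_integral(freqs: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of density over [lo, hi], with the band edges
    placed by log-frequency linear interpolation when they fall between grid
    points."""
    if lo >= hi:
        raise ValueError("band must satisfy lo < hi")
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if lo >= hi:
        return 0.0
    inside = (freqs > lo) & (freqs < hi)
    logf = np.log(freqs)
    f_band = np.concatenate(([lo], freqs[inside], [hi]))
    d_band = np.concatenate(
        (
            [np.interp(math.log(lo), logf, density)],
            density[inside],
            [np.interp(math.log(hi), logf, density)],
        )
    )
    return float(np.trapezoid(d_band, f_band))
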