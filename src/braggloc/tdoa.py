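"""Time-of-arrival estimation by (generalized) cross-correlation.

The delay between two waveforms is taken as the lag that maximizes their
cross-correlation, optionally frequency-weighted (GCC-PHAT / SCOT) and
optionally band-pass prefiltered with a zero-phase filter applied
identically to both channels so the peak location is preserved.
Correlations are computed with zero-padded FFTs (no circular
wrap-around); plain weighting is numerically identical to direct
time-domain cross-correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import butter, sosfiltfilt

from .thermoacoustic import PressureSignal

__all__ = [
    "CorrelationFunction",
    "TDOASet",
    "gcc",
    "estimate_toa",
    "tdoas_from_toas",
]

_WEIGHTINGS = ("plain", "phat", "scot")


@dataclass
class CorrelationFunction:
    """Cross-correlation amplitude versus lag."""

    lags: np.ndarray  # s, uniformly spaced, spanning negative to positive
    values: np.ndarray
    weighting: str = "plain"
    prefilter_band: tuple | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")

    def peak_lag(self, subsample: bool = False) -> float:
        """Lag of the correlation maximum, s.

        Ties at the maximum are broken deterministically toward the
        smallest ``|lag|``.  With ``subsample=True`` a three-point
        parabolic fit refines the peak to sub-sample resolution.
        """
        vmax = self.values.max()
        ties = np.flatnonzero(self.values >= vmax)
        i = int(ties[np.argmin(np.abs(self.lags[ties]))])
        if i == 0 or i == self.values.size - 1:
            warnings.warn(
                "correlation peak at the lag-range boundary: "
                "estimate unreliable",
                stacklevel=2,
            )
            return float(self.lags[i])
        if not subsample:
            return float(self.lags[i])
        ym, y0, yp = self.values[i - 1 : i + 2]
        denom = ym - 2.0 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        dt = self.lags[1] - self.lags[0]
        return float(self.lags[i] + delta * dt)


@dataclass
class TDOASet:
    """Reference-relative time differences of arrival.

    ``tau[i]`` is the arrival-time difference between sensor ``i`` and the
    reference sensor; ``tau[ref_index] == 0`` by construction.
    """

    ref_index: int
    tau: np.ndarray  # s, one entry per sensor (reference entry 0)
    quality: np.ndarray | None = None  # peak-to-secondary ratio per sensor

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if not 0 <= self.ref_index < self.tau.size:
            raise IndexError(
                f"ref_index {self.ref_index} out of range for "
                f"{self.tau.size} sensors"
            )
        if self.tau[self.ref_index] != 0.0:
            raise ValueError("tau at the reference sensor must be 0")


def _prefilter(a: np.ndarray, b: np.ndarray, fs: float, band) -> tuple:
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"prefilter band {band} invalid for fs = {fs}")
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, a), sosfiltfilt(sos, b)


def gcc(
    x_i: PressureSignal,
    x_j: PressureSignal,
    weighting: str = "plain",
    prefilter_band: tuple | None = None,
) -> CorrelationFunction:
    """Generalized cross-correlation of ``x_i`` against ``x_j``.

    The returned correlation at lag ``L`` is
    ``sum_n x_i[n] * x_j[n - L]``: a positive peak lag means ``x_i`` is a
    delayed copy of ``x_j``.  Lags are relative to the sample indices;
    the ``t0`` offsets of the signals are *not* applied here (see
    :func:`estimate_toa`).
    """
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
    if x_i.fs != x_j.fs:
        raise ValueError("signals must share the sample rate")
    a = x_i.samples
    b = x_j.samples
    if not np.any(a) or not np.any(b):
        raise ValueError("all-zero signal: correlation peak undefined")
    if prefilter_band is not None:
        a, b = _prefilter(a, b, x_i.fs, prefilter_band)

    la, lb = a.size, b.size
    nfft = next_fast_len(la + lb - 1)
    fa = rfft(a, nfft)
    fb = rfft(b, nfft)
    spec = fa * np.conj(fb)
    if weighting == "phat":
        mag = np.abs(spec)
        spec = spec / np.where(mag > 0, mag, 1.0)
    elif weighting == "scot":
        denom = np.sqrt(np.abs(fa) ** 2 * np.abs(fb) ** 2)
        spec = spec / np.where(denom > 0, denom, 1.0)
    r = irfft(spec, nfft)
    # lags -(lb-1) .. (la-1)
    values = np.concatenate([r[nfft - (lb - 1) :], r[:la]]) if lb > 1 else r[:la]
    lags = np.arange(-(lb - 1), la) / x_i.fs
    return CorrelationFunction(
        lags=lags, values=values, weighting=weighting,
        prefilter_band=prefilter_band,
    )


def estimate_toa(
    emitted: PressureSignal,
    received: PressureSignal,
    weighting: str = "plain",
    subsample: bool = True,
    prefilter_band: tuple | None = None,
) -> float:
    """Arrival delay (s) of ``received`` relative to ``emitted``.

    The lag of the cross-correlation maximum, plus the difference of the
    signals' start times.  ``subsample=True`` applies three-point
    parabolic peak interpolation.
    """
    corr = gcc(received, emitted, weighting=weighting,
               prefilter_band=prefilter_band)
    return corr.peak_lag(subsample=subsample) + (received.t0 - emitted.t0)


def tdoas_from_toas(toas, ref_index: int = 0) -> TDOASet:
    """Reference-relative TDOAs ``tau_i = t_i - t_ref`` from per-sensor TOAs.

    Invariant under a common additive offset of all TOAs.
    """
    toas = np.asarray(toas, dtype=float)
    if toas.ndim != 1 or toas.size < 2:
        raise ValueError("need at least 2 TOAs")
    if not 0 <= ref_index < toas.size:
        raise IndexError(
            f"ref_index {ref_index} out of range for {toas.size} TOAs"
        )
    return TDOASet(ref_index=ref_index, tau=toas - toas[ref_index])
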