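"""Normalized temporal autocorrelation of complex OCT signals.

The complex analytic signal gives direct access to the first-order field
correlation: after subtracting the temporal mean, the normalized
autocovariance

    g(tau_k) = <S(t) conj(S(t + tau_k))> / <|S(t)|^2>

is the field correlation g1 without invoking the Siegert relation, which
is biased for the non-Gaussian fields produced by small numbers of rods.
An intensity (Siegert) route is provided for comparison.  The zero-lag
point is never reported: it carries the shot-noise power and is excluded
from all downstream fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class DegenerateSignalError(ValueError):
    """Signal has no temporal fluctuation (zero variance after mean removal)."""


class LagGridError(ValueError):
    """Correlation curves do not share a common lag grid."""


@dataclass(frozen=True)
class CorrelationCurve:
    """Lag-indexed normalized autocorrelation, zero lag excluded.

    ``lags_s`` are strictly increasing multiples of the sampling period,
    starting at one period.  ``g`` is dimensionless; with biased (divide by
    N) normalization |g| <= 1 up to estimator noise.
    """

    lags_s: np.ndarray
    g: np.ndarray
    n_samples_used: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_s, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lags_s", lags)
        object.__setattr__(self, "g", g)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValueError("lags and g must be 1-D and equal length")
        if lags.size and (lags[0] <= 0 or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")

    def __len__(self) -> int:
        return self.lags_s.size

    def to_frame(self):
        """Two-column table (lag_s, g), e.g. for CSV export."""
        import pandas as pd

        return pd.DataFrame({"lag_s": self.lags_s, "g": self.g})


def _autocovariance_fft(x: np.ndarray, kmax: int) -> np.ndarray:
    """Biased complex autocovariance for lags 0..kmax via FFT, axis 0."""
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.fft(x, n=nfft, axis=0)
    acov = np.fft.ifft(fx * np.conj(fx), axis=0)[: kmax + 1]
    return acov / n


def normalized_autocorrelation(
    series: np.ndarray,
    dt_s: float,
    *,
    kmax: int | None = None,
    mode: str = "real",
) -> CorrelationCurve:
    """Normalized temporal autocorrelation of one complex time series.

    The temporal mean is subtracted, the biased autocovariance is computed
    (divide by N, which keeps the estimate positive semidefinite), and the
    curve is normalized by its lag-0 value.  Lags run from ``dt_s`` up to
    ``kmax * dt_s`` (default ``kmax = N // 4``, bounding estimator
    variance at long lags).

    Parameters
    ----------
    series : complex ndarray
        Time samples at one depth pixel, length >= 16.
    dt_s : float
        Sampling period (A-line period) in seconds.
    kmax : int, optional
        Largest lag index reported.
    mode : {"real", "magnitude"}
        Report Re g (default; appropriate when there is no systematic
        phase drift) or |g| (robust to slow drift).

    Raises
    ------
    DegenerateSignalError
        If the series has no fluctuation about its mean.
    """
    x = np.asarray(series)
    n = x.shape[0]
    if n < 16:
        raise ValueError(f"series too short for correlation analysis (n={n})")
    if kmax is None:
        kmax = n // 4
    kmax = min(kmax, n - 1)
    x = x - x.mean(axis=0)
    acov = _autocovariance_fft(x, kmax)
    var = acov[0].real
    if np.any(var <= 0) or not np.all(np.isfinite(np.atleast_1d(var))):
        raise DegenerateSignalError("zero variance after mean subtraction")
    gc = acov[1:] / var
    g = np.abs(gc) if mode == "magnitude" else gc.real
    lags = dt_s * np.arange(1, kmax + 1)
    return CorrelationCurve(lags_s=lags, g=g, n_samples_used=n)


def stack_autocorrelations(
    signal: np.ndarray,
    dt_s: float,
    pixels: Sequence[int] | None = None,
    *,
    kmax: int | None = None,
    mode: str = "real",
) -> list[CorrelationCurve]:
    """Per-depth-pixel autocorrelations of a [time, depth] signal.

    Computes all requested pixels in one vectorized FFT pass.  Degenerate
    (zero-variance) pixels yield ``None`` entries rather than raising, so a
    stack with empty above-surface pixels can still be processed.
    """
    sig = np.asarray(signal)
    n, n_depth = sig.shape
    if pixels is None:
        pixels = range(n_depth)
    pixels = list(pixels)
    if kmax is None:
        kmax = n // 4
    kmax = min(kmax, n - 1)
    x = sig[:, pixels] - sig[:, pixels].mean(axis=0)
    acov = _autocovariance_fft(x, kmax)
    var = acov[0].real
    lags = dt_s * np.arange(1, kmax + 1)
    out: list[CorrelationCurve | None] = []
    for j in range(len(pixels)):
        if var[j] <= 0 or not np.isfinite(var[j]):
            out.append(None)
            continue
        gc = acov[1:, j] / var[j]
        g = np.abs(gc) if mode == "magnitude" else gc.real
        out.append(CorrelationCurve(lags_s=lags, g=g, n_samples_used=n))
    return out


def siegert_g1(series: np.ndarray, dt_s: float, *, kmax: int | None = None) -> CorrelationCurve:
    """Field correlation via the intensity route, g1 = sqrt(g2 - 1).

    Computes the normalized intensity autocorrelation g2 of |S|^2 and
    applies the Siegert relation (exact only for circular-Gaussian
    fields).  Values where g2 < 1 are clipped to zero.
    """
    x = np.asarray(series)
    intensity = np.abs(x) ** 2
    n = intensity.shape[0]
    if kmax is None:
        kmax = n // 4
    kmax = min(kmax, n - 1)
    mean_i = intensity.mean()
    if mean_i <= 0:
        raise DegenerateSignalError("zero mean intensity")
    acov = _autocovariance_fft(intensity - mean_i, kmax).real
    var = acov[0]
    if var <= 0:
        raise DegenerateSignalError("zero intensity variance")
    # g2(tau) = <I(t)I(t+tau)>/<I>^2 ; beta = g2(0)-1
    g2_minus_1 = acov[1:] / mean_i**2
    beta = var / mean_i**2
    g1 = np.sqrt(np.clip(g2_minus_1 / beta, 0.0, None))
    lags = dt_s * np.arange(1, kmax + 1)
    return CorrelationCurve(lags_s=lags, g=g1, n_samples_used=n)


def _check_grids(curves: Iterable[CorrelationCurve]) -> np.ndarray:
    curves = list(curves)
    lags = curves[0].lags_s
    for c in curves[1:]:
        if c.lags_s.shape != lags.shape or not np.allclose(c.lags_s, lags):
            raise LagGridError("correlation curves are on different lag grids")
    return lags


def window_average(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of per-pixel curves over a depth window (ROI).

    Averaging the normalized autocorrelations over a depth window of
    pixels suppresses estimator noise; the window is the unit at which
    decay times are fit.
    """
    curves = [c for c in curves if c is not None]
    if not curves:
        raise ValueError("window contains no usable correlation curves")
    lags = _check_grids(curves)
    g = np.mean([c.g for c in curves], axis=0)
    n = int(sum(c.n_samples_used for c in curves))
    return CorrelationCurve(lags_s=lags, g=g, n_samples_used=n)


def iso_combine(g_hh: CorrelationCurve, g_hv: CorrelationCurve) -> CorrelationCurve:
    """Isotropic combination isolating translational decay.

    g_ISO = (9/5) g_HH - (4/5) g_HV removes the orientational term of the
    rod model exactly, leaving exp(-q^2 DT tau) for analytic inputs.
    """
    lags = _check_grids([g_hh, g_hv])
    g = 1.8 * g_hh.g - 0.8 * g_hv.g
    n = min(g_hh.n_samples_used, g_hv.n_samples_used)
    return CorrelationCurve(lags_s=lags, g=g, n_samples_used=n)
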