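"""Exponential decay-time extraction from ROI-averaged correlation curves.

The fit range is set by where the curve itself first falls below 1/e (for
the isotropic, translational curve) or 1/e^2 (for the cross-polarized,
rotational curve); this excludes the noisy correlation tail.  A dynamic
rule extends the 1/e range to 1/e^2 when too few lags remain, as used for
thin-ROI culture analyses.  Fits with fewer than ``min_points`` lags are
rejected, which downstream marks the ROI invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .autocorr import CorrelationCurve

INV_E = math.exp(-1.0)
INV_E2 = math.exp(-2.0)


class FitRangeRule(str, Enum):
    """How the upper end of the fitted lag range is chosen."""

    TO_1_OVER_E = "to_1_over_e"
    TO_1_OVER_E2 = "to_1_over_e2"
    DYNAMIC = "dynamic"  # 1/e, extended to 1/e^2 if fewer than min_points lags


class InsufficientPointsError(ValueError):
    """Fewer usable lags in the fit range than the required minimum."""


class FitRejectionError(ValueError):
    """Fit produced no physically meaningful decay rate."""


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-exponential fit g(tau) = A exp(-rate*tau)."""

    rate_per_s: float
    r_squared: float
    n_points: int
    fit_range_rule: FitRangeRule
    amplitude: float = 1.0
    censored: bool = False

    @property
    def tau_s(self) -> float:
        return 1.0 / self.rate_per_s


def crossing_time(curve: CorrelationCurve, level: float) -> tuple[float, bool]:
    """First lag at which the curve falls below ``level``.

    Returns ``(lag_s, censored)``.  The crossing is the first discrete
    sample strictly below the level (no interpolation).  If the curve never
    falls below, the last lag is returned with ``censored=True``.
    """
    if len(curve) == 0:
        raise ValueError("empty correlation curve")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    below = np.nonzero(curve.g < level)[0]
    if below.size == 0:
        return float(curve.lags_s[-1]), True
    return float(curve.lags_s[below[0]]), False


def _select_range(
    curve: CorrelationCurve, rule: FitRangeRule, min_points: int
) -> tuple[np.ndarray, np.ndarray, FitRangeRule]:
    def lags_upto(level: float) -> np.ndarray:
        t_cross, _ = crossing_time(curve, level)
        return np.nonzero(curve.lags_s <= t_cross)[0]

    if rule is FitRangeRule.TO_1_OVER_E:
        idx = lags_upto(INV_E)
        used = rule
    elif rule is FitRangeRule.TO_1_OVER_E2:
        idx = lags_upto(INV_E2)
        used = rule
    elif rule is FitRangeRule.DYNAMIC:
        idx = lags_upto(INV_E)
        used = FitRangeRule.TO_1_OVER_E
        if idx.size < min_points:
            idx = lags_upto(INV_E2)
            used = FitRangeRule.TO_1_OVER_E2
    else:  # pragma: no cover
        raise ValueError(f"unknown fit-range rule {rule!r}")
    return curve.lags_s[idx], curve.g[idx], used


def fit_decay(
    curve: CorrelationCurve,
    rule: FitRangeRule | str = FitRangeRule.TO_1_OVER_E,
    min_points: int = 4,
    *,
    free_amplitude: bool = False,
) -> DecayFit:
    """Nonlinear least-squares single-exponential fit on the selected lags.

    The model is fit on g itself (not log g), so noisy near-zero or
    negative samples do not break the fit.  The amplitude is pinned to 1 by
    default (the curves are normalized at zero lag); ``free_amplitude``
    releases it.  The initial rate comes from the 1/e crossing.  R^2 is
    computed over the fitted lags only.

    Raises
    ------
    InsufficientPointsError
        If the selected range holds fewer than ``min_points`` lags (after
        dynamic extension where applicable).
    FitRejectionError
        If the fitted rate is not strictly positive.
    """
    rule = FitRangeRule(rule)
    lags, g, used_rule = _select_range(curve, rule, min_points)
    if lags.size < min_points:
        raise InsufficientPointsError(
            f"{lags.size} lags in fit range (need >= {min_points})"
        )
    t_e, censored = crossing_time(curve, INV_E)
    rate0 = 1.0 / t_e

    if free_amplitude:
        def resid(p):
            return p[1] * np.exp(-p[0] * lags) - g
        p0 = [rate0, 1.0]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    else:
        def resid(p):
            return np.exp(-p[0] * lags) - g
        p0 = [rate0]
        bounds = ([0.0], [np.inf])

    sol = least_squares(resid, p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rate = float(sol.x[0])
    amp = float(sol.x[1]) if free_amplitude else 1.0
    # a genuine fit decays by ~1/e over its own range; a censored flat
    # curve converges to a numerically-zero rate instead
    if rate <= 0 or rate * lags[-1] < 1e-6:
        raise FitRejectionError("no measurable decay over the fitted range")
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return DecayFit(
        rate_per_s=rate,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(lags.size),
        fit_range_rule=used_rule,
        amplitude=amp,
        censored=censored,
    )


def estimate_dt(
    g_iso: CorrelationCurve,
    q_per_um: float,
    rule: FitRangeRule | str = FitRangeRule.TO_1_OVER_E,
    min_points: int = 4,
) -> tuple[float, DecayFit]:
    """Translational diffusion (um^2/s) from the isotropic curve.

    The isotropic combination decays as exp(-q^2 DT tau), so DT is the
    fitted rate divided by q^2.
    """
    if q_per_um <= 0:
        raise ValueError("scattering wavenumber must be positive")
    fit = fit_decay(g_iso, rule, min_points)
    return fit.rate_per_s / (q_per_um**2), fit


def estimate_dr(
    g_hv: CorrelationCurve,
    rule: FitRangeRule | str = FitRangeRule.TO_1_OVER_E2,
    min_points: int = 4,
    dt_correction: tuple[float, float] | None = None,
) -> tuple[float, DecayFit]:
    """Rotational diffusion (rad^2/s) from the cross-polarized curve.

    By default uses the fast-rotation approximation DR = rate / 6, valid
    when the translational decay is much slower than the rotational one.
    Passing ``dt_correction=(q_per_um, dt_um2_s)`` subtracts the
    translational contribution: DR = (rate - q^2 DT) / 6.
    """
    fit = fit_decay(g_hv, rule, min_points)
    rate = fit.rate_per_s
    if dt_correction is not None:
        q, dt_coef = dt_correction
        rate = rate - q * q * dt_coef
        if rate <= 0:
            raise FitRejectionError(
                "translational correction leaves no rotational decay"
            )
    return rate / 6.0, fit
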