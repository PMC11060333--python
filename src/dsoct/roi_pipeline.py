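"""Depth-resolved ROI analysis: segmentation, fitting, validity screening.

An M-mode stack is segmented into depth windows (ROIs) below a detected
top surface.  Per-pixel autocorrelations are averaged within each ROI,
the isotropic combination is formed, decay times are fit, and each ROI is
screened by a set of validity rules:

* ``surface``   — the ROI lies a safe offset below the specular surface
  (enforced by segmentation; recorded for provenance);
* ``snr``       — the mean co-polarized power clears a multiple of the
  above-surface background power;
* ``anisotropy``— the decay-time ratio tau_ISO/tau_HV is at least 1.5,
  the signature of rod-dominated dynamic scattering;
* ``iso_range`` / ``hv_range`` — each decay time sits inside the dynamic
  range of the recording (well above the sampling period, well below the
  total duration); the isotropic check gates DT, the cross-polarized
  check gates DR;
* ``r2_iso`` / ``r2_hv`` — per-channel coefficient-of-determination
  thresholds on the exponential fits;
* outlier flags — diffusion values many standard deviations from the
  stack mean are flagged for review, never auto-excluded.

Culture mode (thin ROIs on mucus-secreting cell cultures) disables the
R^2 and outlier screens, whose assumptions of homogeneity do not hold,
and uses a dynamic fit range for the isotropic curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autocorr import CorrelationCurve, iso_combine, stack_autocorrelations, window_average
from .decay_fit import (
    INV_E,
    FitRangeRule,
    FitRejectionError,
    InsufficientPointsError,
    crossing_time,
    estimate_dr,
    estimate_dt,
)
from .speckle_sim import MModeStack


class SurfaceNotFoundError(RuntimeError):
    """No depth pixel rises above the detection threshold."""


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds for ROI segmentation and validity screening.

    Defaults correspond to stationary-sample analysis; see ``PRESETS`` for
    the named configurations (stationary PEO, stationary mucus, culture).
    """

    surface_offset_px: int = 15
    roi_height_px: int = 20
    hh_snr_threshold: float = 3.0
    anisotropy_min: float = 1.5
    tau_min_factor: float = 2.0   # decay time must exceed this many A-line periods
    tau_max_factor: float = 10.0  # and stay under duration / this factor
    r2_threshold: float = 0.90
    outlier_sigma: float = 5.0
    culture_mode: bool = False

    def __post_init__(self) -> None:
        if self.roi_height_px < 1:
            raise ValueError("ROI height must be at least 1 pixel")
        for name in ("hh_snr_threshold", "anisotropy_min", "tau_min_factor",
                     "tau_max_factor", "r2_threshold", "outlier_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FitConfig:
    """Fit-range rules and options for the per-ROI exponential fits."""

    iso_rule: FitRangeRule = FitRangeRule.TO_1_OVER_E
    hv_rule: FitRangeRule = FitRangeRule.TO_1_OVER_E2
    min_points: int = 4
    dt_correction: bool = False  # subtract q^2*DT from the HV rate
    kmax: int | None = None      # max lag index for autocorrelation (default N//4)


PRESETS: dict[str, tuple[CriteriaConfig, FitConfig]] = {
    # dilute polymer solutions: 20-px ROIs, R^2 > 0.88
    "stationary_peo": (
        CriteriaConfig(surface_offset_px=15, roi_height_px=20, r2_threshold=0.88),
        FitConfig(),
    ),
    # stationary mucus samples: 20-px ROIs, R^2 > 0.90
    "stationary_mucus": (
        CriteriaConfig(surface_offset_px=15, roi_height_px=20, r2_threshold=0.90),
        FitConfig(),
    ),
    # mucus layer on live cultures: thin 3-px ROIs close to the surface,
    # dynamic isotropic fit range, no R^2/outlier screening
    "culture": (
        CriteriaConfig(surface_offset_px=5, roi_height_px=3, culture_mode=True),
        FitConfig(iso_rule=FitRangeRule.DYNAMIC),
    ),
}


def get_preset(name: str) -> tuple[CriteriaConfig, FitConfig]:
    try:
        criteria, fit = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return criteria, fit


@dataclass
class ROIResult:
    """Per-ROI decay times, diffusion coefficients and screening outcome."""

    depth_range: tuple[int, int]  # half-open pixel interval [start, stop)
    tau_iso_s: float | None = None
    tau_hv_s: float | None = None
    dt_um2_s: float | None = None
    dr_rad2_s: float | None = None
    r2_iso: float | None = None
    r2_hv: float | None = None
    mean_hh_power: float = float("nan")
    flags: dict[str, bool] = field(default_factory=dict)
    valid_dt: bool = False
    valid_dr: bool = False

    def to_record(self) -> dict:
        rec = {
            "depth_start": self.depth_range[0],
            "depth_stop": self.depth_range[1],
            "tau_iso_s": self.tau_iso_s,
            "tau_hv_s": self.tau_hv_s,
            "dt_um2_s": self.dt_um2_s,
            "dr_rad2_s": self.dr_rad2_s,
            "r2_iso": self.r2_iso,
            "r2_hv": self.r2_hv,
            "mean_hh_power": self.mean_hh_power,
            "valid_dt": self.valid_dt,
            "valid_dr": self.valid_dr,
        }
        rec.update({f"flag_{k}": v for k, v in self.flags.items()})
        return rec


def detect_surface(stack: MModeStack, *, n_noise_px: int = 10, n_sigma: float = 6.0) -> int:
    """Locate the sample top surface from the time-mean co-polarized power.

    The noise floor is estimated robustly (median and scaled median
    absolute deviation) from the shallowest ``n_noise_px`` pixels; the
    surface is the shallowest pixel whose mean power exceeds the floor by
    ``n_sigma`` robust standard deviations.  Deterministic.
    """
    if stack.n_depth < 32:
        raise ValueError("stack too shallow for surface detection (< 32 pixels)")
    power = np.mean(np.abs(stack.s_hh) ** 2, axis=0)
    top = power[: min(n_noise_px, stack.n_depth)]
    floor = float(np.median(top))
    spread = 1.4826 * float(np.median(np.abs(top - floor)))
    threshold = floor + n_sigma * max(spread, 1e-12 * max(floor, 1.0))
    above = np.nonzero(power > threshold)[0]
    if above.size == 0:
        raise SurfaceNotFoundError("no depth pixel exceeds the noise floor")
    return int(above[0])


def segment_rois(
    surface_px: int, n_depth: int, config: CriteriaConfig
) -> list[tuple[int, int]]:
    """Tile contiguous depth windows below ``surface + offset``.

    Windows are half-open ``[start, stop)`` intervals of ``roi_height_px``
    pixels; a final partial window is kept only if it spans at least half
    the nominal height.  Returns an empty list when no room remains.
    """
    start = surface_px + config.surface_offset_px
    h = config.roi_height_px
    rois: list[tuple[int, int]] = []
    while start < n_depth:
        stop = min(start + h, n_depth)
        if (stop - start) * 2 >= h:
            rois.append((start, stop))
        start = stop
    return rois


def _roi_curves(
    stack: MModeStack,
    rois: Sequence[tuple[int, int]],
    fit_config: FitConfig,
) -> list[tuple[CorrelationCurve, CorrelationCurve] | None]:
    """ROI-averaged (g_HH, g_HV) curve pairs; None where degenerate."""
    pixels = sorted({p for a, b in rois for p in range(a, b)})
    index = {p: i for i, p in enumerate(pixels)}
    dt_s = stack.optics.aline_period_s
    hh_curves = stack_autocorrelations(stack.s_hh, dt_s, pixels, kmax=fit_config.kmax)
    hv_curves = stack_autocorrelations(stack.s_hv, dt_s, pixels, kmax=fit_config.kmax)
    out = []
    for a, b in rois:
        hh = [hh_curves[index[p]] for p in range(a, b)]
        hv = [hv_curves[index[p]] for p in range(a, b)]
        try:
            out.append((window_average(hh), window_average(hv)))
        except ValueError:
            out.append(None)
    return out


def apply_criteria(
    result: ROIResult,
    config: CriteriaConfig,
    sample_context: Sequence["ROIResult"] | None = None,
    tau_bounds_s: tuple[float, float] | None = None,
) -> ROIResult:
    """Re-evaluate validity flags of a populated ROI result.

    All screening rules are pure threshold checks on already-computed
    quantities, so the operation is idempotent and monotone: tightening a
    threshold can only turn passes into failures.  ``sample_context``
    supplies the other ROIs of the stack for the outlier flag; the outlier
    flag marks values for visual review and never withdraws validity.
    ``tau_bounds_s`` is the (lower, upper) dynamic range of decay times;
    if omitted, previously computed range flags are kept.
    """
    f = dict(result.flags)
    f.setdefault("surface", True)
    # the snr flag needs the stack background power, computed in
    # analyze_stack; standalone use keeps or defaults it
    f.setdefault("snr", True)

    have_taus = result.tau_iso_s is not None and result.tau_hv_s is not None
    f["anisotropy"] = bool(
        have_taus and result.tau_iso_s / result.tau_hv_s >= config.anisotropy_min
    )
    if tau_bounds_s is not None:
        tau_lo, tau_hi = tau_bounds_s
        f["iso_range"] = bool(
            result.tau_iso_s is not None and tau_lo <= result.tau_iso_s <= tau_hi
        )
        f["hv_range"] = bool(
            result.tau_hv_s is not None and tau_lo <= result.tau_hv_s <= tau_hi
        )
    else:
        f.setdefault("iso_range", result.tau_iso_s is not None)
        f.setdefault("hv_range", result.tau_hv_s is not None)

    if config.culture_mode:
        f["r2_iso"] = True
        f["r2_hv"] = True
    else:
        f["r2_iso"] = bool(result.r2_iso is not None and result.r2_iso > config.r2_threshold)
        f["r2_hv"] = bool(result.r2_hv is not None and result.r2_hv > config.r2_threshold)

    f["outlier_dt"] = False
    f["outlier_dr"] = False
    if sample_context and not config.culture_mode:
        for key, attr in (("outlier_dt", "dt_um2_s"), ("outlier_dr", "dr_rad2_s")):
            vals = np.array(
                [getattr(r, attr) for r in sample_context if getattr(r, attr) is not None],
                dtype=float,
            )
            v = getattr(result, attr)
            if v is not None and vals.size >= 2:
                mu, sd = vals.mean(), vals.std(ddof=1)
                if sd > 0 and abs(v - mu) > config.outlier_sigma * sd:
                    f[key] = True

    result.flags = f
    core = f["surface"] and f["snr"] and f["anisotropy"]
    result.valid_dt = bool(
        core and f["iso_range"] and f["r2_iso"] and result.dt_um2_s is not None
    )
    result.valid_dr = bool(
        core and f["hv_range"] and f["r2_hv"] and result.dr_rad2_s is not None
    )
    return result


def analyze_stack(
    stack: MModeStack,
    config: CriteriaConfig | None = None,
    fit_config: FitConfig | None = None,
) -> list[ROIResult]:
    """Full ROI analysis of one M-mode stack.

    Pipeline: surface detection -> depth segmentation -> per-pixel
    autocorrelation -> ROI window averaging -> isotropic combination ->
    exponential decay fits -> validity screening.  Deterministic given the
    stack and configuration.
    """
    config = config or CriteriaConfig()
    fit_config = fit_config or FitConfig()
    surface = detect_surface(stack)
    rois = segment_rois(surface, stack.n_depth, config)
    if not rois:
        return []

    dt_s = stack.optics.aline_period_s
    duration = stack.n_times * dt_s
    tau_lo = config.tau_min_factor * dt_s
    tau_hi = duration / config.tau_max_factor
    q = stack.optics.q_per_um

    power = np.mean(np.abs(stack.s_hh) ** 2, axis=0)
    background = float(np.mean(power[:surface])) if surface > 0 else 0.0

    curves = _roi_curves(stack, rois, fit_config)
    results: list[ROIResult] = []
    for (a, b), pair in zip(rois, curves):
        r = ROIResult(depth_range=(a, b))
        r.mean_hh_power = float(np.mean(power[a:b]))
        r.flags["surface"] = True
        r.flags["snr"] = (
            background <= 0 or r.mean_hh_power >= config.hh_snr_threshold * background
        )
        if pair is not None:
            g_hh, g_hv = pair
            g_iso = iso_combine(g_hh, g_hv)
            r.tau_iso_s, _ = crossing_time(g_iso, INV_E)
            r.tau_hv_s, _ = crossing_time(g_hv, INV_E)
            try:
                r.dt_um2_s, fit_iso = estimate_dt(
                    g_iso, q, fit_config.iso_rule, fit_config.min_points
                )
                r.r2_iso = fit_iso.r_squared
            except (InsufficientPointsError, FitRejectionError):
                pass
            try:
                corr = (q, r.dt_um2_s) if (fit_config.dt_correction and r.dt_um2_s) else None
                r.dr_rad2_s, fit_hv = estimate_dr(
                    g_hv, fit_config.hv_rule, fit_config.min_points, dt_correction=corr
                )
                r.r2_hv = fit_hv.r_squared
            except (InsufficientPointsError, FitRejectionError):
                pass
        results.append(r)

    for r in results:
        apply_criteria(r, config, sample_context=results, tau_bounds_s=(tau_lo, tau_hi))
    return results


def sample_summary(results: Sequence[ROIResult]) -> dict[str, dict[str, float] | None]:
    """Mean, sample standard deviation and CV% per diffusion coefficient.

    The coefficient of variation is 100 * std / mean over valid ROIs only.
    A coefficient with fewer than two valid ROIs yields ``None``.
    """
    out: dict[str, dict[str, float] | None] = {}
    for key, attr, valid_attr in (
        ("dt", "dt_um2_s", "valid_dt"),
        ("dr", "dr_rad2_s", "valid_dr"),
    ):
        vals = np.array(
            [getattr(r, attr) for r in results if getattr(r, valid_attr)], dtype=float
        )
        if vals.size < 2:
            out[key] = None
            continue
        mean = float(vals.mean())
        std = float(vals.std(ddof=1))
        out[key] = {
            "mean": mean,
            "std": std,
            "cv_percent": 100.0 * std / mean if mean != 0 else float("inf"),
            "n_valid": int(vals.size),
            "median": float(np.median(vals)),
        }
    return out
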