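"""Mucus solids-concentration assay from normalized GNR diffusion.

Translational and rotational diffusion coefficients, normalized to their
same-day solvent references (Dnorm = D / Dsolvent), map affinely to mucus
solids concentration (wt.%).  Each calibration carries a validity window:
the translational map covers well-hydrated mucus, the rotational map
extends into dehydrated, disease-like concentrations.  Where both give a
valid concentration the two are averaged, exploiting their complementary
dynamic ranges.

The built-in "hbe_mucus" calibrations are

    wt.% = -2.75 * DTnorm + 2.53     (valid result: -0.5 .. 2 wt.%)
    wt.% = -8.62 * DRnorm + 8.14     (valid result:  1 .. 8 wt.%)

with the rotational window extrapolating beyond its largest calibrated
concentration of 6.4 wt.%; values above that are flagged as extrapolated.
Users may refit either map from their own (Dnorm, wt.%) tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roi_pipeline import ROIResult


class CalibrationError(ValueError):
    """Calibration inputs are missing or degenerate."""


class DiffusionSource(str, enum.Enum):
    DT = "DT"
    DR = "DR"


class Provenance(str, enum.Enum):
    """Which coefficient(s) produced a concentration estimate."""

    DT_ONLY = "DT_only"
    DR_ONLY = "DR_only"
    AVERAGED = "averaged"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map wt.% = slope * Dnorm + intercept with a validity window."""

    source: DiffusionSource
    slope: float
    intercept: float
    validity_window: tuple[float, float]
    r_squared: float = float("nan")
    max_calibrated: float | None = None  # wt.% above which values are extrapolated

    def __post_init__(self) -> None:
        lo, hi = self.validity_window
        if not lo < hi:
            raise CalibrationError("validity window must be a nonempty interval")
        if not np.isfinite(self.slope):
            raise CalibrationError("slope must be finite")

    def concentration(self, d_norm: float) -> tuple[float, bool]:
        """Map a normalized diffusion value to (wt.%, is_valid)."""
        wt = self.slope * d_norm + self.intercept
        lo, hi = self.validity_window
        return float(wt), bool(lo <= wt <= hi)

    def inverse(self, wt_percent: float) -> float:
        """Normalized diffusion producing the given concentration."""
        return (wt_percent - self.intercept) / self.slope


#: Built-in calibrations of the dual-diffusion hydration assay.
BUILTIN_CALIBRATIONS: dict[str, dict[DiffusionSource, CalibrationModel]] = {
    "hbe_mucus": {
        DiffusionSource.DT: CalibrationModel(
            source=DiffusionSource.DT,
            slope=-2.75,
            intercept=2.53,
            validity_window=(-0.5, 2.0),
            r_squared=0.86,
        ),
        DiffusionSource.DR: CalibrationModel(
            source=DiffusionSource.DR,
            slope=-8.62,
            intercept=8.14,
            validity_window=(1.0, 8.0),
            r_squared=0.95,
            max_calibrated=6.4,
        ),
    }
}


def get_calibration(name: str = "hbe_mucus") -> dict[DiffusionSource, CalibrationModel]:
    try:
        return BUILTIN_CALIBRATIONS[name]
    except KeyError:
        raise CalibrationError(
            f"unknown calibration {name!r}; available: {sorted(BUILTIN_CALIBRATIONS)}"
        ) from None


def normalize_diffusion(d: float, d_solvent: float) -> float:
    """Dnorm = D / Dsolvent (same units top and bottom)."""
    if d_solvent <= 0:
        raise CalibrationError("solvent reference diffusivity must be positive")
    return d / d_solvent


def concentration_from_dt(dt_norm: float, model: CalibrationModel) -> tuple[float, bool]:
    """Concentration (wt.%) and validity from normalized translational diffusion."""
    if model.source is not DiffusionSource.DT:
        raise CalibrationError("model is not a translational (DT) calibration")
    return model.concentration(dt_norm)


def concentration_from_dr(dr_norm: float, model: CalibrationModel) -> tuple[float, bool]:
    """Concentration (wt.%) and validity from normalized rotational diffusion."""
    if model.source is not DiffusionSource.DR:
        raise CalibrationError("model is not a rotational (DR) calibration")
    return model.concentration(dr_norm)


def combine_estimates(
    wt_dt: tuple[float, bool] | None,
    wt_dr: tuple[float, bool] | None,
) -> tuple[float | None, Provenance]:
    """Merge the two concentration estimates by their validity.

    Both valid -> their mean; one valid -> that value; neither -> undefined.
    """
    dt_ok = wt_dt is not None and wt_dt[1]
    dr_ok = wt_dr is not None and wt_dr[1]
    if dt_ok and dr_ok:
        return (wt_dt[0] + wt_dr[0]) / 2.0, Provenance.AVERAGED
    if dt_ok:
        return wt_dt[0], Provenance.DT_ONLY
    if dr_ok:
        return wt_dr[0], Provenance.DR_ONLY
    return None, Provenance.UNDEFINED


def fit_calibration(
    table: pd.DataFrame | Sequence[tuple[float, float]],
    source: DiffusionSource | str,
    validity_window: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Ordinary least squares of wt.% on Dnorm.

    ``table`` is a DataFrame with columns ``d_norm`` and ``wt_percent`` (or
    a sequence of (d_norm, wt_percent) pairs) with at least three rows.  If
    no validity window is given, the default window for the source is used.
    """
    source = DiffusionSource(source)
    if isinstance(table, pd.DataFrame):
        x = table["d_norm"].to_numpy(dtype=float)
        y = table["wt_percent"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(table), dtype=float)
        x, y = (arr[:, 0], arr[:, 1]) if arr.size else (arr, arr)
    if x.size < 3:
        raise CalibrationError(f"need at least 3 calibration points, got {x.size}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise CalibrationError("calibration table contains non-finite values")
    if np.ptp(x) == 0:
        raise CalibrationError("no variance in normalized diffusion values")
    res = stats.linregress(x, y)
    if validity_window is None:
        validity_window = (
            (-0.5, 2.0) if source is DiffusionSource.DT else (1.0, 8.0)
        )
    return CalibrationModel(
        source=source,
        slope=float(res.slope),
        intercept=float(res.intercept),
        validity_window=validity_window,
        r_squared=float(res.rvalue**2),
        max_calibrated=float(y.max()),
    )


def load_calibration_table(path) -> dict[DiffusionSource, CalibrationModel]:
    """Refit calibrations from a CSV with columns d_norm, wt_percent, source."""
    df = pd.read_csv(path, comment="#")
    required = {"d_norm", "wt_percent", "source"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"calibration CSV must have columns {sorted(required)}"
        )
    models = {}
    for src, group in df.groupby("source"):
        source = DiffusionSource(str(src))
        models[source] = fit_calibration(group, source)
    return models


@dataclass
class ConcentrationMap:
    """Depth-ROI x frame grid of estimated solids concentration.

    ``grid`` holds wt.% (NaN where undefined); ``provenance`` records which
    coefficient(s) produced each cell; ``extrapolated`` marks cells whose
    value exceeds the largest calibrated concentration of the rotational
    map.
    """

    grid: np.ndarray          # [n_roi, n_frames], wt.%
    provenance: np.ndarray    # [n_roi, n_frames], Provenance values (object)
    extrapolated: np.ndarray  # [n_roi, n_frames], bool
    depth_ranges: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, roi_index, depth range, wt.%, provenance."""
        records = []
        n_roi, n_frames = self.grid.shape
        for f in range(n_frames):
            for i in range(n_roi):
                records.append(
                    {
                        "frame": f,
                        "roi_index": i,
                        "depth_start": self.depth_ranges[i][0],
                        "depth_stop": self.depth_ranges[i][1],
                        "wt_percent": self.grid[i, f],
                        "provenance": str(
                            getattr(self.provenance[i, f], "value", self.provenance[i, f])
                        ),
                        "extrapolated": bool(self.extrapolated[i, f]),
                    }
                )
        return pd.DataFrame.from_records(records)

    def plot(self, ax=None, frame_period_s: float | None = None):
        """Render the map as a heatmap (frames on x, depth ROIs on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.grid, aspect="auto", origin="upper", cmap="viridis")
        ax.set_xlabel(
            "time (s)" if frame_period_s else "frame"
        )
        ax.set_ylabel("depth ROI")
        if frame_period_s:
            ticks = ax.get_xticks()
            ax.set_xticks(ticks[(ticks >= 0) & (ticks < self.grid.shape[1])])
            ax.set_xticklabels(
                [f"{t * frame_period_s:.0f}" for t in ax.get_xticks()]
            )
        cbar = ax.figure.colorbar(im, ax=ax)
        cbar.set_label("solids concentration (wt.%)")
        return ax


def roi_concentration(
    roi: ROIResult,
    models: dict[DiffusionSource, CalibrationModel],
    dt_solvent: float,
    dr_solvent: float,
) -> tuple[float | None, Provenance, bool]:
    """Concentration estimate for one ROI: (wt.%, provenance, extrapolated)."""
    wt_dt = None
    if roi.valid_dt and roi.dt_um2_s is not None:
        wt_dt = concentration_from_dt(
            normalize_diffusion(roi.dt_um2_s, dt_solvent), models[DiffusionSource.DT]
        )
    wt_dr = None
    if roi.valid_dr and roi.dr_rad2_s is not None:
        wt_dr = concentration_from_dr(
            normalize_diffusion(roi.dr_rad2_s, dr_solvent), models[DiffusionSource.DR]
        )
    wt, prov = combine_estimates(wt_dt, wt_dr)
    max_cal = models[DiffusionSource.DR].max_calibrated
    extrapolated = bool(wt is not None and max_cal is not None and wt > max_cal)
    return wt, prov, extrapolated


def build_concentration_map(
    roi_tables: Sequence[Sequence[ROIResult]],
    models: dict[DiffusionSource, CalibrationModel],
    dt_solvent: float,
    dr_solvent: float,
) -> ConcentrationMap:
    """Assemble a depth x frame concentration map from per-frame ROI results.

    All frames must share ROI geometry (same depth windows).  Cells where
    neither coefficient yields a valid concentration are left undefined.
    """
    if dt_solvent <= 0 or dr_solvent <= 0:
        raise CalibrationError("solvent reference diffusivities must be positive")
    if not roi_tables:
        raise ValueError("no frames provided")
    depth_ranges = [r.depth_range for r in roi_tables[0]]
    for frame in roi_tables[1:]:
        if [r.depth_range for r in frame] != depth_ranges:
            raise ValueError("frames do not share ROI geometry")
    n_roi, n_frames = len(depth_ranges), len(roi_tables)
    grid = np.full((n_roi, n_frames), np.nan)
    prov = np.full((n_roi, n_frames), Provenance.UNDEFINED, dtype=object)
    extra = np.zeros((n_roi, n_frames), dtype=bool)
    for f, frame in enumerate(roi_tables):
        for i, roi in enumerate(frame):
            wt, p, ex = roi_concentration(roi, models, dt_solvent, dr_solvent)
            if wt is not None:
                grid[i, f] = wt
            prov[i, f] = p
            extra[i, f] = ex
    return ConcentrationMap(
        grid=grid, provenance=prov, extrapolated=extra, depth_ranges=depth_ranges
    )
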