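"""HDF5 stack container and tabular export helpers.

M-mode stacks are stored as four real float datasets (/HH_real, /HH_imag,
/HV_real, /HV_imag, shape [time, depth]) with the acquisition metadata as
root attributes.  Tabular outputs (ROI results, concentration maps) are
CSV with a short ``#`` comment header recording provenance (seed, config
hash) so a rerun can be checked for byte-identical numeric content.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import pandas as pd

from .gnr_physics import OpticalConfig
from .roi_pipeline import ROIResult
from .speckle_sim import MModeStack


class StackFormatError(ValueError):
    """HDF5 file is missing required datasets or attributes."""


_REQUIRED_ATTRS = ("lambda0_nm", "n_medium", "dt_s", "depth_pixel_um")


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_stack(
    path: str | Path,
    stack: MModeStack,
    *,
    seed: int | None = None,
    extra_attrs: dict | None = None,
) -> None:
    """Write an M-mode stack and its metadata to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("HH_real", data=stack.s_hh.real)
        f.create_dataset("HH_imag", data=stack.s_hh.imag)
        f.create_dataset("HV_real", data=stack.s_hv.real)
        f.create_dataset("HV_imag", data=stack.s_hv.imag)
        f.attrs["lambda0_nm"] = stack.optics.center_wavelength_nm
        f.attrs["n_medium"] = stack.optics.refractive_index
        f.attrs["dt_s"] = stack.optics.aline_period_s
        f.attrs["depth_pixel_um"] = stack.optics.depth_pixel_um
        f.attrs["label"] = stack.label
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_stack(path: str | Path) -> MModeStack:
    """Read an M-mode stack written by :func:`write_stack`.

    Raises
    ------
    StackFormatError
        If datasets or required metadata attributes are absent.
    """
    with h5py.File(path, "r") as f:
        for name in ("HH_real", "HH_imag", "HV_real", "HV_imag"):
            if name not in f:
                raise StackFormatError(f"{path}: missing dataset /{name}")
        missing = [a for a in _REQUIRED_ATTRS if a not in f.attrs]
        if missing:
            raise StackFormatError(f"{path}: missing attributes {missing}")
        hh = f["HH_real"][()] + 1j * f["HH_imag"][()]
        hv = f["HV_real"][()] + 1j * f["HV_imag"][()]
        optics = OpticalConfig(
            center_wavelength_nm=float(f.attrs["lambda0_nm"]),
            refractive_index=float(f.attrs["n_medium"]),
            aline_period_s=float(f.attrs["dt_s"]),
            depth_pixel_um=float(f.attrs["depth_pixel_um"]),
        )
        label = str(f.attrs.get("label", ""))
    return MModeStack(s_hh=hh, s_hv=hv, optics=optics, label=label)


def results_to_frame(results: Sequence[ROIResult]) -> pd.DataFrame:
    """One row per ROI with fits, flags and validity."""
    return pd.DataFrame.from_records([r.to_record() for r in results])


def write_table(
    path: str | Path, df: pd.DataFrame, *, seed=None, cfg_hash: str | None = None
) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
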