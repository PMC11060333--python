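"""Gold-nanorod geometry and solvent hydrodynamics.

Hydrodynamic radius of a prolate rod from its core dimensions, the
backscattering wavenumber of the interferometric system, and reference
translational/rotational diffusivities of a rod in a Newtonian solvent
(Stokes-Einstein and the Tirado-Garcia de la Torre rigid-rod result).
These provide the ground truth for speckle simulations and the solvent
references used to normalize measured diffusion coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

BOLTZMANN_J_PER_K = 1.380649e-23

#: Dynamic viscosity of water at 293 K, Pa*s.
WATER_VISCOSITY_293K = 1.002e-3
ROOM_TEMPERATURE_K = 293.0


def hydrodynamic_radius(length_nm: float, width_nm: float) -> float:
    """Hydrodynamic radius (nm) of a prolate rod of core length L and width W.

    Uses the end-corrected slender-rod form

        RH = (L/2) / [ln(L/W) + 0.312 + 0.565 (W/L) - 0.1 (W/L)^2]

    valid for L > W (prolate geometry).

    Parameters
    ----------
    length_nm, width_nm : float
        Gold core length and width in nm.

    Returns
    -------
    float
        Hydrodynamic radius in nm.
    """
    if width_nm <= 0:
        raise ValueError(f"width must be positive, got {width_nm}")
    if length_nm <= width_nm:
        raise ValueError(
            "hydrodynamic_radius requires a prolate rod (L > W); "
            f"got L={length_nm} nm, W={width_nm} nm"
        )
    p = width_nm / length_nm
    denom = math.log(length_nm / width_nm) + 0.312 + 0.565 * p - 0.1 * p * p
    return length_nm / 2.0 / denom


def scattering_wavenumber(refractive_index: float, wavelength_um: float) -> float:
    """Backscattering wavenumber q = 4*pi*n/lambda0 in inverse microns.

    ``wavelength_um`` is the center wavelength in microns (in vacuum).
    """
    if wavelength_um <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_um}")
    if refractive_index < 1:
        raise ValueError(f"refractive index must be >= 1, got {refractive_index}")
    return 4.0 * math.pi * refractive_index / wavelength_um


@dataclass(frozen=True)
class GNRBatch:
    """A gold-nanorod batch described by its mean core dimensions.

    The polymer coat thickness is recorded for provenance but does not
    enter the hydrodynamic radius, which is computed from the bare core
    length and width.
    """

    length_nm: float
    width_nm: float
    coat_thickness_nm: float = 0.5
    hydrodynamic_radius_nm: float = field(init=False)

    def __post_init__(self) -> None:
        rh = hydrodynamic_radius(self.length_nm, self.width_nm)
        if not rh < self.length_nm / 2:
            raise ValueError("hydrodynamic radius must be below L/2")
        object.__setattr__(self, "hydrodynamic_radius_nm", rh)

    @classmethod
    def from_dict(cls, d: dict) -> "GNRBatch":
        """Build from a config block {L_nm, W_nm, coat_nm}."""
        return cls(
            length_nm=float(d["L_nm"]),
            width_nm=float(d["W_nm"]),
            coat_thickness_nm=float(d.get("coat_nm", 0.5)),
        )


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and optics of an M-mode recording.

    Attributes
    ----------
    center_wavelength_nm : float
        Vacuum center wavelength of the source, nm.
    refractive_index : float
        Refractive index of the medium.
    aline_period_s : float
        Time between successive depth scans (inverse A-line rate), s.
    depth_pixel_um : float
        Axial extent of one depth pixel, microns.
    """

    center_wavelength_nm: float = 800.0
    refractive_index: float = 1.33
    aline_period_s: float = 1.6e-5
    depth_pixel_um: float = 1.5

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0:
            raise ValueError("center wavelength must be positive")
        if self.aline_period_s <= 0:
            raise ValueError("A-line period must be positive")

    @property
    def q_per_um(self) -> float:
        """Backscattering wavenumber 4*pi*n/lambda0 in um^-1."""
        return scattering_wavenumber(
            self.refractive_index, self.center_wavelength_nm * 1e-3
        )


def solvent_reference_diffusivities(
    batch: GNRBatch,
    temperature_k: float = ROOM_TEMPERATURE_K,
    viscosity_pa_s: float = WATER_VISCOSITY_293K,
) -> tuple[float, float]:
    """Theoretical (DT, DR) of a rigid rod in a Newtonian solvent.

    Translational: Stokes-Einstein with the batch hydrodynamic radius,
    DT = kB*T / (6*pi*eta*RH).  Rotational: rigid-rod result about the
    short axes,

        DR = 3*kB*T*[ln(L/W) + delta_perp] / (pi*eta*L^3),
        delta_perp = -0.662 + 0.917 (W/L) - 0.05 (W/L)^2.

    Returns
    -------
    (DT, DR) : tuple of float
        DT in um^2/s, DR in rad^2/s.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    kt = BOLTZMANN_J_PER_K * temperature_k
    rh_m = batch.hydrodynamic_radius_nm * 1e-9
    dt_m2_s = kt / (6.0 * math.pi * viscosity_pa_s * rh_m)

    p = batch.width_nm / batch.length_nm
    delta_perp = -0.662 + 0.917 * p - 0.05 * p * p
    length_m = batch.length_nm * 1e-9
    dr = (
        3.0 * kt * (math.log(1.0 / p) + delta_perp)
        / (math.pi * viscosity_pa_s * length_m**3)
    )
    if dt_m2_s <= 0 or dr <= 0:
        raise ValueError("degenerate rod geometry yields nonpositive diffusivity")
    return dt_m2_s * 1e12, dr
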