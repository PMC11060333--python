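"""Synthetic GNR speckle generation for M-mode polarization-resolved OCT.

Two backends produce complex co-polarized (HH) and cross-polarized (HV)
time series whose first-order field autocorrelations follow the rod
scattering model

    g1_HH(tau) = exp(-q^2 DT tau) * [5/9 + 4/9 exp(-6 DR tau)]
    g1_HV(tau) = exp(-q^2 DT tau) * exp(-6 DR tau)

* ``simulate_process`` — a fast analytic construction from products of
  complex AR(1) (discrete Ornstein-Uhlenbeck) processes, exact in the
  correlation algebra, O(N) per pixel.
* ``simulate_rod_ensemble`` — a microscopic Brownian-dynamics oracle:
  explicit rods with diffusing phase coordinates and orientations, summed
  coherently with the dipole polarization factors ux^2 (HH) and ux*uy (HV).

``make_phantom_stack`` assembles depth-resolved stacks with a specular
surface, static scattering and additive shot-like noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .gnr_physics import OpticalConfig

#: Rotational step-size bound for the tangent-plane orientation update.
MAX_DR_DT = 0.05


@dataclass(frozen=True)
class MModeStack:
    """Complex HH/HV M-mode signals, shape [time, depth], plus optics."""

    s_hh: np.ndarray
    s_hv: np.ndarray
    optics: OpticalConfig
    label: str = ""

    def __post_init__(self) -> None:
        hh = np.asarray(self.s_hh)
        hv = np.asarray(self.s_hv)
        if hh.shape != hv.shape or hh.ndim != 2:
            raise ValueError(
                f"HH and HV must share a [time, depth] shape; got {hh.shape} vs {hv.shape}"
            )
        if not (np.all(np.isfinite(hh.real)) and np.all(np.isfinite(hv.real))):
            raise ValueError("stack contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.s_hh.shape[0]

    @property
    def n_depth(self) -> int:
        return self.s_hh.shape[1]


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a simulated depth-resolved sample.

    ``dt_profile`` / ``dr_profile`` give the per-depth-pixel translational
    (um^2/s) and rotational (rad^2/s) diffusion coefficients.  Pixels above
    ``surface_index`` contain detection noise only; the surface pixel itself
    carries a strong static specular reflection.  ``static_fraction`` is the
    fraction of each in-sample pixel's power contributed by a static
    (non-fluctuating) field; ``noise_level`` is the additive complex noise
    standard deviation relative to the mean dynamic signal amplitude.
    """

    dt_profile: np.ndarray
    dr_profile: np.ndarray
    surface_index: int = 0
    static_fraction: float = 0.0
    noise_level: float = 0.0
    n_times: int = 1024
    seed: int = 0
    specular_amplitude: float = 20.0

    def __post_init__(self) -> None:
        dt = np.asarray(self.dt_profile, dtype=float)
        dr = np.asarray(self.dr_profile, dtype=float)
        object.__setattr__(self, "dt_profile", dt)
        object.__setattr__(self, "dr_profile", dr)
        if dt.shape != dr.shape or dt.ndim != 1:
            raise ValueError("DT and DR profiles must be 1-D and equal length")
        if np.any(dt < 0) or np.any(dr < 0):
            raise ValueError("diffusion profiles must be nonnegative")
        if not 0 <= self.static_fraction < 1:
            raise ValueError("static_fraction must lie in [0, 1)")
        if self.n_times < 2:
            raise ValueError("n_times must be at least 2")
        if not 0 <= self.surface_index < dt.size:
            raise ValueError("surface_index must index into the depth profile")

    @property
    def n_depth(self) -> int:
        return self.dt_profile.size

    @classmethod
    def uniform(
        cls,
        dt: float,
        dr: float,
        n_depth: int,
        *,
        surface_index: int = 0,
        **kwargs,
    ) -> "PhantomSpec":
        """Homogeneous sample: one (DT, DR) at every depth pixel."""
        return cls(
            dt_profile=np.full(n_depth, float(dt)),
            dr_profile=np.full(n_depth, float(dr)),
            surface_index=surface_index,
            **kwargs,
        )


def _complex_ar1(
    rho: float, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Stationary complex circular-Gaussian AR(1), unit variance, lag-1
    coefficient ``rho``; time along axis 0."""
    n_times = shape[0]
    w = (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ) / np.sqrt(2.0)
    if rho == 0.0:
        return w
    if rho >= 1.0:  # frozen process
        return np.broadcast_to(w[:1], shape).copy()
    x = np.empty(shape, dtype=complex)
    x0 = w[0]
    innov = w[1:] * np.sqrt(1.0 - rho * rho)
    # x[t] = rho*x[t-1] + innov[t]  via an IIR filter with initial state x0
    tail, _ = lfilter(
        [1.0], [1.0, -rho], innov, axis=0, zi=(rho * x0)[None, ...]
    )
    x[0] = x0
    x[1:] = tail
    if n_times == 1:
        x = x[:1]
    return x


def simulate_process(
    dt_coef: float,
    dr_coef: float,
    optics: OpticalConfig,
    n_times: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic-process speckle backend for one depth pixel.

    Three independent unit-variance complex AR(1) processes are combined:
    P carries the translational phase decorrelation (lag-1 coefficient
    exp(-q^2 DT dt)); Q and Q' carry the orientational decorrelation
    (coefficient exp(-6 DR dt)).  The emitted fields

        HH = P * (sqrt(5) + 2 Q) / 3,      HV = P * Q'

    have unit mean power and, by independence, exactly the two-exponential
    (HH) and single-product (HV) field autocorrelations of diffusing rods.

    Parameters
    ----------
    dt_coef, dr_coef : float
        Translational (um^2/s) and rotational (rad^2/s) diffusion.
    optics : OpticalConfig
        Supplies the scattering wavenumber q and the A-line period.
    n_times : int
        Number of A-lines (time samples).
    seed : int or numpy Generator
        Randomness source.

    Returns
    -------
    (hh, hv) : complex ndarrays of length ``n_times``.
    """
    if dt_coef < 0 or dr_coef < 0:
        raise ValueError("diffusion coefficients must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt_s = optics.aline_period_s
    q = optics.q_per_um
    rho_t = float(np.exp(-(q * q) * dt_coef * dt_s))
    rho_r = float(np.exp(-6.0 * dr_coef * dt_s))
    shape = (n_times,)
    p = _complex_ar1(rho_t, shape, rng)
    q_proc = _complex_ar1(rho_r, shape, rng)
    q_prime = _complex_ar1(rho_r, shape, rng)
    hh = p * (np.sqrt(5.0) + 2.0 * q_proc) / 3.0
    hv = p * q_prime
    return hh, hv


def iter_orientations(
    n_rods: int,
    sigma_u: float,
    n_times: int,
    rng: np.random.Generator,
):
    """Yield [n_rods, 3] unit orientations along an isotropic rotational walk.

    Starts from isotropically distributed orientations; each step adds a
    zero-mean Gaussian displacement of standard deviation ``sigma_u`` per
    tangent direction and renormalizes to the unit sphere.  ``sigma_u`` is
    sqrt(2 DR dt) for rotational diffusion DR at time step dt.
    """
    u = rng.standard_normal((n_rods, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    yield u
    for _ in range(n_times - 1):
        if sigma_u > 0:
            # orthonormal tangent basis at each u
            ref = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(u, e1)
            step = rng.standard_normal((n_rods, 2)) * sigma_u
            u = u + step[:, :1] * e1 + step[:, 1:] * e2
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
        yield u


def simulate_rod_ensemble(
    n_rods: int,
    dt_coef: float,
    dr_coef: float,
    optics: OpticalConfig,
    n_times: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Microscopic Brownian-dynamics oracle for the speckle statistics.

    Each rod carries an axial coordinate z_j performing 1-D Brownian motion
    (variance 2 DT dt per step) and a unit orientation u_j performing
    isotropic rotational diffusion (tangent-plane Gaussian step of standard
    deviation sqrt(2 DR dt) per tangent direction, then renormalized to the
    sphere).  The detected fields sum the single-rod contributions with the
    dipole polarization factors of a rod at its longitudinal resonance:

        HH(t) = sum_j ux_j^2 exp(i q z_j),   HV(t) = sum_j ux_j uy_j exp(i q z_j).

    The tangent-step update is accurate only for DR*dt << 1; steps with
    DR*dt > 0.05 are rejected.
    """
    if dt_coef < 0 or dr_coef < 0:
        raise ValueError("diffusion coefficients must be nonnegative")
    if n_rods < 1:
        raise ValueError("need at least one rod")
    dt_s = optics.aline_period_s
    if dr_coef * dt_s > MAX_DR_DT:
        raise ValueError(
            f"DR*dt = {dr_coef * dt_s:.3g} exceeds {MAX_DR_DT}; "
            "reduce the A-line period for an unbiased orientation update"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q = optics.q_per_um

    z = rng.uniform(0.0, 2.0 * np.pi / q, size=n_rods)
    sigma_z = np.sqrt(2.0 * dt_coef * dt_s)
    sigma_u = np.sqrt(2.0 * dr_coef * dt_s)

    hh = np.empty(n_times, dtype=complex)
    hv = np.empty(n_times, dtype=complex)
    for t, u in enumerate(iter_orientations(n_rods, sigma_u, n_times, rng)):
        phase = np.exp(1j * q * z)
        hh[t] = np.sum(u[:, 0] ** 2 * phase)
        hv[t] = np.sum(u[:, 0] * u[:, 1] * phase)
        if sigma_z > 0 and t < n_times - 1:
            z = z + sigma_z * rng.standard_normal(n_rods)
    # normalize to unit mean power
    hh /= np.sqrt(np.mean(np.abs(hh) ** 2)) or 1.0
    hv /= np.sqrt(np.mean(np.abs(hv) ** 2)) or 1.0
    return hh, hv


def _pixel_fields(
    dt_profile: np.ndarray,
    dr_profile: np.ndarray,
    optics: OpticalConfig,
    n_times: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized process backend over depth pixels: [time, depth] fields."""
    dt_s = optics.aline_period_s
    q = optics.q_per_um
    rho_t = np.exp(-(q * q) * dt_profile * dt_s)
    rho_r = np.exp(-6.0 * dr_profile * dt_s)
    n_depth = dt_profile.size
    shape = (n_times, n_depth)

    def ar1_bank(rho: np.ndarray) -> np.ndarray:
        w = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
        x = np.empty(shape, dtype=complex)
        x[0] = w[0]
        if n_times > 1:
            innov = w[1:] * np.sqrt(1.0 - rho * rho)
            # per-column AR(1); lfilter shares coefficients, so loop over
            # the distinct rho values (usually few in layered phantoms)
            for r in np.unique(rho):
                cols = np.nonzero(rho == r)[0]
                if r >= 1.0:
                    x[1:, cols] = x[0, cols]
                    continue
                tail, _ = lfilter(
                    [1.0], [1.0, -r], innov[:, cols], axis=0,
                    zi=(r * x[0, cols])[None, :],
                )
                x[1:, cols] = tail
        return x

    p = ar1_bank(rho_t)
    q_proc = ar1_bank(rho_r)
    q_prime = ar1_bank(rho_r)
    hh = p * (np.sqrt(5.0) + 2.0 * q_proc) / 3.0
    hv = p * q_prime
    return hh, hv


def make_phantom_stack(spec: PhantomSpec, optics: OpticalConfig) -> MModeStack:
    """Assemble a full M-mode stack from a phantom description.

    Depth pixels are simulated independently.  Below the surface each pixel
    carries a unit-power dynamic GNR field with that pixel's (DT, DR); a
    ``static_fraction`` of the power is replaced by a constant complex
    offset (static scattering).  The surface pixel carries a strong static
    specular field.  Pixels above the surface contain additive noise only.
    Additive complex white noise at ``noise_level`` (relative to unit
    dynamic amplitude) is applied to both channels everywhere.

    Deterministic: identical spec (including seed) gives identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    n_times, n_depth = spec.n_times, spec.n_depth
    hh, hv = _pixel_fields(spec.dt_profile, spec.dr_profile, optics, n_times, rng)

    if spec.static_fraction > 0:
        sf = spec.static_fraction
        phases = rng.uniform(0, 2 * np.pi, size=(2, n_depth))
        offs_hh = np.sqrt(sf) * np.exp(1j * phases[0])
        offs_hv = np.sqrt(sf) * np.exp(1j * phases[1])
        hh = np.sqrt(1 - sf) * hh + offs_hh
        hv = np.sqrt(1 - sf) * hv + offs_hv

    surf = spec.surface_index
    hh[:, :surf] = 0.0
    hv[:, :surf] = 0.0
    # specular surface reflection: static, strongly co-polarized
    hh[:, surf] = spec.specular_amplitude * np.exp(1j * rng.uniform(0, 2 * np.pi))
    hv[:, surf] = 0.05 * spec.specular_amplitude * np.exp(1j * rng.uniform(0, 2 * np.pi))

    if spec.noise_level > 0:
        scale = spec.noise_level / np.sqrt(2.0)
        hh = hh + scale * (
            rng.standard_normal((n_times, n_depth))
            + 1j * rng.standard_normal((n_times, n_depth))
        )
        hv = hv + scale * (
            rng.standard_normal((n_times, n_depth))
            + 1j * rng.standard_normal((n_times, n_depth))
        )
    return MModeStack(s_hh=hh, s_hv=hv, optics=optics, label=f"phantom(seed={spec.seed})")
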