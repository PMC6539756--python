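"""Thermoacoustic forward model: pulsed energy deposition to pressure.

A pulsed beam heats a region of water; the resulting pressure at a sensor
is the Kirchhoff-integral solution of the thermoacoustic wave equation.
The deposited power density is factorized as
``epsilon(r) * g(t)`` with ``epsilon`` the cumulative deposited energy
density (J/m^3) and ``g`` a normalized temporal rate profile
(``integral g dt = 1``).  The wave-equation source term is the second
time derivative of the cumulative deposition, i.e. the first derivative
of ``g``, which is applied analytically:

    p(r, t) = alpha' / (4 pi C_p) * sum_voxels dV * epsilon(r') / |r - r'|
              * g'(t - |r - r'| / c_s)

A Gaussian heating pulse therefore yields the characteristic bipolar
(compression / rarefaction) emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .bragg_dose import BeamPulse, DepthDoseProfile
from .constants import (
    DENSITY_WATER,
    MEV_TO_J,
    SOUND_SPEED_WATER,
    SPECIFIC_HEAT_WATER,
    THERMAL_EXPANSION_WATER,
)

__all__ = [
    "Medium",
    "WATER",
    "GaussianKernel",
    "SourceField",
    "PressureSignal",
    "temperature_rise",
    "build_source",
    "kirchhoff_pressure",
    "simulate_beam_pulse",
]


@dataclass(frozen=True)
class Medium:
    """Acoustic/thermal properties of the propagation medium."""

    c_s: float = SOUND_SPEED_WATER  # sound speed, m/s
    c_p: float = SPECIFIC_HEAT_WATER  # specific heat, J/(kg K)
    rho: float = DENSITY_WATER  # density, kg/m^3
    alpha_exp: float = THERMAL_EXPANSION_WATER  # volumetric expansion, 1/K

    def __post_init__(self) -> None:
        for name in ("c_s", "c_p", "rho", "alpha_exp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


WATER = Medium()


@dataclass(frozen=True)
class PressureSignal:
    """A uniformly sampled pressure waveform."""

    samples: np.ndarray  # Pa
    fs: float  # Hz
    t0: float = 0.0  # time of first sample, s

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized Gaussian temporal rate profile g(t), with derivatives."""

    sigma: float  # s
    t_center: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def g(self, t):
        s = (np.asarray(t, dtype=float) - self.t_center) / self.sigma
        return np.exp(-0.5 * s * s) / (self.sigma * math.sqrt(2.0 * math.pi))

    def dg(self, t):
        """First derivative g'(t) — the pressure kernel (bipolar)."""
        s = (np.asarray(t, dtype=float) - self.t_center) / self.sigma
        return -s / self.sigma * np.exp(-0.5 * s * s) / (
            self.sigma * math.sqrt(2.0 * math.pi)
        )

    def shifted(self, delta: float) -> "GaussianKernel":
        return GaussianKernel(self.sigma, self.t_center + delta)


@dataclass
class SourceField:
    """Voxelized deposited-energy field with a separable time profile.

    ``energy_density[i, j, k]`` is the cumulative deposited energy density
    (J/m^3) at ``(x[i], y[j], z[k])``.
    """

    x: np.ndarray  # m
    y: np.ndarray  # m
    z: np.ndarray  # m
    energy_density: np.ndarray  # J/m^3
    kernel: GaussianKernel
    voxel_size: float  # m

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def total_energy(self) -> float:
        """Volume integral of the deposited energy density, J."""
        return float(self.energy_density.sum() * self.voxel_volume)


def temperature_rise(dose, medium: Medium = WATER):
    """Temperature increase (K) from an absorbed dose (Gy = J/kg).

    ``dT = dose / C_p``; about 240 uK/Gy in water.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0 Gy")
    out = dose / medium.c_p
    return float(out) if out.ndim == 0 else out


def build_source(
    profile: DepthDoseProfile,
    beam: BeamPulse,
    medium: Medium = WATER,
    voxel_size: float | None = None,
) -> SourceField:
    """Voxelize the beam's energy deposition into a :class:`SourceField`.

    The field is separable: the depth-dose curve along z times a 2-D
    Gaussian (width ``beam.lateral_sigma``) in x, y, truncated at 5 sigma.
    The beam axis is +z with the entry surface at z = 0.

    ``voxel_size`` must resolve both the lateral width and the straggling
    width (at most a quarter of the smaller of the two).
    """
    sig_lat = beam.lateral_sigma * 1e-3  # m
    sig_str = profile.sigma_straggle * 1e-2  # m
    max_voxel = min(sig_lat, sig_str) / 4.0
    if voxel_size is None:
        voxel_size = max_voxel
    if voxel_size > max_voxel * (1.0 + 1e-9):
        raise ValueError(
            f"voxel_size {voxel_size:.3e} m too coarse: must be <= "
            f"min(lateral_sigma, sigma_straggle)/4 = {max_voxel:.3e} m"
        )

    half = 5.0 * sig_lat
    n_half = int(math.ceil(half / voxel_size))
    x = np.arange(-n_half, n_half + 1) * voxel_size
    y = x.copy()
    z_min = float(profile.z[0]) * 1e-2
    z_max = float(profile.z[-1]) * 1e-2
    z = np.arange(z_min, z_max + voxel_size / 2, voxel_size)

    # per-fluence depth dose resampled to the voxel grid (cm -> m)
    dose_pf = np.interp(z * 1e2, profile.z, profile.dose_per_fluence)

    # areal fluence of the Gaussian beam, protons/cm^2, on the x-y grid
    sig_cm = beam.lateral_sigma_cm
    gx = np.exp(-0.5 * (x * 1e2 / sig_cm) ** 2)
    g2d = (
        beam.n_protons
        / (2.0 * math.pi * sig_cm * sig_cm)
        * np.outer(gx, gx)
    )

    # energy density: rho[g/cm^3] * D_pf[MeV cm^2/g] * phi[1/cm^2]
    # = MeV/cm^3 -> J/m^3
    rho_g_cm3 = medium.rho * 1e-3
    eps = (
        rho_g_cm3
        * g2d[:, :, None]
        * dose_pf[None, None, :]
        * (MEV_TO_J * 1e6)
    )

    kernel = GaussianKernel(sigma=beam.temporal_sigma)
    return SourceField(
        x=x, y=y, z=z, energy_density=eps, kernel=kernel, voxel_size=voxel_size
    )


def kirchhoff_pressure(
    source: SourceField,
    sensor_pos,
    t_grid,
    medium: Medium = WATER,
) -> PressureSignal:
    """Pressure waveform at ``sensor_pos`` from a :class:`SourceField`.

    Discretizes the Kirchhoff retarded-time integral over the voxels.
    Voxel contributions are accumulated on the (uniform) time grid by
    linear binning of the retarded delays followed by convolution with
    the analytic pressure kernel g'.
    """
    sensor_pos = np.asarray(sensor_pos, dtype=float)
    if sensor_pos.shape != (3,):
        raise ValueError("sensor_pos must be a 3-vector (m)")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D vector of >= 2 times")
    dt_all = np.diff(t_grid)
    dt = dt_all[0]
    if not np.allclose(dt_all, dt, rtol=1e-9):
        raise ValueError("t_grid must be uniformly spaced")

    eps = source.energy_density
    thresh = 1e-9 * eps.max() if eps.size else 0.0
    mask = eps > thresh
    if not np.any(mask):
        return PressureSignal(
            samples=np.zeros(t_grid.size), fs=1.0 / dt, t0=float(t_grid[0])
        )
    xi, yi, zi = np.nonzero(mask)
    dx = source.x[xi] - sensor_pos[0]
    dy = source.y[yi] - sensor_pos[1]
    dz = source.z[zi] - sensor_pos[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    if dist.min() < source.voxel_size:
        raise ValueError(
            "sensor lies inside (or within one voxel of) the source region: "
            "the 1/r kernel is singular there"
        )

    coeff = medium.alpha_exp / (4.0 * math.pi * medium.c_p)
    w = coeff * source.voxel_volume * eps[mask] / dist
    tau = dist / medium.c_s

    # linear binning of delays at the sample spacing
    pos = tau / dt
    m0 = int(np.floor(pos.min()))
    m1 = int(np.floor(pos.max())) + 1
    idx = np.floor(pos).astype(np.int64) - m0
    frac = pos - np.floor(pos)
    hist = np.zeros(m1 - m0 + 1)
    np.add.at(hist, idx, w * (1.0 - frac))
    np.add.at(hist, idx + 1, w * frac)

    # p[n] = sum_m hist[m] g'(t[n] - (m0+m) dt): discrete convolution
    n = t_grid.size
    mlen = hist.size
    j = np.arange(-(mlen - 1), n)
    kern = source.kernel.dg(t_grid[0] + (j - m0) * dt)
    full = fftconvolve(hist, kern)
    samples = full[mlen - 1 : mlen - 1 + n]
    return PressureSignal(samples=samples, fs=1.0 / dt, t0=float(t_grid[0]))


def simulate_beam_pulse(
    beam: BeamPulse,
    medium: Medium = WATER,
    sensor_offset: float = 0.04,
    fs: float = 1.0e7,
    duration: float = 60e-6,
    voxel_size: float | None = None,
) -> PressureSignal:
    """Thermoacoustic pulse at a sensor ``sensor_offset`` m from the peak.

    The sensor sits perpendicular to the beam axis at the depth of the
    Bragg peak.  Convenience wrapper chaining the depth-dose model,
    :func:`build_source` and :func:`kirchhoff_pressure`.
    """
    from .bragg_dose import dose_profile

    profile = dose_profile(beam=beam, straggling=True)
    source = build_source(profile, beam, medium, voxel_size=voxel_size)
    z_peak = profile.peak_depth * 1e-2
    sensor = np.array([sensor_offset, 0.0, z_peak])
    t_grid = np.arange(0.0, duration, 1.0 / fs)
    return kirchhoff_pressure(source, sensor, t_grid, medium)
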