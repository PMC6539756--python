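"""Analytical proton depth-dose (Bragg curve) model in water.

Implements the Bortfeld-style analytical depth-dose model: a power-law
range-energy relation ``R0 = alpha * E0**p``, a linear fluence loss from
nuclear interactions with slope ``beta``, and Gaussian range straggling
expressed through parabolic cylinder functions.

This module works in cm and MeV internally, matching the conventional
units of the model parameters ``alpha`` (cm MeV^-p) and ``beta`` (cm^-1).
Conversion to SI happens at the thermoacoustic boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn
from scipy.special import pbdv

from .constants import MEV_PER_G_TO_GY

__all__ = [
    "StoppingModel",
    "BeamPulse",
    "DepthDoseProfile",
    "range_from_energy",
    "energy_from_range",
    "residual_energy",
    "fluence_at_depth",
    "straggling_sigma",
    "dose_profile",
    "default_depth_grid",
]

#: beyond this many straggling widths from the range end the Gaussian
#: smearing kernel is numerically a delta: use the unconvolved curve
#: (plateau side) or zero (beyond the range) to avoid exp overflow in
#: the parabolic-cylinder evaluation.
_ZETA_SWITCH = 12.0

#: energy window (MeV) for which the parameter fit is considered valid.
_ENERGY_VALID = (10.0, 250.0)

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class StoppingModel:
    """Parameters of the analytical range-energy / depth-dose model.

    Attributes
    ----------
    alpha : float
        Range-energy coefficient, cm MeV^-p.
    p : float
        Range-energy exponent (dimensionless, between 1 and 2).
    beta : float
        Slope of the linear fluence loss from nuclear interactions, cm^-1.
    gamma : float
        Fraction of the energy released in nuclear interactions that is
        absorbed locally, in [0, 1].
    epsilon_peak : float
        Small fraction of the primary fluence contributing extra dose in
        the peak (dimensionless, >= 0).
    """

    alpha: float = 2.2e-3
    p: float = 1.77
    beta: float = 0.012
    gamma: float = 0.6
    epsilon_peak: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not 1.0 < self.p < 2.0:
            raise ValueError(f"p must lie in (1, 2), got {self.p}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.epsilon_peak < 0:
            raise ValueError(
                f"epsilon_peak must be >= 0, got {self.epsilon_peak}"
            )


@dataclass(frozen=True)
class BeamPulse:
    """A pulsed proton beam: energy, intensity, lateral and temporal width.

    Attributes
    ----------
    e0 : float
        Initial proton energy, MeV.
    n_protons : float
        Number of protons per pulse.
    lateral_sigma : float
        Transverse Gaussian width of the beam, mm.
    pulse_width : float
        Temporal width parameter of the Gaussian pulse, us.
    width_convention : str
        Whether ``pulse_width`` is the Gaussian ``sigma`` or the ``fwhm``.
    phi0 : float or None
        Primary fluence, protons/cm^2.  When ``None`` it defaults to the
        on-axis fluence of the Gaussian beam,
        ``n_protons / (2 pi lateral_sigma_cm^2)``.
    """

    e0: float
    n_protons: float = 3.4e6
    lateral_sigma: float = 1.0
    pulse_width: float = 1.0
    width_convention: str = "sigma"
    phi0: float | None = None

    _FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError(f"e0 must be >= 0 MeV, got {self.e0}")
        if self.n_protons < 0:
            raise ValueError(f"n_protons must be >= 0, got {self.n_protons}")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0 mm")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0 us")
        if self.width_convention not in ("sigma", "fwhm"):
            raise ValueError(
                f"width_convention must be 'sigma' or 'fwhm', "
                f"got {self.width_convention!r}"
            )
        if self.phi0 is not None and self.phi0 < 0:
            raise ValueError("phi0 must be >= 0")

    @property
    def temporal_sigma(self) -> float:
        """Gaussian sigma of the temporal profile, seconds."""
        w = self.pulse_width * 1e-6
        if self.width_convention == "fwhm":
            w *= self._FWHM_TO_SIGMA
        return w

    @property
    def lateral_sigma_cm(self) -> float:
        return self.lateral_sigma * 0.1

    @property
    def fluence(self) -> float:
        """Primary (on-axis) fluence, protons/cm^2."""
        if self.phi0 is not None:
            return self.phi0
        sig_cm = self.lateral_sigma_cm
        return self.n_protons / (2.0 * math.pi * sig_cm * sig_cm)


@dataclass
class DepthDoseProfile:
    """A sampled depth-dose curve.

    ``dose`` is the absorbed dose along the beam axis for the beam's
    primary fluence, MeV/g.  ``dose_per_fluence`` is the same curve
    normalized per unit fluence (MeV g^-1 cm^2), which is what the
    analytical model produces; ``dose = phi0 * dose_per_fluence``.
    """

    z: np.ndarray  # cm, strictly increasing
    dose_per_fluence: np.ndarray  # MeV g^-1 cm^2
    r0: float  # cm
    sigma_straggle: float  # cm
    includes_straggling: bool
    phi0: float  # protons / cm^2
    dose: np.ndarray = field(init=False)  # MeV / g

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.dose_per_fluence = np.asarray(self.dose_per_fluence, dtype=float)
        if self.z.shape != self.dose_per_fluence.shape:
            raise ValueError("z and dose_per_fluence must have equal shape")
        self.dose = self.phi0 * self.dose_per_fluence

    def dose_gy(self) -> np.ndarray:
        """Absorbed dose converted to gray."""
        return self.dose * MEV_PER_G_TO_GY

    @property
    def peak_depth(self) -> float:
        """Depth of the dose maximum, cm."""
        return float(self.z[int(np.argmax(self.dose_per_fluence))])


def range_from_energy(e0, model: StoppingModel = StoppingModel()):
    """Proton range in water, cm, from the initial energy in MeV.

    ``R0 = alpha * E0**p``; strictly increasing in ``E0``.
    """
    e0 = np.asarray(e0, dtype=float)
    if np.any(e0 < 0):
        raise ValueError("energy must be >= 0 MeV")
    out = model.alpha * np.power(e0, model.p)
    return float(out) if out.ndim == 0 else out


def energy_from_range(r0, model: StoppingModel = StoppingModel()):
    """Inverse of :func:`range_from_energy`: ``E0 = (R0/alpha)**(1/p)``."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 < 0):
        raise ValueError("range must be >= 0 cm")
    out = np.power(r0 / model.alpha, 1.0 / model.p)
    return float(out) if out.ndim == 0 else out


def residual_energy(z, r0: float, model: StoppingModel = StoppingModel()):
    """Remaining proton energy (MeV) at depth ``z`` for range ``r0``.

    ``E(z) = alpha**(-1/p) * (R0 - z)**(1/p)``; returns 0 beyond the
    range (the proton has stopped) with a warning.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0 cm")
    if r0 < 0:
        raise ValueError("range must be >= 0 cm")
    u = r0 - z
    stopped = u < 0
    if np.any(stopped):
        warnings.warn(
            "depth beyond the proton range: residual energy set to 0",
            stacklevel=2,
        )
    out = np.power(np.clip(u, 0.0, None), 1.0 / model.p) / (
        model.alpha ** (1.0 / model.p)
    )
    return float(out) if out.ndim == 0 else out


def fluence_at_depth(
    z, phi0: float, model: StoppingModel = StoppingModel(), r0: float = None
):
    """Proton fluence at depth ``z``, protons/cm^2.

    Linear fluence loss: ``phi(z) = phi0 (1 + beta (R0 - z)) / (1 + beta R0)``.
    Non-increasing in ``z`` with ``phi(0) = phi0``.
    """
    if r0 is None:
        raise ValueError("r0 (proton range, cm) is required")
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > r0):
        raise ValueError("depth must lie in [0, r0]")
    out = phi0 * (1.0 + model.beta * (r0 - z)) / (1.0 + model.beta * r0)
    return float(out) if out.ndim == 0 else out


def straggling_sigma(r0):
    """Gaussian range-straggling width, cm: ``sigma = 0.012 * R0**0.935``."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 < 0):
        raise ValueError("range must be >= 0 cm")
    out = 0.012 * np.power(r0, 0.935)
    return float(out) if out.ndim == 0 else out


def _peak_bracket(model: StoppingModel, r0: float) -> float:
    """The cm^-1 bracket multiplying the (R0-z)**(1/p) dose term."""
    b = model.beta / model.p + model.gamma * model.beta
    if model.epsilon_peak > 0:
        b += model.epsilon_peak / r0
    return b


def _dose_pf_sharp(z: np.ndarray, r0: float, model: StoppingModel) -> np.ndarray:
    """Per-fluence depth dose without range straggling, MeV g^-1 cm^2.

    Density is 1 g/cm^3 (water); vanishes for z >= R0.  The curve has an
    integrable singularity (R0 - z)**(1/p - 1) at the range end.
    """
    u = r0 - z
    out = np.zeros_like(u)
    m = u > 0
    inv_p = 1.0 / model.p
    pref = 1.0 / (model.alpha**inv_p * (1.0 + model.beta * r0))
    b = _peak_bracket(model, r0)
    um = u[m]
    out[m] = pref * (np.power(um, inv_p - 1.0) / model.p + b * np.power(um, inv_p))
    return out


def _dose_pf_straggled(
    z: np.ndarray, r0: float, sigma: float, model: StoppingModel
) -> np.ndarray:
    """Per-fluence depth dose with Gaussian range straggling.

    Gaussian convolution (width ``sigma``) of the unconvolved curve,
    evaluated in closed form with parabolic cylinder functions D_nu:

        D(z) = pref * exp(-zeta^2/4) * [ D_{-1/p}(-zeta)/sigma
                                         + b * D_{-1/p-1}(-zeta) ]

    with zeta = (R0 - z)/sigma and
    pref = sigma^(1/p) Gamma(1/p) / (sqrt(2 pi) p alpha^(1/p) (1 + beta R0)).

    For |zeta| > _ZETA_SWITCH the kernel is numerically a delta and the
    unconvolved curve (plateau side) or zero (beyond range) is used,
    which also avoids overflow of exp(zeta^2/4) terms.
    """
    zeta = (r0 - z) / sigma
    out = np.zeros_like(zeta)
    inv_p = 1.0 / model.p
    b = _peak_bracket(model, r0)

    plateau = zeta > _ZETA_SWITCH
    if np.any(plateau):
        out[plateau] = _dose_pf_sharp(z[plateau], r0, model)

    core = np.abs(zeta) <= _ZETA_SWITCH
    if np.any(core):
        zc = zeta[core]
        d_a = pbdv(-inv_p, -zc)[0]
        d_b = pbdv(-inv_p - 1.0, -zc)[0]
        pref = (
            sigma**inv_p
            * _gamma_fn(inv_p)
            / (_SQRT_2PI * model.p * model.alpha**inv_p * (1.0 + model.beta * r0))
        )
        out[core] = pref * np.exp(-zc * zc / 4.0) * (d_a / sigma + b * d_b)
    return out


def default_depth_grid(r0: float, sigma: float) -> np.ndarray:
    """Default depth grid: 0 to R0 + 6 sigma, step min(sigma/10, 0.01 cm)."""
    step = min(sigma / 10.0, 0.01) if sigma > 0 else 0.01
    return np.arange(0.0, r0 + 6.0 * sigma + step, step)


def dose_profile(
    z_grid=None,
    beam: BeamPulse = None,
    model: StoppingModel = StoppingModel(),
    medium_density: float = 1.0,
    straggling: bool = True,
) -> DepthDoseProfile:
    """Depth-dose curve for a beam, on ``z_grid`` (cm).

    Parameters
    ----------
    z_grid : array_like or None
        Strictly increasing depths, cm.  ``None`` selects
        :func:`default_depth_grid`.
    beam : BeamPulse
        Beam parameters; the curve scales linearly with ``beam.fluence``.
    model : StoppingModel
        Stopping-model parameters.
    medium_density : float
        Medium density, g/cm^3 (water = 1).
    straggling : bool
        Include Gaussian range straggling (smooth peak) or not (sharp
        curve vanishing beyond R0).
    """
    if beam is None:
        raise ValueError("beam is required")
    if beam.e0 > 0 and not (_ENERGY_VALID[0] <= beam.e0 <= _ENERGY_VALID[1]):
        warnings.warn(
            f"beam energy {beam.e0} MeV outside the model validity window "
            f"{_ENERGY_VALID} MeV",
            stacklevel=2,
        )
    r0 = range_from_energy(beam.e0, model)
    sigma = straggling_sigma(r0)
    if z_grid is None:
        z_grid = default_depth_grid(r0, sigma)
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size == 0:
        raise ValueError("z_grid must not be empty")
    if z_grid.ndim != 1 or (z_grid.size > 1 and np.any(np.diff(z_grid) <= 0)):
        raise ValueError("z_grid must be 1-D and strictly increasing")

    if straggling:
        dose_pf = _dose_pf_straggled(z_grid, r0, sigma, model)
    else:
        dose_pf = _dose_pf_sharp(z_grid, r0, model)
    if medium_density != 1.0:
        dose_pf = dose_pf / medium_density

    return DepthDoseProfile(
        z=z_grid,
        dose_per_fluence=dose_pf,
        r0=r0,
        sigma_straggle=sigma,
        includes_straggling=straggling,
        phi0=beam.fluence,
    )
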