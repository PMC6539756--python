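"""TDOA multilateration by damped Gauss-Newton iteration.

Given a sensor array and reference-relative TDOAs, the source position
solves the range-difference system

    f_i(x) = (|x - s_i| - |x - s_ref|) - c * tau_i = 0,  i != ref.

The system is solved iteratively with the analytic Jacobian; for more
than four sensors the update is the least-squares (Gauss-Newton) step.
The step is damped (halved while the residual norm does not decrease) to
tame divergence from poor initial guesses, and non-convergence is always
reported through the ``converged`` flag rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import SOUND_SPEED_WATER
from .tdoa import TDOASet

__all__ = [
    "SensorArray",
    "LocalizationResult",
    "range_residuals",
    "jacobian",
    "localize",
]

_MIN_SENSOR_DIST = 1e-9  # m: closer than this to a sensor is singular


@dataclass(frozen=True)
class SensorArray:
    """Ordered 3-D sensor coordinates with a designated reference sensor."""

    positions: np.ndarray  # (M, 3), m
    ref_index: int = 0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (M, 3) array of meters")
        if pos.shape[0] < 4:
            raise ValueError(
                f"3-D localization needs at least 4 sensors, got {pos.shape[0]}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < _MIN_SENSOR_DIST:
            raise ValueError("two sensors coincide")
        if not 0 <= self.ref_index < pos.shape[0]:
            raise IndexError(
                f"ref_index {self.ref_index} out of range for "
                f"{pos.shape[0]} sensors"
            )

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def span(self) -> float:
        """Largest extent of the array along any axis, m."""
        return float(
            (self.positions.max(axis=0) - self.positions.min(axis=0)).max()
        )

    def subset(self, indices) -> "SensorArray":
        """Sub-array from 0-based sensor indices; first entry is reference."""
        return SensorArray(positions=self.positions[list(indices)], ref_index=0)


@dataclass
class LocalizationResult:
    position: np.ndarray  # (3,), m
    iterations: int
    residual_norm: float  # m
    converged: bool
    history: list = field(default_factory=list)  # per-iteration positions


def _check_aligned(array: SensorArray, tdoas: TDOASet) -> None:
    if tdoas.tau.size != array.n_sensors:
        raise ValueError(
            f"tdoas carry {tdoas.tau.size} entries but the array has "
            f"{array.n_sensors} sensors"
        )
    if tdoas.ref_index != array.ref_index:
        raise ValueError("tdoas and array designate different reference sensors")


def range_residuals(
    x_s,
    array: SensorArray,
    tdoas: TDOASet,
    c: float = SOUND_SPEED_WATER,
) -> np.ndarray:
    """Range-difference residuals f_i(x_s), m, one per non-reference sensor."""
    _check_aligned(array, tdoas)
    x_s = np.asarray(x_s, dtype=float)
    d = np.linalg.norm(array.positions - x_s, axis=1)
    if d.min() < _MIN_SENSOR_DIST:
        raise ValueError(
            "source position coincides with a sensor: gradient undefined"
        )
    others = np.arange(array.n_sensors) != array.ref_index
    return (d[others] - d[array.ref_index]) - c * tdoas.tau[others]


def jacobian(x_s, array: SensorArray) -> np.ndarray:
    """Analytic Jacobian of :func:`range_residuals` w.r.t. the source.

    Row i is the unit vector from sensor i toward the source minus the
    unit vector from the reference sensor toward the source; row norms
    are therefore bounded by 2.
    """
    x_s = np.asarray(x_s, dtype=float)
    diff = x_s - array.positions  # (M, 3)
    d = np.linalg.norm(diff, axis=1)
    if d.min() < _MIN_SENSOR_DIST:
        raise ValueError(
            "source position coincides with a sensor: gradient undefined"
        )
    units = diff / d[:, None]
    others = np.arange(array.n_sensors) != array.ref_index
    return units[others] - units[array.ref_index]


def localize(
    array: SensorArray,
    tdoas: TDOASet,
    c: float = SOUND_SPEED_WATER,
    x0=None,
    tol: float = 1e-6,
    max_iter: int = 100,
    keep_history: bool = False,
) -> LocalizationResult:
    """Solve the TDOA system for the source position.

    Damped Gauss-Newton from ``x0`` (default: the sensor centroid, which
    lies inside the hull where convergence is reliable).  Stops when the
    step norm drops below ``tol`` (m) or after ``max_iter`` iterations;
    the ``converged`` flag is honest and ill-conditioned steps flag
    non-convergence instead of raising.
    """
    _check_aligned(array, tdoas)
    x = array.centroid.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("initial guess must be finite")

    history = [x.copy()] if keep_history else []
    converged = False
    n_iter = 0
    try:
        f = range_residuals(x, array, tdoas, c)
    except ValueError:
        return LocalizationResult(
            position=x, iterations=0, residual_norm=np.inf,
            converged=False, history=history,
        )
    fnorm = np.linalg.norm(f)

    for n_iter in range(1, max_iter + 1):
        try:
            jac = jacobian(x, array)
            step, *_ = np.linalg.lstsq(jac, f, rcond=None)
        except (ValueError, np.linalg.LinAlgError):
            break
        if not np.all(np.isfinite(step)):
            break
        if np.linalg.norm(step) < tol:
            x = x - step
            if keep_history:
                history.append(x.copy())
            converged = True
            try:
                fnorm = np.linalg.norm(range_residuals(x, array, tdoas, c))
            except ValueError:
                pass
            break
        # damping: halve the step while the residual norm fails to decrease
        accepted = False
        scale = 1.0
        for _ in range(11):
            x_new = x - scale * step
            try:
                f_new = range_residuals(x_new, array, tdoas, c)
            except ValueError:
                scale *= 0.5
                continue
            fnorm_new = np.linalg.norm(f_new)
            if fnorm_new < fnorm or np.linalg.norm(scale * step) < tol:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        moved = np.linalg.norm(x_new - x)
        x, f, fnorm = x_new, f_new, fnorm_new
        if keep_history:
            history.append(x.copy())
        if moved < tol:
            converged = True
            break

    return LocalizationResult(
        position=x,
        iterations=n_iter,
        residual_norm=float(fnorm),
        converged=converged,
        history=history,
    )
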