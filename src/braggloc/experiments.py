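"""Seeded study drivers: cube-array simulation, initial-guess convergence
study, and a full signal-level surrogate of the 12-sensor water-tank
measurement.

All geometries are built programmatically: a four-sensor cube layout
parameterized by the edge length H, and a fixed 12-position tank layout
with one source.  Every driver takes an integer seed and records it in
the result so reruns are bit-identical.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .bragg_dose import BeamPulse
from .constants import (
    DEFAULT_RECORD_DURATION,
    DEFAULT_SAMPLE_RATE,
    SOUND_SPEED_WATER,
)
from .localization import LocalizationResult, SensorArray, localize
from .tdoa import estimate_toa, tdoas_from_toas
from .thermoacoustic import WATER, Medium, PressureSignal, simulate_beam_pulse

__all__ = [
    "cube_array",
    "cube_sources_mm",
    "tank_array",
    "tank_source",
    "TANK_GROUPS",
    "StudyConfig",
    "StudyResult",
    "synthesize_received_signals",
    "run_convergence_study",
    "run_cube_study",
    "run_tank_study",
    "run_timing_study",
    "tank_emitted_pulse",
]

# -- geometries --------------------------------------------------------------

#: cube-layout sensor positions as fractions (fx, fy, fz) of the edge H
_CUBE_SENSOR_FRACTIONS = np.array(
    [
        [0.5, 0.0, 0.75],
        [0.0, 0.5, 0.5],
        [0.5, 1.0, 0.5],
        [1.0, 0.5, 0.25],
    ]
)

#: the three simulated source positions for the cube study, mm
_CUBE_SOURCES_MM = np.array(
    [
        [100.0, 100.0, 100.0],
        [100.0, 180.0, 150.0],
        [80.0, 100.0, 180.0],
    ]
)

#: tank sensor positions, cm (12 positions referenced to the tank corner)
_TANK_SENSORS_CM = np.array(
    [
        [70.5, 53.0, 31.0],
        [70.5, 40.5, 31.0],
        [56.5, 40.5, 31.0],
        [42.5, 40.5, 31.0],
        [42.5, 53.0, 31.0],
        [42.5, 65.0, 31.0],
        [56.5, 65.0, 31.0],
        [70.5, 65.0, 31.0],
        [70.5, 65.0, 43.0],
        [70.5, 40.5, 43.0],
        [42.5, 40.5, 43.0],
        [42.5, 65.0, 43.0],
    ]
)

#: tank source position, cm
_TANK_SOURCE_CM = np.array([54.0, 53.0, 38.0])

#: sensor groups evaluated in the tank study (1-based sensor numbers)
TANK_GROUPS: dict[int, tuple[int, ...]] = {
    1: (2, 4, 6, 8),
    2: (9, 10, 11, 12),
    3: (6, 8, 9, 12),
    4: (2, 4, 10, 11),
    5: (3, 4, 9, 11),
    6: (1, 4, 9, 12),
    7: (2, 5, 7, 9, 11, 12),
    8: (1, 3, 4, 6, 7, 8, 10, 11),
    9: (1, 3, 4, 5, 7, 8, 9, 10, 11, 12),
    10: tuple(range(1, 13)),
}


def cube_array(h_mm: float, ref_index: int = 0) -> SensorArray:
    """Four-sensor cube layout with edge ``h_mm`` (mm), in meters."""
    if h_mm <= 0:
        raise ValueError("cube edge H must be > 0 mm")
    return SensorArray(
        positions=_CUBE_SENSOR_FRACTIONS * h_mm * 1e-3, ref_index=ref_index
    )


def cube_sources_mm() -> np.ndarray:
    """The three simulated source positions of the cube study, mm."""
    return _CUBE_SOURCES_MM.copy()


def tank_array(ref_index: int = 0) -> SensorArray:
    """The 12-position tank layout, in meters."""
    return SensorArray(positions=_TANK_SENSORS_CM * 1e-2, ref_index=ref_index)


def tank_source() -> np.ndarray:
    """The tank source position, in meters."""
    return _TANK_SOURCE_CM * 1e-2


# -- result containers -------------------------------------------------------


@dataclass
class StudyConfig:
    """Reproducibility record attached to every study result."""

    study: str
    seed: int
    c: float
    noise_model: dict
    n_repeats: int
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "study": self.study,
            "seed": self.seed,
            "c": self.c,
            "noise_model": dict(self.noise_model),
            "n_repeats": self.n_repeats,
        }
        d.update(self.extras)
        return d


@dataclass
class StudyResult:
    """Per-trial records plus an aggregated summary table."""

    config: StudyConfig
    trials: pd.DataFrame
    summary: pd.DataFrame

    def save(self, out_dir) -> None:
        from pathlib import Path

        from .io import RunManifest

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / f"{self.config.study}_trials.csv", index=False)
        self.summary.to_csv(
            out / f"{self.config.study}_summary.csv", index=False
        )
        RunManifest.create(
            parameters=self.config.as_dict(), seed=self.config.seed
        ).write(out / f"{self.config.study}_manifest.json")


# -- signal synthesis --------------------------------------------------------


def synthesize_received_signals(
    pulse: PressureSignal,
    source_pos,
    array: SensorArray,
    medium: Medium = WATER,
    fs: float = DEFAULT_SAMPLE_RATE,
    duration: float = DEFAULT_RECORD_DURATION,
    snr_db: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PressureSignal]:
    """Per-channel received records for a pulse emitted at ``source_pos``.

    Each channel is the emitted pulse delayed by the exact propagation
    time ``|sensor - source| / c_s`` (fractional-sample delay applied as
    a frequency-domain phase ramp, i.e. band-limited interpolation),
    scaled by 1/r, plus white Gaussian noise at ``snr_db`` (``None``
    means noiseless).  SNR is defined against the mean signal power over
    the pulse-support window.
    """
    if pulse.fs != fs:
        raise ValueError(
            f"pulse sampled at {pulse.fs} Hz but records requested at {fs} Hz"
        )
    source_pos = np.asarray(source_pos, dtype=float)
    dists = np.linalg.norm(array.positions - source_pos, axis=1)
    delays = dists / medium.c_s
    t_needed = delays.max() + pulse.samples.size / fs
    if duration < t_needed:
        raise ValueError(
            f"record duration {duration * 1e6:.1f} us too short: needs at "
            f"least {t_needed * 1e6:.1f} us (max delay + pulse length)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    template = np.zeros(n)
    template[: pulse.samples.size] = pulse.samples
    spec = rfft(template)
    freqs = rfftfreq(n, 1.0 / fs)

    out = []
    for dist, delay in zip(dists, delays):
        shifted = irfft(spec * np.exp(-2j * np.pi * freqs * delay), n)
        clean = shifted / dist
        if snr_db is None:
            samples = clean
        else:
            p_sig = np.sum(clean**2) / pulse.samples.size
            sigma_n = np.sqrt(p_sig * 10.0 ** (-snr_db / 10.0))
            samples = clean + rng.normal(0.0, sigma_n, n)
        out.append(PressureSignal(samples=samples, fs=fs, t0=0.0))
    return out


# -- emitted pulse for the tank surrogate ------------------------------------


@lru_cache(maxsize=4)
def tank_emitted_pulse(
    fs: float = DEFAULT_SAMPLE_RATE, energy_mev: float = 100.0
) -> PressureSignal:
    """The simulated thermoacoustic pulse used as the emitted waveform.

    100 MeV beam, 1 us Gaussian pulse, 3.4e6 protons, 1 mm beam width,
    observed 40 mm from the Bragg peak.  Cached: the Kirchhoff quadrature
    is by far the most expensive step of the tank surrogate.
    """
    beam = BeamPulse(e0=energy_mev)
    return simulate_beam_pulse(beam, WATER, sensor_offset=0.04, fs=fs,
                               duration=60e-6)


# -- study drivers -----------------------------------------------------------


def run_convergence_study(
    array: SensorArray | None = None,
    source=None,
    bounds=None,
    n_sim: int = 10_000,
    seed: int = 0,
    c: float = SOUND_SPEED_WATER,
    max_iter: int = 50,
) -> StudyResult:
    """Convergence versus initial-guess distance on noiseless TDOAs.

    For each trial the initial guess is drawn uniformly in ``bounds``
    (a ``(low, high)`` pair of 3-vectors, default: the array bounding
    box) and the solver runs on exact TDOAs.  Records the start-to-truth
    distance, the final error and the convergence flag.
    """
    if array is None:
        array = cube_array(400.0)
    if source is None:
        source = np.array([0.1, 0.1, 0.1])
    source = np.asarray(source, dtype=float)
    if bounds is None:
        bounds = (array.positions.min(axis=0), array.positions.max(axis=0))
    low = np.asarray(bounds[0], dtype=float)
    high = np.asarray(bounds[1], dtype=float)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")

    rng = np.random.default_rng(seed)
    toas = np.linalg.norm(array.positions - source, axis=1) / c
    tdoas = tdoas_from_toas(toas, array.ref_index)

    rows = []
    for _ in range(n_sim):
        x0 = rng.uniform(low, high)
        res = localize(array, tdoas, c, x0=x0, max_iter=max_iter)
        rows.append(
            (
                np.linalg.norm(x0 - source),
                np.linalg.norm(res.position - source),
                res.converged,
                res.iterations,
            )
        )
    trials = pd.DataFrame(
        rows, columns=["start_dist_m", "final_error_m", "converged", "iterations"]
    )
    conv = trials["converged"] & (trials["final_error_m"] < 1e-6)
    summary = pd.DataFrame(
        {
            "n_sim": [n_sim],
            "fraction_converged": [float(conv.mean())],
            "median_final_error_m": [float(trials["final_error_m"].median())],
        }
    )
    config = StudyConfig(
        study="convergence",
        seed=seed,
        c=c,
        noise_model={},
        n_repeats=n_sim,
        extras={"bounds_low": low.tolist(), "bounds_high": high.tolist()},
    )
    return StudyResult(config=config, trials=trials, summary=summary)


def run_cube_study(
    h_list_mm=(300.0, 400.0, 500.0, 600.0, 700.0),
    toa_jitter_sigma: float = 1e-7,
    fs: float = DEFAULT_SAMPLE_RATE,
    quantize: bool = True,
    n_repeats: int = 20,
    seed: int = 0,
    c: float = SOUND_SPEED_WATER,
) -> StudyResult:
    """Cube-array localization accuracy versus cube volume.

    For each cube edge H and each of the three fixed sources: compute
    exact TOAs at ``c``, add Gaussian jitter ``toa_jitter_sigma`` (s),
    optionally quantize to the sample grid, localize from the centroid
    and aggregate per-coordinate mean +/- SD and the 3-D error.
    """
    h_list_mm = list(h_list_mm)
    if not h_list_mm:
        raise ValueError("h_list_mm must not be empty")
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    rows = []
    for h in h_list_mm:
        array = cube_array(h)
        for s_idx, src_mm in enumerate(_CUBE_SOURCES_MM, start=1):
            src = src_mm * 1e-3
            if np.any(src < 0) or np.any(src > h * 1e-3):
                _warnings.warn(
                    f"source {s_idx} at {src_mm} mm lies outside the "
                    f"H = {h} mm cube covered by the sensors",
                    stacklevel=2,
                )
            toas = np.linalg.norm(array.positions - src, axis=1) / c
            for rep in range(n_repeats):
                noisy = toas + rng.normal(0.0, toa_jitter_sigma, toas.size)
                if quantize:
                    noisy = np.round(noisy * fs) / fs
                res = localize(array, tdoas_from_toas(noisy, array.ref_index), c)
                est_mm = res.position * 1e3
                rows.append(
                    (
                        h,
                        (h * 1e-3) ** 3,
                        s_idx,
                        rep,
                        *est_mm,
                        float(np.linalg.norm(est_mm - src_mm)),
                        res.converged,
                        res.iterations,
                    )
                )
    trials = pd.DataFrame(
        rows,
        columns=[
            "H_mm", "volume_m3", "source", "repeat",
            "x_mm", "y_mm", "z_mm", "error_mm", "converged", "iterations",
        ],
    )
    ok = trials[trials["converged"]]
    agg = ok.groupby(["source", "H_mm", "volume_m3"]).agg(
        x_mean=("x_mm", "mean"), x_sd=("x_mm", "std"),
        y_mean=("y_mm", "mean"), y_sd=("y_mm", "std"),
        z_mean=("z_mm", "mean"), z_sd=("z_mm", "std"),
        error_mean_mm=("error_mm", "mean"),
        error_max_mm=("error_mm", "max"),
        n_converged=("error_mm", "size"),
    ).reset_index()
    config = StudyConfig(
        study="cube",
        seed=seed,
        c=c,
        noise_model={
            "toa_jitter_sigma": toa_jitter_sigma,
            "quantize_fs": fs if quantize else None,
        },
        n_repeats=n_repeats,
        extras={"H_mm": h_list_mm},
    )
    return StudyResult(config=config, trials=trials, summary=agg)


def run_tank_study(
    groups: dict[int, tuple[int, ...]] | None = None,
    snr_db: float | None = 20.0,
    n_repeats: int = 20,
    seed: int = 0,
    c: float = SOUND_SPEED_WATER,
    fs: float = DEFAULT_SAMPLE_RATE,
    duration: float = DEFAULT_RECORD_DURATION,
    subsample: bool = True,
) -> StudyResult:
    """Full signal-level chain on the 12-position tank geometry.

    Simulated thermoacoustic pulse -> per-channel delayed/attenuated
    noisy records -> correlation TOA per channel -> localization per
    sensor group -> mean +/- SD per coordinate (cm) and 3-D error (mm).
    """
    if groups is None:
        groups = TANK_GROUPS
    for gid, members in groups.items():
        if len(members) < 4:
            raise ValueError(
                f"group {gid} has {len(members)} sensors; need at least 4"
            )
        if not set(members) <= set(range(1, 13)):
            raise ValueError(f"group {gid} indices must lie in 1..12")

    medium = Medium(c_s=c, c_p=WATER.c_p, rho=WATER.rho,
                    alpha_exp=WATER.alpha_exp)
    pulse = tank_emitted_pulse(fs)
    full_array = tank_array()
    src = tank_source()
    rng = np.random.default_rng(seed)

    rows = []
    for rep in range(n_repeats):
        signals = synthesize_received_signals(
            pulse, src, full_array, medium=medium, fs=fs,
            duration=duration, snr_db=snr_db, rng=rng,
        )
        toas = np.array(
            [estimate_toa(pulse, sig, subsample=subsample) for sig in signals]
        )
        for gid, members in groups.items():
            idx = [m - 1 for m in members]
            sub = full_array.subset(idx)
            res = localize(sub, tdoas_from_toas(toas[idx], 0), c)
            est_cm = res.position * 1e2
            rows.append(
                (
                    gid,
                    len(members),
                    rep,
                    *est_cm,
                    float(np.linalg.norm(res.position - src) * 1e3),
                    res.converged,
                )
            )
    trials = pd.DataFrame(
        rows,
        columns=["group", "n_sensors", "repeat", "x_cm", "y_cm", "z_cm",
                 "error_mm", "converged"],
    )
    ok = trials[trials["converged"]]
    summary = ok.groupby(["group", "n_sensors"]).agg(
        x_mean=("x_cm", "mean"), x_sd=("x_cm", "std"),
        y_mean=("y_cm", "mean"), y_sd=("y_cm", "std"),
        z_mean=("z_cm", "mean"), z_sd=("z_cm", "std"),
        error_mean_mm=("error_mm", "mean"),
        error_median_mm=("error_mm", "median"),
        n_converged=("error_mm", "size"),
    ).reset_index()
    config = StudyConfig(
        study="tank",
        seed=seed,
        c=c,
        noise_model={"signal_snr_db": snr_db},
        n_repeats=n_repeats,
        extras={"groups": {k: list(v) for k, v in groups.items()},
                "fs": fs, "duration": duration},
    )
    return StudyResult(config=config, trials=trials, summary=summary)


def run_timing_study(
    sensor_counts=(4, 6, 8, 10, 12),
    h_list_mm=(300.0, 400.0, 500.0, 600.0, 700.0),
    n_repeats: int = 10,
    seed: int = 0,
    c: float = SOUND_SPEED_WATER,
) -> pd.DataFrame:
    """Wall-clock solver time per (sensor count, cube edge) configuration.

    Reported, never asserted: timings are hardware-dependent.  Sensor
    counts above 4 place extra sensors at deterministic positions on the
    cube surface.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for h in h_list_mm:
        base = cube_array(h).positions
        extra_rng = np.random.default_rng(12345)  # fixed layout, not noise
        for count in sensor_counts:
            if count < 4:
                raise ValueError("sensor_counts entries must be >= 4")
            extra = extra_rng.uniform(0.0, h * 1e-3, size=(count - 4, 3))
            array = SensorArray(np.vstack([base, extra]))
            src = np.array([0.25, 0.25, 0.25]) * h * 1e-3 + np.array(
                [0.05, 0.05, 0.05]
            ) * h * 1e-3
            toas = np.linalg.norm(array.positions - src, axis=1) / c
            toas = toas + rng.normal(0.0, 1e-7, toas.size)
            tdoas = tdoas_from_toas(toas)
            tic = time.perf_counter()
            for _ in range(n_repeats):
                res = localize(array, tdoas, c)
            elapsed = (time.perf_counter() - tic) / n_repeats
            rows.append((count, h, elapsed, res.iterations, res.converged))
    return pd.DataFrame(
        rows,
        columns=["n_sensors", "H_mm", "seconds", "iterations", "converged"],
    )
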