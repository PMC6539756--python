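"""Readers/writers for geometries, waveforms, TDOAs and run manifests.

Delimited text uses comma separation, '.' decimals and '#'-prefixed
header comments.  The array-container format is NumPy ``.npz`` with
embedded metadata; it round-trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import SensorArray
from .tdoa import TDOASet
from .thermoacoustic import PressureSignal

__all__ = [
    "RunManifest",
    "load_geometry",
    "save_geometry",
    "load_tdoas",
    "save_waveforms",
    "load_waveforms",
]

_UNIT_TO_M = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("braggloc")
    except PackageNotFoundError:  # editable checkout without metadata
        return "unknown"


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run exactly."""

    tool_version: str
    parameters: dict
    seed: int | None
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, parameters: dict, seed: int | None = None,
               input_paths=()) -> "RunManifest":
        digests = {}
        for p in input_paths:
            p = Path(p)
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(
            tool_version=_package_version(),
            parameters=parameters,
            seed=seed,
            input_digests=digests,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return path


def load_geometry(path, units: str = "m") -> SensorArray:
    """Read a sensor geometry table (columns x, y, z) into meters."""
    if units not in _UNIT_TO_M:
        raise ValueError(f"units must be one of {sorted(_UNIT_TO_M)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    table = pd.read_csv(path, comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    for col in ("x", "y", "z"):
        if col not in table.columns:
            raise ValueError(f"geometry file {path} is missing column {col!r}")
    sub = table[["x", "y", "z"]]
    try:
        coords = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in geometry file {path}: {exc}")
    if coords.shape[0] < 4:
        raise ValueError(
            f"geometry file {path} has {coords.shape[0]} sensors; "
            "3-D localization needs at least 4"
        )
    return SensorArray(positions=coords * _UNIT_TO_M[units])


def save_geometry(array: SensorArray, path, units: str = "m") -> Path:
    """Write a sensor geometry as delimited text (columns x, y, z)."""
    if units not in _UNIT_TO_M:
        raise ValueError(f"units must be one of {sorted(_UNIT_TO_M)}")
    path = Path(path)
    coords = array.positions / _UNIT_TO_M[units]
    with path.open("w") as fh:
        fh.write(f"# sensor geometry, units = {units}\n")
        fh.write(f"# ref_index = {array.ref_index}\n")
        pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(
            fh, index=False, float_format="%.17g"
        )
    return path


def load_tdoas(path, ref_index: int = 0) -> TDOASet:
    """Read reference-relative TDOAs (column tau_s, seconds, one per sensor)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TDOA file not found: {path}")
    table = pd.read_csv(path, comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    if "tau_s" not in table.columns:
        raise ValueError(f"TDOA file {path} is missing column 'tau_s'")
    tau = table["tau_s"].to_numpy(dtype=float)
    return TDOASet(ref_index=ref_index, tau=tau)


def save_waveforms(signals, path, format: str = "delimited_text") -> Path:
    """Write one or more waveforms sharing a sample rate.

    ``delimited_text``: columns t_s, ch0, ch1, ... at full float precision
    with fs/t0 metadata in '#' header comments.  ``array_container``:
    ``.npz`` with the sample matrix plus fs and t0 arrays (lossless).
    """
    signals = list(signals)
    if not signals:
        raise ValueError("empty signal list")
    fs = signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("all signals must share the sample rate")
    n = max(s.samples.size for s in signals)
    if any(s.samples.size != n for s in signals):
        raise ValueError("all signals must share the record length")
    path = Path(path)
    if format == "delimited_text":
        t0 = signals[0].t0
        if any(s.t0 != t0 for s in signals):
            raise ValueError("delimited text export requires a common t0")
        data = {"t_s": signals[0].times}
        for i, s in enumerate(signals):
            data[f"ch{i}"] = s.samples
        with path.open("w") as fh:
            fh.write(f"# fs_hz = {fs!r}\n")
            fh.write(f"# t0_s = {t0!r}\n")
            fh.write("# units: s, Pa\n")
            pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")
    elif format == "array_container":
        np.savez(
            path,
            samples=np.stack([s.samples for s in signals]),
            fs=np.array([fs]),
            t0=np.array([s.t0 for s in signals]),
        )
    else:
        raise ValueError(
            "format must be 'delimited_text' or 'array_container'"
        )
    return path


def load_waveforms(path, format: str | None = None) -> list[PressureSignal]:
    """Inverse of :func:`save_waveforms` (format inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "array_container" if path.suffix == ".npz" else "delimited_text"
    if format == "array_container":
        with np.load(path) as data:
            fs = float(data["fs"][0])
            return [
                PressureSignal(samples=row, fs=fs, t0=float(t0))
                for row, t0 in zip(data["samples"], data["t0"])
            ]
    table = pd.read_csv(path, comment="#")
    t = table.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"waveform file {path} has fewer than 2 samples")
    fs = 1.0 / (t[1] - t[0])
    return [
        PressureSignal(samples=table[c].to_numpy(dtype=float), fs=fs,
                       t0=float(t[0]))
        for c in table.columns[1:]
    ]
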