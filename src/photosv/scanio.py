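"""Reading and writing radial fluorescence scan sets.

Two on-disk dialects are supported:

* Beckman/FDS-style ASCII scan files, one file per scan:
  line 1 is a free-text description; line 2 is a whitespace-separated record
  ``flag cell temperature_C rpm time_s omega2t``; every further line is a
  ``radius value`` pair (an optional third column holds the per-point
  standard deviation).

* A long-format CSV holding a whole scan set with header columns
  ``time_s, rpm, temp_C, radius_cm, signal``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RadialScan",
    "ScanSet",
    "ScanParseError",
    "read_scanset",
    "write_scanset",
    "read_scanset_csv",
    "write_scanset_csv",
]


class ScanParseError(ValueError):
    """Malformed scan file; message names the file and offending line."""


@dataclass
class RadialScan:
    """One timestamped radial fluorescence trace a(r) at time t."""

    time: float
    rpm: float
    temperature: float
    radii: np.ndarray
    signal: np.ndarray
    cell_id: int = 1
    stddev: np.ndarray | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.radii.shape != self.signal.shape or self.radii.ndim != 1:
            raise ValueError("radii and signal must be 1-D arrays of equal length")
        dr = np.diff(self.radii)
        if np.any(dr <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.radii.size > 2 and np.ptp(dr) > 0.01 * dr.mean():
            raise ValueError("radial spacing must be uniform within 1%")
        if self.stddev is not None:
            self.stddev = np.asarray(self.stddev, dtype=float)
            if self.stddev.shape != self.radii.shape:
                raise ValueError("stddev must match radii in length")


@dataclass
class ScanSet:
    """A time-ordered collection of radial scans sharing geometry and rpm."""

    scans: list

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda sc: sc.time)
        if not self.scans:
            raise ValueError("ScanSet requires at least one scan")
        rpms = {round(sc.rpm) for sc in self.scans}
        if max(rpms) - min(rpms) > 0.001 * max(rpms):
            raise ValueError(f"mixed rotor speeds in scan set: {sorted(rpms)}")
        cells = {sc.cell_id for sc in self.scans}
        if len(cells) > 1:
            raise ValueError(f"mixed cell ids in scan set: {sorted(cells)}")
        r0 = self.scans[0].radii
        for sc in self.scans[1:]:
            if sc.radii.size != r0.size or not np.allclose(sc.radii, r0, rtol=0, atol=1e-9):
                raise ValueError("scans must share a common radial grid")

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([sc.time for sc in self.scans])

    @property
    def radii(self) -> np.ndarray:
        return self.scans[0].radii

    @property
    def rpm(self) -> float:
        return self.scans[0].rpm

    @property
    def temperature(self) -> float:
        return self.scans[0].temperature

    def to_matrix(self) -> np.ndarray:
        """Signals stacked as a (n_scans x n_radii) matrix."""
        return np.vstack([sc.signal for sc in self.scans])


_NUM = r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"


def _parse_scan_file(path: Path) -> RadialScan:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ScanParseError(f"{path}: fewer than 3 lines")
    header = lines[1].split()
    if len(header) < 6:
        raise ScanParseError(f"{path}, line 2: expected 6 header fields, got {len(header)}")
    flag = header[0]
    try:
        cell = int(header[1])
        temp = float(header[2])
        rpm = float(header[3])
        time = float(header[4])
        float(header[5])  # omega^2 t, informational
    except ValueError as exc:
        raise ScanParseError(f"{path}, line 2: malformed header field ({exc})") from exc
    if not re.fullmatch(r"[A-Za-z]+", flag):
        raise ScanParseError(f"{path}, line 2: bad data-type flag {flag!r}")

    radii, values, sds = [], [], []
    ncols = None
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ScanParseError(f"{path}, line {lineno}: expected 2 or 3 columns")
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise ScanParseError(f"{path}, line {lineno}: inconsistent column count")
        try:
            radii.append(float(parts[0]))
            values.append(float(parts[1]))
            if len(parts) == 3:
                sds.append(float(parts[2]))
        except ValueError as exc:
            raise ScanParseError(f"{path}, line {lineno}: non-numeric value") from exc
        if len(radii) >= 2 and radii[-1] <= radii[-2]:
            raise ScanParseError(f"{path}, line {lineno}: radii not strictly increasing")

    try:
        return RadialScan(
            time=time,
            rpm=rpm,
            temperature=temp,
            radii=np.array(radii),
            signal=np.array(values),
            cell_id=cell,
            stddev=np.array(sds) if sds else None,
            description=lines[0],
        )
    except ValueError as exc:
        raise ScanParseError(f"{path}: {exc}") from exc


def read_scanset(path) -> ScanSet:
    """Read a scan set from a directory of ASCII scan files, a list of files,
    or a single long-format CSV file."""
    if isinstance(path, (list, tuple)):
        files = [Path(p) for p in path]
    else:
        p = Path(path)
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir()
                if f.is_file() and f.suffix.lower() in (".fds", ".txt", ".ra", ".dat")
            )
            if not files:
                raise ScanParseError(f"{p}: no scan files found")
        elif p.suffix.lower() == ".csv":
            return read_scanset_csv(p)
        else:
            files = [p]
    return ScanSet([_parse_scan_file(f) for f in files])


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))


def write_scanset(scanset: ScanSet, directory, prefix: str = "scan") -> list:
    """Write one ASCII file per scan into ``directory``; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sc in enumerate(scanset, start=1):
        path = directory / f"{prefix}{i:05d}.fds"
        omega = 2.0 * math.pi * sc.rpm / 60.0
        lines = [
            sc.description or f"fluorescence scan {i}",
            " ".join(
                [
                    "F",
                    str(sc.cell_id),
                    _fmt(sc.temperature),
                    _fmt(sc.rpm),
                    _fmt(sc.time),
                    _fmt(omega**2 * sc.time),
                ]
            ),
        ]
        if sc.stddev is not None:
            body = (
                f"{_fmt(r)} {_fmt(v)} {_fmt(sd)}"
                for r, v, sd in zip(sc.radii, sc.signal, sc.stddev)
            )
        else:
            body = (f"{_fmt(r)} {_fmt(v)}" for r, v in zip(sc.radii, sc.signal))
        lines.extend(body)
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def read_scanset_csv(path) -> ScanSet:
    """Read the long-format CSV dialect (time_s, rpm, temp_C, radius_cm, signal)."""
    df = pd.read_csv(path)
    required = ["time_s", "rpm", "temp_C", "radius_cm", "signal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScanParseError(f"{path}: missing CSV columns {missing}")
    scans = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("radius_cm")
        try:
            scans.append(
                RadialScan(
                    time=float(t),
                    rpm=float(grp["rpm"].iloc[0]),
                    temperature=float(grp["temp_C"].iloc[0]),
                    radii=grp["radius_cm"].to_numpy(),
                    signal=grp["signal"].to_numpy(),
                )
            )
        except ValueError as exc:
            raise ScanParseError(f"{path}, scan at t={t}: {exc}") from exc
    return ScanSet(scans)


def write_scanset_csv(scanset: ScanSet, path) -> None:
    frames = []
    for sc in scanset:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sc.time,
                    "rpm": sc.rpm,
                    "temp_C": sc.temperature,
                    "radius_cm": sc.radii,
                    "signal": sc.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
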