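"""Reading, writing, and validating time-series sensor logs.

The on-disk format is a plain UTF-8 CSV with '.' decimals and a mandatory
header row ``t,ax,ay,az,gx,gy,gz[,mx,my,mz],p``.  Free-form provenance is
stored in ``# key: value`` comment lines before the header.  Canonical units
are physical: seconds, g, deg/s, µT, Pa.  Files recorded in raw sensor counts
declare ``# units: lsb`` and are converted on read using the device scale
factors (512 LSB/g, 32.8 LSB/°/s, 3.3 LSB/µT, 6 LSB/Pa).

Timestamps are seconds since trace start, strictly increasing; only Δt matters
downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import (
    ACC_LSB_PER_G,
    ACC_RANGE_G,
    GYRO_LSB_PER_DPS,
    MAG_LSB_PER_UT,
    PRESS_LSB_PER_PA,
    PRESSURE_MAX_PA,
    PRESSURE_MIN_PA,
)

BASE_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "p"]
MAG_COLUMNS = ["mx", "my", "mz"]
_HEADER_WITH_MAG = BASE_COLUMNS[:7] + MAG_COLUMNS + ["p"]


class SensorLogError(Exception):
    """Base class for sensor-log problems."""


class FormatError(SensorLogError):
    """Malformed file: bad header or unparsable rows."""


class ValidationError(SensorLogError):
    """Well-formed file whose contents violate a log invariant."""


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped reading in canonical units."""

    t: float                      # s since trace start
    acc: np.ndarray               # (3,) in g
    gyro: np.ndarray              # (3,) in deg/s
    pressure: float               # Pa
    mag: np.ndarray | None = None  # (3,) in µT, optional


@dataclass
class SensorLog:
    """A validated trace stored column-wise for fast numerics.

    ``samples`` iterates :class:`ImuSample` views for row-wise access.
    """

    t: np.ndarray                 # (n,)
    acc: np.ndarray               # (n, 3) g
    gyro: np.ndarray              # (n, 3) deg/s
    pressure: np.ndarray          # (n,) Pa
    mag: np.ndarray | None = None  # (n, 3) µT or None
    rate_hz: float = 100.0
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> Iterator[ImuSample]:
        for i in range(len(self.t)):
            yield ImuSample(
                t=float(self.t[i]),
                acc=self.acc[i],
                gyro=self.gyro[i],
                pressure=float(self.pressure[i]),
                mag=None if self.mag is None else self.mag[i],
            )

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        n = len(self.t)
        if n == 0:
            return
        if self.t[0] < 0:
            raise ValidationError("timestamps must be non-negative (row 1)")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"timestamps must be strictly increasing (row {bad[0] + 2})"
            )
        if np.any(self.pressure < PRESSURE_MIN_PA) or np.any(
            self.pressure > PRESSURE_MAX_PA
        ):
            i = int(
                np.nonzero(
                    (self.pressure < PRESSURE_MIN_PA)
                    | (self.pressure > PRESSURE_MAX_PA)
                )[0][0]
            )
            raise ValidationError(
                f"pressure outside {PRESSURE_MIN_PA:.0f}-{PRESSURE_MAX_PA:.0f} Pa "
                f"(row {i + 1})"
            )
        if np.any(np.abs(self.acc) > ACC_RANGE_G + 1e-9):
            i = int(np.nonzero(np.any(np.abs(self.acc) > ACC_RANGE_G + 1e-9, axis=1))[0][0])
            raise ValidationError(f"acceleration outside ±{ACC_RANGE_G:.0f} g (row {i + 1})")
        if n > 2:
            med = float(np.median(dt))
            nominal = 1.0 / self.rate_hz
            if abs(med - nominal) > 0.1 * nominal:
                raise ValidationError(
                    f"median sample interval {med:.4f} s deviates more than 10% "
                    f"from nominal {nominal:.4f} s"
                )


def lsb_to_physical(log: SensorLog) -> SensorLog:
    """Convert a raw-count log to canonical physical units (linear, invertible)."""
    return SensorLog(
        t=log.t,
        acc=log.acc / ACC_LSB_PER_G,
        gyro=log.gyro / GYRO_LSB_PER_DPS,
        pressure=log.pressure / PRESS_LSB_PER_PA,
        mag=None if log.mag is None else log.mag / MAG_LSB_PER_UT,
        rate_hz=log.rate_hz,
        meta={**log.meta, "units": "physical"},
    )


def physical_to_lsb(log: SensorLog) -> SensorLog:
    """Inverse of :func:`lsb_to_physical` (used for round-trip checks)."""
    return SensorLog(
        t=log.t,
        acc=log.acc * ACC_LSB_PER_G,
        gyro=log.gyro * GYRO_LSB_PER_DPS,
        pressure=log.pressure * PRESS_LSB_PER_PA,
        mag=None if log.mag is None else log.mag * MAG_LSB_PER_UT,
        rate_hz=log.rate_hz,
        meta={**log.meta, "units": "lsb"},
    )


def _parse_meta(path: Path) -> tuple[dict[str, str], int]:
    """Read leading ``# key: value`` lines; return (meta, n_comment_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n


def read_sensor_log(path: str | Path) -> SensorLog:
    """Read and validate a CSV sensor log, converting raw counts if declared."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, skip = _parse_meta(path)
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"unparsable CSV: {exc}") from exc
    cols = list(df.columns)
    if cols not in (BASE_COLUMNS, _HEADER_WITH_MAG):
        raise FormatError(
            f"unexpected header {cols!r}; expected {BASE_COLUMNS!r} "
            f"optionally with {MAG_COLUMNS!r} before 'p'"
        )
    has_mag = "mx" in cols
    if len(df) and not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise FormatError("non-numeric values in data rows")
    rate = float(meta.get("rate_hz", 100.0))
    log = SensorLog(
        t=df["t"].to_numpy(),
        acc=df[["ax", "ay", "az"]].to_numpy() if len(df) else np.empty((0, 3)),
        gyro=df[["gx", "gy", "gz"]].to_numpy() if len(df) else np.empty((0, 3)),
        pressure=df["p"].to_numpy(),
        mag=df[MAG_COLUMNS].to_numpy() if has_mag and len(df) else
        (np.empty((0, 3)) if has_mag else None),
        rate_hz=rate,
        meta=meta,
    )
    units = meta.get("units", "physical").lower()
    if units in ("lsb", "raw") or meta.get("raw_lsb", "").lower() in ("true", "1"):
        log = lsb_to_physical(log)
        log.meta = {**meta, "units": "physical"}
    log.validate()
    return log


def write_sensor_log(log: SensorLog, path: str | Path) -> None:
    """Write a log in the canonical CSV dialect (deterministic formatting)."""
    path = Path(path)
    buf = io.StringIO()
    for key, value in sorted(log.meta.items()):
        buf.write(f"# {key}: {value}\n")
    if "rate_hz" not in log.meta:
        buf.write(f"# rate_hz: {log.rate_hz:g}\n")
    has_mag = log.mag is not None
    header = _HEADER_WITH_MAG if has_mag else BASE_COLUMNS
    buf.write(",".join(header) + "\n")
    for i in range(len(log)):
        fields = [
            f"{log.t[i]:.9g}",
            f"{log.acc[i, 0]:.9g}", f"{log.acc[i, 1]:.9g}", f"{log.acc[i, 2]:.9g}",
            f"{log.gyro[i, 0]:.9g}", f"{log.gyro[i, 1]:.9g}", f"{log.gyro[i, 2]:.9g}",
        ]
        if has_mag:
            fields += [f"{log.mag[i, j]:.9g}" for j in range(3)]
        fields.append(f"{log.pressure[i]:.9g}")
        buf.write(",".join(fields) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
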