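"""Data model for cylinder-grip (manugraphy) records.

A manugraphy measurement unrolls the sensor-covered cylinder surface into a
rectangular grid of perpendicular force values (one value per pressure
sensor).  The hand's contact area is partitioned into seven anatomical
regions -- the five digits plus the thenar and hypothenar eminences -- and
each trial is summarised as the total grip force together with the percent
contribution of each region to that total.  This module holds the domain
types (grids, masks, per-area loads, trial records), the grid-to-area
aggregation, and plain-text file I/O for trial tables and grids.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HandArea",
    "AREAS",
    "BACKGROUND",
    "SensorGrid",
    "AreaMask",
    "AreaLoads",
    "TrialRecord",
    "aggregate_map",
    "read_trials",
    "write_trials",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "TRIALS_COLUMNS",
]

# Tolerance on the percent-composition closure (percents must sum to 100).
PERCENT_CLOSURE_ATOL = 1e-6
# Looser tolerance accepted on file input before renormalising.
PERCENT_INPUT_ATOL = 0.5


class HandArea(str, enum.Enum):
    """The seven anatomical contact regions of the gripping hand.

    ``I``..``V`` are the thumb through little finger; ``TH`` and ``HY`` are
    the thenar and hypothenar eminences at the base of the palm.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    TH = "TH"
    HY = "HY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical area order used everywhere (arrays, CSV columns, reports).
AREAS: tuple[HandArea, ...] = tuple(HandArea)

#: Mask code for sensors outside every anatomical region.
BACKGROUND = ""


def _validate_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class SensorGrid:
    """Rectangular matrix of perpendicular force per sensor (newtons).

    Parameters
    ----------
    values
        2-D array of non-negative force values; rows/columns index the
        unrolled cylinder surface (row-major, no physical origin exposed).
    sensor_area
        Active area of one sensor in mm² (default 7).
    density
        Sensor density in sensors per cm² (default 2).
    cylinder_label
        Nominal cylinder size in mm (default 200).
    """

    values: np.ndarray
    sensor_area: float = 7.0
    density: float = 2.0
    cylinder_label: float = 200.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("grid contains non-finite force values")
        if np.any(arr < 0):
            raise ValueError("grid contains negative force values")
        _validate_positive("sensor_area", self.sensor_area)
        _validate_positive("density", self.density)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_active(self) -> int:
        """Number of sensors registering a strictly positive load."""
        return int(np.count_nonzero(self.values > 0))


@dataclass(frozen=True)
class AreaMask:
    """Assignment of each grid cell to one :class:`HandArea` or background.

    ``assignment`` is an object array of area codes (``"I"`` .. ``"HY"``)
    with :data:`BACKGROUND` marking unassigned cells.
    """

    assignment: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment, dtype=object)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        valid = {a.value for a in HandArea} | {BACKGROUND}
        codes = set(arr.ravel().tolist())
        unknown = codes - valid
        if unknown:
            raise ValueError(f"mask contains unknown area codes: {sorted(unknown)}")
        object.__setattr__(self, "assignment", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.assignment.shape

    def cells(self, area: HandArea) -> np.ndarray:
        """Boolean selector of the cells assigned to ``area``."""
        return self.assignment == area.value


@dataclass(frozen=True)
class AreaLoads:
    """Total grip force plus the compositional per-area percent loads.

    Percents are stored in percentage points (0-100, never fractions) and
    must close to 100 whenever ``total_force`` is positive.
    """

    total_force: float
    percent: Mapping[HandArea, float]

    def __post_init__(self) -> None:
        if not (self.total_force >= 0) or not math.isfinite(self.total_force):
            raise ValueError(f"total_force must be finite and >= 0, got {self.total_force!r}")
        pct = {a: float(self.percent[a]) for a in AREAS}
        if any(v < 0 or not math.isfinite(v) for v in pct.values()):
            raise ValueError("percent loads must be finite and >= 0")
        if self.total_force > 0:
            s = sum(pct.values())
            if abs(s - 100.0) > PERCENT_CLOSURE_ATOL:
                raise ValueError(f"percent loads must sum to 100, got {s!r}")
        object.__setattr__(self, "percent", pct)

    def as_array(self) -> np.ndarray:
        """Percent loads as a vector in canonical :data:`AREAS` order."""
        return np.array([self.percent[a] for a in AREAS], dtype=float)

    @classmethod
    def from_array(cls, total_force: float, percents: Sequence[float]) -> "AreaLoads":
        return cls(total_force=float(total_force), percent=dict(zip(AREAS, map(float, percents))))


_SESSIONS = (1, 2)
_TRIALS = (1, 2, 3)
_HANDS = ("left", "right")
_EFFORTS = ("maximal", "submaximal", "unknown")
_SEXES = ("male", "female")


@dataclass(frozen=True)
class TrialRecord:
    """One hand × one trial of the grip test, with subject metadata.

    ``effort`` is ``"unknown"`` only for blinded classification inputs.
    ``effort_fraction`` is generator provenance (the realised fraction of
    the subject's capacity that was exerted); it is absent (``None``) for
    records read from measurement files.
    """

    subject_id: str
    session: int
    trial: int
    hand: str
    effort: str
    loads: AreaLoads
    age: float
    sex: str
    handedness: str
    grid: SensorGrid | None = None
    effort_fraction: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.session not in _SESSIONS:
            raise ValueError(f"session must be one of {_SESSIONS}, got {self.session!r}")
        if self.trial not in _TRIALS:
            raise ValueError(f"trial must be one of {_TRIALS}, got {self.trial!r}")
        if self.hand not in _HANDS:
            raise ValueError(f"hand must be one of {_HANDS}, got {self.hand!r}")
        if self.effort not in _EFFORTS:
            raise ValueError(f"effort must be one of {_EFFORTS}, got {self.effort!r}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.handedness not in _HANDS:
            raise ValueError(f"handedness must be one of {_HANDS}, got {self.handedness!r}")


def aggregate_map(grid: SensorGrid, mask: AreaMask) -> AreaLoads:
    """Aggregate a sensor grid into total force and per-area percent loads.

    The total force is the sum of forces over all masked (non-background)
    cells; each area's percent contribution is 100 times its masked force
    sum divided by the total.  Background sensors contribute nothing.

    Raises
    ------
    ValueError
        On a shape mismatch, or when the masked total force is zero
        (an empty or failed grip yields no defined composition).
    """
    if grid.shape != mask.shape:
        raise ValueError(f"grid shape {grid.shape} does not match mask shape {mask.shape}")
    area_sums = {a: float(grid.values[mask.cells(a)].sum()) for a in AREAS}
    total = sum(area_sums.values())
    if total <= 0:
        raise ValueError("empty or failed grip: zero total force over the masked area")
    percent = {a: 100.0 * s / total for a, s in area_sums.items()}
    return AreaLoads(total_force=total, percent=percent)


#: Column order of the trials CSV (stable across write/read round-trips).
TRIALS_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "session",
    "trial",
    "hand",
    "effort",
    "age",
    "sex",
    "handedness",
    "total_force",
    "pct_I",
    "pct_II",
    "pct_III",
    "pct_IV",
    "pct_V",
    "pct_TH",
    "pct_HY",
)


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trial records to a UTF-8 CSV with a fixed column order.

    Floats are written with Python's shortest round-trip representation, so
    reading the file back reproduces the stored values bit for bit.
    """
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "session": r.session,
            "trial": r.trial,
            "hand": r.hand,
            "effort": r.effort,
            "age": r.age,
            "sex": r.sex,
            "handedness": r.handedness,
            "total_force": r.loads.total_force,
        }
        for a in AREAS:
            row[f"pct_{a.value}"] = r.loads.percent[a]
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(TRIALS_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path: str | Path, format: str = "csv") -> list[TrialRecord]:
    """Read trial records from a trials CSV.

    Percent columns are renormalised to close exactly to 100 when their sum
    is within ±0.5 of 100; a larger departure raises a validation error
    naming the offending row.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials file {path} is missing columns: {missing}")
    records: list[TrialRecord] = []
    for idx, row in df.iterrows():
        total = float(row["total_force"])
        if total < 0:
            raise ValueError(f"row {idx}: negative total_force {total}")
        pct = np.array([float(row[f"pct_{a.value}"]) for a in AREAS])
        if np.any(pct < 0):
            raise ValueError(f"row {idx}: negative percent load")
        s = pct.sum()
        if abs(s - 100.0) > PERCENT_INPUT_ATOL:
            raise ValueError(f"row {idx}: percent loads sum to {s}, outside 100 ± {PERCENT_INPUT_ATOL}")
        factor = 100.0 / s
        if factor != 1.0:
            pct = pct * factor
        records.append(
            TrialRecord(
                subject_id=str(row["subject_id"]),
                session=int(row["session"]),
                trial=int(row["trial"]),
                hand=str(row["hand"]),
                effort=str(row["effort"]),
                loads=AreaLoads.from_array(total, pct),
                age=float(row["age"]),
                sex=str(row["sex"]),
                handedness=str(row["handedness"]),
            )
        )
    return records


def write_grid(grid: SensorGrid, path: str | Path) -> None:
    """Write a sensor grid as a whitespace-delimited numeric matrix."""
    np.savetxt(path, grid.values, fmt="%.17g")


def read_grid(path: str | Path, **kwargs) -> SensorGrid:
    """Read a whitespace-delimited numeric matrix as a :class:`SensorGrid`."""
    values = np.loadtxt(path, ndmin=2)
    return SensorGrid(values=values, **kwargs)


def write_mask(mask: AreaMask, path: str | Path) -> None:
    """Write an area mask as whitespace-delimited codes; background is ``.``."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in mask.assignment:
            fh.write(" ".join(c if c != BACKGROUND else "." for c in row) + "\n")


def read_mask(path: str | Path) -> AreaMask:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if tokens:
                rows.append([BACKGROUND if t == "." else t for t in tokens])
    return AreaMask(assignment=np.array(rows, dtype=object))
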