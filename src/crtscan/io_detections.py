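"""Reading, validating and writing acoustic detection logs.

A detection log holds one record per acoustic detection: the receiver
(listening station) that logged the transmission, the tagged animal's
identifier, and the detection time.  Two plain-text layouts are
supported:

``supplementary``
    Whitespace-delimited, no header.  Columns are receiver ID, animal
    (tag) ID and an incremental time in seconds; any further columns
    (typically a human-readable ``DD MM YYYY h min sec`` date) are
    ignored — the incremental-seconds column is authoritative.

``generic``
    Delimited text with a header row.  Delimiter and column names are
    configurable; the defaults are whitespace and columns named
    ``receiver_id``, ``animal_id``, ``time``.

Times are plain non-negative scalars in whatever unit the file declares
(seconds for field data, abstract steps for simulated data).  No
timezone or calendar handling is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "DetectionParseError",
    "DetectionTable",
    "read_detections",
    "write_detections",
]

#: canonical column order of the in-memory table
COLUMNS = ("receiver_id", "animal_id", "time")


class DetectionParseError(ValueError):
    """Raised when a detection file cannot be parsed.

    Carries the 1-based line number of the offending line when it is
    known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _canonicalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and put a raw detection frame into canonical order.

    Canonical order is a stable sort by (animal, time): within each
    animal records are time-ascending and ties keep their original file
    order (ties are resolved downstream by the residence-time builder).
    Exact duplicate (animal, receiver, time) triples collapse to one
    record.
    """
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"detection frame missing columns: {missing}")
    frame = frame.loc[:, list(COLUMNS)]

    time = pd.to_numeric(frame["time"], errors="coerce")
    bad = np.flatnonzero(time.isna().to_numpy())
    if bad.size:
        raise DetectionParseError(
            f"non-numeric time value {frame['time'].iloc[bad[0]]!r}",
            line_number=int(bad[0]) + 1,
        )
    if (time < 0).any():
        i = int(np.flatnonzero((time < 0).to_numpy())[0])
        raise DetectionParseError(f"negative time {time.iloc[i]}", line_number=i + 1)
    frame = frame.assign(time=time.to_numpy())

    for col in ("receiver_id", "animal_id"):
        values = frame[col]
        if values.isna().any() or (values.astype(str).str.len() == 0).any():
            raise ValueError(f"empty {col} in detection table")

    before = len(frame)
    frame = frame.drop_duplicates(subset=list(COLUMNS), keep="first")
    if len(frame) < before:
        warnings.warn(
            f"collapsed {before - len(frame)} duplicate detection(s)",
            stacklevel=3,
        )

    per_animal_sorted = (
        frame.groupby("animal_id", sort=False)["time"].is_monotonic_increasing.all()
        if len(frame)
        else True
    )
    if not per_animal_sorted:
        warnings.warn("detections were not time-sorted; sorting", stacklevel=3)
    frame = frame.sort_values(["animal_id", "time"], kind="stable")
    return frame.reset_index(drop=True)


@dataclass
class DetectionTable:
    """Time-ordered acoustic detections for a set of tagged animals.

    The backing :class:`pandas.DataFrame` has columns ``receiver_id``,
    ``animal_id`` and ``time`` and is kept in canonical order (stable
    sort by animal then time, duplicates collapsed).  Construct through
    :meth:`from_frame` or :meth:`from_records` so the invariants hold.
    """

    frame: pd.DataFrame
    time_unit: str = "s"

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, time_unit: str = "s") -> "DetectionTable":
        return cls(_canonicalize(frame), time_unit=time_unit)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        time_unit: str = "s",
    ) -> "DetectionTable":
        """Build a table from ``(receiver_id, animal_id, time)`` tuples."""
        frame = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls.from_frame(frame, time_unit=time_unit)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionTable):
            return NotImplemented
        if self.time_unit != other.time_unit:
            return False
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        return bool(
            (a["receiver_id"].astype(str).to_numpy() == b["receiver_id"].astype(str).to_numpy()).all()
            and (a["animal_id"].astype(str).to_numpy() == b["animal_id"].astype(str).to_numpy()).all()
            and np.allclose(a["time"].to_numpy(float), b["time"].to_numpy(float))
        )

    @property
    def animals(self) -> np.ndarray:
        """Distinct animal identifiers, in order of first appearance."""
        return self.frame["animal_id"].unique()

    def for_animal(self, animal_id) -> pd.DataFrame:
        """All detections of one animal, time-ascending."""
        return self.frame[self.frame["animal_id"] == animal_id]


def read_detections(
    path,
    format: str = "supplementary",
    *,
    delimiter: str | None = None,
    columns: Sequence[str] = COLUMNS,
    time_unit: str = "s",
) -> DetectionTable:
    """Read a detection log from ``path``.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"supplementary"`` (headerless whitespace, columns = receiver,
        animal, incremental time, optional trailing date fields) or
        ``"generic"`` (delimited with header).
    delimiter:
        Field delimiter for the generic format; ``None`` means any
        whitespace.
    columns:
        For the generic format, the header names holding receiver ID,
        animal ID and time, in that order.
    time_unit:
        Unit label recorded on the returned table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "supplementary":
        try:
            raw = pd.read_csv(
                path, sep=r"\s+", header=None, comment="#", dtype=str
            )
        except pd.errors.EmptyDataError:
            raise DetectionParseError("no records")
        if raw.shape[1] < 3:
            raise DetectionParseError(
                f"expected >= 3 columns, found {raw.shape[1]}", line_number=1
            )
        short = raw.iloc[:, 2].isna()
        if short.any():
            raise DetectionParseError(
                "fewer than 3 columns", line_number=int(np.flatnonzero(short)[0]) + 1
            )
        frame = pd.DataFrame(
            {
                "receiver_id": raw.iloc[:, 0],
                "animal_id": raw.iloc[:, 1],
                "time": raw.iloc[:, 2],
            }
        )
    elif format == "generic":
        sep = delimiter if delimiter is not None else r"\s+"
        try:
            raw = pd.read_csv(path, sep=sep, comment="#")
        except pd.errors.EmptyDataError:
            raise DetectionParseError("no records")
        missing = [c for c in columns if c not in raw.columns]
        if missing:
            raise DetectionParseError(f"missing column(s) {missing} in header")
        frame = raw.loc[:, list(columns)]
        frame.columns = list(COLUMNS)
    else:
        raise ValueError(f"unknown format {format!r}")

    if len(frame) == 0:
        raise DetectionParseError("no records")
    return DetectionTable.from_frame(frame, time_unit=time_unit)


def write_detections(
    table: DetectionTable,
    path,
    format: str = "supplementary",
    *,
    delimiter: str = "\t",
) -> None:
    """Write a detection log to ``path``.

    The supplementary layout is whitespace-delimited with no header and
    no trailing date fields (the incremental time column is
    authoritative, so the human-readable date is left blank).  The
    generic layout writes a delimited file with a header row.
    Round-trips through :func:`read_detections` reproduce the table.
    """
    path = Path(path)
    frame = table.frame.copy()
    t = frame["time"].to_numpy()
    if np.all(t == np.floor(t)):
        frame["time"] = t.astype(np.int64)
    if format == "supplementary":
        frame.to_csv(path, sep=" ", header=False, index=False)
    elif format == "generic":
        frame.to_csv(path, sep=delimiter, header=True, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
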