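"""Reading, writing and converting joint-load tables.

The package's table format is a plain CSV with a header row and columns
``activity, sample_index, fx, fy, fz`` ('.' decimal, comma separator).
Force components are either percent of body weight (BW%) or newtons; the
units travel with the dataset, never guessed from the numbers.

Instrumented-prosthesis collections such as HIP98 publish per-activity
time series of hip-contact forces in the pelvic coordinate system in BW%;
exported to this layout (one row per time sample, activities stacked) they
feed directly into :func:`read_load_table`.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Union

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, ParseError, SchemaError

__all__ = [
    "Units",
    "LoadSample",
    "LoadDataset",
    "MajorLoadRow",
    "MajorLoadTable",
    "read_load_table",
    "write_load_table",
    "bw_percent_to_newton",
    "extract_activity_peaks",
    "write_major_loads",
    "read_major_loads",
]

logger = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.81  # m/s^2

_REQUIRED_COLUMNS = ("activity", "sample_index", "fx", "fy", "fz")

PathOrStream = Union[str, Path, IO[str]]


class Units(enum.Enum):
    """Units of force components: percent of body weight, or newtons."""

    BW_PERCENT = "BW_PERCENT"
    NEWTON = "NEWTON"

    @classmethod
    def parse(cls, value: "Units | str") -> "Units":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper().replace("-", "_")
        aliases = {"BW": cls.BW_PERCENT, "BW%": cls.BW_PERCENT, "BW_PERCENT": cls.BW_PERCENT,
                   "N": cls.NEWTON, "NEWTON": cls.NEWTON, "NEWTONS": cls.NEWTON}
        if key not in aliases:
            raise ValueError(f"unknown units {value!r}; expected 'bw' or 'newton'")
        return aliases[key]


@dataclass(frozen=True)
class LoadSample:
    """One recorded force vector of one activity at one time sample."""

    activity: str
    sample_index: int
    f: np.ndarray  # 3 components in `units`
    units: Units

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (3,):
            raise ValueError("force must be a 3-vector")
        if not np.all(np.isfinite(f)):
            raise ValueError("force components must be finite")
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")
        object.__setattr__(self, "f", f)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.f))


@dataclass
class LoadDataset:
    """Ordered collection of load samples with uniform units.

    Internally the samples live in a pandas DataFrame with columns
    ``activity, sample_index, fx, fy, fz``; row order is the dataset order
    and positional row indices are the sample indices used by the covering
    and reporting modules.
    """

    frame: pd.DataFrame
    units: Units
    coordinate_frame: str = "pelvic"

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame is missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)
        dup = self.frame.duplicated(subset=["activity", "sample_index"])
        if dup.any():
            raise SchemaError("sample_index must be unique within each activity")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_samples(cls, samples: list[LoadSample],
                     coordinate_frame: str = "pelvic") -> "LoadDataset":
        if not samples:
            raise EmptyDatasetError("cannot build a dataset from zero samples")
        units = samples[0].units
        if any(s.units is not units for s in samples):
            raise SchemaError("all samples of a dataset must share one unit system")
        frame = pd.DataFrame(
            {"activity": [s.activity for s in samples],
             "sample_index": [s.sample_index for s in samples],
             "fx": [s.f[0] for s in samples],
             "fy": [s.f[1] for s in samples],
             "fz": [s.f[2] for s in samples]})
        return cls(frame, units, coordinate_frame)

    # -- array views -----------------------------------------------------
    def vectors(self) -> np.ndarray:
        """(n, 3) float array of force components in dataset units."""
        return self.frame[["fx", "fy", "fz"]].to_numpy(dtype=float)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors(), axis=1)

    def nonzero_indices(self) -> np.ndarray:
        """Positional indices of samples with a nonzero resultant."""
        return np.flatnonzero(self.magnitudes() > 0.0)

    @property
    def activities(self) -> list[str]:
        """Activity labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["activity"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[LoadSample]:
        for row in self.frame.itertuples(index=False):
            yield LoadSample(str(row.activity), int(row.sample_index),
                             np.array([row.fx, row.fy, row.fz]), self.units)

    def subset(self, positions: np.ndarray) -> "LoadDataset":
        """New dataset keeping the given positional rows, order preserved.

        May be empty (e.g. after an aggressive prefilter); covering runs
        on an empty dataset fail later with :class:`EmptyDatasetError`.
        """
        positions = np.sort(np.asarray(positions, dtype=int))
        return LoadDataset(self.frame.iloc[positions], self.units,
                           self.coordinate_frame)

    def to_newton(self, mass_kg: float, g: float = STANDARD_GRAVITY) -> "LoadDataset":
        """Dataset converted from BW% to newtons; no-op check on units."""
        if self.units is Units.NEWTON:
            raise ValueError("dataset is already in newtons")
        frame = self.frame.copy()
        frame[["fx", "fy", "fz"]] = bw_percent_to_newton(
            frame[["fx", "fy", "fz"]].to_numpy(dtype=float), mass_kg, g)
        return LoadDataset(frame, Units.NEWTON, self.coordinate_frame)


def bw_percent_to_newton(value, mass_kg: float, g: float = STANDARD_GRAVITY):
    """Convert percent-of-body-weight forces to newtons.

    ``value / 100 * mass_kg * g``, applied componentwise to arrays.  100 BW%
    of an 80 kg patient at g = 9.81 m/s^2 is 784.8 N.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    if g <= 0:
        raise ValueError("g must be positive")
    return np.asarray(value, dtype=float) / 100.0 * mass_kg * g


def read_load_table(source: PathOrStream, units: Units | str) -> LoadDataset:
    """Read a delimited load table into a :class:`LoadDataset`.

    The table must carry the columns ``activity, sample_index, fx, fy, fz``;
    row order is preserved.  Zero-magnitude rows are retained (with a logged
    warning) and only excluded later when directions are computed.
    """
    units = Units.parse(units)
    try:
        frame = pd.read_csv(source, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError("load table is empty") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"load table is missing columns: {missing}")
    if len(frame) == 0:
        raise EmptyDatasetError("load table has a header but no data rows")
    for col in ("fx", "fy", "fz"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # 1-based + header
            raise ParseError(f"malformed value in column {col!r} at line {line}")
        frame[col] = coerced
    try:
        frame["sample_index"] = frame["sample_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"sample_index column is not integral: {exc}") from exc
    frame["activity"] = frame["activity"].astype(str)
    dataset = LoadDataset(frame[list(_REQUIRED_COLUMNS)], units)
    n_zero = int(np.sum(dataset.magnitudes() == 0.0))
    if n_zero:
        logger.warning(
            "load table contains %d zero-magnitude row(s); retained, but they are "
            "excluded from direction computation", n_zero)
    return dataset


def write_load_table(dataset: LoadDataset, sink: PathOrStream) -> None:
    """Write a dataset back to the package's CSV layout (lossless)."""
    dataset.frame.to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Major-load tables (the result layout: one named force vector per row)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MajorLoadRow:
    """One named force vector in newtons, optionally with coverage count."""

    name: str
    f: np.ndarray  # 3 components, N
    covered_count: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (3,):
            raise ValueError("force must be a 3-vector")
        object.__setattr__(self, "f", f)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.f))


@dataclass
class MajorLoadTable:
    """Ordered rows of (name, force vector in N); row order is preserved
    across write/read round trips."""

    rows: list[MajorLoadRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[MajorLoadRow]:
        return iter(self.rows)

    def to_dataframe(self, round_newton: bool = False) -> pd.DataFrame:
        """Tabular view; ``round_newton`` gives the integer-newton
        presentation used in printed load tables (full precision is always
        retained in the table itself)."""
        frame = pd.DataFrame(
            {"name": [r.name for r in self.rows],
             "fx_N": [r.f[0] for r in self.rows],
             "fy_N": [r.f[1] for r in self.rows],
             "fz_N": [r.f[2] for r in self.rows],
             "magnitude_N": [r.magnitude for r in self.rows],
             "covered_count": [r.covered_count for r in self.rows]})
        if round_newton:
            for col in ("fx_N", "fy_N", "fz_N", "magnitude_N"):
                frame[col] = frame[col].round().astype(int)
        return frame


def extract_activity_peaks(dataset: LoadDataset, mass_kg: float,
                           g: float = STANDARD_GRAVITY) -> MajorLoadTable:
    """Per-activity peak loads, converted to newtons.

    The peak of an activity is the sample with the maximal resultant
    magnitude (a single coherent vector, not per-component maxima); ties
    are broken by the lowest sample_index.  Activities appear in order of
    first appearance in the dataset.
    """
    if dataset.units is not Units.BW_PERCENT:
        raise ValueError("peak extraction expects a BW% dataset (convert afterwards)")
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot extract peaks from an empty dataset")
    rows: list[MajorLoadRow] = []
    for activity in dataset.activities:
        sub = dataset.frame[dataset.frame["activity"] == activity]
        sub = sub.sort_values("sample_index", kind="stable")
        vecs = sub[["fx", "fy", "fz"]].to_numpy(dtype=float)
        if len(vecs) == 0:
            logger.warning("activity %r has no samples; skipped", activity)
            continue
        mags = np.linalg.norm(vecs, axis=1)
        best = int(np.argmax(mags))  # first max -> lowest sample_index
        rows.append(MajorLoadRow(activity, bw_percent_to_newton(vecs[best], mass_kg, g)))
    return MajorLoadTable(rows)


def write_major_loads(table: MajorLoadTable, sink: PathOrStream,
                      format: str = "csv") -> None:
    """Write a major-load table as CSV or JSON.

    Output is bit-stable for identical input; a read-back with
    :func:`read_major_loads` reproduces the rows exactly.
    """
    if len(table) == 0:
        raise EmptyDatasetError("refusing to write an empty major-load table")
    fmt = format.lower()
    frame = table.to_dataframe()
    if fmt == "csv":
        frame.to_csv(sink, index=False, float_format="%.17g")
    elif fmt == "json":
        records = frame.to_dict(orient="records")
        for rec in records:
            if rec["covered_count"] is None or (isinstance(rec["covered_count"], float)
                                                and math.isnan(rec["covered_count"])):
                rec["covered_count"] = None
            else:
                rec["covered_count"] = int(rec["covered_count"])
        text = json.dumps(records, indent=2)
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text + "\n")
        else:
            sink.write(text + "\n")
    else:
        raise ValueError(f"unknown major-load format {format!r}; use 'csv' or 'json'")


def read_major_loads(source: PathOrStream, format: str = "csv") -> MajorLoadTable:
    """Read back a major-load table written by :func:`write_major_loads`."""
    fmt = format.lower()
    if fmt == "csv":
        frame = pd.read_csv(source, float_precision="round_trip")
        records = frame.to_dict(orient="records")
    elif fmt == "json":
        if isinstance(source, (str, Path)):
            records = json.loads(Path(source).read_text())
        else:
            records = json.load(source)
    else:
        raise ValueError(f"unknown major-load format {format!r}; use 'csv' or 'json'")
    rows = []
    for rec in records:
        count = rec.get("covered_count")
        if count is None or (isinstance(count, float) and math.isnan(count)):
            count = None
        else:
            count = int(count)
        rows.append(MajorLoadRow(str(rec["name"]),
                                 np.array([rec["fx_N"], rec["fy_N"], rec["fz_N"]]),
                                 covered_count=count))
    return MajorLoadTable(rows)
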