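"""Reading and writing digitizing-tablet drawing logs.

The on-disk format is the one used by the open ParkinsonHW collection:
one plain-text file per subject, semicolon-delimited rows of raw device
samples, a ``TestID`` column distinguishing the Static Spiral Test (SST),
Dynamic Spiral Test (DST) and Circular Motion Test (CMT), and one
class-labelled subdirectory per group.  Every dialect decision (column
order, delimiter, test codes, timestamp units, directory names) is
isolated in :class:`TabletDialect` so other tablet exports can be mapped
onto the same in-memory types.

In-memory containers are thin dataclasses around pandas DataFrames:
:class:`DrawingRecord` for one subject x test drawing and
:class:`Dataset` for a labelled collection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical per-sample channels, in storage order
SAMPLE_COLUMNS = ("x", "y", "z", "pressure", "azimuth", "altitude", "timestamp")

#: channels a dialect must provide
_REQUIRED = {"x", "y", "pressure", "timestamp", "test_id"}

LABELS = ("patient", "control")


class TabletFormatError(ValueError):
    """Raised when a drawing log cannot be parsed under the dialect."""


@dataclass(frozen=True)
class TabletDialect:
    """Column layout and conventions of a tablet log file.

    Parameters
    ----------
    delimiter : str
        Field separator.
    columns : tuple of str
        Field names in file order.  Recognised names are the entries of
        ``SAMPLE_COLUMNS`` plus ``test_id``; use ``"_"`` to skip a field.
        The ParkinsonHW files carry a single GripAngle field which is
        mapped to ``azimuth``; ``altitude`` is absent and stored as NaN.
    test_codes : mapping int -> str
        TestID integer codes to test-type names (``SST``/``DST``/``CMT``).
    class_dirs : mapping str -> str
        Subdirectory name -> class label (``patient``/``control``).
    timestamp_unit : {"auto", "s", "ms"}
        ``auto`` treats the column as milliseconds when the median positive
        increment exceeds 0.5 (a >2 Hz pen cannot tick in whole seconds);
        the time origin is always shifted so the first retained sample of
        each record is t = 0.
    pen_lift_policy : {"keep", "drop"}
        What to do with *interior* zero-pressure samples (pen lifts).
        Leading/trailing zeros are always retained — the pressure
        segmentation owns the edges.  ``keep`` retains interior lifts
        (logged); ``drop`` removes them.
    """

    delimiter: str = ";"
    columns: tuple[str, ...] = ("x", "y", "z", "pressure", "azimuth", "timestamp", "test_id")
    test_codes: Mapping[int, str] = field(
        default_factory=lambda: {0: "SST", 1: "DST", 2: "CMT"}
    )
    class_dirs: Mapping[str, str] = field(
        default_factory=lambda: {"control": "control", "parkinson": "patient"}
    )
    timestamp_unit: str = "auto"
    pen_lift_policy: str = "keep"

    def __post_init__(self) -> None:
        missing = _REQUIRED - set(self.columns)
        if missing:
            raise ValueError(f"dialect is missing required columns: {sorted(missing)}")
        if self.timestamp_unit not in ("auto", "s", "ms"):
            raise ValueError(f"unknown timestamp_unit {self.timestamp_unit!r}")
        if self.pen_lift_policy not in ("keep", "drop"):
            raise ValueError(f"unknown pen_lift_policy {self.pen_lift_policy!r}")
        if not set(self.class_dirs.values()) <= set(LABELS):
            raise ValueError(f"class labels must be in {LABELS}")


#: dialect of the public ParkinsonHW files (single GripAngle column)
PARKINSONHW_DIALECT = TabletDialect()

#: dialect used when the synthetic simulator writes cohorts to disk; it
#: carries both pen angles so the full feature battery stays defined
SYNTHETIC_DIALECT = TabletDialect(
    columns=("x", "y", "z", "pressure", "azimuth", "altitude", "timestamp", "test_id")
)


@dataclass
class DrawingRecord:
    """One subject's raw pen samples for one test type.

    ``samples`` is a DataFrame with the ``SAMPLE_COLUMNS`` channels;
    ``timestamp`` is in seconds with the first sample at t = 0.
    """

    subject_id: str
    label: str
    test_type: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if len(self.samples) < 1:
            raise ValueError("a DrawingRecord needs at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        t = self.samples["timestamp"].to_numpy()
        return float(t[-1] - t[0])


@dataclass
class Dataset:
    """A labelled collection of drawing records."""

    records: list[DrawingRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.subject_id, rec.test_type)
            if key in seen:
                raise ValueError(f"duplicate record for subject/test {key}")
            seen.add(key)

    def filter(self, test_type: str) -> "Dataset":
        return Dataset(
            [r for r in self.records if r.test_type == test_type],
            provenance=f"{self.provenance} [test={test_type}]",
        )

    def subjects(self, label: str | None = None) -> list[str]:
        ids = {r.subject_id for r in self.records if label is None or r.label == label}
        return sorted(ids)

    def __len__(self) -> int:
        return len(self.records)


def _convert_timestamps(raw: np.ndarray, unit: str) -> np.ndarray:
    """Timestamp column -> seconds, origin at the first sample."""
    t = raw.astype(float)
    if unit == "auto":
        inc = np.diff(t)
        pos = inc[inc > 0]
        unit = "ms" if pos.size and float(np.median(pos)) > 0.5 else "s"
    if unit == "ms":
        t = t / 1000.0
    return t - t[0]


def _clean_monotone(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Drop rows whose raw timestamp does not increase past the last kept row."""
    ts = df["timestamp"].to_numpy(dtype=float)
    keep = np.ones(len(ts), dtype=bool)
    last = -math.inf
    for i, v in enumerate(ts):
        if v <= last:
            keep[i] = False
        else:
            last = v
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d rows with non-increasing timestamps", context, dropped)
    return df.loc[keep].reset_index(drop=True)


def _handle_pen_lifts(df: pd.DataFrame, policy: str, context: str) -> pd.DataFrame:
    """Apply the dialect's interior zero-pressure (pen lift) policy."""
    p = df["pressure"].to_numpy(dtype=float)
    nonzero = p > 0
    if not nonzero.any():
        return df
    first, last = int(np.argmax(nonzero)), int(len(p) - 1 - np.argmax(nonzero[::-1]))
    interior_lift = (p == 0)
    interior_lift[: first] = False
    interior_lift[last + 1:] = False
    n_lift = int(interior_lift.sum())
    if n_lift:
        logger.info("%s: %d interior pen-lift samples (%s)", context, n_lift, policy)
        if policy == "drop":
            return df.loc[~interior_lift].reset_index(drop=True)
    return df


def read_drawing_file(
    path: str | Path,
    dialect: TabletDialect = PARKINSONHW_DIALECT,
    *,
    subject_id: str | None = None,
    label: str = "control",
) -> list[DrawingRecord]:
    """Parse one tablet log into per-test-type drawing records.

    Rows are partitioned by the TestID column, preserving row order within
    each test.  Rows with non-increasing timestamps are dropped (logged).
    Returns one :class:`DrawingRecord` per test type present, in order of
    first appearance.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncol = len(dialect.columns)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) != ncol:
                raise TabletFormatError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TabletFormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise TabletFormatError(f"{path}: no samples")

    frame = pd.DataFrame(rows, columns=list(dialect.columns))
    if subject_id is None:
        subject_id = path.stem

    records: list[DrawingRecord] = []
    codes = frame["test_id"].astype(int)
    for code in codes.unique():
        code = int(code)
        if code not in dialect.test_codes:
            raise TabletFormatError(f"{path}: unknown TestID code {code}")
        sub = frame.loc[codes.to_numpy() == code].reset_index(drop=True)
        context = f"{path.name}[{dialect.test_codes[code]}]"
        sub = _clean_monotone(sub, context)
        sub = _handle_pen_lifts(sub, dialect.pen_lift_policy, context)
        samples = pd.DataFrame(
            {
                name: (
                    sub[name].to_numpy(dtype=float)
                    if name in sub.columns
                    else np.full(len(sub), np.nan)
                )
                for name in SAMPLE_COLUMNS
            }
        )
        samples["timestamp"] = _convert_timestamps(
            sub["timestamp"].to_numpy(), dialect.timestamp_unit
        )
        records.append(
            DrawingRecord(
                subject_id=subject_id,
                label=label,
                test_type=dialect.test_codes[code],
                samples=samples,
            )
        )
    return records


def write_drawing_file(
    records: Sequence[DrawingRecord],
    path: str | Path,
    dialect: TabletDialect = SYNTHETIC_DIALECT,
) -> None:
    """Serialize records back to the tablet log format.

    Timestamps are written in the dialect's unit (``auto`` writes
    milliseconds, the convention of the source device).  Values that are
    whole numbers are written without a decimal point so integer device
    units round-trip exactly.
    """
    code_of = {v: k for k, v in dialect.test_codes.items()}
    unit = "ms" if dialect.timestamp_unit in ("auto", "ms") else "s"

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "nan"
        if float(v).is_integer():
            return str(int(v))
        return repr(float(v))

    lines: list[str] = []
    for rec in records:
        if rec.test_type not in code_of:
            raise ValueError(f"dialect has no code for test type {rec.test_type!r}")
        code = code_of[rec.test_type]
        for _, row in rec.samples.iterrows():
            out = []
            for name in dialect.columns:
                if name == "test_id":
                    out.append(str(code))
                elif name == "timestamp":
                    t = row["timestamp"] * 1000.0 if unit == "ms" else row["timestamp"]
                    out.append(fmt(round(t, 9)))
                elif name == "_":
                    out.append("0")
                else:
                    out.append(fmt(row[name]))
            lines.append(dialect.delimiter.join(out))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_dataset(
    root: str | Path, dialect: TabletDialect = PARKINSONHW_DIALECT
) -> Dataset:
    """Load a directory tree of tablet logs into a :class:`Dataset`.

    ``root`` must contain the dialect's class subdirectories (defaults
    ``control`` and ``parkinson``); every file inside becomes one record
    per test type it contains, with ``subject_id`` the file stem and the
    label taken from the directory.
    """
    root = Path(root)
    found_dirs = [d for d in dialect.class_dirs if (root / d).is_dir()]
    if not found_dirs:
        raise TabletFormatError(
            f"{root}: no class subdirectories found (expected any of "
            f"{sorted(dialect.class_dirs)})"
        )
    records: list[DrawingRecord] = []
    owner: dict[str, str] = {}
    for dirname in found_dirs:
        label = dialect.class_dirs[dirname]
        for fp in sorted((root / dirname).iterdir()):
            if not fp.is_file():
                continue
            sid = fp.stem
            if sid in owner and owner[sid] != label:
                raise TabletFormatError(
                    f"subject {sid!r} appears in more than one class directory"
                )
            owner[sid] = label
            records.extend(read_drawing_file(fp, dialect, subject_id=sid, label=label))
    return Dataset(records, provenance=str(root))


# ---------------------------------------------------------------------------
# feature tables

META_COLUMNS = ("subject_id", "label", "test_type")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as comma-delimited UTF-8 text with header.

    Columns are ``subject_id, label, test_type`` followed by the feature
    registry columns in registry order; floats use shortest-repr formatting
    so the round-trip through :func:`read_feature_table` is exact.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing metadata columns {missing}")
    ordered = list(META_COLUMNS) + [c for c in table.columns if c not in META_COLUMNS]
    table.loc[:, ordered].to_csv(path, index=False, encoding="utf-8")


def read_feature_table(
    path: str | Path, expected_features: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`.

    When ``expected_features`` is given (normally the registry names) any
    unexpected column raises, listing the offending names.
    """
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if expected_features is not None:
        allowed = set(META_COLUMNS) | set(expected_features)
        unknown = [c for c in table.columns if c not in allowed]
        if unknown:
            raise ValueError(f"{path}: unknown feature columns {unknown}")
    return table
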