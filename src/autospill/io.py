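"""Core containers and file I/O for spillover computation.

The central objects are :class:`EventTable` (events x detectors matrix of one
control sample), :class:`ControlSet` (the indexed collection of single-color
controls, one per dye), :class:`SpilloverMatrix` (the d x c row-normalized
spillover/compensation matrix) and :class:`ConvergenceTrace` (per-iteration
diagnostics of the refinement loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._fcs import read_fcs

__all__ = [
    "EventTable",
    "ControlEntry",
    "ControlIndex",
    "ControlSet",
    "SpilloverMatrix",
    "CompensationErrorMatrix",
    "ConvergenceTrace",
    "TraceRecord",
    "AutospillError",
    "MissingFileError",
    "DetectorMismatchError",
    "DetectorNotFoundError",
    "DuplicateDyeError",
    "NonFiniteDataError",
    "AUTO",
    "read_control_index",
    "read_control_set",
    "write_spillover_csv",
    "read_spillover_csv",
    "write_trace",
]

#: Sentinel naming in a control index: resolve the primary detector from data.
AUTO = "AUTO"

_SCATTER_DEFAULTS = ("FSC-A", "SSC-A")


class AutospillError(Exception):
    """Base class for errors raised by this package."""


class MissingFileError(AutospillError, FileNotFoundError):
    """A control file named in the index does not exist."""


class DetectorMismatchError(AutospillError):
    """Controls in one set do not share the same detector set."""


class DetectorNotFoundError(AutospillError, KeyError):
    """A named detector is absent from a file's detector list."""


class DuplicateDyeError(AutospillError):
    """Two index entries name the same dye."""


class NonFiniteDataError(AutospillError):
    """Event data contains NaN or infinite values."""


@dataclass(frozen=True)
class EventTable:
    """Events x detectors matrix of fluorescence/scatter values.

    Values are kept on the stored linear scale; any transform (bi-exponential
    display scale, compensation) is applied explicitly downstream. Non-finite
    values are rejected at construction rather than silently dropped.
    """

    values: np.ndarray
    detector_names: tuple[str, ...]
    scatter_channels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "detector_names", tuple(self.detector_names))
        if values.ndim != 2:
            raise ValueError("event values must be a 2-d array")
        if values.shape[0] < 1:
            raise ValueError("an EventTable requires at least one event")
        if values.shape[1] != len(self.detector_names):
            raise ValueError("one detector name required per column")
        if len(set(self.detector_names)) != len(self.detector_names):
            raise ValueError("detector names must be unique")
        if not np.all(np.isfinite(values)):
            raise NonFiniteDataError("event data contains non-finite values")
        if self.scatter_channels is not None:
            pair = tuple(self.scatter_channels)
            if len(pair) != 2:
                raise ValueError("scatter_channels must be a (forward, side) pair")
            for name in pair:
                if name not in self.detector_names:
                    raise DetectorNotFoundError(name)
            object.__setattr__(self, "scatter_channels", pair)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            idx = self.detector_names.index(name)
        except ValueError:
            raise DetectorNotFoundError(name) from None
        return self.values[:, idx]

    def scatter(self) -> np.ndarray:
        """(n, 2) forward/side scatter values."""
        if self.scatter_channels is None:
            raise ValueError("no scatter channels designated")
        fsc, ssc = self.scatter_channels
        return np.column_stack([self.column(fsc), self.column(ssc)])

    def fluorescence_names(self) -> tuple[str, ...]:
        """Detector names excluding the designated scatter channels."""
        drop = set(self.scatter_channels or ())
        return tuple(n for n in self.detector_names if n not in drop)

    def fluorescence(self) -> np.ndarray:
        names = self.fluorescence_names()
        idx = [self.detector_names.index(n) for n in names]
        return self.values[:, idx]

    def take(self, row_mask: np.ndarray) -> "EventTable":
        return replace(self, values=self.values[row_mask])


@dataclass(frozen=True)
class ControlEntry:
    file_id: str
    dye_name: str
    primary_detector: str = AUTO
    is_unstained: bool = False


@dataclass(frozen=True)
class ControlIndex:
    """Maps each control file to its dye and (optionally) primary detector."""

    entries: tuple[ControlEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        dyes = [e.dye_name for e in self.entries]
        if len(set(dyes)) != len(dyes):
            dupes = sorted({d for d in dyes if dyes.count(d) > 1})
            raise DuplicateDyeError(f"duplicate dye names in index: {dupes}")
        if sum(e.is_unstained for e in self.entries) > 1:
            raise ValueError("at most one unstained entry is allowed")

    @property
    def unstained(self) -> ControlEntry | None:
        for entry in self.entries:
            if entry.is_unstained:
                return entry
        return None

    @property
    def stained(self) -> tuple[ControlEntry, ...]:
        return tuple(e for e in self.entries if not e.is_unstained)


@dataclass
class ControlSet:
    """Gated or raw single-color controls, one :class:`EventTable` per dye.

    ``primaries`` maps dye name to a detector name, or to :data:`AUTO` until
    resolved by :func:`autospill.spillover.resolve_primary`.
    """

    dyes: list[str]
    tables: dict[str, EventTable]
    primaries: dict[str, str]
    unstained: EventTable | None = None
    detectors: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.detectors and self.dyes:
            self.detectors = self.tables[self.dyes[0]].detector_names
        for dye in self.dyes:
            table = self.tables[dye]
            if table.detector_names != tuple(self.detectors):
                raise DetectorMismatchError(
                    f"control {dye!r} has a different detector set"
                )
            primary = self.primaries.get(dye, AUTO)
            if primary != AUTO and primary not in self.detectors:
                raise DetectorNotFoundError(primary)

    @property
    def n_dyes(self) -> int:
        return len(self.dyes)

    def fluorescence_names(self) -> tuple[str, ...]:
        return self.tables[self.dyes[0]].fluorescence_names()

    def map_tables(self, fn) -> "ControlSet":
        """New ControlSet with ``fn`` applied to every table (incl. unstained)."""
        return ControlSet(
            dyes=list(self.dyes),
            tables={d: fn(t) for d, t in self.tables.items()},
            primaries=dict(self.primaries),
            unstained=fn(self.unstained) if self.unstained is not None else None,
            detectors=tuple(self.detectors),
        )


@dataclass(frozen=True)
class SpilloverMatrix:
    """d x c row-normalized spillover matrix.

    Row i is the emission fingerprint of dye i across detectors, normalized so
    the entry at the dye's primary detector is exactly 1.
    """

    coef: np.ndarray
    dyes: tuple[str, ...]
    detectors: tuple[str, ...]
    primary: dict[str, int]

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=np.float64)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "dyes", tuple(self.dyes))
        object.__setattr__(self, "detectors", tuple(self.detectors))
        d, c = coef.shape
        if d != len(self.dyes) or c != len(self.detectors):
            raise ValueError("coef shape does not match dye/detector labels")
        if d > c:
            raise ValueError("more dyes than detectors: underdetermined system")
        for i, dye in enumerate(self.dyes):
            h = self.primary[dye]
            if not 0 <= h < c:
                raise ValueError(f"primary index out of range for dye {dye!r}")
            if coef[i, h] != 1.0:
                raise ValueError(f"row for dye {dye!r} not normalized at its primary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coef.shape

    def primary_name(self, dye: str) -> str:
        return self.detectors[self.primary[dye]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=list(self.dyes), columns=list(self.detectors))


@dataclass(frozen=True)
class CompensationErrorMatrix:
    """d x d matrix of residual compensation slopes; diagonal identically 0."""

    coef: np.ndarray
    dyes: tuple[str, ...]

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=np.float64)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "dyes", tuple(self.dyes))
        if coef.shape != (len(self.dyes), len(self.dyes)):
            raise ValueError("error matrix must be d x d")
        if np.any(np.diag(coef) != 0.0):
            raise ValueError("error matrix diagonal must be exactly zero")

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.coef))) if self.coef.size else 0.0

    def off_diagonal(self) -> np.ndarray:
        d = self.coef.shape[0]
        mask = ~np.eye(d, dtype=bool)
        return self.coef[mask]

    def sd(self) -> float:
        off = self.off_diagonal()
        return float(np.std(off)) if off.size else 0.0


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    scale: str  # "linear" or "biexp"
    sd_error: float
    max_abs_error: float
    moving_average: float
    damping: float


@dataclass
class ConvergenceTrace:
    """Per-iteration refinement diagnostics (the quantities a convergence
    plot shows: sd of errors, max |error|, oscillation moving average).

    ``final_errors`` is the compensation-error matrix of the last iteration,
    measured in the scale the algorithm was using at that point;
    ``transforms`` holds the per-dye bi-exponential transforms in effect (or
    ``None`` while still in linear scale).
    """

    records: list[TraceRecord] = field(default_factory=list)
    status: str = "running"  # running | converged | not_converged
    final_errors: "CompensationErrorMatrix | None" = None
    transforms: dict | None = None

    def append(self, record: TraceRecord) -> None:
        if self.records and record.iteration <= self.records[-1].iteration:
            raise ValueError("iteration indices must be strictly increasing")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "scale": r.scale,
                    "sd_error": r.sd_error,
                    "max_abs_error": r.max_abs_error,
                    "moving_average": r.moving_average,
                    "damping": r.damping,
                }
                for r in self.records
            ],
            columns=[
                "iteration",
                "scale",
                "sd_error",
                "max_abs_error",
                "moving_average",
                "damping",
            ],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _detect_scatter(names: list[str]) -> tuple[str, str] | None:
    found = []
    for target in _SCATTER_DEFAULTS:
        hit = next((n for n in names if target.lower() in n.lower()), None)
        if hit is None:
            return None
        found.append(hit)
    return tuple(found)  # type: ignore[return-value]


def read_control_index(path: str | Path) -> ControlIndex:
    """Read a control index CSV with columns file,dye,primary_detector,unstained."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"file", "dye"}
    if not required.issubset(frame.columns):
        raise ValueError(f"control index must have columns {sorted(required)}")
    entries = []
    for _, row in frame.iterrows():
        primary = row.get("primary_detector", "") or AUTO
        unstained = str(row.get("unstained", "0")).strip() in ("1", "true", "True")
        entries.append(
            ControlEntry(
                file_id=row["file"],
                dye_name=row["dye"],
                primary_detector=primary,
                is_unstained=unstained,
            )
        )
    return ControlIndex(tuple(entries))


def read_control_set(
    paths: dict[str, str | Path] | str | Path,
    index: ControlIndex,
    scatter_channels: tuple[str, str] | None = None,
) -> ControlSet:
    """Read the raw (ungated) single-color controls named by an index.

    ``paths`` is either a directory containing the files named in the index,
    or an explicit mapping from file_id to path. Detector order is harmonized
    to the first file's order; every file must provide the same detector set.
    """
    if not isinstance(paths, dict):
        base = Path(paths)
        paths = {e.file_id: base / e.file_id for e in index.entries}

    dyes: list[str] = []
    tables: dict[str, EventTable] = {}
    primaries: dict[str, str] = {}
    unstained_table: EventTable | None = None
    reference_names: list[str] | None = None

    for entry in index.entries:
        path = Path(paths[entry.file_id])
        if not path.exists():
            raise MissingFileError(str(path))
        values, names, _ = read_fcs(path)
        if reference_names is None:
            reference_names = names
        else:
            if set(names) != set(reference_names):
                raise DetectorMismatchError(
                    f"{entry.file_id}: detector set differs from {index.entries[0].file_id}"
                )
            if names != reference_names:
                order = [names.index(n) for n in reference_names]
                values = values[:, order]
        scatter = scatter_channels or _detect_scatter(reference_names)
        table = EventTable(values, tuple(reference_names), scatter)
        if entry.primary_detector != AUTO and entry.primary_detector not in reference_names:
            raise DetectorNotFoundError(
                f"{entry.file_id}: detector {entry.primary_detector!r} not in file"
            )
        if entry.is_unstained:
            unstained_table = table
        else:
            dyes.append(entry.dye_name)
            tables[entry.dye_name] = table
            primaries[entry.dye_name] = entry.primary_detector
    if reference_names is None:
        raise ValueError("control index is empty")
    return ControlSet(
        dyes=dyes,
        tables=tables,
        primaries=primaries,
        unstained=unstained_table,
        detectors=tuple(reference_names),
    )


def write_spillover_csv(matrix: SpilloverMatrix, path: str | Path) -> None:
    """Write a spillover (or spreading) matrix as CSV.

    Header row holds detector names, first column the dye names; values are
    written with full repr precision so a read-back is bit-exact as decimal
    text.
    """
    with open(path, "w") as fh:
        fh.write("dye," + ",".join(matrix.detectors) + "\n")
        for dye, row in zip(matrix.dyes, matrix.coef):
            fh.write(dye + "," + ",".join(repr(v) for v in row.tolist()) + "\n")


def read_spillover_csv(path: str | Path) -> SpilloverMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    coef = frame.to_numpy(dtype=np.float64)
    dyes = tuple(str(d) for d in frame.index)
    detectors = tuple(str(c) for c in frame.columns)
    primary = {}
    for i, dye in enumerate(dyes):
        ones = np.flatnonzero(coef[i] == 1.0)
        primary[dye] = int(ones[0]) if ones.size else int(np.argmax(coef[i]))
    return SpilloverMatrix(coef, dyes, detectors, primary)


def write_trace(trace: ConvergenceTrace, path: str | Path) -> None:
    """Write the convergence trace as TSV, one line per iteration."""
    trace.to_frame().to_csv(path, sep="\t", index=False)
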