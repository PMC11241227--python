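"""Core containers for mid-infrared milk spectra and coagulation reference data.

Spectra are stored as a plain absorbance matrix (``log(1/T)``) together with a
wavenumber axis in cm^-1 and unique sample identifiers.  Reference traits
(rennet coagulation time RCT, curd-firming time k20, curd firmness a30) and
gross composition travel in :class:`SampleRecord` rows; milk that fails to clot
within the 30-minute test window carries a ``coagulated=False`` flag and *no*
trait values, so censored observations can never leak into a regression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WAVENUMBER_MIN",
    "WAVENUMBER_MAX",
    "N_POINTS_DEFAULT",
    "DEFAULT_WATER_REGIONS",
    "WavenumberAxis",
    "Spectra",
    "SampleRecord",
    "default_axis",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
    "records_to_frame",
    "frame_to_records",
    "mask_regions",
    "filter_noncoagulating",
]

WAVENUMBER_MIN = 900.0
WAVENUMBER_MAX = 5000.0
N_POINTS_DEFAULT = 1060

#: Water absorption regions excluded before modelling, cm^-1 (closed intervals).
#: The third interval covers the broad O-H stretch band.
DEFAULT_WATER_REGIONS: tuple[tuple[float, float], ...] = (
    (1566.0, 1712.0),
    (1817.0, 2696.0),
    (2975.0, 3700.0),
)

TRAIT_COLUMNS = ("rct_min", "k20_min", "a30_mm")
COMPOSITION_COLUMNS = ("fat_pct", "protein_pct", "casein_pct", "lactose_pct", "scc_cells_ul")


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1.

    Stored ascending regardless of acquisition order; one canonical orientation
    keeps derivative operators unambiguous.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("wavenumber axis must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavenumber axis contains non-finite values")
        if values.size > 1:
            diffs = np.diff(values)
            if not np.all(diffs > 0):
                raise ValueError("wavenumber axis must be strictly increasing")
            step = float(np.median(diffs))
        else:
            step = 0.0
        if values[0] < WAVENUMBER_MIN - step or values[-1] > WAVENUMBER_MAX + step:
            raise ValueError(
                f"axis [{values[0]:.2f}, {values[-1]:.2f}] outside the instrument "
                f"range [{WAVENUMBER_MIN}, {WAVENUMBER_MAX}] cm^-1"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values)
        )


def default_axis(n_points: int = N_POINTS_DEFAULT) -> WavenumberAxis:
    """Uniform grid of ``n_points`` wavenumbers spanning 900-5000 cm^-1."""
    return WavenumberAxis(np.linspace(WAVENUMBER_MIN, WAVENUMBER_MAX, n_points))


@dataclass
class Spectra:
    """Absorbance matrix (n_samples x n_points) with axis and sample ids."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} spectral rows")
        if len(self.axis) != p:
            raise ValueError(f"axis length {len(self.axis)} != {p} spectral columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "Spectra":
        return Spectra(self.axis, self.absorbance.copy(), list(self.sample_ids))

    def select(self, sample_ids: Iterable[str]) -> "Spectra":
        """Row subset in the order of ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        wanted = [str(s) for s in sample_ids]
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in wanted]
        return Spectra(self.axis, self.absorbance[rows], wanted)

    def with_matrix(self, matrix: np.ndarray, axis: WavenumberAxis | None = None) -> "Spectra":
        return Spectra(axis if axis is not None else self.axis, matrix, list(self.sample_ids))


@dataclass
class SampleRecord:
    """Reference traits and gross composition for one bulk-milk sample.

    Trait values are ``None`` (never a sentinel 30.0) for samples that did not
    coagulate within the 30-minute Formagraph window.
    """

    sample_id: str
    rct: float | None = None          # rennet coagulation time, min
    k20: float | None = None          # curd-firming time, min
    a30: float | None = None          # curd firmness at 30 min, mm
    fat: float | None = None          # % w/w
    protein: float | None = None      # % w/w
    casein: float | None = None       # % w/w
    lactose: float | None = None      # % w/w
    scc: float | None = None          # somatic cells, cells/uL
    coagulated: bool = True
    farm_id: str | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id)
        if not self.coagulated:
            if self.rct is not None or self.k20 is not None or self.a30 is not None:
                raise ValueError(
                    f"sample {self.sample_id!r}: censored (noncoagulating) records "
                    "must not carry RCT/k20/a30 values"
                )
        if self.rct is not None and not self.rct > 0:
            raise ValueError(f"sample {self.sample_id!r}: RCT must be > 0")
        if self.a30 is not None and self.a30 < 0:
            raise ValueError(f"sample {self.sample_id!r}: a30 must be >= 0")
        for name in ("fat", "protein", "casein", "lactose", "scc"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"sample {self.sample_id!r}: {name} must be >= 0")


# ---------------------------------------------------------------------------
# spectral-table and trait-table I/O (delimited text)
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path, sep: str = ",") -> Spectra:
    """Read a delimited spectral table: ``sample_id`` column + wavenumber headers.

    Column headers other than ``sample_id`` must parse as wavenumbers (cm^-1).
    Columns are re-ordered so the stored axis is ascending.
    """
    frame = pd.read_csv(path, sep=sep, dtype={0: str})
    if frame.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {frame.columns[0]!r}")
    try:
        wavenumbers = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header ({exc})") from exc
    sample_ids = frame["sample_id"].tolist()
    dupes = frame["sample_id"][frame["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    matrix = frame.iloc[:, 1:].to_numpy()
    if matrix.dtype == object or not np.issubdtype(matrix.dtype, np.number):
        for j, col in enumerate(frame.columns[1:]):
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"{path}: non-numeric absorbance at row {row} "
                    f"(sample {sample_ids[row]!r}), column {col!r}"
                )
        raise ValueError(f"{path}: absorbance table is not numeric")
    matrix = matrix.astype(float)
    if np.isnan(matrix).any():
        i, j = map(int, np.argwhere(np.isnan(matrix))[0])
        raise ValueError(
            f"{path}: missing absorbance at row {i} (sample {sample_ids[i]!r}), "
            f"column {frame.columns[1 + j]!r}"
        )
    order = np.argsort(wavenumbers)
    return Spectra(WavenumberAxis(wavenumbers[order]), matrix[:, order], sample_ids)


def write_spectra(spectra: Spectra, path: str | Path, sep: str = ",") -> None:
    frame = pd.DataFrame(spectra.absorbance,
                         columns=[repr(float(w)) for w in spectra.axis.values])
    frame.insert(0, "sample_id", spectra.sample_ids)
    frame.to_csv(path, sep=sep, index=False)


_FIELD_TO_COLUMN = {
    "rct": "rct_min",
    "k20": "k20_min",
    "a30": "a30_mm",
    "fat": "fat_pct",
    "protein": "protein_pct",
    "casein": "casein_pct",
    "lactose": "lactose_pct",
    "scc": "scc_cells_ul",
}


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id}
        for fld, col in _FIELD_TO_COLUMN.items():
            value = getattr(r, fld)
            row[col] = np.nan if value is None else float(value)
        row["coagulated"] = int(r.coagulated)
        row["farm_id"] = r.farm_id if r.farm_id is not None else ""
        row["date"] = r.date if r.date is not None else ""
        rows.append(row)
    columns = ["sample_id", *_FIELD_TO_COLUMN.values(), "coagulated", "farm_id", "date"]
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for fld, col in _FIELD_TO_COLUMN.items():
            value = row.get(col, np.nan)
            kwargs[fld] = None if pd.isna(value) else float(value)
        farm = row.get("farm_id", "")
        date = row.get("date", "")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                coagulated=bool(int(row.get("coagulated", 1))),
                farm_id=None if (pd.isna(farm) or farm == "") else str(farm),
                date=None if (pd.isna(date) or date == "") else str(date),
                **kwargs,
            )
        )
    return records


def read_traits(path: str | Path, sep: str = ",") -> list[SampleRecord]:
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    dupes = frame["sample_id"][frame["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    return frame_to_records(frame)


def write_traits(records: Sequence[SampleRecord], path: str | Path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# masking and censoring filters
# ---------------------------------------------------------------------------

def _validate_regions(regions: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    cleaned = []
    for lo, hi in regions:
        lo, hi = float(lo), float(hi)
        if not lo < hi:
            raise ValueError(f"invalid region [{lo}, {hi}]: requires lo < hi")
        if lo < WAVENUMBER_MIN or hi > WAVENUMBER_MAX:
            raise ValueError(
                f"region [{lo}, {hi}] outside [{WAVENUMBER_MIN}, {WAVENUMBER_MAX}] cm^-1"
            )
        cleaned.append((lo, hi))
    return cleaned


def region_mask(axis: WavenumberAxis, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask of axis points *retained* after removing the closed intervals."""
    keep = np.ones(len(axis), dtype=bool)
    for lo, hi in _validate_regions(regions):
        keep &= ~((axis.values >= lo) & (axis.values <= hi))
    return keep


def mask_regions(spectra: Spectra, regions: Sequence[tuple[float, float]]) -> Spectra:
    """Drop all wavenumbers falling inside any of the closed intervals.

    Used to excise the water-absorption regions before modelling.
    """
    keep = region_mask(spectra.axis, regions)
    if not keep.any():
        raise ValueError("masking would remove every wavenumber")
    return Spectra(
        WavenumberAxis(spectra.axis.values[keep]),
        spectra.absorbance[:, keep],
        list(spectra.sample_ids),
    )


def filter_noncoagulating(
    records: Sequence[SampleRecord],
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition records into (coagulated, censored-at-30-min).

    Censored samples are discarded from all chemometric modelling; their trait
    values are unknown, not equal to the test limit.
    """
    retained = [r for r in records if r.coagulated]
    removed = [r for r in records if not r.coagulated]
    return retained, removed
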