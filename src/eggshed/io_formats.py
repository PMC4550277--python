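"""Readers, writers and in-memory domain types for the egg-survey pipeline.

All downstream modules operate on the dataclasses defined here:
barcode reference records, egg sequence reads, plankton-tow collection
events, gridded surface-current fields, and coastal exposure kernels.
File formats are deliberately plain: FASTA for sequences, delimited text
for tables, and a self-describing netCDF container (scipy backend) for
gridded fields and kernels.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from Bio import SeqIO

__all__ = [
    "Locus",
    "KernelMode",
    "ReferenceRecord",
    "EggRead",
    "CollectionEvent",
    "CurrentField",
    "ExposureKernel",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_reference_db",
    "write_reference_db",
    "read_collections",
    "write_collections",
    "read_temperature_series",
    "write_temperature_series",
    "read_current_field",
    "write_current_field",
    "read_kernel",
    "write_kernel",
]

# IUPAC nucleotide codes (upper case); '-' tolerated in alignments only.
IUPAC_NT = set("ACGTNRYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class Locus(str, enum.Enum):
    COI = "COI"
    S16 = "16S"


class KernelMode(str, enum.Enum):
    FIT = "FIT"
    BIT = "BIT"


def _check_sequence(seq: str, *, where: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"empty sequence in {where}")
    bad = set(seq) - IUPAC_NT
    if bad:
        raise FormatError(
            f"illegal nucleotide character(s) {sorted(bad)} in {where}"
        )
    return seq


@dataclass(frozen=True)
class ReferenceRecord:
    """One species' barcode sequence for one locus."""

    record_id: str
    species: str
    common_name: str
    locus: Locus
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, where=self.record_id)
        )
        object.__setattr__(self, "locus", Locus(self.locus))


@dataclass(frozen=True)
class EggRead:
    """A (possibly partial) amplicon sequence read from a single egg."""

    read_id: str
    collection_id: str
    locus: Locus
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, where=self.read_id)
        )
        object.__setattr__(self, "locus", Locus(self.locus))


@dataclass
class CollectionEvent:
    """One plankton-net tow: when, how much water, and what was counted."""

    collection_id: str
    datetime: pd.Timestamp
    pulls: int = 4
    net_diameter: float = 1.0  # meters
    depth: float = 5.0  # meters
    counts: dict[str, int] = field(default_factory=dict)
    temperature: float | None = None  # deg C; None when unavailable

    def __post_init__(self) -> None:
        self.datetime = pd.Timestamp(self.datetime)
        if self.pulls < 1:
            raise ValueError(f"{self.collection_id}: pulls must be >= 1")
        if self.net_diameter <= 0 or self.depth <= 0:
            raise ValueError(f"{self.collection_id}: net geometry must be positive")
        for sp, c in self.counts.items():
            if c < 0:
                raise ValueError(f"{self.collection_id}: negative count for {sp}")

    @property
    def total_eggs(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class CurrentField:
    """Hourly gridded surface currents on a regular local grid.

    Axes are cell-center coordinates in meters of a local equirectangular
    projection.  ``u``/``v`` are in cm/s with shape (time, y, x); the
    static ``valid_mask`` marks cells with data coverage.  The coastline
    is an ordered polyline with land to its left (walking along
    increasing vertex index), so the offshore normal is the rightward
    normal of the local tangent.
    """

    x: np.ndarray  # (nx,) meters
    y: np.ndarray  # (ny,) meters
    times: np.ndarray  # (nt,) datetime64, hourly
    u: np.ndarray  # (nt, ny, nx) cm/s
    v: np.ndarray  # (nt, ny, nx) cm/s
    valid_mask: np.ndarray  # (ny, nx) bool
    coastline: np.ndarray  # (k, 2) polyline vertices, meters
    nearshore_band_width: float = 1000.0  # meters

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.coastline = np.asarray(self.coastline, dtype=float)
        shape = (len(self.times), len(self.y), len(self.x))
        if self.u.shape != shape or self.v.shape != shape:
            raise FormatError(
                f"u/v shape {self.u.shape}/{self.v.shape} does not match "
                f"(time, y, x) = {shape}"
            )
        if self.valid_mask.shape != (len(self.y), len(self.x)):
            raise FormatError("valid_mask shape does not match the grid")
        if len(self.times) >= 2:
            steps = np.diff(self.times).astype("timedelta64[s]").astype(float)
            if not np.allclose(steps, steps[0]):
                raise FormatError("time axis is not evenly spaced")
            if steps[0] <= 0:
                raise FormatError("time axis is not strictly increasing")
        if not (
            np.isfinite(self.u[:, self.valid_mask]).all()
            and np.isfinite(self.v[:, self.valid_mask]).all()
        ):
            raise FormatError("non-finite velocities inside the valid mask")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else 1.0

    @property
    def dt_seconds(self) -> float:
        return float(
            np.diff(self.times[:2]).astype("timedelta64[s]").astype(float)[0]
        )

    def time_span(self) -> tuple[np.datetime64, np.datetime64]:
        return self.times[0], self.times[-1]


@dataclass
class ExposureKernel:
    """Per-cell tracer visit counts F and percent kernel P = 100 F / max F."""

    x: np.ndarray
    y: np.ndarray
    F: np.ndarray  # (ny, nx) non-negative integer counts
    P: np.ndarray  # (ny, nx) percent of the maximum count
    window: tuple[pd.Timestamp, pd.Timestamp]
    mode: KernelMode

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F)
        if (self.F < 0).any():
            raise ValueError("visit counts F must be non-negative")
        if not np.issubdtype(self.F.dtype, np.integer):
            if not np.allclose(self.F, np.round(self.F)):
                raise ValueError("visit counts F must be integers")
            self.F = self.F.astype(np.int64)
        self.mode = KernelMode(self.mode)
        self.window = (pd.Timestamp(self.window[0]), pd.Timestamp(self.window[1]))
        self.P = np.asarray(self.P, dtype=float)
        expected = percent_kernel(self.F)
        if not np.allclose(self.P, expected, atol=1e-9):
            raise ValueError("P is inconsistent with 100*F/max(F)")

    @property
    def no_visits(self) -> bool:
        return bool(self.F.max(initial=0) == 0)


def percent_kernel(F: np.ndarray) -> np.ndarray:
    """Normalize visit counts to percent of the busiest cell (0 when empty)."""
    F = np.asarray(F, dtype=float)
    m = F.max(initial=0.0)
    if m <= 0:
        return np.zeros_like(F)
    return 100.0 * F / m


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, uppercased sequence) pairs, in order.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or illegal sequence characters.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, ln in enumerate(text.splitlines()) if ln.strip()
        )
        raise FormatError(f"{path}:{first_bad}: expected FASTA header line")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            line = _line_of_header(text, rec.description)
            raise FormatError(f"{path}:{line}: malformed FASTA header")
        bad = set(seq) - IUPAC_NT
        if bad:
            line = _line_of_header(text, rec.description)
            raise FormatError(
                f"{path}: record '{rec.id}' (header line {line}) contains "
                f"illegal character(s) {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def _line_of_header(text: str, description: str) -> int:
    for i, ln in enumerate(text.splitlines(), start=1):
        if ln.startswith(">") and ln[1:].strip() == description.strip():
            return i
    return 0


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Reference database (FASTA + metadata table)
# ---------------------------------------------------------------------------

def read_reference_db(
    fasta_path: str | Path, metadata_table_path: str | Path, sep: str = "\t"
) -> list[ReferenceRecord]:
    """Join a barcode FASTA with its species metadata table.

    The metadata table must contain columns record_id, species,
    common_name, locus.  Every FASTA id must appear in the table, and a
    (species, locus) pair may appear at most once.
    """
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_table_path, sep=sep, dtype=str)
    required = {"record_id", "species", "common_name", "locus"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata table missing columns {sorted(missing_cols)}")
    meta = meta.set_index("record_id")
    missing = [rid for rid, _ in seqs if rid not in meta.index]
    if missing:
        raise FormatError(f"FASTA ids missing from metadata: {missing}")
    records = []
    for rid, seq in seqs:
        row = meta.loc[rid]
        try:
            locus = Locus(row["locus"])
        except ValueError:
            raise FormatError(f"unknown locus '{row['locus']}' for record {rid}")
        records.append(
            ReferenceRecord(
                record_id=rid,
                species=row["species"],
                common_name=row["common_name"],
                locus=locus,
                sequence=seq,
            )
        )
    pairs = pd.Series([(r.species, r.locus.value) for r in records])
    dups = pairs[pairs.duplicated()].unique().tolist()
    if dups:
        raise FormatError(f"duplicate (species, locus) pairs: {dups}")
    return records


def write_reference_db(
    records: Sequence[ReferenceRecord],
    fasta_path: str | Path,
    metadata_table_path: str | Path,
) -> None:
    write_fasta([(r.record_id, r.sequence) for r in records], fasta_path)
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "species": [r.species for r in records],
            "common_name": [r.common_name for r in records],
            "locus": [r.locus.value for r in records],
        }
    ).to_csv(metadata_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Collection log
# ---------------------------------------------------------------------------

_LONG_COLS = ["collection_id", "datetime", "species", "count"]


def read_collections(
    table_path: str | Path, sep: str = "\t", dialect: str = "long"
) -> list[CollectionEvent]:
    """Read a collection log into events keyed by collection_id.

    The canonical dialect is long format: one row per (collection,
    species) with columns collection_id, datetime, species, count and
    per-collection columns pulls, net_diameter, depth, temperature
    (temperature optional/blank).  ``dialect="wide"`` accepts one row
    per collection with one column per species.
    """
    df = pd.read_csv(table_path, sep=sep)
    if dialect == "wide":
        df = df.melt(
            id_vars=[
                c
                for c in df.columns
                if c
                in ("collection_id", "datetime", "pulls", "net_diameter", "depth", "temperature")
            ],
            var_name="species",
            value_name="count",
        )
    elif dialect != "long":
        raise ValueError(f"unknown collection-table dialect {dialect!r}")
    missing = set(_LONG_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"collection table missing columns {sorted(missing)}")
    if (pd.to_numeric(df["count"], errors="coerce") < 0).any():
        bad = df.loc[pd.to_numeric(df["count"]) < 0, "collection_id"].iloc[0]
        raise FormatError(f"negative count in collection {bad}")
    events = []
    for cid, grp in df.groupby("collection_id", sort=False):
        first = grp.iloc[0]
        temp = first.get("temperature", np.nan)
        temp = None if pd.isna(temp) else float(temp)
        counts = {
            str(r["species"]): int(r["count"])
            for _, r in grp.iterrows()
            if not pd.isna(r["count"])
        }
        events.append(
            CollectionEvent(
                collection_id=str(cid),
                datetime=pd.Timestamp(first["datetime"]),
                pulls=int(first.get("pulls", 4)),
                net_diameter=float(first.get("net_diameter", 1.0)),
                depth=float(first.get("depth", 5.0)),
                counts=counts,
                temperature=temp,
            )
        )
    return events


def write_collections(events: Sequence[CollectionEvent], table_path: str | Path) -> None:
    rows = []
    for ev in events:
        for sp, c in sorted(ev.counts.items()):
            rows.append(
                {
                    "collection_id": ev.collection_id,
                    "datetime": ev.datetime.isoformat(),
                    "species": sp,
                    "count": c,
                    "pulls": ev.pulls,
                    "net_diameter": ev.net_diameter,
                    "depth": ev.depth,
                    "temperature": "" if ev.temperature is None else ev.temperature,
                }
            )
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def read_temperature_series(path: str | Path, sep: str = "\t") -> pd.Series:
    """Read a (timestamp, temperature °C) table into a time-indexed Series."""
    df = pd.read_csv(path, sep=sep)
    if not {"datetime", "temperature"} <= set(df.columns):
        raise FormatError("temperature table needs columns datetime, temperature")
    s = pd.Series(
        df["temperature"].astype(float).values,
        index=pd.to_datetime(df["datetime"]),
        name="temperature",
    )
    return s.sort_index()


def write_temperature_series(temps: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"datetime": temps.index.map(lambda t: t.isoformat()), "temperature": temps.values}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gridded current fields and kernels (netCDF3 via the scipy backend)
# ---------------------------------------------------------------------------

def _field_to_dataset(fieldobj: CurrentField) -> xr.Dataset:
    return xr.Dataset(
        {
            "u": (("time", "y", "x"), fieldobj.u),
            "v": (("time", "y", "x"), fieldobj.v),
            "mask": (("y", "x"), fieldobj.valid_mask.astype(np.int8)),
            "coastline_x": (("vertex",), fieldobj.coastline[:, 0]),
            "coastline_y": (("vertex",), fieldobj.coastline[:, 1]),
        },
        coords={"time": fieldobj.times, "y": fieldobj.y, "x": fieldobj.x},
        attrs={
            "velocity_units": "cm s-1",
            "grid_spacing_m": fieldobj.dx,
            "origin": f"{fieldobj.x[0]},{fieldobj.y[0]}",
            "nearshore_band_width": fieldobj.nearshore_band_width,
        },
    )


def write_current_field(fieldobj: CurrentField, path: str | Path) -> None:
    _field_to_dataset(fieldobj).to_netcdf(path, engine="scipy")


def read_current_field(path: str | Path) -> CurrentField:
    """Load a gridded current field; verifies hourly spacing and units."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    units = ds.attrs.get("velocity_units", "cm s-1")
    scale = {"cm s-1": 1.0, "cm/s": 1.0, "m s-1": 100.0, "m/s": 100.0}.get(units)
    if scale is None:
        raise FormatError(f"unrecognized velocity units {units!r}")
    return CurrentField(
        x=ds["x"].values,
        y=ds["y"].values,
        times=ds["time"].values,
        u=ds["u"].values * scale,
        v=ds["v"].values * scale,
        valid_mask=ds["mask"].values.astype(bool),
        coastline=np.column_stack([ds["coastline_x"].values, ds["coastline_y"].values]),
        nearshore_band_width=float(ds.attrs.get("nearshore_band_width", 1000.0)),
    )


def write_kernel(kernel: ExposureKernel, path: str | Path) -> None:
    """Persist an exposure kernel (grid, F, P, window, mode) losslessly."""
    ds = xr.Dataset(
        {
            "F": (("y", "x"), kernel.F.astype(np.int32)),
            "P": (("y", "x"), kernel.P),
        },
        coords={"y": kernel.y, "x": kernel.x},
        attrs={
            # scipy's netCDF writer reserves the bare name "mode"
            "kernel_mode": kernel.mode.value,
            "window_start": kernel.window[0].isoformat(),
            "window_end": kernel.window[1].isoformat(),
            "no_visits": int(kernel.no_visits),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_kernel(path: str | Path) -> ExposureKernel:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return ExposureKernel(
        x=ds["x"].values,
        y=ds["y"].values,
        F=ds["F"].values,
        P=ds["P"].values,
        window=(
            pd.Timestamp(ds.attrs["window_start"]),
            pd.Timestamp(ds.attrs["window_end"]),
        ),
        mode=KernelMode(ds.attrs["kernel_mode"]),
    )
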