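"""Domain types and I/O for per-batch peak tables and fingerprint matrices.

A *fingerprint* is the vector of integrated areas of the peaks common to
every batch at one detection wavelength.  This module turns long-format
peak-table CSVs into aligned :class:`FingerprintMatrix` objects via
retention-time clustering, and builds the all-batch mean
:class:`ReferenceFingerprint` used as the comparison standard downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousPeakError,
    EmptyResultError,
    ParseError,
    SchemaError,
    ValidationError,
)

DEFAULT_RT_TOLERANCE = 0.2  # minutes

_STANDARD_COLUMNS = ("batch_id", "wavelength", "retention_time", "area")


@dataclass(frozen=True)
class Peak:
    """A single integrated chromatographic peak."""

    retention_time: float  # minutes
    area: float
    peak_id: str | None = None


@dataclass
class PeakTable:
    """All peaks of one batch at one detection wavelength, in RT order."""

    batch_id: str
    wavelength: int  # nanometres
    peaks: list[Peak]

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValidationError(f"wavelength must be positive, got {self.wavelength}")
        rts = [p.retention_time for p in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError(
                f"retention times must be strictly increasing in batch {self.batch_id!r}"
            )
        for i, p in enumerate(self.peaks):
            if p.area < 0:
                raise ValidationError(
                    f"negative area {p.area} at peak index {i} of batch {self.batch_id!r}"
                )

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([p.retention_time for p in self.peaks], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks], dtype=float)


@dataclass
class FingerprintMatrix:
    """Aligned common-peak areas: one row per batch, one column per peak."""

    wavelength: int
    batch_ids: list[str]
    peak_ids: list[str]
    areas: np.ndarray  # shape (B, n)
    retention_times: np.ndarray  # shape (n,), cluster reference RTs

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        B, n = self.areas.shape
        if B < 1 or n < 2:
            raise ValidationError(f"matrix needs B>=1 and n>=2, got {B}x{n}")
        if len(self.batch_ids) != B or len(self.peak_ids) != n:
            raise ValidationError("label lengths do not match area grid shape")
        if self.retention_times.shape != (n,):
            raise ValidationError("retention_times length must equal peak count")
        if np.any(self.areas < 0):
            raise ValidationError("areas must be non-negative")
        if np.any(~self.areas.any(axis=1)):
            raise ValidationError("a batch row is all-zero")

    @property
    def n_batches(self) -> int:
        return self.areas.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.areas.shape[1]

    def row(self, batch_id: str) -> np.ndarray:
        return self.areas[self.batch_ids.index(batch_id)]


@dataclass
class ReferenceFingerprint:
    """Per-wavelength mean fingerprint over all batches."""

    wavelength: int
    peak_ids: list[str]
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if len(self.peak_ids) != self.areas.shape[0]:
            raise ValidationError("peak_ids length must match areas")
        if not np.any(self.areas > 0):
            raise ValidationError("reference fingerprint needs a positive entry")


def read_peak_tables(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[PeakTable]:
    """Read a long-format peak CSV into one :class:`PeakTable` per (batch, wavelength).

    ``schema`` maps the standard column names (``batch_id``, ``wavelength``,
    ``retention_time``, ``area``, optionally ``peak_id``) to the names used
    in the file.  Rows are sorted by retention time within each table.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str)
    colmap = {std: schema.get(std, std) for std in _STANDARD_COLUMNS}
    for std, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"missing required column {actual!r} (for {std})")
    id_col = schema.get("peak_id", "peak_id")
    has_peak_id = id_col in df.columns

    def _num(col: str, kind: str) -> pd.Series:
        converted = pd.to_numeric(df[colmap[col]], errors="coerce")
        bad = converted.isna() & df[colmap[col]].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric {kind} {df[colmap[col]].iloc[row]!r} at row {row}")
        return converted

    rt = _num("retention_time", "retention time")
    area = _num("area", "area")
    neg = area < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"negative area {area.iloc[row]} at row {row}")

    work = pd.DataFrame(
        {
            "batch_id": df[colmap["batch_id"]],
            "wavelength": _num("wavelength", "wavelength").astype(int),
            "retention_time": rt,
            "area": area,
            "peak_id": df[id_col] if has_peak_id else None,
        }
    )
    tables = []
    for (batch, wl), grp in work.groupby(["batch_id", "wavelength"], sort=False):
        grp = grp.sort_values("retention_time")
        peaks = [
            Peak(float(r.retention_time), float(r.area),
                 None if r.peak_id is None or pd.isna(r.peak_id) else str(r.peak_id))
            for r in grp.itertuples()
        ]
        tables.append(PeakTable(str(batch), int(wl), peaks))
    return tables


def write_peak_tables(tables: Sequence[PeakTable], path: str | Path) -> None:
    """Write tables back to the long-format CSV read by :func:`read_peak_tables`."""
    rows = [
        {
            "batch_id": t.batch_id,
            "wavelength": t.wavelength,
            "retention_time": p.retention_time,
            "area": p.area,
            "peak_id": p.peak_id,
        }
        for t in tables
        for p in t.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def match_common_peaks(
    tables: Sequence[PeakTable], rt_tolerance: float = DEFAULT_RT_TOLERANCE
) -> FingerprintMatrix:
    """Cluster peaks across batches by retention time and keep common ones.

    Clustering is greedy in RT order: the earliest unassigned peak seeds a
    cluster whose reference RT is the running median of member RTs; peaks
    within ``rt_tolerance`` of the reference join it.  A cluster is *common*
    iff every batch contributed exactly one member; clusters missing any
    batch are dropped, and a duplicate batch inside a cluster is an error.
    """
    if rt_tolerance <= 0:
        raise ValidationError("rt_tolerance must be positive")
    if not tables:
        raise ValidationError("no peak tables given")
    wavelengths = {t.wavelength for t in tables}
    if len(wavelengths) != 1:
        raise ValidationError(f"tables span multiple wavelengths: {sorted(wavelengths)}")
    wavelength = tables[0].wavelength
    batch_ids = [t.batch_id for t in tables]
    if len(set(batch_ids)) != len(batch_ids):
        raise ValidationError("duplicate batch ids")

    pooled = sorted(
        (
            (p.retention_time, i, p)
            for i, t in enumerate(tables)
            for p in t.peaks
        ),
        key=lambda item: item[0],
    )
    clusters: list[list[tuple[float, int, Peak]]] = []
    current: list[tuple[float, int, Peak]] = []
    for item in pooled:
        if current:
            ref = float(np.median([m[0] for m in current]))
            if abs(item[0] - ref) <= rt_tolerance:
                current.append(item)
                continue
            clusters.append(current)
        current = [item]
    if current:
        clusters.append(current)

    kept: list[tuple[float, list[Peak], str]] = []
    for idx, members in enumerate(clusters):
        batches_in = [m[1] for m in members]
        if len(set(batches_in)) != len(batches_in):
            dup = next(b for b in batches_in if batches_in.count(b) > 1)
            rts = [m[0] for m in members if m[1] == dup]
            raise AmbiguousPeakError(
                f"batch {batch_ids[dup]!r} has {len(rts)} peaks in one cluster "
                f"(RTs {', '.join(f'{r:.3f}' for r in rts)})"
            )
        if set(batches_in) != set(range(len(tables))):
            continue
        ref_rt = float(np.median([m[0] for m in members]))
        by_batch = {m[1]: m[2] for m in members}
        ordered = [by_batch[i] for i in range(len(tables))]
        ids = {p.peak_id for p in ordered}
        name = ids.pop() if len(ids) == 1 and None not in ids else None
        kept.append((ref_rt, ordered, name))

    if not kept:
        raise EmptyResultError("no peaks common to all batches")
    kept.sort(key=lambda c: c[0])
    peak_ids = [
        name if name is not None else f"P{j + 1:02d}"
        for j, (_, _, name) in enumerate(kept)
    ]
    areas = np.array([[c[1][i].area for c in kept] for i in range(len(tables))])
    return FingerprintMatrix(
        wavelength=wavelength,
        batch_ids=batch_ids,
        peak_ids=peak_ids,
        areas=areas,
        retention_times=np.array([c[0] for c in kept]),
    )


def build_reference_fingerprint(matrix: FingerprintMatrix) -> ReferenceFingerprint:
    """Column-wise arithmetic mean over all batches (every batch included)."""
    return ReferenceFingerprint(
        wavelength=matrix.wavelength,
        peak_ids=list(matrix.peak_ids),
        areas=matrix.areas.mean(axis=0),
    )


def write_matrix(matrix: FingerprintMatrix, path: str | Path, **params) -> None:
    """Wide-format CSV (rows = batches) plus a JSON sidecar with reference RTs."""
    path = Path(path)
    pd.DataFrame(matrix.areas, index=pd.Index(matrix.batch_ids, name="batch_id"),
                 columns=matrix.peak_ids).to_csv(path)
    sidecar = {
        "wavelength": matrix.wavelength,
        "peak_ids": matrix.peak_ids,
        "retention_times": matrix.retention_times.tolist(),
        "params": params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path, wavelength: int | None = None) -> FingerprintMatrix:
    """Read a wide-format matrix CSV written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        wavelength = wavelength or int(sidecar["wavelength"])
        rts = np.asarray(sidecar["retention_times"], dtype=float)
    else:
        if wavelength is None:
            raise SchemaError(f"no JSON sidecar next to {path}; pass wavelength explicitly")
        rts = np.arange(df.shape[1], dtype=float)
    return FingerprintMatrix(
        wavelength=int(wavelength),
        batch_ids=[str(b) for b in df.index],
        peak_ids=[str(c) for c in df.columns],
        areas=df.to_numpy(dtype=float),
        retention_times=rts,
    )
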