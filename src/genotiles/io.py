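"""Readers for raw text inputs and the HDF5 pyramid container.

Raw inputs are plain text: contact lists (``chrom1 pos1 chrom2 pos2 [count]``),
bedGraph signal (4 columns), and BED-like annotations (3+ columns, label in
column 4, importance in column 5).  All readers validate against an
:class:`~genotiles.coords.Assembly` and fail with the offending line number;
none of them silently reorders or renames chromosomes.

The multi-resolution container is a single HDF5 file with one group per zoom
level plus the assembly and pyramid metadata, so a write/read round trip is
lossless for values, missing-value accounting, and chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Optional, Union

import h5py
import numpy as np
from scipy import sparse

from .coords import AbsInterval, Assembly, GenomePosition

__all__ = [
    "ContactRecord",
    "SignalRecord",
    "AnnotationRecord",
    "ParseError",
    "PyramidFormatError",
    "read_contacts",
    "read_bedgraph",
    "read_bed_annotations",
    "write_pyramid",
    "read_pyramid",
]

FORMAT_NAME = "genotiles-pyramid"
FORMAT_VERSION = 1

PathArg = Union[str, PathLike]


class ParseError(ValueError):
    """A malformed input line; the message names file and line number."""


class PyramidFormatError(ValueError):
    """The container is not a valid pyramid file of the supported version."""


@dataclass(frozen=True)
class ContactRecord:
    """One observed contact between two genomic positions."""

    pos1: GenomePosition
    pos2: GenomePosition
    count: float = 1.0


@dataclass(frozen=True)
class SignalRecord:
    """A constant-valued stretch of a quantitative 1D track."""

    interval: AbsInterval
    value: float


@dataclass(frozen=True)
class AnnotationRecord:
    """An interval (1D) or rectangle (2D) annotation with optional importance.

    2D records carry a second extent along the matrix's other axis; the
    importance value, once assigned, governs which records survive
    downsampling at coarse zoom levels.
    """

    extent: AbsInterval
    label: str
    importance: Optional[float] = None
    extent2: Optional[AbsInterval] = None

    @property
    def is_2d(self) -> bool:
        return self.extent2 is not None


def _lines(path: PathArg):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def _parse_error(path: PathArg, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


def read_contacts(path: PathArg, assembly: Assembly) -> list[ContactRecord]:
    """Read a raw contact list: ``chrom1 pos1 chrom2 pos2 [count]`` per line.

    A missing count column defaults to 1.  Symmetrization is a binning-time
    decision and is not applied here.
    """
    records: list[ContactRecord] = []
    for lineno, parts in _lines(path):
        if len(parts) not in (4, 5):
            raise _parse_error(path, lineno, f"expected 4 or 5 columns, got {len(parts)}")
        c1, p1, c2, p2 = parts[:4]
        try:
            pos1 = GenomePosition(c1, int(p1))
            pos2 = GenomePosition(c2, int(p2))
            count = float(parts[4]) if len(parts) == 5 else 1.0
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
        for pos in (pos1, pos2):
            if pos.chrom not in assembly:
                raise _parse_error(path, lineno, f"unknown chromosome {pos.chrom!r}")
            if pos.pos_bp >= assembly.chrom_length(pos.chrom):
                raise _parse_error(
                    path, lineno,
                    f"position {pos.pos_bp} outside {pos.chrom} "
                    f"(length {assembly.chrom_length(pos.chrom)})",
                )
        if count <= 0 or not np.isfinite(count):
            raise _parse_error(path, lineno, f"count must be a positive number, got {count}")
        records.append(ContactRecord(pos1, pos2, count))
    return records


def read_bedgraph(path: PathArg, assembly: Assembly) -> list[SignalRecord]:
    """Read 4-column bedGraph into absolute-coordinate signal records.

    Overlapping intervals are rejected: the value of the overlap would be
    ambiguous.  Uncovered regions become missing values at rasterization.
    """
    records: list[SignalRecord] = []
    for lineno, parts in _lines(path):
        if len(parts) != 4:
            raise _parse_error(path, lineno, f"expected 4 columns, got {len(parts)}")
        chrom, s, e, v = parts
        if chrom not in assembly:
            raise _parse_error(path, lineno, f"unknown chromosome {chrom!r}")
        try:
            interval = assembly.abs_interval(chrom, int(s), int(e))
            value = float(v)
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
        records.append(SignalRecord(interval, value))
    by_start = sorted(records, key=lambda r: r.interval.start)
    for a, b in zip(by_start, by_start[1:]):
        if b.interval.start < a.interval.end:
            raise ParseError(
                f"{path}: overlapping intervals "
                f"[{a.interval.start}, {a.interval.end}) and "
                f"[{b.interval.start}, {b.interval.end})"
            )
    return records


def read_bed_annotations(path: PathArg, assembly: Assembly) -> list[AnnotationRecord]:
    """Read BED-like annotations: chrom start end [label [importance]]."""
    records: list[AnnotationRecord] = []
    for lineno, parts in _lines(path):
        if len(parts) < 3:
            raise _parse_error(path, lineno, f"expected >=3 columns, got {len(parts)}")
        chrom, s, e = parts[:3]
        if chrom not in assembly:
            raise _parse_error(path, lineno, f"unknown chromosome {chrom!r}")
        try:
            extent = assembly.abs_interval(chrom, int(s), int(e))
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
        label = parts[3] if len(parts) >= 4 else f"record{len(records)}"
        importance: Optional[float] = None
        if len(parts) >= 5:
            try:
                importance = float(parts[4])
            except ValueError:
                raise _parse_error(path, lineno, f"importance {parts[4]!r} not a number") from None
            if not np.isfinite(importance):
                raise _parse_error(path, lineno, f"importance must be finite, got {importance}")
        records.append(AnnotationRecord(extent, label, importance))
    return records


# ---------------------------------------------------------------------------
# HDF5 pyramid container
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_assembly(grp: h5py.Group, assembly: Assembly) -> None:
    g = grp.create_group("assembly")
    g.create_dataset("names", data=np.array(assembly.names, dtype=_STR))
    g.create_dataset("lengths", data=np.asarray(assembly.lengths, dtype=np.int64))


def _read_assembly(grp: h5py.Group) -> Assembly:
    g = grp["assembly"]
    names = [n.decode("utf-8") if isinstance(n, bytes) else str(n) for n in g["names"][:]]
    lengths = [int(x) for x in g["lengths"][:]]
    return Assembly(zip(names, lengths))


def write_pyramid(pyramid, path: PathArg) -> None:
    """Persist a complete pyramid (all levels, metadata, missing masks)."""
    from .pyramid import AnnotationLevel, MatrixLevel, Pyramid, SignalLevel

    assert isinstance(pyramid, Pyramid)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_NAME
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["kind"] = pyramid.kind
        f.attrs["base_resolution_bp"] = pyramid.base_resolution_bp
        f.attrs["max_zoom"] = pyramid.max_zoom
        f.attrs["tile_bins"] = pyramid.tile_bins
        _write_assembly(f, pyramid.assembly)
        if pyramid.kind == "annotation":
            _write_annotation_records(f, pyramid.records)
        levels = f.create_group("levels")
        for zoom, level in sorted(pyramid.levels.items()):
            g = levels.create_group(str(zoom))
            if isinstance(level, SignalLevel):
                g.attrs["bin_size_bp"] = level.bin_size_bp
                g.attrs["values_per_bin"] = level.values_per_bin
                g.create_dataset("sums", data=level.sums)
                g.create_dataset("nan_counts", data=level.nan_counts)
            elif isinstance(level, MatrixLevel):
                coo = level.upper.tocoo()
                g.attrs["bin_size_bp"] = level.bin_size_bp
                g.attrs["n_bins"] = level.n_bins
                g.create_dataset("row", data=coo.row.astype(np.int64))
                g.create_dataset("col", data=coo.col.astype(np.int64))
                g.create_dataset("data", data=coo.data.astype(np.float64))
            elif isinstance(level, AnnotationLevel):
                g.attrs["capacity_per_tile"] = level.capacity_per_tile
                keys, idx = [], []
                def _key_order(kv):
                    k = kv[0]
                    return k if isinstance(k, tuple) else (k, -1)

                for key, rec_ids in sorted(level.retained.items(), key=_key_order):
                    for r in rec_ids:
                        keys.append(key if isinstance(key, tuple) else (key, -1))
                        idx.append(r)
                g.create_dataset(
                    "tile_keys", data=np.asarray(keys, dtype=np.int64).reshape(-1, 2)
                )
                g.create_dataset("record_index", data=np.asarray(idx, dtype=np.int64))
            else:  # pragma: no cover - guarded by Pyramid invariants
                raise TypeError(f"unknown level type {type(level)!r}")


def _write_annotation_records(f: h5py.File, records) -> None:
    g = f.create_group("annotation_records")
    g.create_dataset("start", data=np.array([r.extent.start for r in records], dtype=np.int64))
    g.create_dataset("end", data=np.array([r.extent.end for r in records], dtype=np.int64))
    g.create_dataset("label", data=np.array([r.label for r in records], dtype=_STR))
    g.create_dataset(
        "importance", data=np.array([r.importance for r in records], dtype=np.float64)
    )
    is_2d = np.array([r.is_2d for r in records], dtype=bool)
    g.create_dataset("is_2d", data=is_2d)
    g.create_dataset(
        "start2",
        data=np.array([r.extent2.start if r.is_2d else -1 for r in records], dtype=np.int64),
    )
    g.create_dataset(
        "end2",
        data=np.array([r.extent2.end if r.is_2d else -1 for r in records], dtype=np.int64),
    )


def _read_annotation_records(f: h5py.File) -> list[AnnotationRecord]:
    g = f["annotation_records"]
    out: list[AnnotationRecord] = []
    labels = g["label"][:]
    for i in range(len(labels)):
        label = labels[i].decode("utf-8") if isinstance(labels[i], bytes) else str(labels[i])
        extent2 = None
        if bool(g["is_2d"][i]):
            extent2 = AbsInterval(int(g["start2"][i]), int(g["end2"][i]))
        out.append(
            AnnotationRecord(
                AbsInterval(int(g["start"][i]), int(g["end"][i])),
                label,
                float(g["importance"][i]),
                extent2,
            )
        )
    return out


def read_pyramid(path: PathArg):
    """Load a pyramid container, verifying format, version, and completeness."""
    from .pyramid import AnnotationLevel, MatrixLevel, Pyramid, SignalLevel

    with h5py.File(path, "r") as f:
        fmt = f.attrs.get("format")
        if fmt != FORMAT_NAME:
            raise PyramidFormatError(f"{path}: not a {FORMAT_NAME} file (format={fmt!r})")
        version = int(f.attrs.get("version", -1))
        if version != FORMAT_VERSION:
            raise PyramidFormatError(
                f"{path}: unsupported container version {version} "
                f"(supported: {FORMAT_VERSION})"
            )
        kind = str(f.attrs["kind"])
        assembly = _read_assembly(f)
        base_resolution = int(f.attrs["base_resolution_bp"])
        max_zoom = int(f.attrs["max_zoom"])
        tile_bins = int(f.attrs["tile_bins"])
        expected = set(range(max_zoom + 1))
        present = {int(k) for k in f["levels"]}
        if present != expected:
            raise PyramidFormatError(
                f"{path}: incomplete pyramid; missing zoom levels "
                f"{sorted(expected - present)}"
            )
        levels = {}
        records = None
        if kind == "annotation":
            records = _read_annotation_records(f)
        for zoom in sorted(present):
            g = f["levels"][str(zoom)]
            if kind == "signal":
                levels[zoom] = SignalLevel(
                    bin_size_bp=int(g.attrs["bin_size_bp"]),
                    sums=g["sums"][:],
                    nan_counts=g["nan_counts"][:],
                    values_per_bin=int(g.attrs["values_per_bin"]),
                )
            elif kind == "matrix":
                n_bins = int(g.attrs["n_bins"])
                upper = sparse.coo_matrix(
                    (g["data"][:], (g["row"][:], g["col"][:])), shape=(n_bins, n_bins)
                ).tocsr()
                levels[zoom] = MatrixLevel(
                    bin_size_bp=int(g.attrs["bin_size_bp"]), upper=upper
                )
            elif kind == "annotation":
                keys = g["tile_keys"][:]
                idx = g["record_index"][:]
                retained: dict = {}
                for (kx, ky), r in zip(keys, idx):
                    key = int(kx) if ky == -1 else (int(kx), int(ky))
                    retained.setdefault(key, []).append(int(r))
                levels[zoom] = AnnotationLevel(
                    zoom=zoom,
                    capacity_per_tile=int(g.attrs["capacity_per_tile"]),
                    retained={k: tuple(v) for k, v in retained.items()},
                )
            else:
                raise PyramidFormatError(f"{path}: unknown pyramid kind {kind!r}")
        return Pyramid(
            assembly=assembly,
            kind=kind,
            base_resolution_bp=base_resolution,
            tile_bins=tile_bins,
            max_zoom=max_zoom,
            levels=levels,
            records=records,
        )
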