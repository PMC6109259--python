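"""Multi-resolution pyramids: recursive aggregation and importance downsampling.

A pyramid stores one dataset at every zoom level from 0 (coarsest: the whole
genome fits in a single tile) to ``max_zoom`` (finest: the base resolution
``r0``).  Each level halves the resolution of the level above it:

* 2D contact matrices — adjacent pairs of bins are merged by summing, i.e.
  each coarser entry is the sum of a 2x2 block of finer entries.  Total
  matrix mass is conserved at every level.
* 1D quantitative signal — adjacent bins are merged by summing values while a
  parallel array counts missing values per bin, so coarse levels can display
  correct averages over the non-missing data only.
* Annotations (qualitative data) — coarser levels cannot sum; instead each
  tile region keeps only its ``capacity_per_tile`` records of highest
  importance.  Records retained at a coarse zoom are automatically retained
  at every finer zoom wherever they intersect.

``max_zoom`` is the number of doublings needed before one tile
(``tile_bins`` bins wide) spans the genome: the smallest z with
``tile_bins * r0 * 2**z >= g``.  For a 3.1 Gb genome at 1 kb resolution with
256-bin tiles this gives 14 doublings and a coarsest bin size of 16.384 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import sparse

from .coords import Assembly
from .io import AnnotationRecord, ContactRecord, SignalRecord

__all__ = [
    "TILE_BINS_2D",
    "TILE_BINS_1D",
    "SignalLevel",
    "MatrixLevel",
    "AnnotationLevel",
    "Pyramid",
    "compute_max_zoom",
    "zoom_bin_size",
    "bin_contacts",
    "aggregate_matrix",
    "rasterize_signal",
    "aggregate_signal",
    "mean_values",
    "assign_importance",
    "downsample_annotations",
    "build_matrix_pyramid",
    "build_signal_pyramid",
    "build_annotation_pyramid",
]

#: Bins along one side of a 2D tile.
TILE_BINS_2D = 256
#: Values in a 1D tile.
TILE_BINS_1D = 1024

TileKey = Union[int, tuple[int, int]]


def compute_max_zoom(g: int, r0: int, tile_bins: int) -> int:
    """Number of resolution doublings between base resolution and zoom 0.

    Returns the smallest ``z`` such that a single tile of ``tile_bins`` bins
    at bin size ``r0 * 2**z`` covers the whole genome of size ``g``
    (``tile_bins * r0 * 2**z >= g``).  Zoom 0 is the coarsest level; the base
    resolution lives at zoom ``z``.  Degenerate tiny genomes return 0.
    """
    if g <= 0 or r0 <= 0 or tile_bins <= 0:
        raise ValueError("g, r0 and tile_bins must be positive")
    z = 0
    span = tile_bins * r0
    while span < g:
        span *= 2
        z += 1
    return z


def zoom_bin_size(base_resolution_bp: int, max_zoom: int, zoom: int) -> int:
    """Bin size at a zoom level: r0 at max_zoom, doubling per zoom-out step."""
    if not (0 <= zoom <= max_zoom):
        raise ValueError(f"zoom {zoom} outside [0, {max_zoom}]")
    return base_resolution_bp * 2 ** (max_zoom - zoom)


# ---------------------------------------------------------------------------
# 1D signal levels
# ---------------------------------------------------------------------------


@dataclass
class SignalLevel:
    """One resolution level of a quantitative 1D track.

    ``sums[i]`` is the sum of the non-missing base-resolution values that fell
    into bin *i*; ``nan_counts[i]`` is how many of the bin's
    ``values_per_bin`` base slots were missing.  Means are recovered as
    ``sums / (values_per_bin - nan_counts)``.
    """

    bin_size_bp: int
    sums: np.ndarray
    nan_counts: np.ndarray
    values_per_bin: int

    def __post_init__(self) -> None:
        self.sums = np.asarray(self.sums, dtype=np.float64)
        self.nan_counts = np.asarray(self.nan_counts, dtype=np.int64)
        if self.sums.shape != self.nan_counts.shape or self.sums.ndim != 1:
            raise ValueError("sums and nan_counts must be 1D arrays of equal length")
        if np.any(self.nan_counts < 0) or np.any(self.nan_counts > self.values_per_bin):
            raise ValueError("nan_counts must lie in [0, values_per_bin]")

    @property
    def n_bins(self) -> int:
        return len(self.sums)


def rasterize_signal(
    records: Sequence[SignalRecord], assembly: Assembly, base_resolution_bp: int
) -> SignalLevel:
    """Rasterize bedGraph-style records onto base-resolution bins.

    A bin's value is the coverage-weighted mean of the records overlapping
    it; bins with no coverage at all are missing.  Input order is irrelevant
    (records are disjoint by construction), so shuffled files rasterize
    identically.
    """
    g = assembly.total_length
    n = -(-g // base_resolution_bp)  # ceil
    wsum = np.zeros(n, dtype=np.float64)
    cov = np.zeros(n, dtype=np.float64)
    for rec in records:
        s, e = int(rec.interval.start), int(rec.interval.end)
        b0, b1 = s // base_resolution_bp, -(-e // base_resolution_bp)
        bins = np.arange(b0, b1)
        lo = np.maximum(s, bins * base_resolution_bp)
        hi = np.minimum(e, (bins + 1) * base_resolution_bp)
        overlap = (hi - lo).astype(np.float64)
        np.add.at(wsum, bins, overlap * rec.value)
        np.add.at(cov, bins, overlap)
    covered = cov > 0
    sums = np.zeros(n, dtype=np.float64)
    sums[covered] = wsum[covered] / cov[covered]
    nan_counts = (~covered).astype(np.int64)
    return SignalLevel(
        bin_size_bp=base_resolution_bp, sums=sums, nan_counts=nan_counts, values_per_bin=1
    )


def aggregate_signal(level: SignalLevel) -> SignalLevel:
    """Merge adjacent bin pairs by summing; missing counts add.

    An odd trailing bin is paired with an absent partner treated as
    all-missing, so the total count of non-missing base values is conserved.
    """
    n = level.n_bins
    m = -(-n // 2)
    sums = np.zeros(2 * m, dtype=np.float64)
    sums[:n] = level.sums
    nan_counts = np.full(2 * m, level.values_per_bin, dtype=np.int64)
    nan_counts[:n] = level.nan_counts
    return SignalLevel(
        bin_size_bp=level.bin_size_bp * 2,
        sums=sums.reshape(m, 2).sum(axis=1),
        nan_counts=nan_counts.reshape(m, 2).sum(axis=1),
        values_per_bin=level.values_per_bin * 2,
    )


def mean_values(level: SignalLevel) -> np.ndarray:
    """Per-bin averages over non-missing values; NaN where a bin is all-missing."""
    denom = level.values_per_bin - level.nan_counts
    out = np.full(level.n_bins, np.nan, dtype=np.float64)
    ok = denom > 0
    out[ok] = level.sums[ok] / denom[ok]
    return out


# ---------------------------------------------------------------------------
# 2D matrix levels
# ---------------------------------------------------------------------------


@dataclass
class MatrixLevel:
    """One resolution level of a symmetric contact matrix.

    Storage holds the upper triangle once (``upper[i, j]`` with ``i <= j``);
    the full symmetric matrix is mirrored on access.  Off-diagonal stored
    entries stand for both (i, j) and (j, i).
    """

    bin_size_bp: int
    upper: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.upper = sparse.csr_matrix(self.upper)
        r, c = self.upper.shape
        if r != c:
            raise ValueError(f"matrix level must be square, got {self.upper.shape}")
        coo = self.upper.tocoo()
        if np.any(coo.row > coo.col):
            raise ValueError("upper-triangle storage contains below-diagonal entries")

    @property
    def n_bins(self) -> int:
        return self.upper.shape[0]

    def symmetric(self) -> sparse.csr_matrix:
        """Full symmetric matrix (mirror of the stored upper triangle)."""
        d = sparse.diags(self.upper.diagonal())
        return (self.upper + self.upper.T - d).tocsr()

    def dense(self) -> np.ndarray:
        return self.symmetric().toarray()

    def total_mass(self) -> float:
        """Total contact count: sum of stored entries (each bin pair once)."""
        return float(self.upper.sum())

    @classmethod
    def from_dense(cls, arr: np.ndarray, bin_size_bp: int) -> "MatrixLevel":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("expected a square 2D array")
        if not np.array_equal(arr, arr.T):
            raise ValueError("contact matrices are symmetric; input is not")
        return cls(bin_size_bp=bin_size_bp, upper=sparse.csr_matrix(np.triu(arr)))


def bin_contacts(
    contacts: Sequence[ContactRecord], assembly: Assembly, bin_size_bp: int
) -> MatrixLevel:
    """Bin a contact list into a symmetric matrix at the given bin size.

    Each off-diagonal contact contributes its count to both (i, j) and
    (j, i); same-bin contacts land on the diagonal once.
    """
    if bin_size_bp <= 0 or int(bin_size_bp) != bin_size_bp:
        raise ValueError(f"bin size must be a positive integer, got {bin_size_bp}")
    bin_size_bp = int(bin_size_bp)
    n = -(-assembly.total_length // bin_size_bp)
    if contacts:
        a1 = np.array([assembly.to_absolute(c.pos1) for c in contacts]) // bin_size_bp
        a2 = np.array([assembly.to_absolute(c.pos2) for c in contacts]) // bin_size_bp
        counts = np.array([c.count for c in contacts], dtype=np.float64)
        row = np.minimum(a1, a2)
        col = np.maximum(a1, a2)
        upper = sparse.coo_matrix((counts, (row, col)), shape=(n, n)).tocsr()
    else:
        upper = sparse.csr_matrix((n, n), dtype=np.float64)
    return MatrixLevel(bin_size_bp=bin_size_bp, upper=upper)


def aggregate_matrix(level: MatrixLevel) -> MatrixLevel:
    """Halve the resolution by merging adjacent bin pairs on both axes.

    Each coarse stored entry is the sum of the stored (upper-triangle)
    entries of its 2x2 block, so every contact is counted exactly once:
    a coarse off-diagonal entry equals the full-matrix block sum, while a
    near-diagonal pair folding onto the coarse diagonal contributes its
    count once — identical to binning the original contact list at the
    doubled bin size.  Absent trailing bins act as zeros; total contact
    count is conserved.
    """
    n = level.n_bins
    m = -(-n // 2)
    coo = level.upper.tocoo()
    upper = sparse.coo_matrix((coo.data, (coo.row // 2, coo.col // 2)), shape=(m, m)).tocsr()
    upper.sum_duplicates()
    return MatrixLevel(bin_size_bp=level.bin_size_bp * 2, upper=upper)


# ---------------------------------------------------------------------------
# Annotation levels (importance-based downsampling)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationLevel:
    """Retained annotation records per tile region at one zoom level.

    ``retained`` maps a tile key (x index for 1D, (x, y) for 2D) to record
    indices, each list capacity-bounded and ordered by decreasing importance
    (ties broken by start coordinate, then label).
    """

    zoom: int
    capacity_per_tile: int
    retained: dict[TileKey, tuple[int, ...]] = field(default_factory=dict)


def assign_importance(
    records: Sequence[AnnotationRecord],
    strategy: Literal["column", "random", "area"],
    seed: Optional[int] = None,
) -> list[AnnotationRecord]:
    """Ensure every record carries a finite importance value.

    ``column`` uses the user-supplied value and errors where it is absent;
    ``random`` draws uniform values from an explicit seed; ``area`` uses the
    interval length (1D) or rectangle area (2D), so larger annotations stay
    visible when zoomed out.
    """
    if strategy == "column":
        for i, rec in enumerate(records):
            if rec.importance is None:
                raise ValueError(f"record {i} ({rec.label!r}) has no importance column")
        return list(records)
    if strategy == "random":
        if seed is None:
            raise ValueError("random importance requires an explicit seed")
        rng = np.random.default_rng(seed)
        values = rng.random(len(records))
        return [
            AnnotationRecord(r.extent, r.label, float(v), r.extent2)
            for r, v in zip(records, values)
        ]
    if strategy == "area":
        out = []
        for r in records:
            imp = float(r.extent.width)
            if r.is_2d:
                imp *= float(r.extent2.width)
            out.append(AnnotationRecord(r.extent, r.label, imp, r.extent2))
        return out
    raise ValueError(f"unknown importance strategy {strategy!r}")


def _tile_range(start: float, end: float, tile_width_bp: int) -> range:
    return range(int(start) // tile_width_bp, (int(end) - 1) // tile_width_bp + 1)


def downsample_annotations(
    records: Sequence[AnnotationRecord],
    zoom: int,
    capacity_per_tile: int,
    *,
    base_resolution_bp: int,
    max_zoom: int,
    tile_bins: int,
) -> AnnotationLevel:
    """Keep, per tile region at this zoom, the top records by importance.

    For each tile the ``capacity_per_tile`` records of highest importance
    among those intersecting the tile's extent are retained; ties break by
    (start, label).  Because a finer tile's candidate set is a subset of its
    parent's, a record retained at zoom z is retained at every zoom > z
    wherever it intersects.
    """
    if capacity_per_tile < 0:
        raise ValueError("capacity_per_tile must be >= 0")
    for i, rec in enumerate(records):
        if rec.importance is None:
            raise ValueError(f"record {i} ({rec.label!r}) has no importance; assign one first")
    t_w = tile_bins * zoom_bin_size(base_resolution_bp, max_zoom, zoom)
    candidates: dict[TileKey, list[int]] = {}
    for i, rec in enumerate(records):
        xs = _tile_range(rec.extent.start, rec.extent.end, t_w)
        if rec.is_2d:
            ys = _tile_range(rec.extent2.start, rec.extent2.end, t_w)
            for tx in xs:
                for ty in ys:
                    candidates.setdefault((tx, ty), []).append(i)
        else:
            for tx in xs:
                candidates.setdefault(tx, []).append(i)
    retained: dict[TileKey, tuple[int, ...]] = {}
    if capacity_per_tile > 0:
        for key, idxs in candidates.items():
            idxs.sort(key=lambda i: (-records[i].importance, records[i].extent.start, records[i].label))
            retained[key] = tuple(idxs[:capacity_per_tile])
    return AnnotationLevel(zoom=zoom, capacity_per_tile=capacity_per_tile, retained=retained)


# ---------------------------------------------------------------------------
# Pyramid container
# ---------------------------------------------------------------------------

Level = Union[SignalLevel, MatrixLevel, AnnotationLevel]


@dataclass
class Pyramid:
    """A complete stack of resolution levels for one dataset.

    ``levels[z]`` holds the data at bin size ``r0 * 2**(max_zoom - z)``;
    zoom 0 fits the whole genome into one tile of ``tile_bins`` bins.
    Annotation pyramids additionally carry the full record list that level
    indices refer to.
    """

    assembly: Assembly
    kind: Literal["signal", "matrix", "annotation"]
    base_resolution_bp: int
    tile_bins: int
    max_zoom: int
    levels: dict[int, Level]
    records: Optional[list[AnnotationRecord]] = None

    def __post_init__(self) -> None:
        expected = set(range(self.max_zoom + 1))
        if set(self.levels) != expected:
            raise ValueError(
                f"pyramid must have every zoom level 0..{self.max_zoom}; "
                f"got {sorted(self.levels)}"
            )
        for z, level in self.levels.items():
            if isinstance(level, (SignalLevel, MatrixLevel)):
                want = zoom_bin_size(self.base_resolution_bp, self.max_zoom, z)
                if level.bin_size_bp != want:
                    raise ValueError(
                        f"zoom {z} has bin size {level.bin_size_bp}, expected {want}"
                    )
        if self.kind == "annotation" and self.records is None:
            raise ValueError("annotation pyramid requires its record list")

    def level(self, zoom: int) -> Level:
        if zoom not in self.levels:
            raise KeyError(f"zoom {zoom} outside [0, {self.max_zoom}]")
        return self.levels[zoom]


def build_matrix_pyramid(
    contacts: Sequence[ContactRecord],
    assembly: Assembly,
    base_resolution_bp: int,
    tile_bins: int = TILE_BINS_2D,
) -> Pyramid:
    """Bin raw contacts at r0, then aggregate up to the single-tile level."""
    max_zoom = compute_max_zoom(assembly.total_length, base_resolution_bp, tile_bins)
    levels: dict[int, Level] = {max_zoom: bin_contacts(contacts, assembly, base_resolution_bp)}
    for z in range(max_zoom - 1, -1, -1):
        levels[z] = aggregate_matrix(levels[z + 1])
    return Pyramid(assembly, "matrix", base_resolution_bp, tile_bins, max_zoom, levels)


def build_signal_pyramid(
    records: Sequence[SignalRecord],
    assembly: Assembly,
    base_resolution_bp: int,
    tile_bins: int = TILE_BINS_1D,
) -> Pyramid:
    """Rasterize 1D signal at r0, then sum-aggregate with missing accounting."""
    max_zoom = compute_max_zoom(assembly.total_length, base_resolution_bp, tile_bins)
    levels: dict[int, Level] = {max_zoom: rasterize_signal(records, assembly, base_resolution_bp)}
    for z in range(max_zoom - 1, -1, -1):
        levels[z] = aggregate_signal(levels[z + 1])
    return Pyramid(assembly, "signal", base_resolution_bp, tile_bins, max_zoom, levels)


def build_annotation_pyramid(
    records: Sequence[AnnotationRecord],
    assembly: Assembly,
    base_resolution_bp: int,
    capacity_per_tile: int,
    tile_bins: int = TILE_BINS_1D,
) -> Pyramid:
    """Downsample annotations by importance independently at every zoom."""
    records = list(records)
    max_zoom = compute_max_zoom(assembly.total_length, base_resolution_bp, tile_bins)
    levels: dict[int, Level] = {
        z: downsample_annotations(
            records,
            z,
            capacity_per_tile,
            base_resolution_bp=base_resolution_bp,
            max_zoom=max_zoom,
            tile_bins=tile_bins,
        )
        for z in range(max_zoom + 1)
    }
    return Pyramid(
        assembly, "annotation", base_resolution_bp, tile_bins, max_zoom, levels, records
    )
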