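"""Tile addressing and extraction.

A tile is the data for one location at one zoom level, exactly as in slippy
web maps: 256x256 matrix bins in 2D, 1024 values in 1D.  Zoom 0 is the
coarsest level (one tile spans the genome) and ``max_zoom`` the finest, so a
tile at zoom z is ``tile_bins * r0 * 2**(max_zoom - z)`` base pairs wide and
the tile covering absolute position ``l_g`` has index ``l_g // t_w``.

Dense payloads always have the full fixed shape; cells past the genome end
are marked missing (NaN), never zero, so aggregated averages stay honest at
the edge.  Annotation tiles instead carry every retained record whose extent
intersects the tile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .coords import AbsInterval
from .io import AnnotationRecord
from .pyramid import (
    AnnotationLevel,
    MatrixLevel,
    Pyramid,
    SignalLevel,
    mean_values,
    zoom_bin_size,
)

__all__ = [
    "TileId",
    "TileData",
    "AnnotationTileData",
    "TilesetInfo",
    "TileAddressError",
    "tile_width",
    "tile_index",
    "extract_tile",
    "tiles_in_range",
    "tiles_in_range_2d",
    "tileset_info",
]


class TileAddressError(ValueError):
    """Zoom or tile index outside the pyramid's addressable range."""


@dataclass(frozen=True)
class TileId:
    """Address of one tile: zoom plus x (and y for 2D) tile indices."""

    tileset_uid: str
    zoom: int
    x: int
    y: Optional[int] = None

    def __str__(self) -> str:
        parts = [self.tileset_uid, self.zoom, self.x] + ([self.y] if self.y is not None else [])
        return ".".join(str(p) for p in parts)


@dataclass
class TileData:
    """Fixed-shape dense payload of one tile; NaN marks missing cells."""

    payload: np.ndarray
    bin_size_bp: int
    tile_extent: tuple[AbsInterval, ...]


@dataclass
class AnnotationTileData:
    """All retained records intersecting one tile's extent."""

    records: list[AnnotationRecord]
    tile_extent: tuple[AbsInterval, ...]


@dataclass
class TilesetInfo:
    """What a client needs to navigate a tileset."""

    min_pos: int
    max_pos: int
    max_zoom: int
    base_resolution_bp: int
    tile_bins: int
    kind: str


def tile_width(pyramid: Pyramid, zoom: int) -> int:
    """Tile extent in bp at a zoom level: tile_bins bins of that level's size.

    Doubles with every zoom-out step; at zoom 0 it covers the whole genome,
    at max_zoom it is ``tile_bins * r0``.
    """
    return pyramid.tile_bins * zoom_bin_size(pyramid.base_resolution_bp, pyramid.max_zoom, zoom)


def tile_index(l_g: int, t_w: int) -> int:
    """Index of the tile containing absolute position l_g: floor(l_g / t_w)."""
    if l_g < 0:
        raise ValueError(f"absolute position must be >= 0, got {l_g}")
    if t_w <= 0:
        raise ValueError(f"tile width must be positive, got {t_w}")
    return int(l_g) // int(t_w)


def _check_id(pyramid: Pyramid, tile_id: TileId) -> None:
    z = tile_id.zoom
    if not (0 <= z <= pyramid.max_zoom):
        raise TileAddressError(f"zoom {z} outside [0, {pyramid.max_zoom}]")
    limit = 2**z
    if not (0 <= tile_id.x < limit):
        raise TileAddressError(f"tile x={tile_id.x} outside [0, {limit}) at zoom {z}")
    if pyramid.kind == "matrix":
        if tile_id.y is None:
            raise TileAddressError("2D tileset requires a y tile index")
        if not (0 <= tile_id.y < limit):
            raise TileAddressError(f"tile y={tile_id.y} outside [0, {limit}) at zoom {z}")
    elif tile_id.y is not None:
        raise TileAddressError(f"{pyramid.kind} tileset takes no y index")


def _extent(pyramid: Pyramid, zoom: int, idx: int) -> AbsInterval:
    t_w = tile_width(pyramid, zoom)
    return AbsInterval(idx * t_w, (idx + 1) * t_w)


def extract_tile(
    pyramid: Pyramid, tile_id: TileId
) -> Union[TileData, AnnotationTileData]:
    """Cut one fixed-size tile out of the matching resolution level.

    2D tiles are the 256x256 block at bin offset ``(x*256, y*256)`` of the
    full symmetric matrix; 1D tiles the 1024 mean values at offset
    ``x*1024``.  Shortfall past the genome end is NaN-padded.  Annotation
    tiles return the retained records intersecting the tile extent.
    """
    _check_id(pyramid, tile_id)
    level = pyramid.level(tile_id.zoom)
    tb = pyramid.tile_bins
    if isinstance(level, MatrixLevel):
        n = level.n_bins
        r0, c0 = tile_id.x * tb, tile_id.y * tb
        payload = np.full((tb, tb), np.nan)
        h = max(0, min(n - r0, tb))
        w = max(0, min(n - c0, tb))
        if h > 0 and w > 0:
            payload[:h, :w] = level.symmetric()[r0 : r0 + h, c0 : c0 + w].toarray()
        return TileData(
            payload=payload,
            bin_size_bp=level.bin_size_bp,
            tile_extent=(
                _extent(pyramid, tile_id.zoom, tile_id.x),
                _extent(pyramid, tile_id.zoom, tile_id.y),
            ),
        )
    if isinstance(level, SignalLevel):
        means = mean_values(level)
        o = tile_id.x * tb
        payload = np.full(tb, np.nan)
        w = max(0, min(level.n_bins - o, tb))
        if w > 0:
            payload[:w] = means[o : o + w]
        return TileData(
            payload=payload,
            bin_size_bp=level.bin_size_bp,
            tile_extent=(_extent(pyramid, tile_id.zoom, tile_id.x),),
        )
    assert isinstance(level, AnnotationLevel)
    extent = _extent(pyramid, tile_id.zoom, tile_id.x)
    key = tile_id.x
    extents: tuple[AbsInterval, ...] = (extent,)
    if tile_id.y is not None:
        key = (tile_id.x, tile_id.y)
        extents = (extent, _extent(pyramid, tile_id.zoom, tile_id.y))
    idxs = level.retained.get(key, ())
    return AnnotationTileData(records=[pyramid.records[i] for i in idxs], tile_extent=extents)


def tiles_in_range(
    pyramid: Pyramid, interval: AbsInterval, zoom: int, tileset_uid: str = ""
) -> list[TileId]:
    """Minimal ordered set of 1D tile ids covering an absolute interval."""
    t_w = tile_width(pyramid, zoom)
    limit = 2**zoom
    first = max(0, tile_index(int(interval.start), t_w))
    last = min(limit - 1, tile_index(int(np.ceil(interval.end)) - 1, t_w))
    return [TileId(tileset_uid, zoom, x) for x in range(first, last + 1)]


def tiles_in_range_2d(
    pyramid: Pyramid,
    x_interval: AbsInterval,
    y_interval: AbsInterval,
    zoom: int,
    tileset_uid: str = "",
) -> list[TileId]:
    """Minimal set of 2D tile ids covering a viewport rectangle, row-major."""
    xs = tiles_in_range(pyramid, x_interval, zoom, tileset_uid)
    ys = tiles_in_range(pyramid, y_interval, zoom, tileset_uid)
    return [TileId(tileset_uid, zoom, tx.x, ty.x) for tx in xs for ty in ys]


def tileset_info(pyramid: Pyramid) -> TilesetInfo:
    return TilesetInfo(
        min_pos=0,
        max_pos=pyramid.assembly.total_length,
        max_zoom=pyramid.max_zoom,
        base_resolution_bp=pyramid.base_resolution_bp,
        tile_bins=pyramid.tile_bins,
        kind=pyramid.kind,
    )
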