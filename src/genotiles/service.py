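"""Tile service: a registry of ingested pyramids and a small request protocol.

The server's job is deliberately narrow: it keeps a registry of available
multi-resolution files, and on request opens one and returns only the tiles
asked for.  Responses are pure functions of (registry contents, request), so
repeated requests are byte-identical and a restart from the on-disk index is
indistinguishable from the original process.

Wire encoding: dense payloads travel as base64 of little-endian float32
inside a JSON body, with missing values encoded as NaN; annotation tiles as
plain JSON records.  The HTTP layer is a dependency-free WSGI application
(servable with ``wsgiref``); every protocol operation is equally usable as a
direct Python call.
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Optional, Union
from urllib.parse import parse_qs

import numpy as np

from . import io as io_formats
from .coords import Assembly
from .pyramid import (
    TILE_BINS_1D,
    TILE_BINS_2D,
    Pyramid,
    assign_importance,
    build_annotation_pyramid,
    build_matrix_pyramid,
    build_signal_pyramid,
)
from .tiling import (
    AnnotationTileData,
    TileAddressError,
    TileData,
    TileId,
    extract_tile,
    tileset_info,
)

__all__ = [
    "TilesetRegistry",
    "RegistryError",
    "encode_tile",
    "decode_dense",
    "create_app",
    "serve",
]

log = logging.getLogger("genotiles.service")

PathArg = Union[str, PathLike]


class RegistryError(ValueError):
    """Duplicate uid, unknown uid, or unreadable tileset."""


@dataclass
class _Entry:
    uid: str
    path: str
    kind: str
    name: str


class TilesetRegistry:
    """Registry of available pyramid files, persisted as a JSON index.

    The index lives at ``<data_dir>/registry.json`` so a restarted service
    sees exactly the tilesets the previous one did.
    """

    def __init__(self, data_dir: PathArg):
        self.data_dir = Path(data_dir)
        self.data_dir.mkdir(parents=True, exist_ok=True)
        self._index_path = self.data_dir / "registry.json"
        self._entries: dict[str, _Entry] = {}
        self._cache: dict[str, Pyramid] = {}
        if self._index_path.exists():
            raw = json.loads(self._index_path.read_text())
            for uid, e in raw.items():
                self._entries[uid] = _Entry(uid=uid, **e)

    def _save(self) -> None:
        payload = {
            uid: {"path": e.path, "kind": e.kind, "name": e.name}
            for uid, e in sorted(self._entries.items())
        }
        self._index_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    # -- ingestion ---------------------------------------------------------

    def ingest(
        self,
        path: PathArg,
        kind: str,
        assembly: Optional[Assembly] = None,
        uid: Optional[str] = None,
        name: Optional[str] = None,
        base_resolution_bp: int = 1000,
        capacity_per_tile: int = 20,
        importance_strategy: str = "column",
    ) -> str:
        """Build (if raw) and register a pyramid; returns its uid.

        ``kind`` is one of ``contacts``, ``bedgraph``, ``bed`` (raw text
        inputs, which require an assembly and are converted to a pyramid at
        ``base_resolution_bp``) or ``pyramid`` (a pre-built container,
        registered as-is).  Uids default to a content hash so re-ingesting
        identical data is idempotent to detect.
        """
        src = Path(path)
        if not src.exists():
            raise RegistryError(f"unreadable input: {src}")
        if uid is None:
            h = hashlib.sha256()
            h.update(kind.encode())
            h.update(src.read_bytes())
            uid = h.hexdigest()[:12]
        if uid in self._entries:
            raise RegistryError(f"uid {uid!r} already registered")

        if kind == "pyramid":
            pyramid = io_formats.read_pyramid(src)
        else:
            if assembly is None:
                raise RegistryError(f"ingesting raw {kind!r} input requires an assembly")
            if kind == "contacts":
                contacts = io_formats.read_contacts(src, assembly)
                pyramid = build_matrix_pyramid(
                    contacts, assembly, base_resolution_bp, TILE_BINS_2D
                )
            elif kind == "bedgraph":
                signal = io_formats.read_bedgraph(src, assembly)
                pyramid = build_signal_pyramid(
                    signal, assembly, base_resolution_bp, TILE_BINS_1D
                )
            elif kind == "bed":
                records = io_formats.read_bed_annotations(src, assembly)
                records = assign_importance(records, importance_strategy)
                pyramid = build_annotation_pyramid(
                    records, assembly, base_resolution_bp, capacity_per_tile, TILE_BINS_1D
                )
            else:
                raise RegistryError(f"unknown input kind {kind!r}")
        stored = self.data_dir / f"{uid}.pyramid.h5"
        io_formats.write_pyramid(pyramid, stored)
        self._entries[uid] = _Entry(
            uid=uid, path=str(stored), kind=pyramid.kind, name=name or src.name
        )
        self._cache[uid] = pyramid
        self._save()
        return uid

    # -- queries -----------------------------------------------------------

    def pyramid(self, uid: str) -> Pyramid:
        if uid not in self._entries:
            raise RegistryError(f"unknown tileset uid {uid!r}")
        if uid not in self._cache:
            self._cache[uid] = io_formats.read_pyramid(self._entries[uid].path)
        return self._cache[uid]

    def list_tilesets(self) -> list[dict]:
        """One metadata entry per registered tileset."""
        out = []
        for uid, e in sorted(self._entries.items()):
            p = self.pyramid(uid)
            out.append(
                {
                    "uid": uid,
                    "name": e.name,
                    "kind": p.kind,
                    "assembly": [[n, l] for n, l in p.assembly.entries],
                    "min_pos": 0,
                    "max_pos": p.assembly.total_length,
                    "max_zoom": p.max_zoom,
                }
            )
        return out

    def get_tileset_info(self, uid: str) -> dict:
        info = tileset_info(self.pyramid(uid))
        return {
            "min_pos": info.min_pos,
            "max_pos": info.max_pos,
            "max_zoom": info.max_zoom,
            "base_resolution_bp": info.base_resolution_bp,
            "tile_bins": info.tile_bins,
            "kind": info.kind,
        }

    def get_tiles(self, requests: Iterable[TileId]) -> dict[str, dict]:
        """Batch tile fetch; unknown/invalid ids get per-item error entries."""
        out: dict[str, dict] = {}
        for tid in requests:
            key = str(tid)
            t0 = time.perf_counter()
            try:
                pyramid = self.pyramid(tid.tileset_uid)
                out[key] = encode_tile(extract_tile(pyramid, tid))
            except (RegistryError, TileAddressError) as exc:
                out[key] = {"error": str(exc)}
            log.info(
                "tile uid=%s z=%s x=%s y=%s latency_ms=%.2f",
                tid.tileset_uid, tid.zoom, tid.x, tid.y,
                1e3 * (time.perf_counter() - t0),
            )
        return out


# ---------------------------------------------------------------------------
# Wire encoding
# ---------------------------------------------------------------------------


def encode_tile(tile: Union[TileData, AnnotationTileData]) -> dict:
    """JSON-safe tile body; dense data as base64 little-endian float32."""
    extent = [[float(iv.start), float(iv.end)] for iv in tile.tile_extent]
    if isinstance(tile, AnnotationTileData):
        return {
            "records": [
                {
                    "start": float(r.extent.start),
                    "end": float(r.extent.end),
                    "start2": float(r.extent2.start) if r.is_2d else None,
                    "end2": float(r.extent2.end) if r.is_2d else None,
                    "label": r.label,
                    "importance": r.importance,
                }
                for r in tile.records
            ],
            "tile_extent": extent,
        }
    dense = np.ascontiguousarray(tile.payload, dtype="<f4")
    return {
        "dense": base64.b64encode(dense.tobytes()).decode("ascii"),
        "shape": list(tile.payload.shape),
        "dtype": "<f4",
        "bin_size_bp": tile.bin_size_bp,
        "tile_extent": extent,
    }


def decode_dense(body: dict) -> np.ndarray:
    """Inverse of the dense part of :func:`encode_tile`."""
    raw = base64.b64decode(body["dense"])
    return np.frombuffer(raw, dtype=body["dtype"]).reshape(body["shape"]).astype(np.float64)


def parse_tile_spec(spec: str) -> TileId:
    """Parse ``uid.z.x[.y]`` into a TileId."""
    parts = spec.split(".")
    if len(parts) not in (3, 4):
        raise TileAddressError(f"malformed tile spec {spec!r} (want uid.z.x[.y])")
    try:
        nums = [int(p) for p in parts[1:]]
    except ValueError:
        raise TileAddressError(f"malformed tile spec {spec!r}: non-integer index") from None
    return TileId(parts[0], *nums)


# ---------------------------------------------------------------------------
# WSGI application
# ---------------------------------------------------------------------------


def create_app(registry: TilesetRegistry):
    """A minimal WSGI app exposing the tile protocol.

    Routes: ``GET /api/v1/tilesets``, ``GET /api/v1/tileset_info?d=<uid>``,
    ``GET /api/v1/tiles?d=<uid>.<z>.<x>[.<y>]`` (``d`` repeatable for
    batching).
    """

    def respond(start_response, status: str, body: dict | list):
        data = json.dumps(body, sort_keys=True).encode("utf-8")
        start_response(
            status,
            [("Content-Type", "application/json"), ("Content-Length", str(len(data)))],
        )
        return [data]

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "").rstrip("/")
        query = parse_qs(environ.get("QUERY_STRING", ""))
        if environ.get("REQUEST_METHOD") != "GET":
            return respond(start_response, "405 Method Not Allowed", {"error": "GET only"})
        if path == "/api/v1/tilesets":
            return respond(start_response, "200 OK", registry.list_tilesets())
        if path == "/api/v1/tileset_info":
            out = {}
            for uid in query.get("d", []):
                try:
                    out[uid] = registry.get_tileset_info(uid)
                except RegistryError as exc:
                    out[uid] = {"error": str(exc)}
            return respond(start_response, "200 OK", out)
        if path == "/api/v1/tiles":
            out = {}
            ids = []
            for spec in query.get("d", []):
                try:
                    ids.append(parse_tile_spec(spec))
                except TileAddressError as exc:
                    out[spec] = {"error": str(exc)}
            out.update(registry.get_tiles(ids))
            return respond(start_response, "200 OK", out)
        return respond(start_response, "404 Not Found", {"error": f"no route {path!r}"})

    return app


def serve(registry: TilesetRegistry, host: str = "127.0.0.1", port: int = 8989):
    """Run the WSGI app in the stdlib reference server (blocking)."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_app(registry)) as httpd:
        log.info("serving on http://%s:%d (data dir %s)", host, port, registry.data_dir)
        httpd.serve_forever()
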