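"""Composable linked views: views, tracks, locks, and viewport projections.

A view is a collection of 1D and 2D tracks sharing genomic axes; a
composition arranges several views on a grid and declares how they are
synchronized.  Two views can be locked by *location* (equal centers,
independent widths — the overview/detail pattern), by *zoom* (equal widths,
independent centers), or by *both* (identical domains).  Navigating any
member of a lock propagates to the other members in a single step; disjoint
locks never cascade.

The whole composition serializes to a canonical JSON document (sorted keys,
fixed separators, explicit schema version), so structurally equal
compositions produce identical text and a serialized state can be stored and
shared as an interactive snapshot.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "Domain",
    "Track",
    "View",
    "Lock",
    "ValueScaleLock",
    "ViewComposition",
    "ViewConfigError",
    "SCHEMA_VERSION",
    "serialize",
    "deserialize",
    "link_views",
    "apply_navigation",
    "project_viewport",
]

SCHEMA_VERSION = 1

TRACK_TYPES = frozenset(
    {
        "heatmap",
        "horizontal-heatmap",
        "signal",
        "annotation-1d",
        "annotation-2d",
        "gene",
        "viewport-projection",
    }
)
TRACK_POSITIONS = frozenset({"top", "bottom", "left", "right", "center"})
LOCK_KINDS = frozenset({"location", "zoom", "both"})


class ViewConfigError(ValueError):
    """Schema violation; ``paths`` lists the offending document locations."""

    def __init__(self, paths: list[str]):
        self.paths = paths
        super().__init__("invalid view composition: " + "; ".join(paths))


@dataclass(frozen=True)
class Domain:
    """A view's visible extent on the absolute genome axis.

    Real-valued and deliberately unclamped: continuous panning and
    center-preserving zooming may carry a viewport past the assembly edge,
    which renders as blank space rather than being an error.
    """

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"domain start {self.start} must be < end {self.end}")

    @property
    def width(self) -> float:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @classmethod
    def from_center_width(cls, center: float, width: float) -> "Domain":
        return cls(center - width / 2, center + width / 2)


@dataclass
class Track:
    """One data layer in a view.

    Data tracks reference a tileset by uid; viewport-projection tracks
    instead reference the *view* whose extent they display.
    """

    uid: str
    type: str
    tileset_uid: Optional[str] = None
    source_view_uid: Optional[str] = None
    options: dict = field(default_factory=dict)


@dataclass
class View:
    """Tracks sharing common genomic axes, plus the visible domains."""

    uid: str
    x_domain: Domain
    y_domain: Optional[Domain] = None
    tracks: dict[str, list[Track]] = field(default_factory=dict)


@dataclass
class Lock:
    """Axis synchronization between >=2 views, by location, zoom, or both."""

    kind: str
    members: tuple[str, ...]


@dataclass
class ValueScaleLock:
    """Shared value range between tracks; min/max propagate, nothing renders."""

    members: tuple[str, ...]
    value_range: tuple[float, float]


@dataclass
class ViewComposition:
    """Views, their grid layout, and the locks tying them together."""

    views: list[View] = field(default_factory=list)
    locks: list[Lock] = field(default_factory=list)
    value_scale_locks: list[ValueScaleLock] = field(default_factory=list)
    layout: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def view(self, uid: str) -> View:
        for v in self.views:
            if v.uid == uid:
                return v
        raise KeyError(f"no view with uid {uid!r}")

    def validate(self) -> None:
        errors = _validate(self)
        if errors:
            raise ViewConfigError(errors)


def _validate(comp: ViewComposition) -> list[str]:
    errors: list[str] = []
    uids = [v.uid for v in comp.views]
    if len(set(uids)) != len(uids):
        errors.append("views: duplicate view uids")
    known = set(uids)
    for i, v in enumerate(comp.views):
        where = f"views[{i}]"
        for pos, tracks in v.tracks.items():
            if pos not in TRACK_POSITIONS:
                errors.append(f"{where}.tracks: unknown position {pos!r}")
                continue
            for j, t in enumerate(tracks):
                twhere = f"{where}.tracks.{pos}[{j}]"
                if t.type not in TRACK_TYPES:
                    errors.append(f"{twhere}.type: unknown type {t.type!r}")
                if t.type == "viewport-projection":
                    if t.source_view_uid is None or t.source_view_uid not in known:
                        errors.append(
                            f"{twhere}.source_view_uid: must reference an existing view"
                        )
                elif t.tileset_uid is None:
                    errors.append(f"{twhere}.tileset_uid: data track needs a tileset")
                if pos == "center" and v.y_domain is None:
                    errors.append(f"{where}.y_domain: center tracks require both domains")
    seen_kinds: dict[tuple[str, str], int] = {}
    for i, lock in enumerate(comp.locks):
        where = f"locks[{i}]"
        if lock.kind not in LOCK_KINDS:
            errors.append(f"{where}.kind: unknown kind {lock.kind!r}")
            continue
        if len(set(lock.members)) < 2:
            errors.append(f"{where}.members: a lock needs >=2 distinct views")
        for m in lock.members:
            if m not in known:
                errors.append(f"{where}.members: unknown view {m!r}")
            for k in _occupied_kinds(lock.kind):
                if (m, k) in seen_kinds:
                    errors.append(
                        f"{where}.members: view {m!r} already in a {k} lock "
                        f"(locks[{seen_kinds[(m, k)]}])"
                    )
                else:
                    seen_kinds[(m, k)] = i
    for uid in comp.layout:
        if uid not in known:
            errors.append(f"layout: unknown view {uid!r}")
    return errors


def _occupied_kinds(kind: str) -> tuple[str, ...]:
    # a "both" lock occupies the location and zoom slots of its members
    return ("location", "zoom") if kind == "both" else (kind,)


# ---------------------------------------------------------------------------
# Canonical serialization
# ---------------------------------------------------------------------------


def _domain_to_json(d: Optional[Domain]):
    return None if d is None else [d.start, d.end]


def _domain_from_json(raw) -> Optional[Domain]:
    return None if raw is None else Domain(float(raw[0]), float(raw[1]))


def serialize(comp: ViewComposition) -> str:
    """Canonical JSON text: sorted keys, compact separators, versioned."""
    comp.validate()
    doc = {
        "version": SCHEMA_VERSION,
        "views": [
            {
                "uid": v.uid,
                "xDomain": _domain_to_json(v.x_domain),
                "yDomain": _domain_to_json(v.y_domain),
                "tracks": {
                    pos: [
                        {
                            "uid": t.uid,
                            "type": t.type,
                            "tilesetUid": t.tileset_uid,
                            "sourceViewUid": t.source_view_uid,
                            "options": t.options,
                        }
                        for t in tracks
                    ]
                    for pos, tracks in sorted(v.tracks.items())
                },
            }
            for v in comp.views
        ],
        "locks": [
            {"kind": lk.kind, "members": sorted(lk.members)} for lk in comp.locks
        ],
        "valueScaleLocks": [
            {"members": sorted(l.members), "range": list(l.value_range)}
            for l in comp.value_scale_locks
        ],
        "layout": {uid: list(rect) for uid, rect in sorted(comp.layout.items())},
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def deserialize(text: str) -> ViewComposition:
    """Inverse of :func:`serialize`; schema violations list document paths."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ViewConfigError([f"$: not valid JSON ({exc})"]) from None
    if not isinstance(doc, dict):
        raise ViewConfigError(["$: document must be an object"])
    if doc.get("version") != SCHEMA_VERSION:
        raise ViewConfigError(
            [f"version: expected {SCHEMA_VERSION}, got {doc.get('version')!r}"]
        )
    errors: list[str] = []
    views: list[View] = []
    for i, raw in enumerate(doc.get("views", [])):
        try:
            views.append(
                View(
                    uid=str(raw["uid"]),
                    x_domain=_domain_from_json(raw["xDomain"]),
                    y_domain=_domain_from_json(raw.get("yDomain")),
                    tracks={
                        pos: [
                            Track(
                                uid=str(t["uid"]),
                                type=str(t["type"]),
                                tileset_uid=t.get("tilesetUid"),
                                source_view_uid=t.get("sourceViewUid"),
                                options=t.get("options", {}),
                            )
                            for t in tracks
                        ]
                        for pos, tracks in raw.get("tracks", {}).items()
                    },
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"views[{i}]: {exc}")
    locks = [
        Lock(kind=str(raw["kind"]), members=tuple(raw["members"]))
        for raw in doc.get("locks", [])
    ]
    vlocks = [
        ValueScaleLock(
            members=tuple(raw["members"]),
            value_range=(float(raw["range"][0]), float(raw["range"][1])),
        )
        for raw in doc.get("valueScaleLocks", [])
    ]
    layout = {uid: tuple(rect) for uid, rect in doc.get("layout", {}).items()}
    if errors:
        raise ViewConfigError(errors)
    comp = ViewComposition(views=views, locks=locks, value_scale_locks=vlocks, layout=layout)
    comp.validate()
    return comp


# ---------------------------------------------------------------------------
# Linking and navigation
# ---------------------------------------------------------------------------


def _reconcile(target: View, source: View, kind: str) -> None:
    """Adjust *target*'s domains to *source*'s, per lock kind."""
    if kind == "both":
        target.x_domain = source.x_domain
        if source.y_domain is not None and target.y_domain is not None:
            target.y_domain = source.y_domain
        return
    if kind == "zoom":
        target.x_domain = Domain.from_center_width(
            target.x_domain.center, source.x_domain.width
        )
        if source.y_domain is not None and target.y_domain is not None:
            target.y_domain = Domain.from_center_width(
                target.y_domain.center, source.y_domain.width
            )
        return
    # location: move the center, keep the width
    target.x_domain = Domain.from_center_width(
        source.x_domain.center, target.x_domain.width
    )
    if source.y_domain is not None and target.y_domain is not None:
        target.y_domain = Domain.from_center_width(
            source.y_domain.center, target.y_domain.width
        )


def link_views(
    comp: ViewComposition, uids: Sequence[str], kind: str
) -> ViewComposition:
    """Add a lock between views; synchronization starts from the first uid.

    On creation the remaining members' domains are immediately reconciled to
    the initiating view, so the lock invariant holds from the moment the
    link exists.  A view already holding a lock of the same kind (or of a
    kind subsumed by ``both``) is a conflict.
    """
    if kind not in LOCK_KINDS:
        raise ValueError(f"unknown lock kind {kind!r}")
    if len(set(uids)) < 2:
        raise ValueError("a lock needs at least two distinct views")
    out = copy.deepcopy(comp)
    for uid in uids:
        out.view(uid)  # existence check
    occupied = {
        (m, k)
        for lock in out.locks
        for m in lock.members
        for k in _occupied_kinds(lock.kind)
    }
    for uid in uids:
        for k in _occupied_kinds(kind):
            if (uid, k) in occupied:
                raise ViewConfigError([f"locks: view {uid!r} already in a {k} lock"])
    initiator = out.view(uids[0])
    for uid in uids[1:]:
        _reconcile(out.view(uid), initiator, kind)
    out.locks.append(Lock(kind=kind, members=tuple(uids)))
    return out


def apply_navigation(
    comp: ViewComposition,
    view_uid: str,
    new_x_domain: Domain,
    new_y_domain: Optional[Domain] = None,
) -> ViewComposition:
    """Navigate one view and propagate through its locks (single step).

    Both-locked members receive identical domains; zoom-locked members are
    rescaled about their own centers; location-locked members are translated
    keeping their own widths.  Members of disjoint locks are untouched.
    """
    out = copy.deepcopy(comp)
    target = out.view(view_uid)
    target.x_domain = new_x_domain
    if new_y_domain is not None:
        target.y_domain = new_y_domain
    for lock in out.locks:
        if view_uid not in lock.members:
            continue
        for member in lock.members:
            if member != view_uid:
                _reconcile(out.view(member), target, lock.kind)
    return out


# ---------------------------------------------------------------------------
# Viewport projection
# ---------------------------------------------------------------------------


def project_viewport(
    source_view: View,
    target_view: View,
    target_pixel_box: tuple[float, float, float, float],
) -> tuple[float, float, float, float]:
    """Pixel rectangle marking *source*'s extent inside *target*'s viewport.

    The source domains are mapped linearly through the target domains into
    ``target_pixel_box = (x, y, width, height)`` and clipped to the box;
    disjoint domains give a zero-area rectangle at the nearest box edge.
    """
    bx, by, bw, bh = target_pixel_box

    def axis(src: Domain, tgt: Domain, off: float, size: float):
        f0 = (src.start - tgt.start) / tgt.width
        f1 = (src.end - tgt.start) / tgt.width
        f0c = min(1.0, max(0.0, f0))
        f1c = min(1.0, max(0.0, f1))
        return off + f0c * size, max(0.0, (f1c - f0c) * size)

    px, pw = axis(source_view.x_domain, target_view.x_domain, bx, bw)
    if source_view.y_domain is not None and target_view.y_domain is not None:
        py, ph = axis(source_view.y_domain, target_view.y_domain, by, bh)
    else:
        py, ph = by, bh
    return (px, py, pw, ph)
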