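"""Chromosome ordering and absolute genome coordinates.

Genomes are composed of chromosomes and have no intrinsic linear position, so
every dataset carries an explicit, ordered chromosome list (an
:class:`Assembly`).  Concatenating the chromosomes in that order yields a
single absolute axis on which binning, tiling, and viewport arithmetic
operate.  All coordinates are 0-based and half-open (BED convention); an
absolute position sitting exactly on a chromosome boundary belongs to the
*following* chromosome.

The order is fixed at construction, persisted with every pyramid, and never
inferred or natural-sorted behind the caller's back.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from os import PathLike
from typing import Iterable, Union

import numpy as np

Number = Union[int, float]

__all__ = [
    "Assembly",
    "GenomePosition",
    "AbsInterval",
    "UnknownChromosomeError",
    "CoordinateBoundsError",
    "total_length",
    "to_absolute",
    "from_absolute",
]


class UnknownChromosomeError(KeyError):
    """A chromosome name is not part of the assembly."""


class CoordinateBoundsError(ValueError):
    """A position or interval falls outside its chromosome or assembly."""


@dataclass(frozen=True)
class GenomePosition:
    """A 0-based position on a named chromosome."""

    chrom: str
    pos_bp: int

    def __post_init__(self) -> None:
        if self.pos_bp < 0:
            raise CoordinateBoundsError(f"negative position {self.pos_bp}")


@dataclass(frozen=True)
class AbsInterval:
    """Half-open interval [start, end) on the absolute genome axis.

    Ends may be fractional: view domains produced by continuous zooming are
    real-valued, while tile and bin extents are integral.
    """

    start: Number
    end: Number

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise CoordinateBoundsError(
                f"interval start {self.start} must be < end {self.end}"
            )
        if self.start < 0:
            raise CoordinateBoundsError(f"interval start {self.start} < 0")

    @property
    def width(self) -> Number:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def intersects(self, other: "AbsInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True, eq=False)
class Assembly:
    """An ordered chromosome list defining the absolute coordinate system.

    Parameters
    ----------
    entries
        Ordered ``(name, length_bp)`` pairs.  Names must be unique and
        lengths strictly positive.  The order given here *is* the coordinate
        system: changing it changes every absolute coordinate.
    """

    entries: tuple[tuple[str, int], ...]

    def __init__(self, entries: Iterable[tuple[str, int]]) -> None:
        entries = tuple((str(n), int(l)) for n, l in entries)
        if not entries:
            raise ValueError("assembly needs at least one chromosome")
        names = [n for n, _ in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in entries:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "entries", entries)

    # -- derived, cached ---------------------------------------------------

    @cached_property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @cached_property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l for _, l in self.entries)

    @cached_property
    def _offsets(self) -> np.ndarray:
        # cumulative start offset of each chromosome, plus the total at the end
        return np.concatenate([[0], np.cumsum(self.lengths)])

    @cached_property
    def _index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    @property
    def total_length(self) -> int:
        return int(self._offsets[-1])

    # -- queries -----------------------------------------------------------

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Assembly) and self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.entries)

    def chrom_length(self, chrom: str) -> int:
        return self.lengths[self._chrom_index(chrom)]

    def chrom_offset(self, chrom: str) -> int:
        """Absolute coordinate of the first base of *chrom*."""
        return int(self._offsets[self._chrom_index(chrom)])

    def _chrom_index(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise UnknownChromosomeError(
                f"chromosome {chrom!r} not in assembly {self.names}"
            ) from None

    def to_absolute(self, p: GenomePosition) -> int:
        """Map a (chromosome, position) pair to the absolute axis."""
        i = self._chrom_index(p.chrom)
        if not (0 <= p.pos_bp < self.lengths[i]):
            raise CoordinateBoundsError(
                f"position {p.pos_bp} outside {p.chrom} (length {self.lengths[i]})"
            )
        return int(self._offsets[i]) + p.pos_bp

    def from_absolute(self, abs_pos: int) -> GenomePosition:
        """Inverse of :meth:`to_absolute`; boundary positions belong to the
        following chromosome (half-open convention)."""
        if not (0 <= abs_pos < self.total_length):
            raise CoordinateBoundsError(
                f"absolute position {abs_pos} outside [0, {self.total_length})"
            )
        i = int(np.searchsorted(self._offsets, abs_pos, side="right")) - 1
        return GenomePosition(self.names[i], int(abs_pos - self._offsets[i]))

    def abs_interval(self, chrom: str, start: int, end: int) -> AbsInterval:
        """Absolute interval for a chromosome-relative half-open range."""
        i = self._chrom_index(chrom)
        if not (0 <= start < end <= self.lengths[i]):
            raise CoordinateBoundsError(
                f"[{start}, {end}) outside {chrom} (length {self.lengths[i]})"
            )
        off = int(self._offsets[i])
        return AbsInterval(off + start, off + end)

    # -- serialization helpers --------------------------------------------

    @classmethod
    def from_chromsizes(cls, path: Union[str, PathLike]) -> "Assembly":
        """Read a two-column chrom.sizes TSV (name, length; no header).

        The order of appearance in the file is the imposed chromosome order.
        """
        entries: list[tuple[str, int]] = []
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                name, raw_len = parts
                try:
                    length = int(raw_len)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: length {raw_len!r} is not an integer"
                    ) from None
                entries.append((name, length))
        return cls(entries)

    def to_chromsizes(self, path: Union[str, PathLike]) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")


# -- module-level functional surface ---------------------------------------


def total_length(assembly: Assembly) -> int:
    """Total genome size g: the sum of chromosome lengths."""
    return assembly.total_length


def to_absolute(assembly: Assembly, p: GenomePosition) -> int:
    return assembly.to_absolute(p)


def from_absolute(assembly: Assembly, abs_pos: int) -> GenomePosition:
    return assembly.from_absolute(abs_pos)
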