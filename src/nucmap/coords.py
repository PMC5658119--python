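"""Coordinate arithmetic for circular minichromosome maps.

A :class:`CircularSequenceMap` fixes the frame of reference that every other
module uses: a named sequence of ``length`` bases, numbered 1-based and
inclusive, optionally anchored to a chromosomal source locus through a fixed
offset (the minichromosome is colinear with its genomic source, so no
alignment-aware liftover is needed).  On circular maps position ``length + 1``
is the same base as position 1, and all distances, spans and midpoints wrap
accordingly.

Three span conventions coexist because footprinting practice uses them
interchangeably: the number of bases *strictly between* two nuclease cut
sites (the protected length), the plain coordinate *difference* (the width of
a signal region), and the *inclusive* count of a region's bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class SpanConvention(str, Enum):
    INCLUSIVE = "inclusive"
    STRICT_BETWEEN = "strict_between"
    DIFFERENCE = "difference"


class CoordinateError(ValueError):
    """A position falls outside the valid range of a map."""


@dataclass(frozen=True)
class CircularSequenceMap:
    """Reference frame for a (usually circular) minichromosome.

    Parameters
    ----------
    name : str
        Reference name used in read records and track output.
    length : int
        Number of bases; canonical positions are ``1..length``.
    topology : Topology or str
        ``circular`` (default) or ``linear``.
    genomic_offset : int, optional
        1-based chromosomal coordinate that maps to local position 1.
    genomic_ref : str, optional
        Name of the source chromosome.
    """

    name: str
    length: int
    topology: Topology = Topology.CIRCULAR
    genomic_offset: int | None = None
    genomic_ref: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"map length must be >= 1, got {self.length}")
        object.__setattr__(self, "topology", Topology(self.topology))

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR

    def check(self, p: int) -> int:
        """Validate that ``p`` is a canonical position; return it."""
        if not 1 <= p <= self.length:
            raise CoordinateError(
                f"position {p} outside canonical range [1, {self.length}] of {self.name}"
            )
        return p

    def wrap(self, p: int) -> int:
        """Canonicalize an arbitrary integer position into ``[1, length]``.

        Linear maps accept only in-range positions and raise
        :class:`CoordinateError` otherwise.
        """
        if self.is_circular:
            return (p - 1) % self.length + 1
        return self.check(p)

    # -- genome <-> local conversion -------------------------------------

    def to_local(self, chrom_coord: int) -> int:
        """Convert a chromosomal coordinate to a local 1-based position."""
        if self.genomic_offset is None:
            raise ValueError(f"map {self.name} has no genomic_offset")
        lo = self.genomic_offset
        hi = lo + self.length - 1
        if not lo <= chrom_coord <= hi:
            raise CoordinateError(
                f"chromosomal coordinate {chrom_coord} outside the locus "
                f"interval [{lo}, {hi}]"
            )
        return chrom_coord - lo + 1

    def to_genomic(self, local: int) -> int:
        """Inverse of :meth:`to_local`."""
        if self.genomic_offset is None:
            raise ValueError(f"map {self.name} has no genomic_offset")
        self.check(local)
        return local + self.genomic_offset - 1

    # -- distances, spans, midpoints -------------------------------------

    def clockwise_distance(self, a: int, b: int) -> int:
        """Single-base steps from ``a`` to ``b`` in increasing-coordinate
        direction, wrapping on circular maps.  ``clockwise_distance(a, a) == 0``.
        """
        self.check(a)
        self.check(b)
        if self.is_circular:
            return (b - a) % self.length
        if b < a:
            raise CoordinateError(
                f"on a linear map the clockwise distance requires a <= b; got {a} > {b}"
            )
        return b - a

    def circular_distance(self, a: int, b: int, direction: str = "clockwise") -> int:
        if direction == "clockwise":
            return self.clockwise_distance(a, b)
        if direction == "shortest":
            self.check(a)
            self.check(b)
            if self.is_circular:
                d = (b - a) % self.length
                return min(d, self.length - d)
            return abs(b - a)
        raise ValueError(f"unknown direction {direction!r}")

    def span_length(
        self, start: int, end: int, convention: SpanConvention | str
    ) -> int:
        """Length of the clockwise span ``start -> end`` under a convention.

        ``inclusive`` counts both endpoints, ``strict_between`` counts only
        interior bases (0 for adjacent or identical endpoints), ``difference``
        is the raw clockwise distance.
        """
        convention = SpanConvention(convention)
        d = self.clockwise_distance(start, end)
        if convention is SpanConvention.INCLUSIVE:
            return d + 1
        if convention is SpanConvention.STRICT_BETWEEN:
            return d - 1 if d > 1 else 0
        return d

    def midpoint(self, a: int, b: int) -> int:
        """Midpoint of the clockwise arc ``a -> b``.

        Half-integer centers round toward ``a`` (the lower/first coordinate of
        the arc), so even-distance spans get a deterministic integer center.
        """
        d = self.clockwise_distance(a, b)
        return self.wrap(a + d // 2)

    def positions_clockwise(self, a: int, b: int) -> list[int]:
        """Canonical positions along the clockwise arc from ``a`` to ``b``,
        inclusive of both endpoints."""
        d = self.clockwise_distance(a, b)
        return [self.wrap(a + k) for k in range(d + 1)]
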