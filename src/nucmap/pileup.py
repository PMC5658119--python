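"""Strand-resolved cleavage-site and occupancy tracks from aligned reads.

A hydroxyl-radical or MNase strand break is read out by sequencing the
resulting fragment, so the break position is inferred from the 5' end of each
aligned read.  The pipeline is: pile up 5' ends per strand
(:func:`five_prime_track`), shift them 1 bp upstream — relative to the read's
own 5'->3' orientation — to the actual broken bond
(:func:`to_cleavage_sites`), sum replicates (:func:`combine`), optionally
combine strands and smooth with a centred moving average (default 7 bp,
wrapping on circular maps), or extend reads to a fixed length for
nucleosome-occupancy views (:func:`occupancy_track`).

For a minus-strand read "1 bp upstream" means +1 in reference coordinates:
upstream is defined along the fragment's own orientation, matching the
chemistry in which each strand's new 5' end sits one base 3' (in reference
coordinates) of the broken bond.  The convention is isolated in
:func:`to_cleavage_sites` so it can be flipped if needed.

Counts are stored as non-negative floats so smoothed tracks reuse the type.
Track output/input is plain-text wiggle (variableStep, span=1) and bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .coords import CircularSequenceMap


class Strand(str, Enum):
    PLUS = "plus"
    MINUS = "minus"


class TrackKind(str, Enum):
    FIVE_PRIME = "five_prime"
    CLEAVAGE = "cleavage"
    OCCUPANCY = "occupancy"
    SMOOTHED = "smoothed"


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read: reference name, 1-based leftmost position, aligned
    length and strand.  On circular maps ``start + read_length - 1`` may run
    past the end (it wraps)."""

    ref: str
    start: int
    read_length: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")
        object.__setattr__(self, "strand", Strand(self.strand))


@dataclass
class StrandedTrack:
    """Per-base, per-strand numeric signal spanning an entire map."""

    map: CircularSequenceMap
    plus: np.ndarray
    minus: np.ndarray
    kind: TrackKind

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        self.kind = TrackKind(self.kind)
        for arr in (self.plus, self.minus):
            if arr.shape != (self.map.length,):
                raise ValueError(
                    f"strand arrays must have length {self.map.length}, got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError("track values must be non-negative")

    def total_mass(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def combined(self) -> np.ndarray:
        return self.plus + self.minus


def _five_prime_position(smap: CircularSequenceMap, rec: AlignedReadRecord) -> int:
    if rec.strand is Strand.PLUS:
        return smap.wrap(rec.start)
    return smap.wrap(rec.start + rec.read_length - 1)


def five_prime_track(
    records: Iterable[AlignedReadRecord], smap: CircularSequenceMap
) -> StrandedTrack:
    """Pile up read 5' ends: a plus read counts at its leftmost position, a
    minus read at its rightmost (its 5' end)."""
    plus = np.zeros(smap.length)
    minus = np.zeros(smap.length)
    for rec in records:
        if rec.ref != smap.name:
            raise ValueError(f"record on unknown map {rec.ref!r} (expected {smap.name!r})")
        p = _five_prime_position(smap, rec)
        if rec.strand is Strand.PLUS:
            plus[p - 1] += 1.0
        else:
            minus[p - 1] += 1.0
    return StrandedTrack(smap, plus, minus, TrackKind.FIVE_PRIME)


def to_cleavage_sites(track: StrandedTrack) -> StrandedTrack:
    """Shift 5'-end counts 1 bp upstream (read orientation) to the broken
    bond: plus-strand mass moves -1, minus-strand mass +1 in reference
    coordinates.  Wraps on circular maps; on linear maps mass shifted off the
    end is dropped."""
    if track.kind is not TrackKind.FIVE_PRIME:
        raise ValueError(f"expected a five_prime track, got {track.kind.value}")
    if track.map.is_circular:
        plus = np.roll(track.plus, -1)
        minus = np.roll(track.minus, 1)
    else:
        plus = np.zeros_like(track.plus)
        plus[:-1] = track.plus[1:]
        minus = np.zeros_like(track.minus)
        minus[1:] = track.minus[:-1]
    return StrandedTrack(track.map, plus, minus, TrackKind.CLEAVAGE)


def combine(tracks: Sequence[StrandedTrack]) -> StrandedTrack:
    """Element-wise sum of replicate tracks (same map and kind)."""
    if not tracks:
        raise ValueError("no tracks to combine")
    first = tracks[0]
    for t in tracks[1:]:
        if t.map != first.map or t.kind != first.kind:
            raise ValueError("tracks must share map and kind to be combined")
    plus = np.sum([t.plus for t in tracks], axis=0)
    minus = np.sum([t.minus for t in tracks], axis=0)
    return StrandedTrack(first.map, plus, minus, first.kind)


def _moving_average_1d(values: np.ndarray, window: int, circular: bool) -> np.ndarray:
    half = window // 2
    if circular:
        out = np.zeros_like(values)
        for k in range(-half, half + 1):
            out += np.roll(values, -k)
        return out / window
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def moving_average(track: StrandedTrack, window: int = 7) -> StrandedTrack:
    """Centred moving average per strand; wraps on circular maps, shrinks the
    window at the edges of linear maps."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    circ = track.map.is_circular
    return StrandedTrack(
        track.map,
        _moving_average_1d(track.plus, window, circ),
        _moving_average_1d(track.minus, window, circ),
        TrackKind.SMOOTHED,
    )


def combine_strands(track: StrandedTrack) -> np.ndarray:
    """Element-wise plus + minus signal."""
    return track.combined()


def occupancy_track(
    records: Iterable[AlignedReadRecord],
    smap: CircularSequenceMap,
    extsize: int,
) -> StrandedTrack:
    """Extend each read to ``extsize`` bases from its 5' end in its own 3'
    direction and pile up coverage (the MACS-pileup style occupancy view).
    Wraps on circular maps; truncates at the ends of linear maps."""
    if extsize < 1:
        raise ValueError(f"extsize must be >= 1, got {extsize}")
    L = smap.length
    plus = np.zeros(L)
    minus = np.zeros(L)
    for rec in records:
        if rec.ref != smap.name:
            raise ValueError(f"record on unknown map {rec.ref!r} (expected {smap.name!r})")
        e5 = _five_prime_position(smap, rec)
        if rec.strand is Strand.PLUS:
            idx = np.arange(e5 - 1, e5 - 1 + extsize)
            target = plus
        else:
            idx = np.arange(e5 - extsize, e5)
            target = minus
        if smap.is_circular:
            np.add.at(target, idx % L, 1.0)
        else:
            idx = idx[(idx >= 0) & (idx < L)]
            np.add.at(target, idx, 1.0)
    return StrandedTrack(smap, plus, minus, TrackKind.OCCUPANCY)


# ---------------------------------------------------------------------------
# read-record input
# ---------------------------------------------------------------------------

def read_table_records(path: str | Path) -> list[AlignedReadRecord]:
    """Read the minimal tab-delimited record table: columns
    ``ref  start  length  strand`` with a header line."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"ref", "start", "length", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"record table must have columns {sorted(required)}")
    return [
        AlignedReadRecord(str(r.ref), int(r.start), int(r.length), Strand(r.strand))
        for r in df.itertuples(index=False)
    ]


def read_sam_records(path: str | Path) -> list[AlignedReadRecord]:
    """Read a SAM-subset file via pysam, selecting strands by FLAG exactly as
    single-end chemical-mapping reads are handled: FLAG 0 -> plus (Watson),
    FLAG 16 -> minus (Crick); other flags are skipped.  Aligned length comes
    from the CIGAR reference-consumed length when present, else the sequence
    length."""
    import pysam

    records: list[AlignedReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for read in fh:
            if read.flag not in (0, 16):
                continue
            length = read.reference_length
            if not length:
                length = read.query_length
            if not length:
                continue
            records.append(
                AlignedReadRecord(
                    ref=read.reference_name,
                    start=read.reference_start + 1,
                    read_length=int(length),
                    strand=Strand.MINUS if read.flag & 16 else Strand.PLUS,
                )
            )
    return records


# ---------------------------------------------------------------------------
# track output: wiggle (variableStep span=1) and bedGraph
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else format(float(v), ".17g")


def write_wiggle(values: np.ndarray, smap: CircularSequenceMap, path: str | Path) -> None:
    """Write a per-base vector as variableStep wiggle (span=1, 1-based
    positions, zero-valued bases omitted)."""
    values = np.asarray(values, dtype=float)
    lines = [f"variableStep chrom={smap.name} span=1"]
    for i, v in enumerate(values):
        if v != 0:
            lines.append(f"{i + 1} {_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wiggle(path: str | Path, smap: CircularSequenceMap) -> np.ndarray:
    values = np.zeros(smap.length)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("track", "variableStep", "fixedStep", "#")):
            continue
        pos_s, val_s = line.split()
        values[int(pos_s) - 1] = float(val_s)
    return values


def write_bedgraph(values: np.ndarray, smap: CircularSequenceMap, path: str | Path) -> None:
    """Write a per-base vector as bedGraph (0-based half-open intervals,
    adjacent equal-value runs merged, zero runs omitted)."""
    values = np.asarray(values, dtype=float)
    lines: list[str] = []
    i = 0
    n = values.size
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if values[i] != 0:
            lines.append(f"{smap.name}\t{i}\t{j + 1}\t{_fmt(values[i])}")
        i = j + 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path: str | Path, smap: CircularSequenceMap) -> np.ndarray:
    values = np.zeros(smap.length)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("track", "#")):
            continue
        _, start_s, end_s, val_s = line.split("\t")
        values[int(start_s):int(end_s)] = float(val_s)
    return values
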