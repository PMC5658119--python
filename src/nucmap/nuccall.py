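"""Nucleosome inference from parallel chemical and MNase cut-site data.

MNase preferentially cuts linker DNA, so naked-DNA cut sites that disappear
in chromatin delimit nucleosome footprints (:func:`find_protected_regions`);
site-directed hydroxyl radicals generated at histone H4 S47C cut near the
nucleosome dyad, so the intensity-weighted centre of the chemical signal
locates the dyad directly (:func:`chemical_center`).  Comparing the two —
the signed offset between chemical centre and MNase-footprint midpoint
(:func:`center_offset`), the footprint length, and the classification rules
in :func:`classify` — separates well-positioned nucleosomes from wide,
shifted, or short/unstable footprints.  :func:`nfr_size` converts a pair of
dyads into the edge-to-edge nucleosome-free gap assuming canonical cores,
and :func:`enumerate_frames` lists every cut pair of roughly core-particle
width, exposing alternative overlapping nucleosome positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .coords import CircularSequenceMap, SpanConvention


class SampleKind(str, Enum):
    NAKED_MNASE = "naked_mnase"
    CHROMATIN_MNASE = "chromatin_mnase"
    CHEMICAL = "chemical"


class EmptyWindowError(ValueError):
    """No cut sites fall inside the requested window."""


class ZeroSignalError(ValueError):
    """Sites exist in the window but carry zero total intensity."""


@dataclass
class CutSiteSet:
    """Cut coordinates with intensities for one sample on one map."""

    map: CircularSequenceMap
    sample_kind: SampleKind
    positions: np.ndarray
    intensities: np.ndarray
    strand: str = "combined"
    label: str = ""

    def __post_init__(self) -> None:
        self.sample_kind = SampleKind(self.sample_kind)
        self.positions = np.asarray(self.positions, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        for p in self.positions:
            self.map.check(int(p))
        if np.unique(self.positions).size != self.positions.size:
            raise ValueError("cut positions must be unique within a set")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.intensities = self.intensities[order]

    @classmethod
    def from_pairs(
        cls,
        smap: CircularSequenceMap,
        sample_kind: SampleKind | str,
        pairs: Sequence[tuple[int, float]],
        strand: str = "combined",
        label: str = "",
    ) -> "CutSiteSet":
        pos = [p for p, _ in pairs]
        inten = [w for _, w in pairs]
        return cls(smap, SampleKind(sample_kind), np.array(pos), np.array(inten),
                   strand=strand, label=label)

    def total(self) -> float:
        return float(self.intensities.sum())

    def normalized(self) -> np.ndarray:
        t = self.total()
        if t == 0:
            return np.zeros_like(self.intensities)
        return self.intensities / t


@dataclass(frozen=True)
class ProtectedRegion:
    """A nucleosomal footprint: the two bounding chromatin cut sites, the
    strictly-between protected length, its midpoint, and how many naked-DNA
    cut sites were suppressed inside it."""

    left_cut: int
    right_cut: int
    length: int
    midpoint: int
    suppressed_naked_sites: int = 0


def protected_region(
    smap: CircularSequenceMap,
    left_cut: int,
    right_cut: int,
    suppressed: int = 0,
) -> ProtectedRegion:
    """Build a region from its bounding cuts, deriving length and midpoint."""
    return ProtectedRegion(
        left_cut=smap.check(left_cut),
        right_cut=smap.check(right_cut),
        length=smap.span_length(left_cut, right_cut, SpanConvention.STRICT_BETWEEN),
        midpoint=smap.midpoint(left_cut, right_cut),
        suppressed_naked_sites=suppressed,
    )


def find_protected_regions(
    naked: CutSiteSet,
    chromatin: CutSiteSet,
    suppression_ratio: float = 0.5,
    min_suppressed: int = 1,
    match_tol: int = 3,
) -> list[ProtectedRegion]:
    """Call MNase-protected regions by naked-vs-chromatin comparison.

    Intensities are normalized to each set's total.  A naked cut site is
    *suppressed* when no chromatin site within ``match_tol`` bp retains a
    normalized intensity of at least ``suppression_ratio`` times the naked
    signal there (gel bands and cut positions never coincide exactly, hence
    the positional tolerance).  Both sides of the comparison use the maximum
    normalized intensity within the same ``match_tol`` window, so the rescue
    bar reflects the local naked signal rather than the sampling noise of a
    single base.  Maximal runs of at least ``min_suppressed`` consecutive
    suppressed naked sites, bounded on both sides by chromatin cut
    positions, become protected regions with those cuts as boundaries.
    """
    smap = naked.map
    if chromatin.map != smap:
        raise ValueError("naked and chromatin sets must share one map")
    if chromatin.positions.size == 0:
        raise ValueError("chromatin set is empty: no bounding cuts available")
    if naked.positions.size == 0:
        return []

    naked_norm = naked.normalized()
    chrom_pos = chromatin.positions
    chrom_norm = chromatin.normalized()

    def _window_max(positions, norms, p):
        sel = np.array(
            [smap.circular_distance(int(p), int(q), "shortest") <= match_tol
             for q in positions]
        )
        return float(norms[sel].max()) if sel.any() else 0.0

    suppressed = np.zeros(naked.positions.size, dtype=bool)
    for i, p in enumerate(naked.positions):
        naked_ref = _window_max(naked.positions, naked_norm, p)
        chrom_max = _window_max(chrom_pos, chrom_norm, p)
        suppressed[i] = chrom_max < suppression_ratio * naked_ref

    # maximal runs of suppressed naked sites, circular adjacency included
    n = suppressed.size
    runs: list[tuple[int, int]] = []  # (start index, run length) in naked-site order
    if np.all(suppressed):
        runs = [(0, n)]
    else:
        i = 0
        while i < n:
            if suppressed[i]:
                j = i
                while j + 1 < n and suppressed[j + 1]:
                    j += 1
                runs.append((i, j - i + 1))
                i = j + 1
            else:
                i += 1
        # join a run touching the end with one touching the start (circular)
        if (
            smap.is_circular
            and len(runs) >= 2
            and runs[0][0] == 0
            and runs[-1][0] + runs[-1][1] == n
        ):
            first, last = runs[0], runs.pop()
            runs[0] = (last[0], last[1] + first[1])

    regions: list[ProtectedRegion] = []
    for start_idx, run_len in runs:
        if run_len < min_suppressed:
            continue
        first = int(naked.positions[start_idx])
        last = int(naked.positions[(start_idx + run_len - 1) % n])
        left = _nearest_cut(smap, chrom_pos, first, upstream=True)
        right = _nearest_cut(smap, chrom_pos, last, upstream=False)
        if left is None or right is None:
            continue  # run reaches a linear-map end with no bounding cut
        regions.append(protected_region(smap, left, right, suppressed=run_len))
    return sorted(regions, key=lambda r: r.left_cut)


def _nearest_cut(
    smap: CircularSequenceMap,
    cuts: np.ndarray,
    anchor: int,
    upstream: bool,
) -> int | None:
    """Nearest cut strictly before (upstream) or after ``anchor`` in the
    clockwise sense; None if a linear map has no cut on that side."""
    best = None
    best_d = None
    for q in cuts:
        q = int(q)
        try:
            d = (
                smap.clockwise_distance(q, anchor)
                if upstream
                else smap.clockwise_distance(anchor, q)
            )
        except Exception:
            continue  # wrong side of a linear map
        if d < 1:
            continue
        if best_d is None or d < best_d:
            best, best_d = q, d
    return best


# ---------------------------------------------------------------------------
# chemical centres and classification
# ---------------------------------------------------------------------------

def _as_site_arrays(source, smap=None):
    if isinstance(source, CutSiteSet):
        return source.map, source.positions.astype(int), source.intensities
    # StrandedTrack-like (has .map and .combined)
    if hasattr(source, "combined") and hasattr(source, "map"):
        values = source.combined()
        return source.map, np.arange(1, values.size + 1), values
    if isinstance(source, tuple) and len(source) == 2:
        smap, values = source
        values = np.asarray(values, dtype=float)
        return smap, np.arange(1, values.size + 1), values
    raise TypeError("expected a CutSiteSet, a StrandedTrack, or (map, values)")


def chemical_center(
    source,
    window: tuple[int, int],
    mode: str = "centroid",
) -> int:
    """Dyad position from chemical cleavage signal inside a window.

    ``source`` is a :class:`CutSiteSet`, a stranded track, or a
    ``(map, per_base_values)`` pair; ``window`` is the clockwise arc
    ``(start, end)``.  The default mode is the intensity-weighted centroid
    along the arc (respecting origin wrap), rounded to the nearest base with
    ties toward the lower coordinate; ``mode='argmax'`` takes the highest
    site instead.
    """
    smap, positions, weights = _as_site_arrays(source)
    a, b = window
    arc = smap.clockwise_distance(a, b)
    offs = []
    w = []
    for p, inten in zip(positions, weights):
        d = smap.clockwise_distance(a, int(p))
        if d <= arc:
            offs.append(d)
            w.append(float(inten))
    if not offs:
        raise EmptyWindowError(f"no sites inside window ({a}, {b})")
    offs_arr = np.array(offs, dtype=float)
    w_arr = np.array(w, dtype=float)
    if w_arr.sum() <= 0:
        raise ZeroSignalError(f"zero total intensity inside window ({a}, {b})")
    if mode == "centroid":
        m = float(np.average(offs_arr, weights=w_arr))
        return smap.wrap(a + int(np.ceil(m - 0.5)))  # ties round toward lower coord
    if mode == "argmax":
        top = w_arr.max()
        cands = [smap.wrap(a + int(o)) for o, wi in zip(offs_arr, w_arr) if wi == top]
        return min(cands)
    raise ValueError(f"unknown mode {mode!r}")


def center_offset(
    smap: CircularSequenceMap,
    chemical: int,
    midpoint: int | ProtectedRegion,
) -> int:
    """Signed shortest circular distance from the MNase midpoint to the
    chemical centre; positive when the chemical centre lies clockwise of the
    midpoint.  ``|offset| <= length/2`` always."""
    if isinstance(midpoint, ProtectedRegion):
        midpoint = midpoint.midpoint
    smap.check(chemical)
    smap.check(midpoint)
    if not smap.is_circular:
        return chemical - midpoint
    d = smap.clockwise_distance(midpoint, chemical)
    if d == 0:
        return 0
    if 2 * d <= smap.length:
        return d
    return d - smap.length


class NucClass(str, Enum):
    CONSISTENT = "consistent"
    WIDE_PROTECTION = "wide_protection"
    SHIFTED = "shifted"
    SHORT_PROTECTION = "short_protection"


@dataclass(frozen=True)
class Classification:
    label: NucClass
    flags: frozenset = frozenset()


def classify(
    offset: int,
    protected_length: int,
    consistent_tol: int = 20,
    wide_threshold: int = 150,
    core_len: int = 147,
) -> Classification:
    """Classify a nucleosome call from its centre offset and footprint length.

    Footprints wider than ``wide_threshold`` are ambiguous
    (``wide_protection``): the core could sit anywhere inside.  Otherwise an
    offset within ``consistent_tol`` bp means the chemical and MNase centres
    agree (``consistent``).  Larger offsets are ``shifted``; when the
    footprint is also clearly shorter than a canonical core
    (``length <= core_len - 15``), the ``short_protection`` flag is added —
    the hallmark of an unstable or partially accessible nucleosome.
    """
    if protected_length > wide_threshold:
        return Classification(NucClass.WIDE_PROTECTION)
    if abs(offset) <= consistent_tol:
        return Classification(NucClass.CONSISTENT)
    if protected_length <= core_len - 15:
        return Classification(NucClass.SHIFTED, frozenset({"shifted", "short_protection"}))
    return Classification(NucClass.SHIFTED, frozenset({"shifted"}))


@dataclass(frozen=True)
class NucleosomeCall:
    """A complete per-nucleosome result: chemical centre, MNase footprint,
    their signed offset, and the classification."""

    label: str
    chemical_center: int
    mnase_region: ProtectedRegion
    center_offset: int
    classification: Classification


def call_nucleosome(
    smap: CircularSequenceMap,
    label: str,
    chemical: int,
    region: ProtectedRegion,
    consistent_tol: int = 20,
    wide_threshold: int = 150,
    core_len: int = 147,
) -> NucleosomeCall:
    off = center_offset(smap, chemical, region)
    cls = classify(off, region.length, consistent_tol, wide_threshold, core_len)
    return NucleosomeCall(label, chemical, region, off, cls)


# ---------------------------------------------------------------------------
# NFR sizes and overlapping frames
# ---------------------------------------------------------------------------

def nfr_size(
    smap: CircularSequenceMap,
    dyad_a: int,
    dyad_b: int,
    core_len: int = 147,
) -> int:
    """Edge-to-edge nucleosome-free gap between two dyads carrying centred
    cores of ``core_len`` bp: clockwise centre-to-centre distance minus
    ``core_len``, floored at zero."""
    if core_len < 1:
        raise ValueError("core_len must be >= 1")
    d = smap.clockwise_distance(dyad_a, dyad_b)
    return max(d - core_len, 0)


@dataclass(frozen=True)
class Frame:
    left_cut: int
    right_cut: int
    length: int


@dataclass
class FrameSet:
    """Candidate overlapping nucleosome positions: every ordered cut pair
    whose strictly-between length is close to the target width."""

    frames: list[Frame] = field(default_factory=list)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self):
        return len(self.frames)

    def pairs(self) -> list[tuple[int, int]]:
        return [(f.left_cut, f.right_cut) for f in self.frames]


def enumerate_frames(
    cuts: Sequence[int],
    target_width: int,
    tol: int,
    smap: CircularSequenceMap,
) -> FrameSet:
    """All ordered cut pairs whose strictly-between length lies within
    ``target_width +/- tol``, sorted by left cut.  Overlapping frames are the
    point: they expose alternative nucleosome positions over one locus."""
    cuts = sorted({smap.check(int(c)) for c in cuts})
    if len(cuts) < 2:
        raise ValueError("frame enumeration needs >= 2 cuts")
    frames: list[Frame] = []
    for a in cuts:
        for b in cuts:
            if a == b:
                continue
            if not smap.is_circular and b < a:
                continue
            length = smap.span_length(a, b, SpanConvention.STRICT_BETWEEN)
            if abs(length - target_width) <= tol:
                frames.append(Frame(a, b, length))
    frames.sort(key=lambda f: (f.left_cut, f.right_cut))
    return FrameSet(frames)
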