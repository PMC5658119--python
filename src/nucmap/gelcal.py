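"""Gel-lane densitometry calibration.

Turns 1-D lane-intensity traces (as exported by "Plot Profile"-style
densitometry of an electrophoresis gel image) into base-coordinate-calibrated
per-base signals:

* band detection on a trace (:func:`detect_bands`),
* semi-log standard curves from size-marker lanes (:func:`fit_size_curve`),
* migration -> base interpolation through manually assigned anchor bands
  (:func:`calibrate_bases`),
* the one-base correction for primer-extension lanes
  (:func:`apply_taq_correction`) — Taq polymerase adds one untemplated
  nucleotide at the 3' end, so extension products run one base longer than
  dideoxy-terminated sequencing-ladder controls, and primer-extension calls
  must be shifted one base shorter,
* resampling a calibrated trace onto the integer base grid
  (:func:`trace_to_base_grid`) and correlating it against a sequencing-derived
  cleavage track (:func:`correlate_with_track`).

Trace orientation (whether increasing migration means increasing or
decreasing base coordinate) is inferred from the anchor ordering, never
assumed.  Interpolation outside the anchor or marker range is permitted but
always flagged as extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .coords import CircularSequenceMap


class LaneKind(str, Enum):
    PRIMER_EXTENSION = "primer_extension"
    SEQUENCING_LADDER = "sequencing_ladder"
    INDIRECT_END_LABEL = "indirect_end_label"


class CalibrationError(ValueError):
    """Invalid marker/anchor input for a calibration."""


@dataclass
class LaneTrace:
    """A densitometry profile: intensity ``y`` sampled at strictly increasing
    migration coordinates ``x`` (both in arbitrary units)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.size < 2:
            raise ValueError("trace requires matching 1-D x/y with >= 2 samples")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("trace x must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError("trace intensities must be non-negative")


@dataclass(frozen=True)
class BandCall:
    """A detected band: its migration center, height, prominence and width at
    half height, all in trace units."""

    center: float
    height: float
    prominence: float
    width_at_half_height: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("band height must be positive")
        if self.prominence > self.height + 1e-12:
            raise ValueError("band prominence cannot exceed its height")


@dataclass(frozen=True)
class Calibrated:
    """A calibrated value plus a flag marking extrapolation beyond the
    outermost markers/anchors."""

    value: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class SizeStandard:
    """Size-marker ladder: (fragment size in bp, migration in a.u.) pairs."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        pts = [(float(s), float(m)) for s, m in self.points]
        if len(pts) < 2:
            raise CalibrationError("size standard needs >= 2 marker points")
        sizes = [s for s, _ in pts]
        if min(sizes) <= 0:
            raise CalibrationError("marker sizes must be positive")
        if len(set(sizes)) != len(sizes):
            raise CalibrationError("marker sizes must be distinct")
        pts.sort(key=lambda p: p[0])
        migr = [m for _, m in pts]
        inc = all(b > a for a, b in zip(migr, migr[1:]))
        dec = all(b < a for a, b in zip(migr, migr[1:]))
        if not (inc or dec):
            bad = [
                (pts[i], pts[i + 1])
                for i in range(len(pts) - 1)
                if (migr[i + 1] - migr[i]) * (migr[1] - migr[0]) <= 0
            ]
            raise CalibrationError(
                f"marker migrations not monotone in size; offending pairs: {bad}"
            )
        self.points = pts


@dataclass
class AnchorSet:
    """Manually assigned (migration, base coordinate) anchor bands for one
    lane, plus the lane kind that decides whether the Taq correction applies."""

    anchors: list[tuple[float, float]]
    lane_kind: LaneKind = LaneKind.SEQUENCING_LADDER

    def __post_init__(self) -> None:
        self.lane_kind = LaneKind(self.lane_kind)
        pts = [(float(m), float(b)) for m, b in self.anchors]
        if len(pts) < 2:
            raise CalibrationError("anchor set needs >= 2 anchors")
        pts.sort(key=lambda p: p[0])
        migr = [m for m, _ in pts]
        if any(b <= a for a, b in zip(migr, migr[1:])):
            raise CalibrationError("anchor migrations must be strictly monotone")
        bases = [b for _, b in pts]
        inc = all(b > a for a, b in zip(bases, bases[1:]))
        dec = all(b < a for a, b in zip(bases, bases[1:]))
        if not (inc or dec):
            raise CalibrationError("anchor bases must be strictly monotone")
        self.anchors = pts

    @property
    def migrations(self) -> np.ndarray:
        return np.array([m for m, _ in self.anchors])

    @property
    def bases(self) -> np.ndarray:
        return np.array([b for _, b in self.anchors])


def _interp_with_ends(x: float, xs: np.ndarray, ys: np.ndarray) -> tuple[float, bool]:
    """Piecewise-linear interpolation through (xs, ys); beyond the outermost
    knots the terminal segment is extended and the result flagged."""
    if x < xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + (x - xs[0]) * slope), True
    if x > xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + (x - xs[-1]) * slope), True
    return float(np.interp(x, xs, ys)), False


# ---------------------------------------------------------------------------
# band detection
# ---------------------------------------------------------------------------

def detect_bands(
    trace: LaneTrace,
    min_prominence: float = 0.05,
    min_separation: float = 0.0,
    median_smooth: bool = False,
    mode: str = "maximum",
) -> list[BandCall]:
    """Detect bands as local intensity maxima on a lane trace.

    A peak qualifies if its prominence is at least
    ``min_prominence * max(y)``; peaks closer than ``min_separation`` (in
    migration units) are greedily thinned keeping the higher one.  A flat
    trace yields no bands.  ``mode='centroid'`` reports the intensity
    centroid over the half-height window instead of the maximum sample.
    """
    if not 0 < min_prominence <= 1:
        raise ValueError("min_prominence must be in (0, 1]")
    x, y = trace.x, trace.y
    if median_smooth:
        y = _signal.medfilt(y, kernel_size=3)
    ymax = float(np.max(y))
    if ymax == float(np.min(y)):
        return []
    peaks, props = _signal.find_peaks(y, prominence=min_prominence * ymax)
    if peaks.size == 0:
        return []
    widths, _, left_ips, right_ips = _signal.peak_widths(y, peaks, rel_height=0.5)
    idx = np.arange(x.size)

    calls = []
    for k, p in enumerate(peaks):
        xl = float(np.interp(left_ips[k], idx, x))
        xr = float(np.interp(right_ips[k], idx, x))
        if mode == "centroid":
            sel = (x >= xl) & (x <= xr)
            center = float(np.average(x[sel], weights=y[sel])) if np.any(sel) else float(x[p])
        elif mode == "maximum":
            center = float(x[p])
        else:
            raise ValueError(f"unknown band-center mode {mode!r}")
        calls.append(
            BandCall(
                center=center,
                height=float(y[p]),
                prominence=float(props["prominences"][k]),
                width_at_half_height=xr - xl,
            )
        )

    if min_separation > 0:
        kept: list[BandCall] = []
        for c in sorted(calls, key=lambda c: -c.height):
            if all(abs(c.center - k.center) >= min_separation for k in kept):
                kept.append(c)
        calls = kept
    return sorted(calls, key=lambda c: c.center)


# ---------------------------------------------------------------------------
# standard curves and anchor calibration
# ---------------------------------------------------------------------------

@dataclass
class SizeCurve:
    """Piecewise-linear migration <-> log10(size) calibration (classic
    semi-log gel behaviour), interpolating between flanking markers and
    extending the terminal segment beyond them (flagged)."""

    standard: SizeStandard
    _mig: np.ndarray = field(init=False, repr=False)
    _logs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = sorted(self.standard.points, key=lambda p: p[1])  # by migration
        self._mig = np.array([m for _, m in pts])
        self._logs = np.array([math.log10(s) for s, _ in pts])

    def migration_to_size(self, migration: float) -> Calibrated:
        logsize, extrap = _interp_with_ends(float(migration), self._mig, self._logs)
        return Calibrated(10.0 ** logsize, extrap)

    def size_to_migration(self, size: float) -> Calibrated:
        if size <= 0:
            raise ValueError("fragment size must be positive")
        order = np.argsort(self._logs)
        mig, extrap = _interp_with_ends(
            math.log10(size), self._logs[order], self._mig[order]
        )
        return Calibrated(mig, extrap)


def fit_size_curve(standard: SizeStandard) -> SizeCurve:
    """Build the semi-log standard curve from a size-marker ladder."""
    return SizeCurve(standard)


def calibrate_bases(anchors: AnchorSet, query_x: float) -> Calibrated:
    """Fractional base coordinate for a migration, by linear interpolation
    between the two anchors flanking ``query_x`` (linear extrapolation from
    the nearest two anchors outside the range, flagged)."""
    value, extrap = _interp_with_ends(float(query_x), anchors.migrations, anchors.bases)
    return Calibrated(value, extrap)


def apply_taq_correction(
    base: float,
    lane_kind: LaneKind | str,
    smap: CircularSequenceMap | None = None,
):
    """Shift primer-extension base calls one base shorter.

    Sequencing-ladder and indirect-end-label calls pass through unchanged.
    With a circular map the corrected coordinate is wrapped.
    """
    lane_kind = LaneKind(lane_kind)
    if lane_kind is not LaneKind.PRIMER_EXTENSION:
        corrected = base
    else:
        corrected = base - 1
    if smap is not None and smap.is_circular:
        if float(corrected) == int(corrected):
            return smap.wrap(int(corrected))
        return (float(corrected) - 1) % smap.length + 1
    return corrected


# ---------------------------------------------------------------------------
# per-base resampling and track comparison
# ---------------------------------------------------------------------------

@dataclass
class BaseGrid:
    """A trace resampled onto the integer base grid: for each base the mean
    trace intensity of the samples whose calibrated coordinate falls in
    ``[base - 0.5, base + 0.5)``."""

    bases: np.ndarray
    values: np.ndarray
    extrapolated: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return {int(b): float(v) for b, v in zip(self.bases, self.values)}

    def value_at(self, base: int) -> float:
        hits = np.nonzero(self.bases == base)[0]
        if hits.size == 0:
            raise KeyError(f"base {base} not covered by this grid")
        return float(self.values[hits[0]])


def trace_to_base_grid(
    trace: LaneTrace,
    anchors: AnchorSet,
    smap: CircularSequenceMap | None = None,
) -> BaseGrid:
    """Calibrate every trace sample to a fractional base (Taq correction
    applied per lane kind), bin samples to integer bases and average, and
    fill uncovered bases by linear interpolation of neighbouring base values.
    """
    x, y = trace.x, trace.y
    mig = anchors.migrations
    if mig[-1] < x[0] or mig[0] > x[-1]:
        raise CalibrationError(
            "anchors lie entirely outside the trace migration range"
        )
    base_f = np.empty_like(x)
    extrap = np.zeros(x.size, dtype=bool)
    for i, xi in enumerate(x):
        base_f[i], extrap[i] = _interp_with_ends(xi, mig, anchors.bases)
    if anchors.lane_kind is LaneKind.PRIMER_EXTENSION:
        base_f = base_f - 1.0

    bins = np.floor(base_f + 0.5).astype(int)
    bmin, bmax = int(bins.min()), int(bins.max())
    grid = np.arange(bmin, bmax + 1)
    values = np.full(grid.size, np.nan)
    flagged = np.zeros(grid.size, dtype=bool)
    for j, b in enumerate(grid):
        sel = bins == b
        if np.any(sel):
            values[j] = float(np.mean(y[sel]))
            flagged[j] = bool(np.any(extrap[sel]))
    covered = ~np.isnan(values)
    if not np.all(covered):
        values[~covered] = np.interp(
            grid[~covered], grid[covered], values[covered]
        )
    if smap is not None and smap.is_circular:
        canonical = (grid - 1) % smap.length + 1
    else:
        canonical = grid
    return BaseGrid(bases=canonical, values=values, extrapolated=flagged)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlation between a gel-derived per-base signal
    and a sequencing-derived cleavage track; ``nan`` marks an undefined
    correlation (zero variance)."""

    pearson: float
    spearman: float
    n: int


def correlate_with_track(
    grid: BaseGrid,
    track,
    strand: str = "combined",
    window: tuple[int, int] | None = None,
) -> CorrelationResult:
    """Correlate gel intensity with per-base cleavage counts on one strand.

    ``track`` is a :class:`nucmap.pileup.StrandedTrack`; ``window`` is a
    clockwise (start, end) arc on the track's map, defaulting to the grid's
    coverage.  Zero-variance input yields NaN correlations, not an exception.
    """
    smap = track.map
    if strand == "plus":
        per_base = track.plus
    elif strand == "minus":
        per_base = track.minus
    elif strand == "combined":
        per_base = track.plus + track.minus
    else:
        raise ValueError(f"unknown strand {strand!r}")

    lookup = grid.as_dict()
    if window is None:
        positions = [int(b) for b in grid.bases]
    else:
        positions = smap.positions_clockwise(window[0], window[1])
        missing = [p for p in positions if p not in lookup]
        if missing:
            raise ValueError(f"window positions not covered by the gel grid: {missing[:5]}")
    gel = np.array([lookup[p] for p in positions])
    seq = np.array([per_base[p - 1] for p in positions])
    if gel.size < 2 or np.std(gel) == 0 or np.std(seq) == 0:
        return CorrelationResult(float("nan"), float("nan"), gel.size)
    pr = _stats.pearsonr(gel, seq).statistic
    sr = _stats.spearmanr(gel, seq).statistic
    return CorrelationResult(float(pr), float(sr), gel.size)
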