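"""Forward simulators with known ground truth for every pipeline input.

Three generators emulate the study's chromatin substrates:

* :func:`simulate_chemical_reads` — sequencing reads whose 5' ends cluster
  around specified nucleosome dyads with strand-specific offsets, emulating
  site-directed hydroxyl-radical cleavage near the dyad.  Reads are placed so
  that the standard pileup -> 1-bp-upstream-shift recovers a cleavage at
  ``dyad + offset`` on the sampled strand.
* :func:`simulate_mnase_cuts` — MNase cut-site sets for naked versus
  chromatinized circular templates: uniform cutting on naked DNA, strong
  linker preference and core protection on chromatin, with an optional A/T
  sequence preference.
* :func:`simulate_gel_lane` / :func:`simulate_primer_extension_lane` —
  densitometry traces as sums of Gaussian bands under a semi-log migration
  model, together with the marker standards and anchor sets needed to
  calibrate them back.

:func:`trp1ars1_fixture` bundles the 1,453-bp circular TRP1ARS1 yeast
minichromosome: map, dyads, hypersensitive-region span, and the named cut
coordinate sets used throughout the tests.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coords import CircularSequenceMap, Topology
from .gelcal import AnchorSet, LaneKind, LaneTrace, SizeStandard
from .nuccall import CutSiteSet, SampleKind
from .pileup import AlignedReadRecord, Strand

#: Default strand-symmetric chemical offset model: small offsets around the
#: dyad.  The true strand-specific cleavage offsets of the S47C chemistry are
#: not asserted here; the model is configurable so asymmetric chemistry can
#: be expressed.
DEFAULT_CHEMICAL_OFFSETS: dict[int, float] = {-2: 0.15, -1: 0.2, 0: 0.3, 1: 0.2, 2: 0.15}


@dataclass(frozen=True)
class Dyad:
    """One positioned nucleosome: dyad position, sampling weight, optional
    alternative-frame offsets (each an (offset, weight) pair), and whether the
    position comes from the literature or is a fixture placeholder."""

    position: int
    weight: float = 1.0
    label: str = ""
    from_literature: bool = False
    alternatives: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("dyad weight must be positive")


@dataclass
class ChromatinSpec:
    """Ground truth driving the simulators: a map, its positioned dyads, the
    core length, and the relative MNase cut rates in linkers versus cores."""

    map: CircularSequenceMap
    dyads: list[Dyad]
    core_len: int = 147
    linker_cut_weight: float = 1.0
    core_cut_weight: float = 0.05
    at_preference: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        for d in self.dyads:
            self.map.check(d.position)
        if self.core_cut_weight > self.linker_cut_weight:
            raise ValueError("core_cut_weight must not exceed linker_cut_weight")

    def core_mask(self) -> np.ndarray:
        """Boolean per-base mask of core footprints (dyad +/- core_len//2)."""
        mask = np.zeros(self.map.length, dtype=bool)
        half = self.core_len // 2
        for d in self.dyads:
            for k in range(-half, half + 1):
                mask[self.map.wrap(d.position + k) - 1] = True
        return mask


@dataclass
class ChemicalOffsetModel:
    """Per-strand distribution of cleavage offsets relative to the dyad."""

    plus: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CHEMICAL_OFFSETS))
    minus: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CHEMICAL_OFFSETS))

    def __post_init__(self) -> None:
        for name, table in (("plus", self.plus), ("minus", self.minus)):
            total = sum(table.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name}-strand offset probabilities sum to {total}, not 1")


@dataclass
class GelModel:
    """Semi-log gel forward model: migration(size) = intercept − slope·log10(size),
    Gaussian band shapes, optional white noise, uniform sampling density."""

    intercept: float = 150.0
    slope: float = 35.0
    band_sigma: float = 0.6
    noise_sigma: float = 0.0
    samples_per_au: int = 20

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.band_sigma <= 0:
            raise ValueError("slope and band_sigma must be positive")

    def migration(self, size: float) -> float:
        return self.intercept - self.slope * math.log10(size)

    def size_standard(self, sizes: Sequence[float]) -> SizeStandard:
        return SizeStandard([(s, self.migration(s)) for s in sizes])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# chemical-cleavage reads
# ---------------------------------------------------------------------------

def simulate_chemical_reads(
    spec: ChromatinSpec,
    n: int,
    offsets: ChemicalOffsetModel | None = None,
    read_length: int = 50,
    seed: int | np.random.Generator = 0,
) -> list[AlignedReadRecord]:
    """Draw ``n`` chemical-cleavage reads around the spec's dyads.

    Each read picks a dyad placement by weight (alternative frames contribute
    extra placements at ``position + offset`` weighted by
    ``dyad.weight * frame_weight``), a strand uniformly, and an offset from
    that strand's table.  The 5' end is placed one base 3' (in read
    orientation) of the cleavage position ``dyad + offset``, so that
    pileup -> upstream shift recovers the cleavage exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not spec.dyads:
        raise ValueError("spec has no dyads")
    offsets = offsets or ChemicalOffsetModel()
    rng = _rng(seed)
    smap = spec.map

    placements: list[int] = []
    weights: list[float] = []
    for d in spec.dyads:
        placements.append(d.position)
        weights.append(d.weight)
        for off, w in d.alternatives:
            placements.append(smap.wrap(d.position + off))
            weights.append(d.weight * w)
    probs = np.array(weights) / np.sum(weights)
    dyad_idx = rng.choice(len(placements), size=n, p=probs)
    strands = rng.integers(0, 2, size=n)  # 0 = plus, 1 = minus

    plus_offs = np.array(sorted(offsets.plus))
    plus_p = np.array([offsets.plus[o] for o in plus_offs])
    minus_offs = np.array(sorted(offsets.minus))
    minus_p = np.array([offsets.minus[o] for o in minus_offs])
    off_plus = rng.choice(plus_offs, size=n, p=plus_p)
    off_minus = rng.choice(minus_offs, size=n, p=minus_p)

    records: list[AlignedReadRecord] = []
    for i in range(n):
        dyad = placements[dyad_idx[i]]
        if strands[i] == 0:
            cleave = dyad + int(off_plus[i])
            five = smap.wrap(cleave + 1)
            records.append(AlignedReadRecord(smap.name, five, read_length, Strand.PLUS))
        else:
            cleave = dyad + int(off_minus[i])
            five = smap.wrap(cleave - 1)
            start = smap.wrap(five - read_length + 1)
            records.append(AlignedReadRecord(smap.name, start, read_length, Strand.MINUS))
    return records


# ---------------------------------------------------------------------------
# MNase cut sets
# ---------------------------------------------------------------------------

def simulate_mnase_cuts(
    spec: ChromatinSpec,
    substrate: str,
    n: int,
    seed: int | np.random.Generator = 0,
    sequence: str | None = None,
) -> CutSiteSet:
    """Draw ``n`` MNase cuts on a naked or chromatinized template.

    Naked DNA is cut uniformly (times the optional A/T preference applied to
    the base 5' of the cut on the top strand); chromatin is cut at
    ``linker_cut_weight`` in linkers and ``core_cut_weight`` inside any core
    footprint.  Returns positions with draw multiplicities as intensities.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if substrate not in ("naked", "chromatin"):
        raise ValueError("substrate must be 'naked' or 'chromatin'")
    rng = _rng(seed)
    L = spec.map.length
    if substrate == "naked":
        weights = np.ones(L)
        kind = SampleKind.NAKED_MNASE
    else:
        weights = np.full(L, spec.linker_cut_weight)
        weights[spec.core_mask()] = spec.core_cut_weight
        kind = SampleKind.CHROMATIN_MNASE
    if sequence is not None and spec.at_preference != 1.0:
        if len(sequence) != L:
            raise ValueError("sequence length must equal map length")
        at = np.array([c in "ATat" for c in sequence])
        weights = np.where(at, weights * spec.at_preference, weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all cut weights are zero")
    draws = rng.choice(L, size=n, p=weights / total)
    counts = np.bincount(draws, minlength=L)
    pos = np.nonzero(counts)[0] + 1
    return CutSiteSet(
        spec.map, kind, pos, counts[pos - 1].astype(float), label=spec.label
    )


# ---------------------------------------------------------------------------
# gel lanes
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLane:
    """A simulated trace plus its ground truth band centres
    (size, migration, abundance)."""

    trace: LaneTrace
    bands: list[tuple[float, float, float]]


def simulate_gel_lane(
    fragments: Sequence[tuple[float, float]],
    gel: GelModel,
    seed: int | np.random.Generator = 0,
    pad: float = 5.0,
) -> SimulatedLane:
    """Render fragments as abundance-scaled Gaussian bands at their model
    migrations, plus optional white noise.  An empty fragment list yields a
    flat (noise-only) trace."""
    rng = _rng(seed)
    bands = []
    for size, abundance in fragments:
        if size <= 0:
            raise ValueError("fragment sizes must be positive")
        bands.append((float(size), gel.migration(size), float(abundance)))
    if bands:
        lo = min(m for _, m, _ in bands) - pad
        hi = max(m for _, m, _ in bands) + pad
    else:
        lo, hi = 0.0, 10.0
    n_samples = max(int(round((hi - lo) * gel.samples_per_au)) + 1, 2)
    x = np.linspace(lo, hi, n_samples)
    y = np.zeros_like(x)
    for _, m, abundance in bands:
        y += abundance * np.exp(-0.5 * ((x - m) / gel.band_sigma) ** 2)
    if gel.noise_sigma > 0:
        y += rng.normal(0.0, gel.noise_sigma, size=x.size)
    y = np.clip(y, 0.0, None)
    return SimulatedLane(LaneTrace(x, y, label="simulated"), bands)


def simulate_primer_extension_lane(
    bases: Sequence[int],
    values: Sequence[float],
    lane_kind: LaneKind | str = LaneKind.PRIMER_EXTENSION,
    migration_origin: float = 20.0,
    migration_per_base: float = 0.5,
    band_sigma: float = 0.12,
    noise_sigma: float = 0.0,
    anchor_stride: int = 10,
    samples_per_base: int = 20,
    seed: int | np.random.Generator = 0,
) -> tuple[LaneTrace, AnchorSet]:
    """Render known per-base cleavage intensities as a sequencing-gel lane.

    The migration model is linear in base coordinate.  On a primer-extension
    lane the product of a cleavage at base ``b`` runs one base *longer* than
    the ladder product terminating at ``b`` (the untemplated Taq addition),
    so its band sits at the migration of base ``b + 1``; the returned anchor
    set is assigned from the ladder, so calibration plus the Taq correction
    recovers ``b``.
    """
    lane_kind = LaneKind(lane_kind)
    bases = np.asarray(bases, dtype=int)
    values = np.asarray(values, dtype=float)
    if bases.shape != values.shape or bases.size < 2:
        raise ValueError("bases and values must match and have >= 2 entries")
    rng = _rng(seed)
    shift = 1 if lane_kind is LaneKind.PRIMER_EXTENSION else 0

    def mig(b: float) -> float:
        return migration_origin + migration_per_base * b

    centers = np.array([mig(b + shift) for b in bases])
    lo = centers.min() - 2 * migration_per_base
    hi = centers.max() + 2 * migration_per_base
    dx = migration_per_base / samples_per_base
    x = np.arange(lo, hi + dx / 2, dx)
    y = np.zeros_like(x)
    for c, v in zip(centers, values):
        y += v * np.exp(-0.5 * ((x - c) / band_sigma) ** 2)
    if noise_sigma > 0:
        y += rng.normal(0.0, noise_sigma, size=x.size)
    y = np.clip(y, 0.0, None)

    anchor_bases = list(bases[::anchor_stride])
    if anchor_bases[-1] != bases[-1]:
        anchor_bases.append(int(bases[-1]))
    anchors = AnchorSet(
        [(mig(b), float(b)) for b in anchor_bases], lane_kind=lane_kind
    )
    return LaneTrace(x, y, label="simulated-pe"), anchors


# ---------------------------------------------------------------------------
# TRP1ARS1 fixture
# ---------------------------------------------------------------------------

@dataclass
class Trp1Ars1Fixture:
    """The 1,453-bp circular TRP1ARS1 minichromosome study locus.

    ``chromatin.dyads`` carries literature dyads for nucleosomes II (1,132),
    III (1,308) and IV (104), flagged ``from_literature=True``; the dyads of
    nucleosomes I and V–VII are plausible placeholders, flagged False, and
    must not be treated as ground truth.  ``cut_sets`` holds the printed
    MNase band-pair coordinates per nucleosome and strand; ``frame_cuts``
    the listed multi-frame cut positions (slash-separated alternatives
    treated as independent cuts); ``hsrb`` the hypersensitive-region span.
    """

    map: CircularSequenceMap
    chromatin: ChromatinSpec
    cut_sets: dict[str, CutSiteSet]
    frame_cuts: dict[str, tuple[int, ...]]
    hsrb: tuple[int, int]
    anchor_set: AnchorSet

    def literature_dyads(self) -> dict[str, int]:
        return {
            d.label: d.position for d in self.chromatin.dyads if d.from_literature
        }


def trp1ars1_fixture() -> Trp1Ars1Fixture:
    """Build the TRP1ARS1 fixture used across the tests and the pipeline."""
    smap = CircularSequenceMap(
        name="TRP1ARS1",
        length=1453,
        topology=Topology.CIRCULAR,
        genomic_offset=461_740,
        genomic_ref="chrIV",
    )
    dyads = [
        Dyad(104, label="NucIV", from_literature=True),
        Dyad(270, label="NucV", from_literature=False),
        Dyad(435, label="NucVI", from_literature=False),
        Dyad(600, label="NucVII", from_literature=False),
        Dyad(940, label="NucI", from_literature=False),
        Dyad(1132, label="NucII", from_literature=True),
        Dyad(1308, label="NucIII", from_literature=True),
    ]
    spec = ChromatinSpec(map=smap, dyads=dyads, label="TRP1ARS1")

    def cuts(name, pairs, strand):
        return CutSiteSet.from_pairs(
            smap, SampleKind.CHROMATIN_MNASE,
            [(p, 1.0) for p in pairs], strand=strand, label=name,
        )

    cut_sets = {
        "nucII": cuts("nucII", (1077, 1187), "combined"),
        "nucIII_top": cuts("nucIII_top", (1271, 1346), "plus"),
        "nucIII_bottom": cuts("nucIII_bottom", (1268, 1334), "minus"),
        "nucIV_top": cuts("nucIV_top", (70, 158), "plus"),
        "nucIV_bottom": cuts("nucIV_bottom", (87, 168), "minus"),
    }
    frame_cuts = {
        "nucIII_top": (1227, 1246, 1264, 1271, 1346, 1362, 1376, 1388),
        "nucIII_bottom": (1224, 1230, 1242, 1246, 1268, 1334, 1343, 1362, 1387),
        "nucIV_top": (45, 55, 70, 78, 158, 168, 181, 189),
        "nucIV_bottom": (53, 69, 79, 87, 168, 178, 188),
    }
    # synthetic anchor set (linear migration model) covering the NucII window
    anchor_set = AnchorSet(
        [(10.0 + 0.1 * (b - 1050), float(b)) for b in range(1050, 1211, 20)],
        lane_kind=LaneKind.SEQUENCING_LADDER,
    )
    return Trp1Ars1Fixture(
        map=smap,
        chromatin=spec,
        cut_sets=cut_sets,
        frame_cuts=frame_cuts,
        hsrb=(1337, 62),
        anchor_set=anchor_set,
    )
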