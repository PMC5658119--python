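"""Plain-text readers/writers for the pipeline's tabular inputs and outputs.

All formats are small headered delimited-text files: two-column lane traces
(as exported by "Plot Profile"-style densitometry), size-marker tables,
anchor tables, cut-site tables, aligned-read tables, and a SAM-subset writer
for interoperability with standard tooling.  Track formats (wiggle/bedGraph)
live in :mod:`nucmap.pileup`.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coords import CircularSequenceMap
from .gelcal import AnchorSet, LaneKind, LaneTrace, SizeStandard
from .nuccall import CutSiteSet, NucleosomeCall, ProtectedRegion, SampleKind
from .pileup import AlignedReadRecord


def read_lane_trace(path: str | Path, label: str = "") -> LaneTrace:
    """Read a two-column (migration, intensity) trace, tab- or
    comma-delimited, with an optional one-line header."""
    lines = Path(path).read_text().splitlines()
    xs, ys = [], []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        parts = re.split(r"[,\t]+|\s+", line)
        try:
            x, y = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if i == 0:
                continue  # header
            raise ValueError(f"malformed trace line {i + 1}: {line!r}")
        xs.append(x)
        ys.append(y)
    return LaneTrace(np.array(xs), np.array(ys), label=label or Path(path).stem)


def write_lane_trace(trace: LaneTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\n")
        for x, y in zip(trace.x, trace.y):
            fh.write(f"{x:.6g}\t{y:.6g}\n")


def read_size_standard(path: str | Path) -> SizeStandard:
    """Read a headered (size, migration) marker table."""
    df = pd.read_csv(path, sep=None, engine="python")
    return SizeStandard(list(zip(df["size"], df["migration"])))


def write_size_standard(standard: SizeStandard, path: str | Path) -> None:
    pd.DataFrame(standard.points, columns=["size", "migration"]).to_csv(
        path, sep="\t", index=False
    )


def read_anchor_set(path: str | Path) -> AnchorSet:
    """Read a headered (migration, base, lane_kind) anchor table; the lane
    kind must be uniform across rows."""
    df = pd.read_csv(path, sep=None, engine="python")
    kinds = set(df["lane_kind"])
    if len(kinds) != 1:
        raise ValueError(f"anchor table mixes lane kinds: {sorted(kinds)}")
    return AnchorSet(
        list(zip(df["migration"], df["base"])), lane_kind=LaneKind(kinds.pop())
    )


def write_anchor_set(anchors: AnchorSet, path: str | Path) -> None:
    rows = [
        {"migration": m, "base": b, "lane_kind": anchors.lane_kind.value}
        for m, b in anchors.anchors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cut_sites(
    path: str | Path,
    smap: CircularSequenceMap,
    sample_kind: SampleKind | str,
    strand: str = "combined",
) -> CutSiteSet:
    """Read a headered (position, intensity) cut-site table."""
    df = pd.read_csv(path, sep="\t")
    return CutSiteSet(
        smap,
        SampleKind(sample_kind),
        df["position"].to_numpy(int),
        df["intensity"].to_numpy(float),
        strand=strand,
        label=Path(path).stem,
    )


def write_cut_sites(sites: CutSiteSet, path: str | Path) -> None:
    pd.DataFrame(
        {"position": sites.positions, "intensity": sites.intensities}
    ).to_csv(path, sep="\t", index=False)


def write_read_table(records: Sequence[AlignedReadRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ref": [r.ref for r in records],
            "start": [r.start for r in records],
            "length": [r.read_length for r in records],
            "strand": [r.strand.value for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_sam(
    records: Sequence[AlignedReadRecord],
    smap: CircularSequenceMap,
    path: str | Path,
) -> None:
    """Write records as a minimal single-end SAM file (FLAG 0/16, full-match
    CIGAR, placeholder sequence)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{smap.name}\tLN:{smap.length}\n")
        for i, r in enumerate(records):
            flag = 16 if r.strand.value == "minus" else 0
            seq = "N" * r.read_length
            fh.write(
                f"read{i}\t{flag}\t{r.ref}\t{r.start}\t60\t{r.read_length}M\t"
                f"*\t0\t0\t{seq}\t*\n"
            )


def write_regions_bed(
    regions: Sequence[ProtectedRegion],
    smap: CircularSequenceMap,
    path: str | Path,
    name_prefix: str = "protected",
) -> None:
    """Write protected regions as BED (0-based half-open); the score column
    is the suppressed-naked-site count.  A region wrapping the circular
    origin is split into two lines suffixed ``/a`` and ``/b``."""
    lines = []
    for i, r in enumerate(regions):
        name = f"{name_prefix}_{i + 1}"
        score = r.suppressed_naked_sites
        if r.right_cut >= r.left_cut:
            lines.append(f"{smap.name}\t{r.left_cut - 1}\t{r.right_cut}\t{name}\t{score}\t.")
        else:
            lines.append(f"{smap.name}\t{r.left_cut - 1}\t{smap.length}\t{name}/a\t{score}\t.")
            lines.append(f"{smap.name}\t0\t{r.right_cut}\t{name}/b\t{score}\t.")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_call_table(calls: Sequence[NucleosomeCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "label": c.label,
                "left_cut": c.mnase_region.left_cut,
                "right_cut": c.mnase_region.right_cut,
                "protected_length": c.mnase_region.length,
                "midpoint": c.mnase_region.midpoint,
                "chemical_center": c.chemical_center,
                "center_offset": c.center_offset,
                "classification": c.classification.label.value,
                "flags": ",".join(sorted(c.classification.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
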