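# Methods

## Model and assumptions

`nucmap` analyses *parallel mapping* data: the same chromatin substrate
(isolated nuclei carrying a circular minichromosome) digested in parallel
with MNase and with site-directed hydroxyl radicals generated at histone
H4 S47C. The analysis assumes:

* a single, fixed reference frame — a circular (or linear) sequence of
  known length, 1-based and inclusive, optionally colinear with a genomic
  source locus through a fixed offset (no indels, so no chain-based
  liftover is needed);
* MNase cuts linker DNA preferentially and is largely excluded from the
  ~147-bp core footprint, so naked-DNA cut sites that vanish in chromatin
  mark footprints;
* dyad-proximal chemical cleavage: the S47C-tethered chemistry cuts within
  a few bp of the nucleosome centre on both strands, so the
  intensity-weighted centre of chemical signal estimates the dyad;
* sequencing reads report strand breaks at their 5′ ends, one base 3′ (in
  read orientation) of the broken bond.

## Coordinate conventions

All public coordinates are 1-based inclusive. Three span conventions
coexist deliberately: `strict_between` (bases strictly between two cut
sites — the protected length), `difference` (raw clockwise distance — the
width of a signal region), and `inclusive`. The midpoint of a clockwise
arc rounds half-integer centres toward the arc's first coordinate; the
rule only affects even-distance spans and makes centres deterministic.
`strict_between` of adjacent or identical positions is 0, never negative.

The signed centre offset is the shortest circular distance from the MNase
midpoint to the chemical centre, positive clockwise; the orientation is
arbitrary but fixed and documented.

## Cleavage-site tracks

5′-end pileups are shifted 1 bp *upstream in read orientation*: −1 in
reference coordinates for plus-strand reads, +1 for minus-strand reads.
The minus-strand direction follows from the chemistry — each strand's new
5′ end lies one base 3′ (in reference coordinates) of the broken bond —
and is isolated in a single function so the convention can be flipped.
Smoothing is a centred 7-bp moving average by default (odd windows only),
wrapping on circular maps (mass-conserving) and shrinking at linear map
edges. Occupancy tracks extend each read to a fixed `extsize` from its 5′
end in its own 3′ direction, truncated at linear boundaries. Counts are
floats so smoothed tracks reuse the same container. Effective read length
comes from the CIGAR reference-consumed length when present, else the
sequence length; paired-end data should be supplied as two single-end
strand-split groups.

## Gel calibration

The standard curve is piecewise-linear in migration vs. log10(size) —
classic semi-log gel behaviour; no global functional form is forced, so
local deviations are absorbed by the interpolation knots. Band centres
are local maxima (after optional 3-sample median smoothing) rather than
centroids, because maxima are robust to the asymmetric tails of agarose
lanes; a centroid mode exists. Baseline subtraction is off by default (raw
profiles are compared). Anchor-based base calibration is linear between
the two flanking anchors; beyond the outermost anchors or markers the
terminal segment is extended and the value *flagged* as extrapolated —
permitted because bands near gel ends are otherwise unassignable. Trace
orientation is inferred from the anchor ordering. Primer-extension calls
are shifted one base shorter than ladder calls (the untemplated 3′
addition by Taq polymerase); the correction applies only to
primer-extension lanes, since dideoxy-terminated ladder products and
indirect-end-label fragments do not carry the extra base.

Per-base resampling averages all trace samples whose calibrated coordinate
falls in `[b − 0.5, b + 0.5)` and fills uncovered bases by linear
interpolation, which conserves the trace integral to ≲2% at ≥10 samples
per base.

## Protected-region calling

Intensities are normalized to each set's total, and a naked site counts as
suppressed when the chromatin signal near it falls below
`suppression_ratio` (default 0.5) of the naked signal there. Both sides of
that comparison use the *maximum* normalized intensity within the same
±`match_tol` window (default ±3 bp, because band positions never match
exactly between lanes): a per-site threshold would inherit the sampling
noise of a single base and fragment footprints whenever one naked position
happens to draw a low count. Maximal runs of ≥`min_suppressed` suppressed
naked sites bounded by chromatin cuts become regions; midpoint and
strictly-between length derive from the bounding cuts.

The chemical centre is the intensity-weighted centroid along the window
arc (computed from clockwise offsets off the window start, so origin wrap
is exact), rounded to the nearest base with ties toward the lower
coordinate; an argmax mode is available. Zero signal inside a window and
an empty window raise distinct errors.

Classification thresholds default to: footprints >150 bp are
`wide_protection` (the core position inside is ambiguous); offsets ≤20 bp
are `consistent`; larger offsets are `shifted`, additionally flagged
`short_protection` when the footprint is ≤132 bp (core length 147 minus
15) — clearly shorter than a canonical core. All thresholds are
parameters.

NFR size is centre-to-centre distance minus `core_len` (default 147,
canonical octamer), floored at 0 and translation-invariant on circles.
With the study dyads 1,308 and 104 this gives 102 bp for any core in
145–147 (102–104 bp), slightly below the rounded "about 105 bp" figure;
the default is documented rather than tuned to reproduce the rounding.
Frame enumeration returns *every* ordered cut pair whose strictly-between
length is within `target ± tol` — overlapping frames are the point, as
they expose alternative nucleosome positions; slash-separated alternative
cut positions are treated as independent cuts.

## Synthetic data

The simulators generate every pipeline input with known ground truth:

* **Chemical reads** — dyad chosen by weight (alternative frames are extra
  placements), strand uniform, offset from a per-strand table; the read 5′
  end is placed so pileup → upstream shift recovers a cleavage at
  `dyad + offset` exactly. The default offset table is symmetric
  (±2 bp, probabilities 0.15/0.2/0.3/0.2/0.15) — a stand-in expressing
  "near the dyad", not a claim about the real per-strand chemistry, and
  fully configurable.
* **MNase cuts** — multinomial draws over per-base weights: uniform on
  naked DNA; `linker_cut_weight` (1.0) in linkers vs `core_cut_weight`
  (0.05, i.e. 20-fold protection) inside core footprints (dyad ±
  `core_len`//2) on chromatin; an optional A/T preference multiplies the
  weight where the base 5′ of the cut is A or T when sequence is supplied.
* **Gel lanes** — Gaussian bands at `intercept − slope·log10(size)` plus
  optional white noise; the primer-extension lane simulator renders known
  per-base intensities under a linear migration model and emits the
  matching ladder anchor set (on primer-extension lanes each band sits at
  the migration of base b+1, so calibration plus the Taq correction
  recovers b).

What the simulators do *not* emulate: sequence-derived nucleosome
affinities, transcription-coupled dynamics, MNase end-trimming (available
as an option but off by default), and NGS library-prep biases (end repair,
ligation, size selection, PCR). Passing recovery tests therefore
demonstrates the correctness of the analysis conventions and estimators
under the stated noise model, not robustness to every bias of real data.

All generators are deterministic given a seed; a frozen checksum test
guards the generator stream.

## Problem sizes and numerical choices

Tests use the study-scale problem sizes: 2,000 reads per dyad for chemical
centre recovery (±2 bp, including the origin-spanning dyad), 5,000 cuts
for footprint recovery (±5 bp), 20,000 reads for offset-histogram checks,
50,000 cuts for cut-weight convergence, and 200 random read sets for exact
brute-force oracle equivalence of the pileup operations. Mass conservation
of the shift and circular smoothing is asserted to 1e-9. The whole suite
runs in well under a minute on one CPU.

## Known limitations

* The fixture dyads for nucleosomes I and V–VII are placeholders at
  plausible spacing (flagged `from_literature=False`); only the dyads of
  nucleosomes II–IV and the printed cut coordinates are study values.
* Protected regions whose bounding runs reach the end of a linear map are
  dropped (no bounding cut exists); circular maps have no such edge.
* BED export splits origin-wrapping regions into two lines, since BED
  cannot represent wrapped intervals.
* The suppression caller assumes both cut sets are deep enough for the
  normalized comparison to be meaningful; single-digit counts per site
  make the footprint boundaries noisy at the ±match_tol scale.
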