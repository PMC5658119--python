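# nucmap

Gel-based **parallel mapping** of nucleosome positions: site-directed
chemical cleavage analysed side by side with micrococcal nuclease (MNase)
footprinting on circular yeast minichromosomes.

## The problem

MNase preferentially cuts the linker DNA between nucleosomes, so comparing
the digestion of chromatin with that of naked DNA delimits nucleosome
footprints — but MNase is sequence-biased, trims fragment ends, and cannot
say where inside a wide or short footprint the histone core actually sits.
Site-directed hydroxyl radicals generated at histone H4 S47C cut the DNA
backbone near the nucleosome *dyad* (the centre of the ~147-bp wrapped DNA),
locating the core directly. Run in parallel on the same nuclei, the two
readouts give both sides of each nucleosome: the linkers from MNase and the
centre from chemistry. `nucmap` implements the desk side of that analysis
for anyone mapping chromatin on a defined locus with gels and/or targeted
sequencing:

* **`nucmap.coords`** — 1-based circular coordinate arithmetic
  (wrapping, clockwise distances, span conventions, midpoints, fixed-offset
  genome↔plasmid conversion).
* **`nucmap.gelcal`** — lane densitometry to base coordinates: band
  detection, semi-log size-marker standard curves, anchor-band
  interpolation, the one-base Taq correction for primer-extension lanes,
  per-base resampling, and correlation against sequencing-derived tracks.
* **`nucmap.pileup`** — strand-resolved 5′-end pileups, the 1-bp upstream
  shift from read ends to broken bonds, replicate summing, 7-bp circular
  moving averages, extsize-style occupancy tracks, wiggle/bedGraph I/O.
* **`nucmap.nuccall`** — protected-region calling from naked-vs-chromatin
  cut suppression, intensity-weighted chemical dyad centres, signed
  centre offsets, classification (consistent / wide / shifted / short),
  nucleosome-free-region (NFR) sizes, and overlapping-frame enumeration.
* **`nucmap.synth`** — fully seeded forward simulators for every input
  (chemical reads, MNase cut sets, gel lanes) with known ground truth, plus
  the bundled 1,453-bp circular TRP1ARS1 minichromosome fixture.
* **`nucmap` CLI / `nucmap.pipeline`** — subcommands `simulate`, `pileup`,
  `gelcal`, `callnuc`, `frames`, `compare` and a config-driven `run` that
  writes a checksummed, reproducible manifest.

## Core quantities

With cut sites `l` and `r` flanking a footprint on a circle of length `L`
(all positions 1-based), the package computes

* protected length  `strict_between(l, r) = d(l, r) − 1` where
  `d(l, r) = (r − l) mod L` is the clockwise distance,
* footprint midpoint  `mid(l, r) = wrap(l + ⌊d(l, r)/2⌋)`,
* chemical centre  = intensity-weighted centroid of dyad-proximal cleavage
  inside a window (wrap-aware), and centre offset = signed shortest
  circular distance `chemical − mid`,
* NFR size between dyads `a, b` with a core of `c` bp:
  `max(d(a, b) − c, 0)`.

## Worked example

```python
>>> import nucmap as nm
>>> fx = nm.trp1ars1_fixture()
>>> m = fx.map                       # 1,453-bp circle, chrIV offset 461,740
>>> m.span_length(1077, 1187, "strict_between")   # nucleosome II footprint
109
>>> m.midpoint(1077, 1187)                        # its midpoint
1132
>>> nm.nfr_size(m, 1308, 104, core_len=147)       # gap between dyads III, IV
102
>>> spec = nm.ChromatinSpec(map=m, dyads=[nm.Dyad(104)])
>>> reads = nm.simulate_chemical_reads(spec, n=2000, seed=7)
>>> track = nm.moving_average(nm.to_cleavage_sites(nm.five_prime_track(reads, m)), 7)
>>> nm.chemical_center((m, nm.combine_strands(track)), (m.wrap(104-73), m.wrap(104+73)))
104
```

The footprint between cuts 1,077 and 1,187 is 109 bp with midpoint 1,132 —
a stably positioned nucleosome whose chemical centre coincides with the
MNase midpoint. The two dyads flanking the hypersensitive region sit 249 bp
apart, leaving a 102-bp nucleosome-free gap between canonical 147-bp cores.
The simulated chemical reads around the origin-spanning dyad at position
104 are recovered exactly by the pileup → shift → smooth → centroid path.

Command-line equivalent of the frame analysis (alternative overlapping
nucleosome positions from a cut list):

```
$ nucmap frames --cuts 1227,1246,1264,1271,1346,1362,1376,1388 \
    --map TRP1ARS1:1453:circular --target 115 --tol 10
left_cut  right_cut  length
1227      1346       118
1246      1362       115
1264      1376       111
...
```

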