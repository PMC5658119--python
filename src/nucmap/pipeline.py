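"""End-to-end orchestration: simulate -> pileup -> callnuc with a flat config
file and a reproducible run manifest.

The config is INI-style (one section per stage, ``key = value``); rerunning
with the same config and seed reproduces byte-identical outputs, which the
manifest records as SHA-256 checksums alongside per-stage record counts.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .coords import CircularSequenceMap
from .io import (
    write_call_table,
    write_cut_sites,
    write_read_table,
    write_regions_bed,
)
from .nuccall import (
    EmptyWindowError,
    ZeroSignalError,
    call_nucleosome,
    chemical_center,
    find_protected_regions,
    protected_region,
)
from .pileup import (
    combine_strands,
    five_prime_track,
    moving_average,
    to_cleavage_sites,
    write_bedgraph,
    write_wiggle,
)
from .synth import simulate_chemical_reads, simulate_mnase_cuts, trp1ars1_fixture

log = logging.getLogger("nucmap.pipeline")


class ConfigError(ValueError):
    """The run configuration is invalid; raised before any stage executes."""


class RunConfig:
    """Validated pipeline configuration parsed from a flat INI file."""

    def __init__(self, parser: configparser.ConfigParser, base_dir: Path):
        self.parser = parser
        self.base_dir = base_dir
        if not parser.has_section("output") or not parser.get("output", "dir", fallback=""):
            raise ConfigError("config requires [output] dir")
        self.outdir = (base_dir / parser.get("output", "dir")).resolve()
        self.simulate_enabled = parser.has_section("simulate")
        if self.simulate_enabled and parser.get("simulate", "seed", fallback="") == "":
            raise ConfigError("[simulate] requires a seed when simulation is enabled")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        parser = configparser.ConfigParser()
        if not parser.read(path):
            raise ConfigError(f"cannot read config {path}")
        return cls(parser, path.parent)

    def getint(self, section, key, default):
        return self.parser.getint(section, key, fallback=default)

    def getfloat(self, section, key, default):
        return self.parser.getfloat(section, key, fallback=default)

    def get(self, section, key, default=""):
        return self.parser.get(section, key, fallback=default)

    def build_map(self):
        if self.get("simulate", "fixture") == "trp1ars1" or not self.parser.has_section("map"):
            return None  # fixture map, resolved by run()
        sec = self.parser["map"]
        return CircularSequenceMap(
            name=sec.get("name", "map"),
            length=int(sec["length"]),
            topology=sec.get("topology", "circular"),
            genomic_offset=int(sec["genomic_offset"]) if sec.get("genomic_offset") else None,
            genomic_ref=sec.get("genomic_ref") or None,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig | str | Path) -> dict:
    """Execute the configured stages in dependency order and return the run
    manifest (also written as ``manifest.json`` in the output directory)."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_file(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {s: dict(config.parser[s]) for s in config.parser.sections()},
        "outputs": {},
        "counts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    fixture = None
    smap = config.build_map()
    if smap is None:
        fixture = trp1ars1_fixture()
        smap = fixture.map

    stage = "simulate"
    try:
        if not config.simulate_enabled:
            raise ConfigError("only simulation-driven runs are supported in this pipeline")
        seed = config.getint("simulate", "seed", 0)
        n_chem = config.getint("simulate", "n_chemical", 6000)
        n_mnase = config.getint("simulate", "n_mnase", 20000)
        read_length = config.getint("simulate", "read_length", 50)
        spec = fixture.chromatin if fixture is not None else None
        if spec is None:
            raise ConfigError("non-fixture simulation requires [simulate] fixture = trp1ars1")
        log.info("simulate: %d chemical reads, %d MNase cuts, seed %d", n_chem, n_mnase, seed)
        reads = simulate_chemical_reads(spec, n=n_chem, read_length=read_length, seed=seed)
        naked = simulate_mnase_cuts(spec, "naked", n=n_mnase, seed=seed + 1)
        chromatin = simulate_mnase_cuts(spec, "chromatin", n=n_mnase, seed=seed + 2)
        p_reads = outdir / "chemical_reads.tsv"
        write_read_table(reads, p_reads)
        record("chemical_reads", p_reads)
        p_naked = outdir / "naked_cuts.tsv"
        write_cut_sites(naked, p_naked)
        record("naked_cuts", p_naked)
        p_chrom = outdir / "chromatin_cuts.tsv"
        write_cut_sites(chromatin, p_chrom)
        record("chromatin_cuts", p_chrom)
        manifest["counts"]["simulate"] = {
            "chemical_reads": len(reads),
            "naked_cuts": int(naked.total()),
            "chromatin_cuts": int(chromatin.total()),
        }

        stage = "pileup"
        smooth_window = config.getint("pileup", "smooth_window", 7)
        track5 = five_prime_track(reads, smap)
        cleavage = to_cleavage_sites(track5)
        smoothed = moving_average(cleavage, smooth_window)
        p_wig = outdir / "chemical_smoothed.wig"
        write_wiggle(combine_strands(smoothed), smap, p_wig)
        record("chemical_smoothed_wig", p_wig)
        p_bg = outdir / "chemical_cleavage.bedgraph"
        write_bedgraph(combine_strands(cleavage), smap, p_bg)
        record("chemical_cleavage_bedgraph", p_bg)
        manifest["counts"]["pileup"] = {"reads": len(reads)}

        stage = "callnuc"
        ratio = config.getfloat("callnuc", "suppression_ratio", 0.5)
        min_sup = config.getint("callnuc", "min_suppressed", 2)
        match_tol = config.getint("callnuc", "match_tol", 3)
        regions = find_protected_regions(
            naked, chromatin, suppression_ratio=ratio,
            min_suppressed=min_sup, match_tol=match_tol,
        )
        p_bed = outdir / "protected_regions.bed"
        write_regions_bed(regions, smap, p_bed)
        record("protected_regions", p_bed)

        calls = []
        named = []
        if fixture is not None:
            labels = {
                "nucII": "NucII",
                "nucIII_top": "NucIII_top",
                "nucIII_bottom": "NucIII_bottom",
                "nucIV_top": "NucIV_top",
                "nucIV_bottom": "NucIV_bottom",
            }
            for key, label in labels.items():
                cs = fixture.cut_sets[key]
                left, right = int(cs.positions[0]), int(cs.positions[1])
                named.append((label, protected_region(smap, left, right)))
        for i, r in enumerate(regions):
            named.append((f"region_{i + 1}", r))
        for label, region in named:
            try:
                center = chemical_center(
                    (smap, combine_strands(smoothed)),
                    (region.left_cut, region.right_cut),
                )
            except (EmptyWindowError, ZeroSignalError):
                log.info("callnuc: no chemical signal for %s, skipping", label)
                continue
            calls.append(call_nucleosome(smap, label, center, region))
        p_calls = outdir / "nucleosome_calls.tsv"
        write_call_table(calls, p_calls)
        record("nucleosome_calls", p_calls)
        manifest["counts"]["callnuc"] = {"regions": len(regions), "calls": len(calls)}
    except ConfigError:
        raise
    except Exception as exc:  # annotate which stage failed
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    p_manifest = outdir / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
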