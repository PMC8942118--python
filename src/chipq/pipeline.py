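"""End-to-end orchestration from a single declarative run configuration.

A run config (YAML or dict) names either a set of simulation profiles or
real input files per sample, plus the analysis parameters; ``run`` executes
the stages in dependency order (simulate/load -> quantify -> rank ->
signal matrices & metagene profiles -> control-locus tracks -> motif
neighborhood scan -> liftover -> bound sets, Venn, category tallies,
distribution comparisons) and writes a machine-readable manifest with the
seed and a SHA-256 digest of every artifact.  Reruns with an identical
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import compare as cmp
from . import motifs as mot
from .genomic_io import (Genome, RegionSet, read_chain, read_fragments,
                         read_regions, liftover)
from .occupancy import QTable, QuantConfig, locus_signal, quantify, rank_regions, top_n
from .profiles import SignalMatrix, average_profile, signal_matrix, write_coverage_bedgraph
from .simulate import (PROFILES, SimConfig, make_category_table, make_genome,
                       simulate_chip, write_simulation)

logger = logging.getLogger(__name__)

__all__ = ["run", "load_config", "validate_config"]

DEFAULTS = {
    "quant": {"window_upstream": 500, "window_downstream": 500,
              "anchor": "gene_start", "rpm_normalize": True,
              "per_kb_normalize": False},
    "heatmap": {"flank": 10000, "bin_size": 50, "anchor": "gene_centre"},
    "motifs": {"flank": 20000, "min_p": mot.DEFAULT_MIN_P, "top": 19},
    "compare": {"threshold": 0.5, "top_n": 50},
}


class ConfigError(ValueError):
    """An invalid run configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> dict:
    cfg = dict(cfg)
    has_sim = "simulate" in cfg
    has_real = "samples" in cfg
    if has_sim == has_real:
        raise ConfigError("exactly one of 'simulate' or 'samples' is required")
    if has_real:
        if "regions" not in cfg:
            raise ConfigError("real-input runs need a 'regions' BED path")
        for sample in cfg["samples"]:
            if "name" not in sample or "fragments" not in sample:
                raise ConfigError("each sample needs 'name' and 'fragments'")
            if not Path(sample["fragments"]).exists():
                raise ConfigError(f"missing fragments file "
                                  f"{sample['fragments']!r}")
        for key in ("regions", "genome", "chain", "categories"):
            if key in cfg and cfg[key] and not Path(cfg[key]).exists():
                raise ConfigError(f"missing {key} file {cfg[key]!r}")
    for section, defaults in DEFAULTS.items():
        merged = dict(defaults)
        merged.update(cfg.get(section, {}) or {})
        cfg[section] = merged
    cfg.setdefault("seed", 0)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: Mapping[str, Any] | str | Path, outdir: str | Path | None = None
        ) -> dict:
    """Execute the pipeline described by ``config``; returns the manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = validate_config(config)
    out = Path(outdir or cfg.get("output_dir", "chipq_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}
    stages: list[str] = []

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # ---- stage: inputs -------------------------------------------------
    samples: dict[str, Any] = {}
    genome: Genome | None = None
    categories = None
    truth = None
    if "simulate" in cfg:
        stages.append("simulate")
        sim_cfg = SimConfig(**{**(cfg["simulate"].get("config") or {}),
                               "seed": seed})
        genome, annotations, truth = make_genome(sim_cfg)
        regions = annotations["tdna"]
        profiles = cfg["simulate"].get("profiles", ["mcf7_like"])
        for i, profile in enumerate(profiles):
            if profile not in PROFILES:
                raise ConfigError(f"unknown simulation profile {profile!r}")
            frags, chip_truth = simulate_chip(
                annotations, genome.chrom_lengths, sim_cfg, truth,
                profile=profile, seed=seed + 1 + i)
            samples[profile] = frags
            sdir = out / "sim" / profile
            sdir.mkdir(parents=True, exist_ok=True)
            chip_truth.to_json(sdir / "truth.json")
            record(f"sim/{profile}/truth", sdir / "truth.json")
        for kind, rs in annotations.items():
            p = out / "sim" / f"{kind}.bed"
            p.parent.mkdir(exist_ok=True)
            rs.to_bed(p)
            record(f"sim/{kind}.bed", p)
        categories = make_category_table(regions, seed=seed)
        control = annotations.get("control")
    else:
        stages.append("load")
        regions = read_regions(cfg["regions"], cfg.get("regions_format", "BED6"),
                               assembly=cfg.get("assembly", ""))
        for sample in cfg["samples"]:
            samples[sample["name"]] = read_fragments(
                sample["fragments"], sample.get("format"),
                single_end_extension=sample.get("single_end_extension", 200))
        genome = Genome.from_fasta(cfg["genome"]) if cfg.get("genome") else None
        categories = cmp.CategoryTable.from_tsv(cfg["categories"]) \
            if cfg.get("categories") else None
        control = None

    # ---- stage: quantify ----------------------------------------------
    stages.append("quantify")
    qcfg = QuantConfig(**cfg["quant"])
    qtables: dict[str, QTable] = {}
    for name, frags in samples.items():
        qt = rank_regions(quantify(frags, regions, qcfg))
        qtables[name] = qt
        p = out / f"{name}.qtable.tsv"
        qt.to_tsv(p)
        record(f"{name}.qtable", p)

    # ---- stage: profiles ------------------------------------------------
    stages.append("profiles")
    hm = cfg["heatmap"]
    for name, frags in samples.items():
        m = signal_matrix(frags, regions, order=qtables[name],
                          flank=hm["flank"], bin_size=hm["bin_size"],
                          anchor=hm["anchor"])
        p = out / f"{name}.heatmap.tsv"
        m.to_tsv(p)
        record(f"{name}.heatmap", p)
        prof = average_profile(m)
        pp = out / f"{name}.profile.tsv"
        with open(pp, "w") as fh:
            fh.write("offset\tmean_rpm\n")
            for mid, v in zip(m.bin_midpoints, prof):
                fh.write(f"{mid:g}\t{v:.6g}\n")
        record(f"{name}.profile", pp)

    # ---- stage: control-locus tracks ------------------------------------
    if control is not None and len(control):
        stages.append("tracks")
        for name, frags in samples.items():
            for iv in control:
                p = out / f"{name}.{iv.name}.bedgraph"
                write_coverage_bedgraph(p, frags, iv, flank=2500)
                record(f"{name}.{iv.name}.track", p)

    # ---- stage: motif scan ----------------------------------------------
    if genome is not None:
        stages.append("motifs")
        mo = cfg["motifs"]
        first = next(iter(qtables.values()))
        n_top = min(int(mo["top"]), len(first))
        scan_regions = top_n(first, n_top, regions)
        report = mot.scan_neighborhood(genome, scan_regions,
                                       flank=mo["flank"], min_p=mo["min_p"])
        p = out / "motif_hits.tsv"
        report.to_gff_tsv(p)
        record("motif_hits", p)
        p2 = out / "motif_presence.tsv"
        report.presence.to_csv(p2, sep="\t")
        record("motif_presence", p2)

    # ---- stage: liftover ------------------------------------------------
    excluded: set[str] = set()
    if cfg.get("chain"):
        stages.append("liftover")
        chain = read_chain(cfg["chain"], source_assembly=regions.assembly)
        lift = liftover(regions, chain)
        excluded = set(lift.unmapped)
        p = out / "remapped.bed"
        lift.mapped.to_bed(p)
        record("remapped", p)
        with open(out / "liftover.json", "w") as fh:
            json.dump({"remap_rate": lift.remap_rate,
                       "unmapped": lift.unmapped}, fh, indent=1)
        record("liftover", out / "liftover.json")

    # ---- stage: comparative ---------------------------------------------
    stages.append("comparative")
    comp = cfg["compare"]
    bound = {name: sorted(cmp.bound_set(qt, comp["threshold"], exclude=excluded))
             for name, qt in qtables.items()}
    with open(out / "bound_sets.json", "w") as fh:
        json.dump({"threshold": comp["threshold"], "sets": bound}, fh, indent=1)
    record("bound_sets", out / "bound_sets.json")
    if 2 <= len(qtables) <= 3:
        vres = cmp.venn({k: set(v) for k, v in bound.items()})
        vres.threshold = comp["threshold"]
        with open(out / "venn.json", "w") as fh:
            json.dump(vres.to_dict(), fh, indent=1)
        record("venn", out / "venn.json")
    if categories is not None:
        n = min(comp["top_n"], len(next(iter(qtables.values()))))
        for name, qt in qtables.items():
            tallies, detail = cmp.classify_top(top_n(qt, n, regions),
                                               categories, qt)
            p = out / f"{name}.categories.json"
            with open(p, "w") as fh:
                json.dump(tallies, fh, indent=1)
            record(f"{name}.categories", p)
            detail.to_csv(out / f"{name}.categories.tsv", sep="\t", index=False)
            record(f"{name}.categories.detail", out / f"{name}.categories.tsv")
    if len(qtables) >= 2:
        results = cmp.compare_q_distributions(qtables)
        df = cmp.comparison_table(results)
        p = out / "comparisons.tsv"
        df.to_csv(p, sep="\t", index=False)
        record("comparisons", p)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": seed,
        "stages": stages,
        "artifacts": {name: {"path": path, "sha256": _sha256(Path(path))}
                      for name, path in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
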