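"""End-to-end pipeline: simulate -> annotate -> chip-call -> mfa -> rnai.

The pipeline is configured from a YAML file (unknown keys rejected) and
writes a JSON run manifest recording package version, seeds, stage
parameters and input digests, so identical config + inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, annotation, chip, mfa, rnai, simulate
from . import io as oio


@dataclass
class PipelineConfig:
    out_dir: str = "orcmap_out"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "annotate", "chip", "mfa", "rnai"]
    )
    simulation: dict = field(default_factory=dict)
    chip_params: dict = field(default_factory=dict)
    mfa_params: dict = field(default_factory=dict)
    rnai_params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> simulate.SimulationConfig:
        cfg = simulate.SimulationConfig(**self.simulation)
        cfg.validate()
        return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the manifest (also written to disk).

    A stage failure raises with a stage-scoped message.  Disabling the chip
    stage degrades gracefully: the MFA colocalization step reports sites as
    unavailable and the pipeline continues.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
        "parameters": {
            "simulation": config.simulation,
            "chip": config.chip_params,
            "mfa": config.mfa_params,
            "rnai": config.rnai_params,
        },
        "outputs": {},
    }
    state: dict = {}

    def stage(name: str):
        return name in config.stages

    try:
        if stage("simulate"):
            cfg = config.simulation_config()
            _, genes, truth = simulate.generate_genome(cfg, seed=config.seed)
            state.update(cfg=cfg, genes=genes, truth=truth)
            oio.write_genes_gff3(genes, out / "genes.gff3")
            oio.write_chrom_lengths(cfg.chromosomes, out / "chrom_lengths.tsv")
            manifest["stages"].append("simulate")
            manifest["outputs"]["genes"] = "genes.gff3"
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    try:
        if stage("annotate"):
            cfg = state["cfg"]
            genes = state["genes"]
            tracks = {}
            for chrom, length in cfg.chromosomes.items():
                cgenes = [g for g in genes if g.chromosome == chrom]
                tracks[chrom] = annotation.demarcate_chromosome(cgenes, length)
            dgcs, ssrs = [], []
            for chrom in cfg.chromosomes:
                core = [
                    g
                    for g in genes
                    if g.chromosome == chrom
                    and tracks[chrom].class_at(g.midpoint) == "core"
                ]
                d = annotation.build_dgcs(core)
                dgcs.extend(d)
                ssrs.extend(annotation.classify_ssrs(d))
            state.update(tracks=tracks, dgcs=dgcs, ssrs=ssrs)
            oio.write_region_bed(tracks, out / "regions.bed")
            oio.write_features_gff3(dgcs, ssrs, state["truth"].cassettes, out / "features.gff3")
            manifest["stages"].append("annotate")
            manifest["outputs"]["regions"] = "regions.bed"
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc

    try:
        if stage("chip"):
            cfg = state["cfg"]
            probes = simulate.simulate_chip(state["truth"], cfg, seed=config.seed + 1)
            sites = chip.call_sites(probes, seed=config.seed + 2, **config.chip_params)
            state["sites"] = sites
            oio.write_probe_tsv(probes, out / "probes.tsv")
            oio.write_sites_bed(sites, out / "sites.bed")
            assoc = chip.associate_sites_with_regions(
                sites, state["tracks"], state["ssrs"], state["dgcs"],
                state["truth"].cassettes,
            )
            for name, table in assoc.items():
                oio.write_tsv(table, out / f"association_{name}.tsv")
            manifest["stages"].append("chip")
            manifest["outputs"]["sites"] = "sites.bed"
    except Exception as exc:
        raise RuntimeError(f"stage chip failed: {exc}") from exc

    try:
        if stage("mfa"):
            cfg = state["cfg"]
            s_tracks, g2_tracks = simulate.simulate_replication(
                state["truth"], cfg, seed=config.seed + 3
            )
            peaks = []
            ratio_tracks = {}
            for chrom in cfg.chromosomes:
                rt = mfa.ratio_and_normalize(
                    mfa.bin_depth(s_tracks[chrom]),
                    mfa.bin_depth(g2_tracks[chrom]),
                    chromosome=chrom,
                )
                ratio_tracks[chrom] = rt
                peaks.extend(mfa.call_obr_peaks(rt, **config.mfa_params))
            state.update(peaks=peaks, ratio_tracks=ratio_tracks)
            with open(out / "obr_peaks.tsv", "w") as fh:
                fh.write("name\tchromosome\tcenter\tamplitude\tleft_slope\t"
                         "right_slope\tsymmetry\n")
                for p in peaks:
                    fh.write(
                        f"{p.name}\t{p.chromosome}\t{p.center:.0f}\t{p.amplitude:.3f}"
                        f"\t{p.left_slope:.3e}\t{p.right_slope:.3e}\t{p.symmetry}\n"
                    )
            summary = mfa.replicated_fraction(ratio_tracks, state.get("tracks"))
            if "sites" in state:
                merged = chip.merge_sites(state["sites"])
                coloc = mfa.colocalize_peaks_with_features(peaks, merged)
                manifest["outputs"]["colocalization"] = {
                    "n_matched": coloc["n_matched"],
                    "n_peaks": coloc["n_peaks"],
                }
            else:
                manifest["outputs"]["colocalization"] = "sites unavailable"
            manifest["outputs"]["replicated_fraction"] = summary.replicated_fraction
            manifest["stages"].append("mfa")
    except Exception as exc:
        raise RuntimeError(f"stage mfa failed: {exc}") from exc

    try:
        if stage("rnai"):
            cfg = state["cfg"]
            induced, uninduced = simulate.simulate_rnai(
                state["truth"], cfg, seed=config.seed + 4
            )
            fold_frames = []
            for chrom in cfg.chromosomes:
                genes = [
                    g for g in state["genes"]
                    if g.chromosome == chrom and g.category != "hypothetical"
                ]
                i_n, u_n = rnai.quantile_normalize(induced[chrom], uninduced[chrom])
                fold_frames.append(
                    rnai.gene_fold_changes(i_n, u_n, genes, **config.rnai_params)
                )
            import pandas as pd

            folds = pd.concat(fold_frames, ignore_index=True)
            oio.write_tsv(folds, out / "gene_fold_changes.tsv")
            manifest["outputs"]["n_significant_genes"] = int(folds["significant"].sum())
            manifest["stages"].append("rnai")
    except Exception as exc:
        raise RuntimeError(f"stage rnai failed: {exc}") from exc

    manifest["input_digests"] = {
        p.name: _digest(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
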