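"""End-to-end pipeline: simulate -> preprocess -> scan -> windows ->
consensus -> annotate -> bayescan, driven by one validated config mapping.

Defaults equal the scan's standard parameters: MAF 0.05, LD pruning 50/5/0.5,
PI-HAT 0.25 (commercial) / 0.1 (local), EHH max gap 500 kb, significance
threshold -log10 p = 3 with 3/4/4 markers per window for iHS/Rsb/XP-EHH,
1-Mb windows on a 10-kb grid, q <= 0.05 for the FST outlier arm.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, bayescan, ehh, io_formats, preprocess, windows
from .datatypes import (AlleleCountMatrix, FeatureSet, HaplotypeMatrix,
                        PopulationMap, RegionSet)
from .simulate import SimulationConfig, SimulatedDataset, simulate_outgroups, \
    simulate_wright_fisher, write_dataset

logger = logging.getLogger("sweepscan")

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level", "inputs", "simulate", "preprocess",
    "scan", "windows", "consensus", "annotate", "bayescan",
}
_STAGE_DEFAULTS = {
    "preprocess": {"maf": 0.05, "ld_window": 50, "ld_step": 5, "ld_r2": 0.5,
                   "pihat_commercial": 0.25, "pihat_local": 0.1,
                   "skip_relatedness": False, "skip_ld": False},
    "scan": {"focal_group": "NorthAFT", "ref_groups": ["AFT"],
             "max_gap_bp": 500_000, "ehh_cutoff": 0.05},
    "windows": {"size_bp": 1_000_000, "step_bp": 10_000, "threshold": 3.0},
    "consensus": {"min_methods": 2},
    "annotate": {"genes": None, "qtl": None, "sv": None, "max_sv_mb": 8.0},
    "bayescan": {"reduced": True, "q_max": 0.05},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "sweepscan_out"
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)  # vcf/haps/popmap/outgroups paths
    stages: dict = field(default_factory=dict)  # stage name -> params or None

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        stages = {}
        for name, defaults in _STAGE_DEFAULTS.items():
            if name in raw:
                params = dict(defaults)
                extra = raw[name] or {}
                bad = set(extra) - set(defaults)
                if bad and name != "simulate":
                    raise ValueError(f"unknown key(s) in stage {name!r}: {sorted(bad)}")
                params.update(extra)
                stages[name] = params
        if "simulate" in raw:
            stages["simulate"] = raw["simulate"] or {}
        return cls(seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "sweepscan_out")),
                   log_level=str(raw.get("log_level", "INFO")),
                   inputs=raw.get("inputs", {}) or {}, stages=stages)


def _load_inputs(inputs: dict) -> tuple[HaplotypeMatrix, PopulationMap, Optional[object]]:
    if "vcf" in inputs:
        matrix = io_formats.read_phased_vcf(inputs["vcf"])
    elif "haps" in inputs:
        matrix = io_formats.read_haps(inputs["haps"], inputs["sample"])
    else:
        raise ValueError("inputs must provide 'vcf' or 'haps'/'sample'")
    popmap = io_formats.read_population_map(inputs["popmap"])
    popmap.check_covers(matrix.sample_ids)
    matrix.pop_labels = [popmap.population_of(s) for s in matrix.sample_ids]
    outgroups = (io_formats.read_outgroup_alleles(inputs["outgroups"])
                 if "outgroups" in inputs else None)
    return matrix, popmap, outgroups


def _group_counts(matrix: HaplotypeMatrix, popmap: PopulationMap,
                  groups: list[str]) -> AlleleCountMatrix:
    derived, total = [], []
    for g in groups:
        sub = preprocess.pool_haplotypes(matrix, popmap, g)
        derived.append(sub.haplotypes.sum(axis=0))
        total.append(np.full(sub.n_markers, sub.n_haplotypes))
    return AlleleCountMatrix(np.stack(derived, axis=1), np.stack(total, axis=1),
                             list(matrix.markers["marker_id"]), groups)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Returns the manifest mapping; every stage appends its parameters and a
    marker/sample accounting so the counts reconcile across stages.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {"sweepscan_version": __version__, "seed": config.seed,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": []}
    matrix = popmap = outgroups = None
    dataset: Optional[SimulatedDataset] = None
    tracks: list = []
    region_sets: list[RegionSet] = []

    if "simulate" in config.stages:
        params = dict(config.stages["simulate"])
        params.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**params)
        dataset = simulate_wright_fisher(sim_cfg)
        simulate_outgroups(dataset, concordance=0.95, seed=sim_cfg.seed + 1)
        paths = write_dataset(dataset, outdir / "simulated")
        matrix, popmap = dataset.haplotypes, dataset.population_map
        outgroups = dataset.outgroup_alleles
        manifest["stages"].append({"stage": "simulate", "params": asdict(sim_cfg),
                                   "outputs": paths,
                                   "n_markers": matrix.n_markers,
                                   "n_samples": matrix.n_samples})
        logger.info("simulate: %d samples x %d markers", matrix.n_samples,
                    matrix.n_markers)

    if matrix is None and config.inputs:
        matrix, popmap, outgroups = _load_inputs(config.inputs)
        import hashlib
        manifest["input_sha256"] = {
            key: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for key, p in config.inputs.items()}
    if matrix is None and config.stages:
        raise ValueError("no input data: enable the simulate stage or set inputs")

    if "preprocess" in config.stages:
        pp = config.stages["preprocess"]
        reports = []
        if not pp["skip_relatedness"]:
            estimates = preprocess.estimate_pi_hat(matrix)
            kept, rep = preprocess.relatedness_filter(
                estimates, popmap,
                thresholds={"commercial": pp["pihat_commercial"],
                            "north_african": pp["pihat_local"]})
            matrix = matrix.subset_samples(kept)
            reports.append(rep)
        matrix, rep = preprocess.maf_filter(matrix, pp["maf"])
        reports.append(rep)
        if not pp["skip_ld"]:
            matrix, rep = preprocess.ld_prune(matrix, pp["ld_window"],
                                              pp["ld_step"], pp["ld_r2"])
            reports.append(rep)
        if outgroups is not None:
            matrix, rep = preprocess.infer_ancestral(matrix, outgroups)
            reports.append(rep)
        if not all(r.reconciles() for r in reports):
            raise RuntimeError("filter report does not reconcile")
        io_formats.write_phased_vcf(matrix, outdir / "filtered.vcf")
        manifest["stages"].append({"stage": "preprocess",
                                   "params": pp,
                                   "reports": [r.to_dict() for r in reports],
                                   "n_markers": matrix.n_markers,
                                   "n_samples": matrix.n_samples})
        logger.info("preprocess: %d markers, %d samples retained",
                    matrix.n_markers, matrix.n_samples)

    if "scan" in config.stages:
        sc = config.stages["scan"]
        focal = preprocess.pool_haplotypes(matrix, popmap, sc["focal_group"])
        track = ehh.ihs_scan(focal, sc["max_gap_bp"], sc["ehh_cutoff"])
        io_formats.write_scores(track, outdir / "scores_ihs.tsv")
        tracks.append(track)
        ies_focal = ehh.ies_scan(focal, sc["max_gap_bp"], sc["ehh_cutoff"])
        for ref in sc["ref_groups"]:
            pooled = preprocess.pool_haplotypes(matrix, popmap, ref)
            ies_ref = ehh.ies_scan(pooled, sc["max_gap_bp"], sc["ehh_cutoff"])
            for scan_fn, name in ((ehh.rsb_scan, "rsb"), (ehh.xpehh_scan, "xpehh")):
                track = scan_fn(ies_ref, ies_focal, contrast=ref)
                io_formats.write_scores(track, outdir / f"scores_{name}_{ref}.tsv")
                tracks.append(track)
        manifest["stages"].append({"stage": "scan",
                                   "params": sc,
                                   "tracks": [f"{t.test}/{t.contrast or 'none'}"
                                              for t in tracks],
                                   "n_markers": matrix.n_markers})
        logger.info("scan: %d score tracks", len(tracks))

    if "windows" in config.stages:
        wc = config.stages["windows"]
        chrom_lengths = {str(c): int(sub["pos_bp"].max())
                         for c, sub in matrix.markers.groupby("chrom")}
        grid = windows.make_windows(chrom_lengths, wc["size_bp"], wc["step_bp"])
        for track in tracks:
            classified = windows.classify_windows(grid, track, wc["threshold"])
            regions = windows.merge_windows_to_regions(classified, track.test,
                                                       track.contrast)
            region_sets.append(regions)
            tag = f"{track.test}_{track.contrast or 'none'}"
            io_formats.write_regions(regions, outdir / f"regions_{tag}.bed")
        manifest["stages"].append({"stage": "windows", "params": wc,
                                   "n_windows": len(grid),
                                   "n_regions": [len(r) for r in region_sets]})

    if "consensus" in config.stages and region_sets:
        cc = config.stages["consensus"]
        cons = windows.consensus_regions(region_sets, cc["min_methods"])
        io_formats.write_regions(cons, outdir / "consensus.bed")
        manifest["stages"].append({"stage": "consensus", "params": cc,
                                   "n_regions": len(cons)})
        logger.info("consensus: %d regions", len(cons))

        if "annotate" in config.stages:
            ac = config.stages["annotate"]
            feats = []
            for kind, key in (("gene", "genes"), ("QTL", "qtl"), ("SV", "sv")):
                if ac.get(key):
                    feats.extend(io_formats.read_features(ac[key], kind))
            ann = windows.annotate_regions(
                cons, FeatureSet(feats),
                max_sv_length_bp=int(ac["max_sv_mb"] * 1e6))
            with open(outdir / "annotated.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tmethods\tfeatures\n")
                for region, fs in ann.items():
                    tags = ",".join(sorted(t for t, _ in region.methods))
                    names = ",".join(f.name for f in fs)
                    fh.write(f"{region.chrom}\t{region.start_bp}\t"
                             f"{region.end_bp}\t{tags}\t{names}\n")
            manifest["stages"].append({"stage": "annotate", "params": ac,
                                       "n_regions": len(ann)})

    if "bayescan" in config.stages:
        bc = config.stages["bayescan"]
        sc = config.stages.get("scan", _STAGE_DEFAULTS["scan"])
        groups = [sc["focal_group"]] + list(sc["ref_groups"])
        counts = _group_counts(matrix, popmap, groups)
        settings = (bayescan.McmcSettings.reduced(seed=config.seed)
                    if bc["reduced"] else bayescan.McmcSettings(seed=config.seed))
        chains = bayescan.rjmcmc_run(counts, settings)
        result = bayescan.outlier_result(chains, bc["q_max"])
        result.table.to_csv(outdir / "bayescan.tsv", sep="\t", index=False)
        n_out = int(result.table["outlier"].sum())
        manifest["stages"].append({"stage": "bayescan",
                                   "params": {"reduced": bc["reduced"],
                                              "q_max": bc["q_max"]},
                                   "n_loci": counts.n_loci,
                                   "n_outliers": n_out})
        logger.info("bayescan: %d outliers at q<=%.2f", n_out, bc["q_max"])

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
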