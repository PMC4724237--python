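"""End-to-end pipeline driver and configuration.

Stages run in the order simulate -> timing -> domains -> profiles ->
seqfeatures -> contacts; every threshold used is recorded in a JSON
manifest so a run is fully reproducible from its config.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BinnedTrack, GenomicInterval, IntervalSet
from . import contacts as ct
from . import domain_arch as da
from . import genome_model as gm
from . import io as rio
from . import profiles as pr
from . import seqfeatures as sf
from . import timing as tm

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds and stage toggles, with paper-anchored defaults."""

    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_timing: bool = True
    run_domains: bool = True
    run_profiles: bool = True
    run_seqfeatures: bool = True
    run_contacts: bool = True
    # timing
    pseudocount: float = 0.5
    early_thr: float = 0.5
    late_thr: float = -0.5
    delta_thr: float = 1.0
    loess_span_bp: int = 300_000
    tile_bp: int = 60
    min_domain_len_bp: int = 200_000
    # domain calling
    gap_penalty: float = 4.0
    n_perm: int = 200
    fdr: float = 0.05
    min_lamin_frac: float = 0.5
    # profiles
    n_body_bins: int = 40
    flank_bp: int = 200_000
    n_flank_bins: int = 20
    k_clusters: int = 4
    # seqfeatures
    sns_half_width_bp: int = 5_000
    delta_half_width_bp: int = 250_000
    tss_overlap_bp: int = 1_000
    rt_class_bin_bp: int = 200_000
    # contacts
    min_rpm: float = 10.0
    rpm_edges: Tuple[float, float, float] = (10.0, 200.0, float("inf"))
    call_factor: float = 3.0
    vp_zone_bp: int = 10_000
    # synthetic genome overrides (passed to SyntheticGenomeSpec)
    genome: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.early_thr <= self.late_thr:
            raise ValueError("early_thr must exceed late_thr")
        if self.delta_thr <= 0:
            raise ValueError("delta_thr must be positive")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 < self.min_lamin_frac <= 1):
            raise ValueError("min_lamin_frac must lie in (0, 1]")

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rpm_edges" in data:
            data = dict(data)
            data["rpm_edges"] = tuple(
                float("inf") if str(v).lower() in ("inf", "infinity") else float(v)
                for v in data["rpm_edges"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_manifest_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["rpm_edges"] = [("inf" if np.isinf(v) else v) for v in self.rpm_edges]
        return d


def _switch_calls_bed(path: Path, calls: List[tm.SwitchCall]) -> None:
    rio.write_bed(
        path,
        [c.interval for c in calls],
        names=[c.switch_class for c in calls],
        scores=[int(np.clip(round(abs(c.delta_rt) * 1000), 0, 1000)) for c in calls],
    )


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute the configured stages; returns the manifest dictionary.

    Outputs are deterministic functions of the config, so reruns with the
    same config produce byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config": config.to_manifest_dict(),
        "stages": [],
        "outputs": [],
    }

    def _done(stage: str, paths: List[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(sorted(str(p.relative_to(out)) for p in paths))

    if not config.run_simulate:
        raise ValueError("the pipeline driver currently requires the simulate stage")

    spec = gm.SyntheticGenomeSpec(seed=config.seed, **config.genome)
    sequences, truth = gm.simulate_genome(spec)
    assays = gm.simulate_replication_assays(spec, truth)
    libs = gm.simulate_4c_libraries(spec, truth, sequences) if spec.n_viewpoints else None

    paths: List[Path] = []
    rio.write_fasta(out / "genome.fa", sequences)
    paths.append(out / "genome.fa")
    rio.write_bed(out / "truth_rads.bed", truth.rads)
    rio.write_bed(out / "truth_lads.bed", truth.lads)
    rio.write_bed(
        out / "truth_switches.bed",
        [iv for iv, _ in truth.switch_classes],
        names=[cls for _, cls in truth.switch_classes],
    )
    paths += [out / "truth_rads.bed", out / "truth_lads.bed", out / "truth_switches.bed"]
    for genotype in ("wt", "ko"):
        rio.write_bedgraph(out / f"early_{genotype}.bedgraph", assays.early[genotype])
        rio.write_bedgraph(out / f"late_{genotype}.bedgraph", assays.late[genotype])
        paths += [out / f"early_{genotype}.bedgraph", out / f"late_{genotype}.bedgraph"]
    for factor in ("rif1", "laminB1"):
        rio.write_bedgraph(out / f"chip_{factor}.bedgraph", assays.chip[factor])
        paths.append(out / f"chip_{factor}.bedgraph")
    rio.write_bedgraph(out / "chip_input.bedgraph", assays.chip_input)
    paths.append(out / "chip_input.bedgraph")
    rio.write_bed(
        out / "truth_tss.bed",
        [GenomicInterval(c, p, p + 1) for c, p, _ in truth.tss],
        names=["cpg_island" if isl else "plain" for _, _, isl in truth.tss],
    )
    rio.write_bed(
        out / "truth_sns.bed", [GenomicInterval(c, p, p + 1) for c, p in truth.sns]
    )
    paths += [out / "truth_tss.bed", out / "truth_sns.bed"]
    if libs is not None:
        rio.write_bed(
            out / "viewpoints.bed",
            [GenomicInterval(v.chrom, v.pos, v.pos + 1) for v in truth.viewpoints],
            names=[v.name for v in truth.viewpoints],
        )
        paths.append(out / "viewpoints.bed")
        for (vp_name, genotype, rep), counts in sorted(libs.counts.items()):
            p = out / f"4c_{vp_name}_{genotype}_rep{rep}.tsv"
            rio.write_fragment_counts(p, counts, libs.fragment_map.fragments)
            paths.append(p)
    _done("simulate", paths)

    # --- timing -----------------------------------------------------------
    rt: Dict[str, Dict[str, BinnedTrack]] = {"wt": {}, "ko": {}}
    enr: Dict[str, Dict[str, BinnedTrack]] = {"rif1": {}, "laminB1": {}}
    for chrom in spec.chrom_lengths:
        for genotype in ("wt", "ko"):
            rt[genotype][chrom] = tm.compute_rt(
                assays.early[genotype][chrom],
                assays.late[genotype][chrom],
                config.pseudocount,
            )
        for factor in ("rif1", "laminB1"):
            enr[factor][chrom] = tm.compute_rt(
                assays.chip[factor][chrom], assays.chip_input[chrom], config.pseudocount
            )

    domains_by_chrom: Dict[str, List[tm.RTDomain]] = {}
    calls: List[tm.SwitchCall] = []
    if config.run_timing:
        paths = []
        for genotype in ("wt", "ko"):
            smooth = {
                c: tm.loess_smooth(t, config.loess_span_bp)
                for c, t in rt[genotype].items()
            }
            rio.write_bedgraph(out / f"rt_{genotype}.bedgraph", rt[genotype])
            rio.write_bedgraph(out / f"rt_{genotype}_smooth.bedgraph", smooth)
            paths += [out / f"rt_{genotype}.bedgraph", out / f"rt_{genotype}_smooth.bedgraph"]
        dist = {
            g: tm.rt_distribution(list(rt[g].values()), tile_bp=config.tile_bp)
            for g in ("wt", "ko")
        }
        pd.DataFrame(
            {
                "genotype": ["wt", "ko"],
                "bimodality": [dist["wt"].bimodality, dist["ko"].bimodality],
                "n_tiles": [dist["wt"].n_tiles, dist["ko"].n_tiles],
            }
        ).to_csv(out / "rt_distribution.tsv", sep="\t", index=False)
        paths.append(out / "rt_distribution.tsv")
        all_domains: List[tm.RTDomain] = []
        for chrom in sorted(spec.chrom_lengths):
            doms = tm.segment_rt_domains(
                rt["wt"][chrom],
                config.early_thr,
                config.late_thr,
                config.min_domain_len_bp,
            )
            domains_by_chrom[chrom] = doms
            all_domains += doms
            calls += tm.classify_switches(
                rt["wt"][chrom], rt["ko"][chrom], doms, config.delta_thr
            )
        rio.write_bed(
            out / "rt_domains_wt.bed",
            [d.interval for d in all_domains],
            names=[d.rt_class for d in all_domains],
        )
        _switch_calls_bed(out / "switch_calls.bed", calls)
        paths += [out / "rt_domains_wt.bed", out / "switch_calls.bed"]
        _done("timing", paths)

    # --- domain architecture ---------------------------------------------
    rads: List[GenomicInterval] = []
    if config.run_domains:
        paths = []
        for chrom in sorted(spec.chrom_lengths):
            for d in da.call_broad_domains(
                enr["rif1"][chrom],
                gap_penalty=config.gap_penalty,
                n_perm=config.n_perm,
                fdr=config.fdr,
                seed=config.seed,
            ):
                rads.append(d.interval)
        rad_set = IntervalSet(rads)
        venn = da.overlap_venn(rad_set, truth.lads)
        lb_plus, lb_minus = da.partition_rads(rads, truth.lads, config.min_lamin_frac)
        late_set = IntervalSet(
            [
                d.interval
                for doms in domains_by_chrom.values()
                for d in doms
                if d.rt_class == "late"
            ]
        )
        rows = [
            {"metric": "rad_bp", "value": rad_set.total_bp},
            {"metric": "lad_bp", "value": truth.lads.total_bp},
            {"metric": "shared_bp", "value": venn.shared_bp},
            {"metric": "jaccard", "value": venn.jaccard},
            {"metric": "n_rad_lb_plus", "value": len(lb_plus)},
            {"metric": "n_rad_lb_minus", "value": len(lb_minus)},
        ]
        if len(late_set):
            cov = da.late_genome_coverage(late_set, rad_set, truth.lads)
            rows += [
                {"metric": "late_frac_rads", "value": cov.frac_rads},
                {"metric": "late_frac_lads", "value": cov.frac_lads},
                {"metric": "late_frac_union", "value": cov.frac_union},
            ]
        pd.DataFrame(rows).to_csv(out / "domain_summary.tsv", sep="\t", index=False)
        rio.write_bed(out / "rads_called.bed", rads)
        scatter, summary = da.enrichment_by_switch_class(calls, enr["rif1"], enr["laminB1"])
        scatter.to_csv(out / "switch_enrichment.tsv", sep="\t", index=False)
        paths += [out / "domain_summary.tsv", out / "rads_called.bed", out / "switch_enrichment.tsv"]
        _done("domains", paths)

    # --- profiles ---------------------------------------------------------
    if config.run_profiles:
        paths = []
        lad_list = sorted(truth.lads)
        meta = pr.meta_domain_matrix(
            lad_list,
            enr["rif1"],
            n_body_bins=config.n_body_bins,
            flank_bp=config.flank_bp,
            n_flank_bins=config.n_flank_bins,
        )
        k = min(config.k_clusters, max(2, len(lad_list)))
        sol = pr.cluster_rows(meta, k=k, seed=config.seed)
        rt_rows = [rt["wt"][iv.chrom].mean_over(iv.start, iv.end) for iv in lad_list]
        ko_rows = [rt["ko"][iv.chrom].mean_over(iv.start, iv.end) for iv in lad_list]
        summary = pr.cluster_rt_summary(sol, rt_rows, ko_rows)
        meta.to_frame().to_csv(out / "lad_meta_matrix.tsv", sep="\t")
        pd.DataFrame(
            {"domain": meta.row_ids, "cluster": sol.labels}
        ).to_csv(out / "lad_clusters.tsv", sep="\t", index=False)
        summary.to_csv(out / "lad_cluster_rt.tsv", sep="\t", index=False)
        paths += [out / "lad_meta_matrix.tsv", out / "lad_clusters.tsv", out / "lad_cluster_rt.tsv"]
        _done("profiles", paths)

    # --- sequence features -------------------------------------------------
    if config.run_seqfeatures:
        paths = []
        rows = []
        hw = config.sns_half_width_bp
        for chrom, pos in truth.sns:
            lo = max(0, pos - hw)
            hi = min(len(sequences[chrom]), pos + hw)
            feat = sf.window_features(sequences[chrom], GenomicInterval(chrom, lo, hi))
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "gc": feat.gc_fraction,
                    "cpg_ratio": feat.cpg_ratio,
                    "n_g4": feat.n_g4,
                    "n_ogre": feat.n_ogre,
                }
            )
        pd.DataFrame(rows).to_csv(out / "sns_features.tsv", sep="\t", index=False)
        strata, _rate = sf.stratify_loci(
            truth.sns,
            [(c, p) for c, p, _ in truth.tss],
            rt["wt"],
            overlap_bp=config.tss_overlap_bp,
            rt_bin_bp=config.rt_class_bin_bp,
            early_thr=config.early_thr,
            late_thr=config.late_thr,
        )
        strata.to_csv(out / "sns_strata.tsv", sep="\t", index=False)
        paths += [out / "sns_features.tsv", out / "sns_strata.tsv"]
        _done("seqfeatures", paths)

    # --- contacts ----------------------------------------------------------
    if config.run_contacts and libs is not None:
        paths = []
        sets: Dict[str, Dict[str, ct.ContactSet]] = {"wt": {}, "ko": {}}
        for vp in truth.viewpoints:
            for genotype in ("wt", "ko"):
                rpms = []
                for rep in (1, 2):
                    rpm, _ = ct.rpm_normalize(
                        libs.counts[(vp.name, genotype, rep)],
                        libs.fragment_map,
                        vp.chrom,
                        vp.pos,
                        exclude_bp=config.vp_zone_bp,
                    )
                    rpms.append(rpm)
                sets[genotype][vp.name] = ct.call_contacts(
                    rpms[0],
                    rpms[1],
                    libs.fragment_map,
                    vp.name,
                    vp.chrom,
                    vp.pos,
                    min_rpm=config.min_rpm,
                    call_factor=config.call_factor,
                )
        summary = ct.rpm_bin_compare(sets["wt"], sets["ko"], edges=config.rpm_edges)
        summary.per_viewpoint.to_csv(out / "contacts_rpm_bins.tsv", sep="\t", index=False)
        scope_rows = []
        for vp in truth.viewpoints:
            for genotype in ("wt", "ko"):
                cis, intra = ct.classify_scope(sets[genotype][vp.name], vp.rt_domain)
                scope_rows.append(
                    {"viewpoint": vp.name, "genotype": genotype, "cis": cis, "intra": intra}
                )
        pd.DataFrame(scope_rows).to_csv(out / "contacts_scope.tsv", sep="\t", index=False)
        for genotype in ("wt", "ko"):
            rows = []
            for vp in truth.viewpoints:
                cons = sets[genotype][vp.name].consistent()
                for _, r in cons.iterrows():
                    rows.append(
                        GenomicInterval(str(r["chrom"]), int(r["start"]), int(r["end"]))
                    )
            rio.write_bed(out / f"contacts_{genotype}.bed", rows)
            paths.append(out / f"contacts_{genotype}.bed")
        paths += [out / "contacts_rpm_bins.tsv", out / "contacts_scope.tsv"]
        _done("contacts", paths)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
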