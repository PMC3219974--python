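"""End-to-end orchestration: simulate -> call -> map -> overlap -> enrich -> annotate.

Each stage is a function over a :class:`PipelineConfig` that reads its inputs
from, and writes its outputs to, the configured output directory, so the CLI
subcommands and :func:`run_pipeline` compose to identical results.  All
randomness flows from the single config seed through named substreams; the
JSON report is byte-identical across reruns except for its timestamp field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .calling import CallerParams, call_cnvs, merge_sample_calls
from .core import AcghSample, CnvInterval, GenomeModel, OverlapCriteria, TruthTable
from .functional import (GeneIndex, ScoreTrack, compare_k_distributions,
                         conservation_compare, expression_proportions,
                         genic_context_table, genic_enrichment,
                         positive_selection_fraction)
from .liftover import map_cnv_set
from .overlap import (classify_complex, collapse_hotspots, find_three_species_overlaps,
                      find_two_species_overlaps, hotspot_summary)
from .permutation import enrichment_test, null_overlap_distribution
from .synthetic import (derive_sample_events, make_block_map, make_genome,
                        make_probe_layout, simulate_acgh_sample,
                        simulate_annotations_and_scores, simulate_multispecies_cnvs)

logger = logging.getLogger("cnvhotspots")

# named substream indices off the config seed, one per consumer of randomness
_STREAMS = {"genome": 0, "probes": 1, "cnvs": 2, "events": 3, "samples": 4,
            "blockmap": 5, "annotations": 6, "null_hc": 7, "null_hr": 8,
            "null_hcr": 9, "genic": 10}


def _stream_seed(seed: int, name: str) -> int:
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS[name]]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one YAML-serialisable document."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # genome / probes
    n_chromosomes: int = 3
    mean_chrom_length: int = 5_000_000
    gap_fraction: float = 0.05
    probe_spacing: int = 3_000
    # CNV simulation
    n_hotspots: int = 8
    n_human: int = 400
    n_chimp: int = 120
    n_macaque: int = 150
    size_law_log_mean: float = 9.5
    size_law_log_sd: float = 1.2
    hotspot_share: float = 0.3
    noise_sd: float = 0.15
    n_samples: int = 8
    # block map
    use_block_map: bool = True
    block_size: int = 200_000
    drop_fraction: float = 0.07
    min_mapped_fraction: float = 0.95
    # annotations
    n_genes: int = 400
    genic_bias: float = 5.0
    k_effect: float = 0.3
    cons_effect: float = 0.15
    de_boost: float = 2.0
    # caller
    z_threshold: float = 2.0
    min_probes: int = 5
    min_abs_mean_log2: float = 0.3
    max_interrupt: int = 0
    # overlap criteria
    pairwise_fraction: float = 0.5
    three_way_pair_fraction: float = 0.2
    three_way_total_fraction: float = 0.5
    anchor: str = "human"
    merge_gap: int = 0
    # enrichment / annotation
    n_iter: int = 200
    k_threshold: float = 0.05
    promoter_bp: int = 2_000

    def criteria(self) -> OverlapCriteria:
        return OverlapCriteria(pairwise_fraction=self.pairwise_fraction,
                               three_way_pair_fraction=self.three_way_pair_fraction,
                               three_way_total_fraction=self.three_way_total_fraction,
                               anchor=self.anchor)

    def caller_params(self) -> CallerParams:
        return CallerParams(z_threshold=self.z_threshold, min_probes=self.min_probes,
                            min_abs_mean_log2=self.min_abs_mean_log2,
                            max_interrupt=self.max_interrupt)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    return {k: out / v for k, v in {
        "sizes": "genome.chrom.sizes", "gaps": "gaps.bed", "probes": "probes.tsv",
        "samples": "samples.tsv", "human": "human_cnvs.bed", "chimp": "chimp_cnvs.bed",
        "truth_hotspots": "truth_hotspots.tsv", "truth_cnvs": "truth_cnvs.tsv",
        "truth_events": "truth_events.tsv", "block_map": "block_map.tsv",
        "genes": "genes.bed12", "k_table": "k_values.tsv",
        "expression": "expression.tsv", "conservation": "conservation.bedgraph",
        "calls": "macaque_calls.tsv", "macaque_loci": "macaque_loci.bed",
        "macaque_mapped": "macaque_mapped.bed", "hc": "hc_cnvs.bed",
        "hr": "hr_cnvs.bed", "hcr": "hcr_cnvs.bed", "hotspots": "hotspot_regions.bed",
        "hotspots_json": "hotspot_regions.json",
        "stage_call": "stage_call.json", "stage_map": "stage_map.json",
        "stage_overlap": "stage_overlap.json", "stage_enrich": "stage_enrich.json",
        "stage_annotate": "stage_annotate.json", "report": "report.json",
    }.items()}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate genome, probes, CNV sets, per-sample aCGH data and annotation tracks."""
    t0 = time.monotonic()
    p = _paths(cfg)
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    genome = make_genome(cfg.n_chromosomes, cfg.mean_chrom_length, cfg.gap_fraction,
                         seed=_stream_seed(cfg.seed, "genome"))
    io.write_genome(genome, p["sizes"], p["gaps"], config_hash=h)
    layout = make_probe_layout(genome, cfg.probe_spacing,
                               seed=_stream_seed(cfg.seed, "probes"))
    io.write_tsv(layout.probes, p["probes"], config_hash=h)

    cnv_sets, truth = simulate_multispecies_cnvs(
        genome, cfg.n_hotspots, (cfg.n_human, cfg.n_chimp, cfg.n_macaque),
        size_law=(cfg.size_law_log_mean, cfg.size_law_log_sd),
        hotspot_share=cfg.hotspot_share, seed=_stream_seed(cfg.seed, "cnvs"),
        criteria=cfg.criteria())
    io.write_bed(cnv_sets["human"], p["human"], config_hash=h)
    io.write_bed(cnv_sets["chimp"], p["chimp"], config_hash=h)
    io.write_tsv(truth.hotspots, p["truth_hotspots"], config_hash=h)
    io.write_tsv(truth.cnvs, p["truth_cnvs"], config_hash=h)

    events = derive_sample_events(truth, species="macaque", n_samples=cfg.n_samples,
                                  seed=_stream_seed(cfg.seed, "events"))
    io.write_tsv(events, p["truth_events"], config_hash=h)

    sample_frames = []
    sample_seed = _stream_seed(cfg.seed, "samples")
    for i in range(cfg.n_samples):
        sid = f"macaque_{i:02d}"
        evs = [((r.chrom, int(r.start), int(r.end)), float(r.log2_shift))
               for r in events.itertuples(index=False) if r.sample == sid]
        sample = simulate_acgh_sample(layout, evs, cfg.noise_sd,
                                      seed=sample_seed + i, sample_id=sid)
        df = sample.data.copy()
        df.insert(0, "sample", sid)
        sample_frames.append(df)
    io.write_tsv(pd.concat(sample_frames, ignore_index=True), p["samples"], config_hash=h)

    # macaque hotspot CNVs must survive the orthology map
    keep = [(r.chrom, int(r.start), int(r.end))
            for r in truth.cnvs[(truth.cnvs.species == "macaque")
                                & (truth.cnvs.hotspot_id != "")].itertuples(index=False)]
    block_map = make_block_map(genome, block_size=cfg.block_size,
                               drop_fraction=cfg.drop_fraction,
                               seed=_stream_seed(cfg.seed, "blockmap"),
                               keep_intervals=keep)
    io.write_block_map(block_map, p["block_map"], config_hash=h)

    genes, k_table, cons_track, expr_table = simulate_annotations_and_scores(
        genome, cfg.n_genes, truth, genic_bias=cfg.genic_bias, k_effect=cfg.k_effect,
        cons_effect=cfg.cons_effect, de_boost=cfg.de_boost,
        seed=_stream_seed(cfg.seed, "annotations"))
    io.write_genes_bed12(genes, p["genes"], config_hash=h)
    io.write_tsv(k_table, p["k_table"], config_hash=h)
    io.write_score_track(cons_track, p["conservation"], config_hash=h)
    io.write_tsv(expr_table, p["expression"], config_hash=h)
    logger.info("simulate: %d probes, %d/%d/%d CNVs in %.1fs", len(layout),
                cfg.n_human, cfg.n_chimp, cfg.n_macaque, time.monotonic() - t0)


def stage_call(cfg: PipelineConfig) -> None:
    """Call macaque CNVs per sample and merge them into loci."""
    t0 = time.monotonic()
    p = _paths(cfg)
    h = cfg.config_hash()
    samples_df = io.read_tsv(p["samples"])
    params = cfg.caller_params()
    all_calls = []
    for sid, sub in samples_df.groupby("sample", sort=True):
        sample = AcghSample(sample_id=str(sid),
                            data=sub[["chrom", "pos", "log2"]].reset_index(drop=True))
        all_calls.extend(call_cnvs(sample, params))
    loci = merge_sample_calls(all_calls)
    calls_df = pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end, "sample": c.sample_id,
          "direction": c.direction, "n_probes": c.n_probes,
          "mean_log2": round(c.mean_log2, 6)} for c in all_calls])
    io.write_tsv(calls_df, p["calls"], config_hash=h)
    loci_cnvs = [CnvInterval(id=f"macaque_locus_{i:05d}", chrom=l.chrom, start=l.start,
                             end=l.end, species="macaque", state=l.state)
                 for i, l in enumerate(loci)]
    io.write_bed(loci_cnvs, p["macaque_loci"], config_hash=h)
    io.write_json_report({"n_calls": len(all_calls), "n_loci": len(loci),
                          "n_multiallelic": sum(1 for l in loci if l.state == "multiallelic")},
                         p["stage_call"])
    logger.info("call: %d calls -> %d loci in %.1fs", len(all_calls), len(loci),
                time.monotonic() - t0)


def stage_map(cfg: PipelineConfig) -> None:
    """Map macaque loci onto the human coordinate system through the block map."""
    t0 = time.monotonic()
    p = _paths(cfg)
    h = cfg.config_hash()
    loci = io.read_bed(p["macaque_loci"])
    if cfg.use_block_map:
        block_map = io.read_block_map(p["block_map"])
        mapped, fraction, tally = map_cnv_set(block_map, loci, cfg.min_mapped_fraction)
    else:
        mapped, fraction, tally = list(loci), 1.0, {"mapped": len(loci),
                                                    "unmapped": 0, "split": 0,
                                                    "low_coverage": 0,
                                                    "total": len(loci)}
    io.write_bed(mapped, p["macaque_mapped"], config_hash=h)
    io.write_json_report({"mapped_fraction": fraction, "tally": tally}, p["stage_map"])
    logger.info("map: %d/%d loci mapped (%.1f%%) in %.1fs", tally["mapped"],
                tally["total"], 100 * fraction, time.monotonic() - t0)


def stage_overlap(cfg: PipelineConfig) -> None:
    """Identify HC/HR/HCR CNVs, complex CNVs, and collapsed hotspot regions."""
    t0 = time.monotonic()
    p = _paths(cfg)
    h = cfg.config_hash()
    human = io.read_bed(p["human"])
    chimp = io.read_bed(p["chimp"])
    macaque = io.read_bed(p["macaque_mapped"])
    criteria = cfg.criteria()

    hc = find_two_species_overlaps(human, chimp, criteria)
    hr = find_two_species_overlaps(human, macaque, criteria)
    hcr = find_three_species_overlaps(human, chimp, macaque, criteria)

    complex_flags = dict(zip((c.id for c in human), classify_complex(human)))
    hc_ids = {a.cnv.id for a in hc}
    hr_ids = {a.cnv.id for a in hr}
    hcr_ids = {a.cnv.id for a in hcr}

    def complex_fraction(ids):
        if not ids:
            return None
        return sum(1 for i in ids if complex_flags[i]) / len(ids)

    partner_map = {c.id: (c.chrom, c.start, c.end) for c in chimp + macaque}
    regions = collapse_hotspots(hcr, merge_gap=cfg.merge_gap,
                                partner_intervals=partner_map,
                                complex_flags=complex_flags)
    io.write_bed([a.cnv for a in hc], p["hc"], config_hash=h)
    io.write_bed([a.cnv for a in hr], p["hr"], config_hash=h)
    io.write_bed([a.cnv for a in hcr], p["hcr"], config_hash=h)
    region_cnvs = [CnvInterval(id=f"hotspot_region_{i:04d}", chrom=r.chrom,
                               start=r.start, end=r.end, species="human")
                   for i, r in enumerate(regions)]
    io.write_bed(region_cnvs, p["hotspots"], config_hash=h)
    io.write_json_report(
        {"regions": [{"id": f"hotspot_region_{i:04d}", "chrom": r.chrom,
                      "start": r.start, "end": r.end, "members": r.member_ids,
                      "species_counts": r.species_counts, "complex": r.complex}
                     for i, r in enumerate(regions)]},
        p["hotspots_json"])
    io.write_json_report(
        {"n_human": len(human), "n_chimp": len(chimp), "n_macaque_mapped": len(macaque),
         "n_hc": len(hc), "n_hr": len(hr), "n_hcr": len(hcr),
         "n_hotspot_regions": len(regions),
         "complex_fraction_all": complex_fraction({c.id for c in human}),
         "complex_fraction_hc": complex_fraction(hc_ids),
         "complex_fraction_hr": complex_fraction(hr_ids),
         "complex_fraction_hcr": complex_fraction(hcr_ids)},
        p["stage_overlap"])
    logger.info("overlap: |HC|=%d |HR|=%d |HCR|=%d -> %d regions in %.1fs",
                len(hc), len(hr), len(hcr), len(regions), time.monotonic() - t0)


def stage_enrich(cfg: PipelineConfig) -> None:
    """Size-matched permutation nulls and fold enrichment for HC, HR and HCR counts."""
    t0 = time.monotonic()
    p = _paths(cfg)
    genome = io.read_genome(p["sizes"], p["gaps"])
    human = io.read_bed(p["human"])
    chimp = io.read_bed(p["chimp"])
    macaque = io.read_bed(p["macaque_mapped"])
    counts = json.loads(Path(p["stage_overlap"]).read_text())
    criteria = cfg.criteria()
    sizes = [c.length for c in human]
    results = {}
    for key, targets, observed, stream in (
            ("hc", [chimp], counts["n_hc"], "null_hc"),
            ("hr", [macaque], counts["n_hr"], "null_hr"),
            ("hcr", [chimp, macaque], counts["n_hcr"], "null_hcr")):
        if all(len(t) for t in targets):
            null = null_overlap_distribution(sizes, targets, criteria,
                                             n_iter=cfg.n_iter, genome=genome,
                                             seed=_stream_seed(cfg.seed, stream))
            results[key] = enrichment_test(observed, null).to_dict()
        else:
            results[key] = None
    io.write_json_report(results, p["stage_enrich"])
    logger.info("enrich: %s in %.1fs",
                {k: (None if v is None else round(v["fold"], 2))
                 for k, v in results.items()}, time.monotonic() - t0)


def stage_annotate(cfg: PipelineConfig) -> None:
    """Genic context, genic enrichment, selection, conservation and expression."""
    t0 = time.monotonic()
    p = _paths(cfg)
    genome = io.read_genome(p["sizes"], p["gaps"])
    human = io.read_bed(p["human"])
    hcr = io.read_bed(p["hcr"])
    regions = io.read_bed(p["hotspots"])
    genes = io.read_genes_bed12(p["genes"])
    k_table = io.read_tsv(p["k_table"])
    expr_table = io.read_tsv(p["expression"])
    track = ScoreTrack(io.read_score_track(p["conservation"]))
    index = GeneIndex(genes, promoter_bp=cfg.promoter_bp)

    report: dict = {}
    hcr_ids = {c.id for c in hcr}
    non_hcr = [c for c in human if c.id not in hcr_ids]

    ctx = genic_context_table(hcr, genes, promoter_bp=cfg.promoter_bp)
    report["hcr_genic_context"] = ctx["context"].value_counts().to_dict()
    summary = hotspot_summary(
        [_region_from_cnv(r) for r in regions],
        gene_intervals=[(g.chrom, g.start, g.end) for g in genes])
    summary.pop("regions")
    report["hotspot_summary"] = summary

    if hcr:
        report["hcr_genic_enrichment"] = genic_enrichment(
            hcr, genes, genome, n_iter=cfg.n_iter,
            seed=_stream_seed(cfg.seed, "genic")).to_dict()
    else:
        report["hcr_genic_enrichment"] = None

    genes_hcr = sorted({g for c in hcr
                        for g in index.overlapping_genes(c.chrom, c.start, c.end)})
    genes_h = sorted({g for c in human
                      for g in index.overlapping_genes(c.chrom, c.start, c.end)})
    report["n_genes_hcr"] = len(genes_hcr)
    report["n_genes_h"] = len(genes_h)
    report["positive_selection_hcr"] = positive_selection_fraction(
        genes_hcr, k_table, cfg.k_threshold)
    report["positive_selection_h"] = positive_selection_fraction(
        genes_h, k_table, cfg.k_threshold)
    if genes_hcr and genes_h:
        report["k_comparison"] = compare_k_distributions(genes_hcr, genes_h,
                                                         k_table).to_dict()
    else:
        report["k_comparison"] = None

    if hcr and non_hcr:
        cons = conservation_compare(hcr, non_hcr, track)
        report["conservation"] = {"test": cons["test"].to_dict(),
                                  "mean_hcr": cons["mean_a"],
                                  "mean_non_hcr": cons["mean_b"]}
    else:
        report["conservation"] = None

    if genes_hcr and genes_h:
        expr = expression_proportions(genes_hcr, genes_h, expr_table)
        report["expression"] = {
            "n_hotspot": expr["n_hotspot"], "n_background": expr["n_background"],
            "categories": {cat: {"proportion_hotspot": e["proportion_hotspot"],
                                 "proportion_background": e["proportion_background"],
                                 "p_value": None if e["test"] is None
                                 else e["test"].p_value}
                           for cat, e in expr["categories"].items()}}
    else:
        report["expression"] = None
    io.write_json_report(report, p["stage_annotate"])
    logger.info("annotate: %d HCR genes vs %d H genes in %.1fs",
                len(genes_hcr), len(genes_h), time.monotonic() - t0)


def _region_from_cnv(c: CnvInterval):
    from .core import HotspotRegion
    return HotspotRegion(chrom=c.chrom, start=c.start, end=c.end, member_ids=[c.id],
                         species_counts={}, complex=False)


def stage_report(cfg: PipelineConfig) -> dict:
    """Merge the per-stage JSON blocks into the single run report."""
    p = _paths(cfg)
    report = {
        "software": f"cnvhotspots {__version__}",
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for key in ("stage_call", "stage_map", "stage_overlap", "stage_enrich",
                "stage_annotate"):
        path = p[key]
        report[key.removeprefix("stage_")] = (
            json.loads(Path(path).read_text()) if Path(path).exists() else None)
    io.write_json_report(report, p["report"])
    return report


_STAGES = (("simulate", stage_simulate), ("call", stage_call), ("map", stage_map),
           ("overlap", stage_overlap), ("enrich", stage_enrich),
           ("annotate", stage_annotate))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the merged run report."""
    for name, fn in _STAGES:
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return stage_report(config)
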