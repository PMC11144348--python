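"""End-to-end orchestration of the discovery pipeline.

These functions are the library's top layer: detect prophages heuristically
across a genome collection, integrate multi-method reports into a
Table-style region report, and compute the similarity matrix with ICTV
clusterings. Each stage logs input/output counts so the detection funnel
(per-method call counts down to the final consensus set) can be audited.

Configuration is a plain dataclass, loadable from YAML; the example scripts
under ``examples/`` show typical use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io as pk_io
from .consensus import (
    ConsensusParams,
    ConsensusRegion,
    apply_support_rule,
    assess_quality,
    match_calls,
    name_regions,
    support_matrix,
)
from .detector import DetectorParams, annotate_gene_roles, detect_prophages, detection_report
from .morphology import classify_morphology, detect_defence_systems, score_gene_order
from .records import AnnotatedGenome, DetectionReport
from .similarity import AlignParams, ClusterParams, cluster_at_threshold, similarity_matrix

logger = logging.getLogger("prophagekit")

__all__ = ["PipelineConfig", "run_detect", "run_integrate", "run_similarity"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run."""

    annotation_paths: List[str] = field(default_factory=list)
    annotation_format: str = "genbank"
    report_paths: Dict[str, str] = field(default_factory=dict)  # method -> TSV
    prophage_fasta: Optional[str] = None
    output_dir: str = "prophagekit_out"
    aliases: Dict[str, str] = field(default_factory=dict)
    detector: DetectorParams = field(default_factory=DetectorParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    align: AlignParams = field(default_factory=AlignParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("detector", DetectorParams),
            ("consensus", ConsensusParams),
            ("align", AlignParams),
            ("cluster", ClusterParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _load_annotations(config: PipelineConfig) -> Dict[str, AnnotatedGenome]:
    genomes = {}
    for path in config.annotation_paths:
        ann = pk_io.read_annotations(path, format=config.annotation_format)
        genomes[ann.id] = ann
    return genomes


def run_detect(
    config: PipelineConfig,
    annotations: Optional[Dict[str, AnnotatedGenome]] = None,
) -> DetectionReport:
    """Run the manual-inspection heuristic over every genome.

    Returns the combined report (method ``manual_heuristic``) and writes it
    as a detector-report TSV into the output directory.
    """
    annotations = annotations if annotations is not None else _load_annotations(config)
    if not annotations:
        raise ValueError("run_detect needs annotated genomes")
    per_genome = []
    for gid, ann in sorted(annotations.items()):
        if not ann.genes:
            logger.warning("detect: genome %s has no genes; 0 calls", gid)
            per_genome.append([])
            continue
        candidates = detect_prophages(ann, config.detector)
        logger.info("detect: genome %s -> %d candidate(s)", gid, len(candidates))
        per_genome.append(candidates)
    report = detection_report(per_genome)
    logger.info("detect: %d call(s) total over %d genome(s)",
                len(report), len(annotations))
    pk_io.write_detector_report(report, config.outdir() / "manual_heuristic.tsv")
    return report


def run_integrate(
    config: PipelineConfig,
    reports: Optional[List[DetectionReport]] = None,
    annotations: Optional[Dict[str, AnnotatedGenome]] = None,
) -> List[ConsensusRegion]:
    """Match calls, apply the support rule, gate on quality and characterise.

    Produces the region-table TSV, the support-matrix TSV and the extracted
    prophage multi-FASTA in the output directory.
    """
    if reports is None:
        reports = [
            pk_io.read_detector_report(path, method)
            for method, path in sorted(config.report_paths.items())
        ]
    if not reports:
        raise ValueError("run_integrate needs at least one detection report")
    annotations = annotations if annotations is not None else _load_annotations(config)

    regions = match_calls(reports, config.consensus, annotations or None,
                          config.detector)
    logger.info("integrate: %d call(s) -> %d matched region(s)",
                sum(len(r) for r in reports), len(regions))
    regions = apply_support_rule(regions, config.consensus)
    logger.info("integrate: %d region(s) after support rule", len(regions))

    kept: List[ConsensusRegion] = []
    for region in regions:
        ann = annotations.get(region.genome_id) if annotations else None
        if ann is None:
            kept.append(region)
            continue
        region.quality = assess_quality(region, ann)
        if region.quality.tier == "rejected":
            logger.info(
                "integrate: rejected %s:%d-%d (no viral genes)",
                region.genome_id, region.interval.start_bp, region.interval.end_bp,
            )
            continue
        genes = ann.genes_in(region.interval)
        region.cds_count = len(genes)
        region.gc_pct = pk_io.gc_content(
            pk_io.extract_region(ann.genome, region.interval).sequence
        )
        sub = AnnotatedGenome(genome=ann.genome, genes=[])
        sub.genes = genes
        roles = [t.role for t in annotate_gene_roles(sub)]
        region.morphology = classify_morphology(roles).morphology
        region.intact = score_gene_order(roles).intact
        region.defence_systems = [
            f"{hit.system}({','.join(hit.component_genes)})"
            for hit in detect_defence_systems(genes)
        ]
        kept.append(region)
    name_regions(kept, config.aliases)
    logger.info("integrate: %d region(s) in final report", len(kept))

    outdir = config.outdir()
    pk_io.write_region_table(kept, outdir / "region_table.tsv")
    support_matrix(kept).to_csv(outdir / "support_matrix.tsv", sep="\t", index=False)
    if annotations:
        extracted = [
            pk_io.extract_region(annotations[r.genome_id].genome, r.interval)
            for r in kept
            if r.genome_id in annotations
        ]
        for rec, region in zip(extracted, kept):
            rec.id = region.name or rec.id
        if extracted:
            pk_io.write_genome_fasta(extracted, outdir / "prophage_regions.fasta")
    return kept


def run_similarity(config: PipelineConfig, records=None):
    """All-vs-all similarity and clustering at genus/species thresholds.

    Returns (matrix, {threshold: ClusterAssignment}); writes matrix and
    per-threshold cluster TSVs.
    """
    if records is None:
        if not config.prophage_fasta:
            raise ValueError("run_similarity needs a prophage FASTA or records")
        records = pk_io.read_genome_fasta(config.prophage_fasta)
    if len(records) < 2:
        raise ValueError("similarity needs at least 2 records")
    matrix = similarity_matrix(records, config.align)
    outdir = config.outdir()
    matrix.write_tsv(outdir / "similarity_matrix.tsv")
    assignments = {}
    for threshold in (config.cluster.genus_threshold, config.cluster.species_threshold):
        assignment = cluster_at_threshold(matrix, threshold)
        assignments[threshold] = assignment
        sizes = sorted(assignment.sizes().values(), reverse=True)
        logger.info("similarity: threshold %.0f%% -> %d cluster(s), sizes %s",
                    threshold, len(sizes), sizes[:10])
        assignment.to_dataframe().to_csv(
            outdir / f"clusters_{int(threshold)}.tsv", sep="\t", index=False
        )
    return matrix, assignments
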