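"""Multi-detector consensus: call matching, the >=2-method support rule with
the manual-only exception, quality gating and region naming.

Calls from different detection methods are considered the same region when
they overlap reciprocally (overlap/len >= r on both sides); connected
components of that graph become consensus regions. Regions supported by at
least ``min_support`` methods are kept; a region supported only by the manual
heuristic is kept but flagged ``manual_only`` for downstream judgement, since
real pipelines have accepted such regions case by case.

Quality is a CheckV-style proxy: a region with no recognisable viral gene is
rejected outright; completeness is the fraction of the ten canonical
structural roles present, tiered high (>90), medium (50-90) or low (<50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import networkx as nx
import pandas as pd

from .detector import (
    CANONICAL_STRUCTURAL_ROLES,
    CandidateRegion,
    DetectorParams,
    MANUAL_METHOD_NAME,
    annotate_gene_roles,
    refine_boundaries,
)
from .records import AnnotatedGenome, DetectionReport, Interval

__all__ = [
    "ConsensusParams",
    "QualityAssessment",
    "ConsensusRegion",
    "match_calls",
    "apply_support_rule",
    "assess_quality",
    "name_regions",
    "support_matrix",
]


@dataclass(frozen=True)
class ConsensusParams:
    min_support: int = 2
    reciprocal_overlap: float = 0.5
    allow_manual_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class QualityAssessment:
    viral_gene_count: int
    completeness_pct: float
    tier: str  # rejected | low | medium | high


@dataclass
class ConsensusRegion:
    genome_id: str
    interval: Interval
    support_methods: set
    manual_only: bool = False
    quality: Optional[QualityAssessment] = None
    cds_count: int = 0
    gc_pct: float = float("nan")
    morphology: Optional[str] = None
    intact: bool = False
    defence_systems: List[str] = field(default_factory=list)
    name: str = ""

    @property
    def length_kb(self) -> float:
        return self.interval.length_bp / 1000.0


def match_calls(
    reports: List[DetectionReport],
    params: ConsensusParams = ConsensusParams(),
    annotations: Optional[Dict[str, AnnotatedGenome]] = None,
    detector_params: DetectorParams = DetectorParams(),
) -> List[ConsensusRegion]:
    """Merge calls across methods into consensus regions.

    Two calls on the same genome are linked when their reciprocal overlap is
    >= ``params.reciprocal_overlap``; connected components become regions
    whose interval is the union span of member intervals. When annotations
    are supplied, each merged interval gets one boundary-refinement pass.
    Output is sorted by (genome_id, start) and independent of input order.
    """
    calls = [c for rep in reports for c in rep.calls]
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    by_genome: Dict[str, List[int]] = {}
    for idx, c in enumerate(calls):
        by_genome.setdefault(c.genome_id, []).append(idx)
    for idxs in by_genome.values():
        for a_pos, a in enumerate(idxs):
            for b in idxs[a_pos + 1 :]:
                ro = calls[a].interval.reciprocal_overlap(calls[b].interval)
                if ro >= params.reciprocal_overlap:
                    g.add_edge(a, b)
    regions = []
    for comp in nx.connected_components(g):
        members = [calls[i] for i in comp]
        interval = Interval(
            min(c.interval.start_bp for c in members),
            max(c.interval.end_bp for c in members),
        )
        genome_id = members[0].genome_id
        if annotations and genome_id in annotations:
            interval = _refine_interval(
                interval, annotations[genome_id], detector_params
            )
        regions.append(
            ConsensusRegion(
                genome_id=genome_id,
                interval=interval,
                support_methods={c.method for c in members},
                manual_only=False,
            )
        )
    regions.sort(key=lambda r: (r.genome_id, r.interval.start_bp, r.interval.end_bp))
    return regions


def _refine_interval(
    interval: Interval, ann: AnnotatedGenome, detector_params: DetectorParams
) -> Interval:
    genes = ann.genes_in(interval)
    if not genes:
        return interval
    candidate = CandidateRegion(
        genome_id=ann.id,
        interval=Interval(genes[0].start_bp, genes[-1].end_bp),
        gene_ids=[g.feature_id for g in genes],
    )
    refined = refine_boundaries(candidate, ann, detector_params)
    return refined.interval


def apply_support_rule(
    regions: List[ConsensusRegion], params: ConsensusParams = ConsensusParams()
) -> List[ConsensusRegion]:
    """Keep regions with enough method support.

    Regions with >= ``min_support`` distinct methods pass. A region supported
    only by the manual heuristic is kept (flagged ``manual_only``) when
    ``allow_manual_only``; any other under-supported region is dropped.
    """
    kept = []
    for r in regions:
        if len(r.support_methods) >= params.min_support:
            r.manual_only = False
            kept.append(r)
        elif r.support_methods == {MANUAL_METHOD_NAME} and params.allow_manual_only:
            r.manual_only = True
            kept.append(r)
    return kept


def assess_quality(
    region: ConsensusRegion, annotated_genome: AnnotatedGenome, lexicon=None
) -> QualityAssessment:
    """CheckV-style quality proxy from annotation roles within the region."""
    if region.interval.end_bp > annotated_genome.genome.length_bp:
        raise ValueError(
            f"region {region.interval.start_bp}-{region.interval.end_bp} outside "
            f"annotation bounds of {annotated_genome.id}"
        )
    genes = annotated_genome.genes_in(region.interval)
    sub = AnnotatedGenome(genome=annotated_genome.genome, genes=[])
    sub.genes = genes  # reuse role tagging without re-validation
    roles = [t.role for t in annotate_gene_roles(sub, lexicon)]
    viral = sum(1 for r in roles if r not in ("bacterial", "hypothetical"))
    canonical_present = {r for r in roles if r in CANONICAL_STRUCTURAL_ROLES}
    completeness = 100.0 * len(canonical_present) / len(CANONICAL_STRUCTURAL_ROLES)
    if viral == 0:
        tier = "rejected"
    elif completeness > 90:
        tier = "high"
    elif completeness >= 50:
        tier = "medium"
    else:
        tier = "low"
    return QualityAssessment(
        viral_gene_count=viral, completeness_pct=completeness, tier=tier
    )


def name_regions(
    regions: List[ConsensusRegion], aliases: Optional[Dict[str, str]] = None
) -> List[ConsensusRegion]:
    """Assign names ``{alias}P{k}`` with k by ascending start within a genome."""
    aliases = aliases or {}
    by_genome: Dict[str, List[ConsensusRegion]] = {}
    for r in regions:
        by_genome.setdefault(r.genome_id, []).append(r)
    for genome_id, group in by_genome.items():
        alias = aliases.get(genome_id, genome_id)
        for k, r in enumerate(
            sorted(group, key=lambda r: r.interval.start_bp), start=1
        ):
            r.name = f"{alias}P{k}"
    return regions


def support_matrix(regions: List[ConsensusRegion]) -> pd.DataFrame:
    """Region x method boolean support table."""
    methods = sorted({m for r in regions for m in r.support_methods})
    rows = [
        {"name": r.name or f"{r.genome_id}:{r.interval.start_bp}",
         **{m: m in r.support_methods for m in methods}}
        for r in regions
    ]
    return pd.DataFrame(rows, columns=["name"] + methods)
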