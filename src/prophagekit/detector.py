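"""Heuristic prophage detection from gene annotations.

Encodes the manual-inspection procedure used by curators of spirochete
genomes as a deterministic algorithm: genes are tagged with phage roles via
an ordered keyword lexicon, candidate cores are maximal gene runs carrying
phage evidence (hallmark genes or runs of hypothetical proteins) on a mostly
single strand, and boundaries are refined outwards until the annotation turns
bacterial or strands start switching again, snapping to nearby integrases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import yaml

from .records import AnnotatedGenome, DetectionCall, DetectionReport, Interval

__all__ = [
    "ROLES",
    "HALLMARK_ROLES",
    "CANONICAL_STRUCTURAL_ROLES",
    "RoleTag",
    "DetectorParams",
    "CandidateRegion",
    "load_lexicon",
    "default_lexicon",
    "annotate_gene_roles",
    "find_candidate_cores",
    "refine_boundaries",
    "detect_prophages",
    "detection_report",
    "MANUAL_METHOD_NAME",
]

MANUAL_METHOD_NAME = "manual_heuristic"

ROLES = (
    "integrase",
    "terminase",
    "portal",
    "protease",
    "scaffold",
    "major_capsid",
    "head_tail_joining",
    "tail_shaft",
    "tape_measure",
    "baseplate",
    "tail_fibre",
    "tail_sheath",
    "lysis",
    "other_phage",
    "hypothetical",
    "bacterial",
)

#: The ten structural roles whose canonical head-to-tail order defines the
#: completeness proxy and the gene-order (intactness) score.
CANONICAL_STRUCTURAL_ROLES = (
    "terminase",
    "portal",
    "protease",
    "scaffold",
    "major_capsid",
    "head_tail_joining",
    "tail_shaft",
    "tape_measure",
    "baseplate",
    "tail_fibre",
)

#: Roles treated as conserved phage hallmarks (criterion: recognisable phage
#: proteins already annotated). Excludes the catch-all ``other_phage``.
HALLMARK_ROLES = frozenset(CANONICAL_STRUCTURAL_ROLES) | {
    "integrase",
    "tail_sheath",
    "lysis",
}

_GAP_CAP_BP = 1000  # intergenic gap cap inside a co-transcribed run


@dataclass(frozen=True)
class RoleTag:
    gene_id: str
    role: str


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the heuristic detector.

    Defaults are sized for real prophages: the smallest regions reported for
    treponemes are ~12 kb with ~27 CDS, so 10 kb / 15 genes leaves margin
    without admitting single-gene noise.
    """

    min_hallmarks: int = 1
    min_run_genes: int = 15
    min_hypothetical_run: int = 5
    min_region_bp: int = 10000
    max_bacterial_gap: int = 2
    strand_coherence: float = 0.7

    def __post_init__(self) -> None:
        for name in ("min_hallmarks", "min_run_genes", "min_hypothetical_run",
                     "min_region_bp", "max_bacterial_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.strand_coherence <= 1:
            raise ValueError("strand_coherence must be in (0, 1]")


@dataclass
class CandidateRegion:
    """A candidate prophage: a contiguous gene run plus its evidence."""

    genome_id: str
    interval: Interval
    gene_ids: List[str]
    evidence: set = field(default_factory=set)
    hallmark_roles: set = field(default_factory=set)
    score: float = 0.0


# ---------------------------------------------------------------------------
# Lexicon


def load_lexicon(path=None) -> List[Tuple[re.Pattern, str]]:
    """Load an ordered (pattern, role) lexicon from YAML.

    With no path, the lexicon shipped with the package is used.
    """
    if path is None:
        text = resources.files("prophagekit.data").joinpath("phage_lexicon.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = yaml.safe_load(text)
    compiled = []
    for rule in rules:
        role = rule["role"]
        if role not in ROLES:
            raise ValueError(f"lexicon rule maps to unknown role {role!r}")
        compiled.append((re.compile(rule["pattern"], re.IGNORECASE), role))
    return compiled


_DEFAULT_LEXICON: Optional[List[Tuple[re.Pattern, str]]] = None


def default_lexicon() -> List[Tuple[re.Pattern, str]]:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = load_lexicon()
    return _DEFAULT_LEXICON


def assign_role(product: str, is_hypothetical: bool, lexicon=None) -> str:
    """Role of a single gene: first matching lexicon rule wins, then the
    hypothetical lexicon, then bacterial."""
    for pattern, role in (lexicon if lexicon is not None else default_lexicon()):
        if pattern.search(product):
            return role
    return "hypothetical" if is_hypothetical else "bacterial"


def annotate_gene_roles(annotated_genome: AnnotatedGenome, lexicon=None) -> List[RoleTag]:
    """One RoleTag per gene, in gene order. Total function."""
    lex = lexicon if lexicon is not None else default_lexicon()
    return [
        RoleTag(g.feature_id, assign_role(g.product, bool(g.is_hypothetical), lex))
        for g in annotated_genome.genes
    ]


# ---------------------------------------------------------------------------
# Candidate cores


def _max_strand_fraction(plus: int, total: int) -> float:
    return max(plus, total - plus) / total


def find_candidate_cores(
    annotated_genome: AnnotatedGenome,
    params: DetectorParams = DetectorParams(),
    lexicon=None,
    roles: Optional[Sequence[str]] = None,
) -> List[CandidateRegion]:
    """Maximal qualifying gene runs, sorted by start.

    A window of consecutive genes qualifies when every intergenic gap is
    <= 1 kb, it contains no run of more than ``max_bacterial_gap`` consecutive
    bacterial genes, it neither starts nor ends on a bacterial gene, it holds
    >= ``min_hallmarks`` hallmark genes or a hypothetical run of
    >= ``min_hypothetical_run``, at least ``strand_coherence`` of its genes
    share one strand, its span is >= ``min_region_bp`` and it has
    >= ``min_run_genes`` genes. Candidates are the qualifying windows not
    contained in any other qualifying window.
    """
    genes = annotated_genome.genes
    n = len(genes)
    if n == 0:
        return []
    if roles is None:
        roles = [t.role for t in annotate_gene_roles(annotated_genome, lexicon)]
    roles = list(roles)

    # G[i]: largest j such that window i..j qualifies (-1 if none).
    best_j = [-1] * n
    for i in range(n):
        hallmarks = 0
        plus = 0
        bact_run = 0
        hyp_run = 0
        max_hyp_run = 0
        for j in range(i, n):
            g = genes[j]
            if j > i:
                gap = g.start_bp - genes[j - 1].end_bp - 1
                if gap > _GAP_CAP_BP:
                    break
            role = roles[j]
            if role == "bacterial":
                bact_run += 1
                if bact_run > params.max_bacterial_gap:
                    break
            else:
                bact_run = 0
            if role == "hypothetical":
                hyp_run += 1
                max_hyp_run = max(max_hyp_run, hyp_run)
            else:
                hyp_run = 0
            if role in HALLMARK_ROLES:
                hallmarks += 1
            if g.strand == "+":
                plus += 1
            count = j - i + 1
            if (
                count >= params.min_run_genes
                and roles[i] != "bacterial"
                and role != "bacterial"
                and (hallmarks >= params.min_hallmarks
                     or max_hyp_run >= params.min_hypothetical_run)
                and _max_strand_fraction(plus, count) >= params.strand_coherence
                and (g.end_bp - genes[i].start_bp + 1) >= params.min_region_bp
            ):
                best_j[i] = j

    candidates = []
    best_prev = -1
    for i in range(n):
        j = best_j[i]
        if j > best_prev:
            candidates.append(_make_candidate(annotated_genome, roles, i, j, params))
        best_prev = max(best_prev, j)
    return candidates


def _make_candidate(annotated_genome, roles, i, j, params) -> CandidateRegion:
    genes = annotated_genome.genes[i : j + 1]
    window_roles = roles[i : j + 1]
    hallmarks = {r for r in window_roles if r in HALLMARK_ROLES}
    n_hallmark = sum(1 for r in window_roles if r in HALLMARK_ROLES)
    max_hyp = run = 0
    for r in window_roles:
        run = run + 1 if r == "hypothetical" else 0
        max_hyp = max(max_hyp, run)
    evidence = {"strand_coherent_run"}
    if n_hallmark >= params.min_hallmarks:
        evidence.add("hallmark_gene")
    if max_hyp >= params.min_hypothetical_run:
        evidence.add("hypothetical_run")
    return CandidateRegion(
        genome_id=annotated_genome.id,
        interval=Interval(genes[0].start_bp, genes[-1].end_bp),
        gene_ids=[g.feature_id for g in genes],
        evidence=evidence,
        hallmark_roles=hallmarks,
        score=n_hallmark + 0.1 * max_hyp,
    )


# ---------------------------------------------------------------------------
# Boundary refinement

_INTEGRASE_SNAP_GENES = 5


def refine_boundaries(
    candidate: CandidateRegion,
    annotated_genome: AnnotatedGenome,
    params: DetectorParams = DetectorParams(),
    lexicon=None,
    roles: Optional[Sequence[str]] = None,
) -> CandidateRegion:
    """Move candidate boundaries outward gene-by-gene.

    Extension continues over phage-role or hypothetical genes while the
    region stays strand-coherent; it stops at ``max_bacterial_gap``
    consecutive bacterial genes, or at a strand switch that follows a
    bacterial gene. If an integrase lies within five genes beyond a final
    edge the boundary snaps outward to include it. The final interval spans
    whole genes only, clamped to the genome.
    """
    genes = annotated_genome.genes
    if roles is None:
        roles = [t.role for t in annotate_gene_roles(annotated_genome, lexicon)]
    roles = list(roles)
    id_to_idx = {g.feature_id: k for k, g in enumerate(genes)}
    lo = id_to_idx[candidate.gene_ids[0]]
    hi = id_to_idx[candidate.gene_ids[-1]]

    plus = sum(1 for g in genes[lo : hi + 1] if g.strand == "+")
    total = hi - lo + 1
    majority = "+" if plus * 2 >= total else "-"

    def try_extend(edge: int, step: int) -> int:
        """Return the new edge index after one extension pass."""
        nonlocal plus, total
        pos = edge + step
        bact_run = 0
        pend_plus = pend_total = 0  # bacterial genes awaiting a phage gene beyond
        last_included = edge
        while 0 <= pos < len(genes):
            role = roles[pos]
            g = genes[pos]
            if role == "bacterial":
                bact_run += 1
                if bact_run >= params.max_bacterial_gap:
                    break
                pend_plus += g.strand == "+"
                pend_total += 1
            else:
                if bact_run > 0 and g.strand != majority:
                    break  # strands start switching again after bacterial genes
                new_plus = plus + pend_plus + (g.strand == "+")
                new_total = total + pend_total + 1
                if _max_strand_fraction(new_plus, new_total) < params.strand_coherence:
                    break
                plus, total = new_plus, new_total
                pend_plus = pend_total = 0
                bact_run = 0
                last_included = pos
            pos += step
        return last_included

    def snap_integrase(edge: int, step: int) -> int:
        """Snap to the outermost integrase within the snap window."""
        snapped = edge
        for offset in range(1, _INTEGRASE_SNAP_GENES + 1):
            pos = edge + step * offset
            if not 0 <= pos < len(genes):
                break
            if roles[pos] == "integrase":
                snapped = pos
        return snapped

    changed = True
    while changed:
        changed = False
        for step in (-1, +1):
            edge = lo if step < 0 else hi
            new_edge = try_extend(edge, step)
            snapped = snap_integrase(new_edge, step)
            if snapped != new_edge:
                # include intervening genes in the bookkeeping
                a, b = sorted((new_edge, snapped))
                plus += sum(
                    1 for q in range(a, b + 1) if q != new_edge and genes[q].strand == "+"
                )
                total += b - a
                new_edge = snapped
            if step < 0 and new_edge < lo:
                lo, changed = new_edge, True
            elif step > 0 and new_edge > hi:
                hi, changed = new_edge, True

    return _make_candidate(annotated_genome, roles, lo, hi, params)


# ---------------------------------------------------------------------------
# Full per-genome detection


def _merge_overlapping(annotated_genome, roles, params, candidates):
    if not candidates:
        return []
    id_to_idx = {g.feature_id: k for k, g in enumerate(annotated_genome.genes)}
    spans = sorted(
        (id_to_idx[c.gene_ids[0]], id_to_idx[c.gene_ids[-1]]) for c in candidates
    )
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        prev = merged[-1]
        prev_iv = Interval(
            annotated_genome.genes[prev[0]].start_bp, annotated_genome.genes[prev[1]].end_bp
        )
        cur_iv = Interval(
            annotated_genome.genes[lo].start_bp, annotated_genome.genes[hi].end_bp
        )
        if prev_iv.overlaps(cur_iv) or hi <= prev[1] or lo <= prev[1] + 1:
            prev[1] = max(prev[1], hi)
        else:
            merged.append([lo, hi])
    return [_make_candidate(annotated_genome, roles, lo, hi, params) for lo, hi in merged]


def detect_prophages(
    annotated_genome: AnnotatedGenome,
    params: DetectorParams = DetectorParams(),
    lexicon=None,
) -> List[CandidateRegion]:
    """Cores + boundary refinement + merge of overlapping refined regions."""
    roles = [t.role for t in annotate_gene_roles(annotated_genome, lexicon)]
    cores = find_candidate_cores(annotated_genome, params, roles=roles)
    refined = [
        refine_boundaries(c, annotated_genome, params, roles=roles) for c in cores
    ]
    return _merge_overlapping(annotated_genome, roles, params, refined)


def detection_report(genomes_candidates) -> DetectionReport:
    """Package per-genome candidate lists as a manual_heuristic DetectionReport."""
    calls = []
    for candidates in genomes_candidates:
        for c in candidates:
            calls.append(
                DetectionCall(
                    genome_id=c.genome_id,
                    interval=c.interval,
                    method=MANUAL_METHOD_NAME,
                    score=c.score,
                )
            )
    return DetectionReport(method=MANUAL_METHOD_NAME, calls=calls)
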