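"""Synthetic annotated genomes with implanted prophages of known truth.

The generator emulates what the detection heuristics key on in real genomes:
a bacterial background of mixed-strand housekeeping genes, implanted phage
cassettes with canonical gene orders and hypothetical-protein runs on a
single strand, GC offsets against the host background, deletion-degraded
(cryptic) variants, and per-method detector reports with configurable
sensitivity, boundary jitter and false-call rates. Every generator is a pure
function of (arguments, seed): repeated calls are byte-identical.

It deliberately does not emulate codon structure, Markov base composition,
mobile elements other than prophages, or assembly artefacts; green tests on
this substrate establish algorithmic correctness, not real-genome accuracy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import AnnotatedGenome, DetectionCall, DetectionReport, GeneFeature, GenomeRecord, Interval

__all__ = [
    "ProphageTemplate",
    "MethodProfile",
    "TruthEntry",
    "TruthSet",
    "intact_siphoviral_template",
    "intact_myoviral_template",
    "generate_host_background",
    "implant_prophage",
    "degrade_prophage",
    "simulate_detector_reports",
    "mutate_sequence",
    "write_truth_tsv",
    "random_sequence",
    "sequence_with_exact_gc",
    "generate_scenario",
    "ROLE_PRODUCTS",
    "BACTERIAL_PRODUCTS",
]

_MIN_BACKGROUND_BP = 50_000

BACTERIAL_PRODUCTS = (
    "ABC transporter permease",
    "DNA gyrase subunit B",
    "50S ribosomal protein L3",
    "elongation factor Tu",
    "sensor histidine kinase",
    "MFS transporter",
    "glycosyltransferase family 2 protein",
    "two-component response regulator",
    "aminotransferase class I",
    "peptide ABC transporter substrate-binding protein",
    "flagellar motor protein MotB",
    "chemotaxis response regulator CheY",
    "cell division protein FtsZ",
    "phosphoglycerate kinase",
)

#: Products emitted for each phage role; all resolve back to the same role
#: through the default detection lexicon (asserted in tests).
ROLE_PRODUCTS: Dict[str, Tuple[str, ...]] = {
    "integrase": ("site-specific integrase", "phage integrase"),
    "terminase": ("terminase large subunit", "terminase small subunit"),
    "portal": ("phage portal protein",),
    "protease": ("prohead protease",),
    "scaffold": ("phage scaffold protein",),
    "major_capsid": ("major capsid protein",),
    "head_tail_joining": ("head-tail joining protein", "head-tail connector protein"),
    "tail_shaft": ("tail shaft protein", "major tail protein"),
    "tape_measure": ("phage tail tape measure protein",),
    "baseplate": ("baseplate assembly protein",),
    "tail_fibre": ("tail fiber protein",),
    "tail_sheath": ("phage tail sheath protein",),
    "lysis": ("endolysin", "holin"),
    "other_phage": ("phage protein",),
    "hypothetical": ("hypothetical protein",),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, tag: str, *index: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, operation, index)."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF, *index]
    )


@dataclass(frozen=True)
class ProphageTemplate:
    """Blueprint for one implanted prophage."""

    name: str
    morphology: str  # Myoviral | Siphoviral
    role_order: Tuple[str, ...]
    gene_length_dist: Tuple[float, float] = (800.0, 150.0)
    gc_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.morphology == "Myoviral" and "tail_sheath" not in self.role_order:
            raise ValueError("Myoviral template must contain tail_sheath")
        if self.morphology == "Siphoviral" and (
            "tape_measure" not in self.role_order or "tail_sheath" in self.role_order
        ):
            raise ValueError(
                "Siphoviral template must contain tape_measure and no tail_sheath"
            )
        for role in self.role_order:
            if role not in ROLE_PRODUCTS:
                raise ValueError(f"unknown role {role!r} in template")


@dataclass(frozen=True)
class MethodProfile:
    method: str
    sensitivity: float = 0.9
    boundary_jitter_sd_bp: float = 500.0
    false_call_rate_per_mb: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.boundary_jitter_sd_bp < 0 or self.false_call_rate_per_mb < 0:
            raise ValueError("jitter and false-call rate must be non-negative")


@dataclass
class TruthEntry:
    genome_id: str
    interval: Interval
    template_name: str
    strand: str
    gene_ids: List[str] = field(default_factory=list)
    degraded: bool = False
    deleted_roles: set = field(default_factory=set)


@dataclass
class TruthSet:
    entries: List[TruthEntry] = field(default_factory=list)

    def for_genome(self, genome_id: str) -> List[TruthEntry]:
        return [e for e in self.entries if e.genome_id == genome_id]

    def __len__(self) -> int:
        return len(self.entries)


def intact_siphoviral_template(name: str = "sipho_intact",
                               gc_offset: float = 0.0) -> ProphageTemplate:
    """Canonical 10 structural roles in order, integrase first, with
    hypothetical runs interleaved — scores as intact by construction."""
    return ProphageTemplate(
        name=name,
        morphology="Siphoviral",
        role_order=(
            "integrase",
            "hypothetical", "hypothetical", "hypothetical",
            "terminase", "portal", "protease", "scaffold", "major_capsid",
            "hypothetical",
            "head_tail_joining", "tail_shaft", "tape_measure",
            "hypothetical", "hypothetical",
            "baseplate", "tail_fibre", "lysis",
            "hypothetical",
        ),
        gc_offset=gc_offset,
    )


def intact_myoviral_template(name: str = "myo_intact",
                             gc_offset: float = 0.0) -> ProphageTemplate:
    return ProphageTemplate(
        name=name,
        morphology="Myoviral",
        role_order=(
            "integrase",
            "hypothetical", "hypothetical",
            "terminase", "portal", "protease", "scaffold", "major_capsid",
            "hypothetical", "hypothetical",
            "head_tail_joining", "tail_shaft", "tail_sheath", "tape_measure",
            "hypothetical",
            "baseplate", "tail_fibre", "lysis",
            "hypothetical", "hypothetical",
        ),
        gc_offset=gc_offset,
    )


# ---------------------------------------------------------------------------
# Sequence helpers


def random_sequence(length: int, gc_pct: float, rng: np.random.Generator) -> str:
    p_gc = gc_pct / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs)
    return _BASES[codes].tobytes().decode()


def sequence_with_exact_gc(length: int, gc_count: int, rng: np.random.Generator) -> str:
    """Random sequence with exactly ``gc_count`` G/C bases."""
    if not 0 <= gc_count <= length:
        raise ValueError("gc_count out of range")
    codes = np.empty(length, dtype=np.int64)
    gc_positions = rng.choice(length, size=gc_count, replace=False)
    mask = np.zeros(length, dtype=bool)
    mask[gc_positions] = True
    codes[mask] = rng.choice([1, 2], size=gc_count)       # C or G
    codes[~mask] = rng.choice([0, 3], size=length - gc_count)  # A or T
    return _BASES[codes].tobytes().decode()


def mutate_sequence(
    seq: str, substitution_rate: float, indel_rate: float, seed: int
) -> str:
    """Per-base substitutions to a uniformly chosen different base, plus
    geometric-length insertions/deletions. Deterministic per seed."""
    if not (0 <= substitution_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("mutation rates must be in [0, 1)")
    rng = _rng(seed, "mutate")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lookup[b] = i
    num = lookup[codes]
    valid = num < 4
    if substitution_rate > 0:
        sub_mask = (rng.random(num.size) < substitution_rate) & valid
        shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
        num[sub_mask] = (num[sub_mask] + shifts) % 4
    out_codes = np.where(valid, _BASES[np.minimum(num, 3)], codes)
    result = out_codes.tobytes().decode()
    if indel_rate > 0:
        positions = np.flatnonzero(rng.random(len(result)) < indel_rate)
        pieces = []
        cursor = 0
        for pos in positions:
            if pos < cursor:
                continue
            pieces.append(result[cursor:pos])
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion
                ins = random_sequence(length, 50.0, rng)
                pieces.append(ins)
                cursor = pos
            else:  # deletion
                cursor = pos + length
        pieces.append(result[cursor:])
        result = "".join(pieces)
    return result


# ---------------------------------------------------------------------------
# Host background


def generate_host_background(
    length_bp: int, gc_pct: float, seed: int, genome_id: Optional[str] = None
) -> AnnotatedGenome:
    """An i.i.d.-base host genome tiled with mixed-strand bacterial genes.

    Genes average ~1 kb with short intergenic gaps and carry housekeeping
    product labels that never match the phage lexicon.
    """
    if length_bp < _MIN_BACKGROUND_BP:
        raise ValueError(
            f"background too short: {length_bp} < {_MIN_BACKGROUND_BP} bp"
        )
    if not 0 < gc_pct < 100:
        raise ValueError("gc_pct must be inside (0, 100)")
    rng = _rng(seed, "host_background")
    gid = genome_id or f"synth_host_{seed}"
    sequence = random_sequence(length_bp, gc_pct, rng)
    genes = []
    pos = int(rng.integers(100, 300))
    idx = 0
    while True:
        glen = int(np.clip(rng.normal(1000, 200), 300, 2500))
        end = pos + glen - 1
        if end > length_bp - 100:
            break
        idx += 1
        genes.append(
            GeneFeature(
                feature_id=f"{gid}_g{idx:04d}",
                start_bp=pos,
                end_bp=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=str(rng.choice(BACTERIAL_PRODUCTS)),
            )
        )
        pos = end + 1 + int(rng.integers(50, 150))
    genome = GenomeRecord(id=gid, sequence=sequence, description="synthetic host")
    return AnnotatedGenome(genome=genome, genes=genes)


# ---------------------------------------------------------------------------
# Prophage implantation


def implant_prophage(
    annotated_genome: AnnotatedGenome,
    template: ProphageTemplate,
    position_bp: int,
    seed: int,
    truth: Optional[TruthSet] = None,
) -> Tuple[AnnotatedGenome, TruthEntry]:
    """Overwrite the host at ``position_bp`` with a phage cassette.

    Genes follow the template role order on one randomly chosen strand with
    short gaps; products are drawn from the role lexicon, sequence segments
    are sampled at host GC plus the template's offset. The truth interval is
    recorded exactly; overlap with an existing truth entry raises.
    """
    from .io import gc_content  # local import to avoid a cycle

    rng = _rng(seed, "implant", position_bp)
    mean_len, sd_len = template.gene_length_dist
    gene_lengths = [
        int(np.clip(rng.normal(mean_len, sd_len), 200, mean_len * 4))
        for _ in template.role_order
    ]
    # tape measure proteins are characteristically long
    for i, role in enumerate(template.role_order):
        if role == "tape_measure":
            gene_lengths[i] = int(gene_lengths[i] * 3)
    gaps = [int(rng.integers(20, 100)) for _ in template.role_order]
    span = sum(gene_lengths) + sum(gaps[:-1])
    genome = annotated_genome.genome
    if position_bp < 1 or position_bp + span - 1 > genome.length_bp:
        raise ValueError(
            f"template span {span} bp does not fit at position {position_bp} "
            f"in genome of {genome.length_bp} bp"
        )
    interval = Interval(position_bp, position_bp + span - 1)
    if truth is not None:
        for entry in truth.for_genome(annotated_genome.id):
            if entry.interval.overlaps(interval):
                raise ValueError(
                    f"implant at {position_bp} overlaps existing truth entry "
                    f"{entry.interval.start_bp}-{entry.interval.end_bp}"
                )

    host_gc = gc_content(genome.sequence)
    phage_gc = float(np.clip(host_gc + template.gc_offset, 5.0, 95.0))
    phage_seq = random_sequence(span, phage_gc, rng)
    new_sequence = (
        genome.sequence[: position_bp - 1]
        + phage_seq
        + genome.sequence[position_bp - 1 + span :]
    )
    strand = "+" if rng.random() < 0.5 else "-"
    phage_genes = []
    pos = position_bp
    for i, (role, glen) in enumerate(zip(template.role_order, gene_lengths), start=1):
        fid = f"{annotated_genome.id}_{template.name}_{position_bp}_p{i:03d}"
        phage_genes.append(
            GeneFeature(
                feature_id=fid,
                start_bp=pos,
                end_bp=pos + glen - 1,
                strand=strand,
                product=str(rng.choice(ROLE_PRODUCTS[role])),
            )
        )
        pos += glen + gaps[i - 1]
    kept = [g for g in annotated_genome.genes if not g.interval.overlaps(interval)]
    new_annotated = AnnotatedGenome(
        genome=GenomeRecord(id=genome.id, sequence=new_sequence,
                            description=genome.description),
        genes=kept + phage_genes,
    )
    entry = TruthEntry(
        genome_id=genome.id,
        interval=interval,
        template_name=template.name,
        strand=strand,
        gene_ids=[g.feature_id for g in phage_genes],
    )
    if truth is not None:
        truth.entries.append(entry)
    return new_annotated, entry


def degrade_prophage(
    annotated_genome: AnnotatedGenome,
    truth_entry: TruthEntry,
    deletion_fraction: float,
    seed: int,
) -> Tuple[AnnotatedGenome, TruthEntry]:
    """Delete a contiguous block of phage genes, making the prophage cryptic.

    The deleted genes' sequence is overwritten with host-composition random
    sequence and their roles are recorded on the updated truth entry.
    """
    from .detector import assign_role
    from .io import gc_content

    if not 0 <= deletion_fraction < 1:
        raise ValueError("deletion_fraction must be in [0, 1)")
    if deletion_fraction == 0:
        return annotated_genome, replace(
            truth_entry, degraded=False, deleted_roles=set(),
            gene_ids=list(truth_entry.gene_ids),
        )
    rng = _rng(seed, "degrade", truth_entry.interval.start_bp)
    gene_map = {g.feature_id: g for g in annotated_genome.genes}
    phage_genes = [gene_map[fid] for fid in truth_entry.gene_ids if fid in gene_map]
    n_del = int(round(deletion_fraction * len(phage_genes)))
    if n_del == 0:
        return annotated_genome, replace(
            truth_entry, degraded=False, deleted_roles=set(),
            gene_ids=list(truth_entry.gene_ids),
        )
    start_idx = int(rng.integers(0, len(phage_genes) - n_del + 1))
    doomed = phage_genes[start_idx : start_idx + n_del]
    deleted_roles = {
        assign_role(g.product, bool(g.is_hypothetical)) for g in doomed
    }
    lo = min(g.start_bp for g in doomed)
    hi = max(g.end_bp for g in doomed)
    genome = annotated_genome.genome
    host_gc = gc_content(genome.sequence)
    filler = random_sequence(hi - lo + 1, host_gc, rng)
    new_sequence = genome.sequence[: lo - 1] + filler + genome.sequence[hi:]
    doomed_ids = {g.feature_id for g in doomed}
    new_genes = [g for g in annotated_genome.genes if g.feature_id not in doomed_ids]
    new_annotated = AnnotatedGenome(
        genome=GenomeRecord(id=genome.id, sequence=new_sequence,
                            description=genome.description),
        genes=new_genes,
    )
    new_entry = replace(
        truth_entry,
        degraded=True,
        deleted_roles=deleted_roles,
        gene_ids=[fid for fid in truth_entry.gene_ids if fid not in doomed_ids],
    )
    return new_annotated, new_entry


# ---------------------------------------------------------------------------
# Detector-report simulation


def simulate_detector_reports(
    truth: TruthSet,
    profiles: Sequence[MethodProfile],
    seed: int,
    genome_lengths: Optional[Dict[str, int]] = None,
) -> List[DetectionReport]:
    """Per-method detector reports over a truth set.

    Each truth entry is detected by each method with probability
    ``sensitivity``; detected boundaries receive independent Gaussian jitter.
    False calls arrive Poisson at ``false_call_rate_per_mb`` per genome,
    placed uniformly but never overlapping a truth interval (so recall/FDR
    accounting stays unambiguous).
    """
    if not profiles:
        raise ValueError("at least one method profile is required")
    genome_lengths = genome_lengths or {}
    reports = []
    for m_idx, profile in enumerate(profiles):
        rng = _rng(seed, "detector_report", m_idx)
        calls = []
        for entry in truth.entries:
            if rng.random() >= profile.sensitivity:
                continue
            glen = genome_lengths.get(entry.genome_id, entry.interval.end_bp + 10_000)
            jit = profile.boundary_jitter_sd_bp
            start = entry.interval.start_bp + int(round(rng.normal(0, jit))) if jit else entry.interval.start_bp
            end = entry.interval.end_bp + int(round(rng.normal(0, jit))) if jit else entry.interval.end_bp
            start = max(1, min(start, glen - 1))
            end = max(start + 1, min(end, glen))
            calls.append(
                DetectionCall(
                    genome_id=entry.genome_id,
                    interval=Interval(start, end),
                    method=profile.method,
                )
            )
        if profile.false_call_rate_per_mb > 0:
            for genome_id, glen in sorted(genome_lengths.items()):
                lam = profile.false_call_rate_per_mb * glen / 1e6
                for _ in range(int(rng.poisson(lam))):
                    for _attempt in range(100):
                        length = int(rng.integers(8_000, 30_000))
                        if glen <= length + 1:
                            break
                        start = int(rng.integers(1, glen - length))
                        iv = Interval(start, start + length - 1)
                        if not any(
                            iv.overlaps(e.interval)
                            for e in truth.for_genome(genome_id)
                        ):
                            calls.append(
                                DetectionCall(
                                    genome_id=genome_id, interval=iv,
                                    method=profile.method,
                                )
                            )
                            break
        reports.append(DetectionReport(method=profile.method, calls=calls))
    return reports


def write_truth_tsv(truth: TruthSet, path):
    """Ground-truth table: one row per implanted prophage."""
    import pandas as pd

    rows = [
        {
            "genome_id": e.genome_id,
            "start_bp": e.interval.start_bp,
            "end_bp": e.interval.end_bp,
            "template": e.template_name,
            "strand": e.strand,
            "degraded": e.degraded,
            "deleted_roles": ",".join(sorted(e.deleted_roles)),
        }
        for e in truth.entries
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "start_bp", "end_bp", "template", "strand",
                 "degraded", "deleted_roles"],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Scenario convenience


def generate_scenario(
    n_genomes: int,
    seed: int,
    host_length_bp: int = 100_000,
    host_gc_pct: float = 40.0,
    implants_per_genome: int = 1,
) -> Tuple[Dict[str, AnnotatedGenome], TruthSet]:
    """Hosts with implanted intact prophages (alternating morphologies)."""
    genomes: Dict[str, AnnotatedGenome] = {}
    truth = TruthSet()
    for g_idx in range(n_genomes):
        seed_g = (seed * 1009 + g_idx) % (2**31 - 1)
        ann = generate_host_background(
            host_length_bp, host_gc_pct, seed_g, genome_id=f"synth_{seed}_{g_idx:03d}"
        )
        rng = _rng(seed, "scenario_positions", g_idx)
        slot = host_length_bp // max(implants_per_genome, 1)
        for k in range(implants_per_genome):
            template = (
                intact_myoviral_template(gc_offset=-1.5)
                if (g_idx + k) % 2
                else intact_siphoviral_template(gc_offset=-1.5)
            )
            lo = k * slot + 2_000
            hi = (k + 1) * slot - 35_000
            if hi <= lo:
                raise ValueError("host too short for requested implants")
            position = int(rng.integers(lo, hi))
            ann, _ = implant_prophage(ann, template, position, seed_g + 7 * k, truth=truth)
        genomes[ann.id] = ann
    return genomes, truth
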