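"""Core domain containers shared across the package.

Coordinates are 1-based and inclusive at both ends throughout the public
surface, matching the GenBank/GFF3 convention of the input formats. Any
half-open arithmetic is internal and never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Interval",
    "GenomeRecord",
    "GeneFeature",
    "AnnotatedGenome",
    "DetectionCall",
    "DetectionReport",
    "HYPOTHETICAL_LEXICON",
    "is_hypothetical_product",
]

#: Case-insensitive substrings that mark a gene product as "hypothetical".
HYPOTHETICAL_LEXICON = ("hypothetical protein", "uncharacterized protein", "duf")


def is_hypothetical_product(product: str) -> bool:
    """True if *product* matches the hypothetical-protein lexicon."""
    low = product.lower()
    return any(term in low for term in HYPOTHETICAL_LEXICON)


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive genomic interval."""

    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"inverted interval: start {self.start_bp} > end {self.end_bp}"
            )
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlap_bp(self, other: "Interval") -> int:
        return max(
            0, min(self.end_bp, other.end_bp) - max(self.start_bp, other.start_bp) + 1
        )

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap_bp(other) > 0

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 when disjoint."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length_bp, ov / other.length_bp)

    def union_span(self, other: "Interval") -> "Interval":
        return Interval(
            min(self.start_bp, other.start_bp), max(self.end_bp, other.end_bp)
        )


@dataclass
class GenomeRecord:
    """A nucleotide sequence with identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A CDS feature: 1-based inclusive coordinates, strand and product text."""

    feature_id: str
    start_bp: int
    end_bp: int
    strand: str  # "+" or "-"
    product: str = ""
    is_hypothetical: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.start_bp > self.end_bp:
            raise ValueError(
                f"feature {self.feature_id}: invalid coordinates "
                f"{self.start_bp}..{self.end_bp}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be '+' or '-'")
        if self.is_hypothetical is None:
            self.is_hypothetical = is_hypothetical_product(self.product)

    @property
    def interval(self) -> Interval:
        return Interval(self.start_bp, self.end_bp)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class AnnotatedGenome:
    """A genome plus its ordered CDS features (sorted by start coordinate)."""

    genome: GenomeRecord
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start_bp, g.end_bp))
        for g in self.genes:
            if g.end_bp > self.genome.length_bp:
                raise ValueError(
                    f"feature {g.feature_id} extends to {g.end_bp} beyond "
                    f"genome end {self.genome.length_bp}"
                )

    @property
    def id(self) -> str:
        return self.genome.id

    def genes_in(self, interval: Interval) -> list:
        """Genes overlapping *interval* (any overlap)."""
        return [g for g in self.genes if g.interval.overlaps(interval)]


@dataclass(frozen=True)
class DetectionCall:
    """One detector's candidate prophage interval on one genome."""

    genome_id: str
    interval: Interval
    method: str
    score: Optional[float] = None


@dataclass
class DetectionReport:
    """All calls from a single detection method."""

    method: str
    calls: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.method != self.method:
                raise ValueError(
                    f"call method {c.method!r} does not match report {self.method!r}"
                )

    def __len__(self) -> int:
        return len(self.calls)

    @classmethod
    def from_calls(cls, method: str, calls: Iterable[DetectionCall]) -> "DetectionReport":
        return cls(method=method, calls=list(calls))
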