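"""SYNTHETIC stand-in for the published 38-prophage nucleotide set.

The real supplementary multi-FASTA of 38 treponeme prophage regions is not
redistributable here, so this module rebuilds a synthetic surrogate from the
published per-prophage summary statistics: each record reproduces the printed
name, length (to 0.1 kb) and GC content (to 0.1%), the three reported
sequence clusters (A: 10 members, B: 10, C: 4) are emulated as mutation
families sharing a cluster ancestor with per-member divergence chosen inside
the reported 58-96% intergenomic-similarity range, and the remaining 14
prophages are unrelated random sequences. Names not individually printed in
the source tables use the published host-strain alias scheme with invented
P-numbers.

Every sequence is generated — none is real treponeme DNA. The set exists so
the whole pipeline (FASTA IO, GC, similarity, ICTV clustering) can be
exercised against the published summary numbers without the original data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import GenomeRecord
from .simulate import _rng, mutate_sequence, random_sequence, sequence_with_exact_gc

__all__ = [
    "ReferenceRow",
    "REFERENCE_TABLE",
    "CLUSTER_ANCESTORS",
    "build_synthetic_reference_set",
    "expected_clusters",
]


@dataclass(frozen=True)
class ReferenceRow:
    name: str
    cluster: Optional[str]  # A | B | C | None (unclustered)
    length_bp: int
    gc_pct: float  # target GC, matched exactly to 1 d.p.
    divergence: float  # substitution rate vs the cluster ancestor (0 for singletons)
    morphology: str


# (ancestor_length_bp, ancestor_gc_pct) per cluster family
CLUSTER_ANCESTORS: Dict[str, Tuple[int, float]] = {
    "A": (73_500, 39.5),
    "B": (53_600, 39.5),
    "C": (65_300, 39.3),
}

REFERENCE_TABLE: List[ReferenceRow] = [
    # cluster A: published as myoviral, 52.5-73.5 kb
    ReferenceRow("B43P7", "A", 64_200, 40.9, 0.055, "Myoviral"),
    ReferenceRow("ReiterP1", "A", 52_500, 40.0, 0.060, "Myoviral"),
    ReferenceRow("27087P2", "A", 67_600, 40.0, 0.045, "Myoviral"),
    ReferenceRow("KS1P5", "A", 65_900, 39.5, 0.019, "Myoviral"),
    ReferenceRow("T320AP2", "A", 54_000, 38.9, 0.065, "Myoviral"),
    ReferenceRow("27087P3", "A", 73_200, 39.5, 0.030, "Myoviral"),
    ReferenceRow("B43P4", "A", 73_500, 39.8, 0.035, "Myoviral"),
    ReferenceRow("B43P5", "A", 73_000, 39.4, 0.040, "Myoviral"),
    ReferenceRow("KS1P4", "A", 65_900, 39.5, 0.019, "Myoviral"),
    ReferenceRow("KS1P7", "A", 62_100, 40.8, 0.050, "Myoviral"),
    # cluster B: published as siphoviral, 33.4-53.6 kb
    ReferenceRow("B43P1", "B", 40_600, 40.1, 0.035, "Siphoviral"),
    ReferenceRow("B43P2", "B", 46_800, 39.8, 0.040, "Siphoviral"),
    ReferenceRow("KS1P8", "B", 39_500, 39.2, 0.045, "Siphoviral"),
    ReferenceRow("T320AP3", "B", 53_100, 38.8, 0.030, "Siphoviral"),
    ReferenceRow("KS1P1", "B", 33_400, 39.9, 0.050, "Siphoviral"),
    ReferenceRow("KS1P2", "B", 52_900, 39.7, 0.035, "Siphoviral"),
    ReferenceRow("KS1P3", "B", 33_900, 39.5, 0.055, "Siphoviral"),
    ReferenceRow("B43P3", "B", 36_100, 39.1, 0.045, "Siphoviral"),
    ReferenceRow("B43P8", "B", 53_600, 37.7, 0.040, "Siphoviral"),
    ReferenceRow("27087P1", "B", 33_500, 39.6, 0.060, "Siphoviral"),
    # cluster C: published as siphoviral, 44.2-65.3 kb
    ReferenceRow("B43P6", "C", 47_600, 39.2, 0.040, "Siphoviral"),
    ReferenceRow("T320AP1", "C", 65_300, 39.6, 0.030, "Siphoviral"),
    ReferenceRow("27087P4", "C", 52_900, 38.8, 0.045, "Siphoviral"),
    ReferenceRow("KS1P6", "C", 44_200, 39.8, 0.050, "Siphoviral"),
    # unclustered prophages: only the set-level marginals are published
    # (38 records, 12.4-75.1 kb extremes, mean GC 41.6%); per-record values
    # below are synthetic choices consistent with those marginals and with
    # the host strains' GC.
    ReferenceRow("ReiterP2", None, 41_200, 38.9, 0.0, "Siphoviral"),
    ReferenceRow("PrimP1", None, 75_100, 49.6, 0.0, "Unclassified"),
    ReferenceRow("PrimP2", None, 43_600, 49.9, 0.0, "Unclassified"),
    ReferenceRow("PrimP3", None, 38_200, 50.3, 0.0, "Unclassified"),
    ReferenceRow("PrimP4", None, 29_500, 49.5, 0.0, "Unclassified"),
    ReferenceRow("PrimP5", None, 21_800, 49.2, 0.0, "Unclassified"),
    ReferenceRow("AzoP1", None, 51_300, 48.9, 0.0, "Unclassified"),
    ReferenceRow("AzoP2", None, 33_000, 49.3, 0.0, "Unclassified"),
    ReferenceRow("AzoP3", None, 18_600, 48.6, 0.0, "Unclassified"),
    ReferenceRow("VinP1", None, 55_400, 42.0, 0.0, "Unclassified"),
    ReferenceRow("VinP2", None, 27_900, 40.4, 0.0, "Unclassified"),
    ReferenceRow("RuP1", None, 12_400, 39.7, 0.0, "Unclassified"),
    ReferenceRow("td1", None, 49_300, 37.9, 0.0, "Siphoviral"),
    ReferenceRow("BryP1", None, 30_700, 37.5, 0.0, "Unclassified"),
]


def _target_gc_count(length_bp: int, gc_pct: float) -> int:
    return int(round(gc_pct * length_bp / 100.0))


def _repair_gc(seq: str, target_count: int, rng: np.random.Generator) -> str:
    """Flip the minimum number of bases so the G+C count is exact."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    delta = target_count - int(is_gc.sum())
    if delta > 0:
        pool = np.flatnonzero(~is_gc)
        picks = rng.choice(pool, size=delta, replace=False)
        codes[picks] = rng.choice([ord("G"), ord("C")], size=delta)
    elif delta < 0:
        pool = np.flatnonzero(is_gc)
        picks = rng.choice(pool, size=-delta, replace=False)
        codes[picks] = rng.choice([ord("A"), ord("T")], size=-delta)
    return codes.tobytes().decode()


def build_synthetic_reference_set(seed: int = 0) -> List[GenomeRecord]:
    """Generate the 38-record synthetic surrogate, deterministically per seed.

    Cluster members are truncated, substitution-mutated, GC-repaired copies
    of a per-cluster ancestor; unclustered records are independent random
    sequences with exact GC counts.
    """
    ancestors = {
        cluster: random_sequence(length, gc, _rng(seed, "refset_ancestor", idx))
        for idx, (cluster, (length, gc)) in enumerate(sorted(CLUSTER_ANCESTORS.items()))
    }
    records = []
    for idx, row in enumerate(REFERENCE_TABLE):
        target = _target_gc_count(row.length_bp, row.gc_pct)
        if row.cluster is not None:
            base = ancestors[row.cluster][: row.length_bp]
            member_seed = (seed * 4099 + 17 * idx + 1) % (2**31 - 1)
            seq = mutate_sequence(base, row.divergence, 0.0, member_seed)
            seq = _repair_gc(seq, target, _rng(seed, "refset_gc_repair", idx))
        else:
            seq = sequence_with_exact_gc(
                row.length_bp, target, _rng(seed, "refset_singleton", idx)
            )
        records.append(
            GenomeRecord(
                id=row.name,
                sequence=seq,
                description="synthetic prophage region (stand-in, not real DNA)",
            )
        )
    return records


def expected_clusters() -> Dict[str, List[str]]:
    """Cluster membership encoded in the table (A/B/C only)."""
    out: Dict[str, List[str]] = {}
    for row in REFERENCE_TABLE:
        if row.cluster:
            out.setdefault(row.cluster, []).append(row.name)
    return out
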