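"""Morphology, gene-order intactness and defence-system classification.

Morphology follows the tail-gene convention for integrated phages: a tail
sheath protein marks a contractile (myoviral) tail; a tape measure protein
without a tail sheath marks a long non-contractile (siphoviral) tail.

Intactness scores how much of the canonical head-to-tail structural cassette
(terminase - portal - protease - scaffold - major capsid - head/tail joining -
tail shaft - tape measure - baseplate - tail fibre) appears in the correct
genomic order, with each role credited at most once. A region is called
potentially intact when it has an integrase, a terminase, and at least 7 of
the 10 roles in order (the cutoff is configurable; curators have used order +
integrase + terminase without a printed threshold).

Defence systems are screened with keyword/proximity rules (see
data/defence_rules.yaml); this is a screen, not a substitute for PADLOC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import re

import yaml

from .detector import CANONICAL_STRUCTURAL_ROLES

__all__ = [
    "MorphologyCall",
    "OrderScore",
    "DefenceHit",
    "classify_morphology",
    "score_gene_order",
    "load_defence_rules",
    "detect_defence_systems",
    "DEFAULT_PROXIMITY_WINDOW",
    "DEFAULT_INTACT_ORDER_MIN",
]

DEFAULT_PROXIMITY_WINDOW = 5
DEFAULT_INTACT_ORDER_MIN = 7


@dataclass
class MorphologyCall:
    morphology: str  # Myoviral | Siphoviral | Unclassified
    basis: List[str] = field(default_factory=list)


@dataclass
class OrderScore:
    ordered_roles_found: List[str]
    longest_in_order: int
    has_integrase: bool
    has_terminase: bool
    intact: bool


@dataclass
class DefenceHit:
    system: str
    component_genes: List[str]


def classify_morphology(region_roles: Sequence[str]) -> MorphologyCall:
    """Myoviral if any tail sheath; else siphoviral if any tape measure;
    else unclassified. Order-invariant over the region's genes."""
    roles = set(region_roles)
    if "tail_sheath" in roles:
        return MorphologyCall("Myoviral", basis=["tail_sheath"])
    if "tape_measure" in roles:
        return MorphologyCall("Siphoviral", basis=["tape_measure"])
    return MorphologyCall("Unclassified", basis=[])


def score_gene_order(
    region_roles_in_order: Sequence[str],
    intact_order_min: int = DEFAULT_INTACT_ORDER_MIN,
) -> OrderScore:
    """Score the canonical structural gene order of a region.

    ``longest_in_order`` is the length of the longest subsequence of the
    region's role sequence that follows the canonical 10-role order, each
    role credited once (computed as the longest strictly increasing
    subsequence of canonical indices, so tandem duplicates cannot inflate
    the score and adding genes can never decrease it).
    """
    order_index = {r: k for k, r in enumerate(CANONICAL_STRUCTURAL_ROLES)}
    idx_seq = [order_index[r] for r in region_roles_in_order if r in order_index]
    # longest strictly increasing subsequence, with reconstruction
    best_len = 0
    lis_prev = [-1] * len(idx_seq)
    lis_len = [1] * len(idx_seq)
    best_end = -1
    for i, v in enumerate(idx_seq):
        for j in range(i):
            if idx_seq[j] < v and lis_len[j] + 1 > lis_len[i]:
                lis_len[i] = lis_len[j] + 1
                lis_prev[i] = j
        if lis_len[i] > best_len:
            best_len, best_end = lis_len[i], i
    found: List[str] = []
    k = best_end
    while k >= 0:
        found.append(CANONICAL_STRUCTURAL_ROLES[idx_seq[k]])
        k = lis_prev[k]
    found.reverse()
    has_integrase = "integrase" in region_roles_in_order
    has_terminase = "terminase" in region_roles_in_order
    return OrderScore(
        ordered_roles_found=found,
        longest_in_order=best_len,
        has_integrase=has_integrase,
        has_terminase=has_terminase,
        intact=has_integrase and has_terminase and best_len >= intact_order_min,
    )


def load_defence_rules(path=None) -> Dict[str, Dict[str, re.Pattern]]:
    """Load defence keyword rules (system -> component -> compiled regex)."""
    if path is None:
        text = resources.files("prophagekit.data").joinpath("defence_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        system: {comp: re.compile(pat, re.IGNORECASE) for comp, pat in comps.items()}
        for system, comps in raw.items()
    }


_DEFAULT_RULES: Optional[Dict[str, Dict[str, re.Pattern]]] = None


def _default_rules():
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_defence_rules()
    return _DEFAULT_RULES


def detect_defence_systems(
    region_genes,
    rules: Optional[Dict[str, Dict[str, re.Pattern]]] = None,
    proximity_window: int = DEFAULT_PROXIMITY_WINDOW,
) -> List[DefenceHit]:
    """Rule-based defence-system screen over a region's genes (in order).

    For each system, genes matching each component keyword rule are collected;
    a hit is emitted whenever one gene per component can be chosen with all
    chosen genes within ``proximity_window`` gene positions of one another.
    Matched genes are consumed greedily left-to-right so tandem systems yield
    separate hits and a lone component never fires.
    """
    rules = rules if rules is not None else _default_rules()
    hits: List[DefenceHit] = []
    for system, comps in rules.items():
        comp_positions = {
            comp: [
                i for i, g in enumerate(region_genes) if pat.search(g.product or "")
            ]
            for comp, pat in comps.items()
        }
        if any(not positions for positions in comp_positions.values()):
            continue
        used = {comp: set() for comp in comp_positions}
        anchor_comp = min(comp_positions, key=lambda c: len(comp_positions[c]))
        for anchor in comp_positions[anchor_comp]:
            if anchor in used[anchor_comp]:
                continue
            chosen = {anchor_comp: anchor}
            for comp, positions in comp_positions.items():
                if comp == anchor_comp:
                    continue
                avail = [
                    p for p in positions
                    if p not in used[comp]
                    and abs(p - anchor) <= proximity_window
                    and p != anchor
                ]
                if not avail:
                    chosen = None
                    break
                chosen[comp] = min(avail, key=lambda p: abs(p - anchor))
            if chosen is None:
                continue
            for comp, p in chosen.items():
                used[comp].add(p)
            hits.append(
                DefenceHit(
                    system=system,
                    component_genes=[
                        region_genes[p].feature_id
                        for _, p in sorted(chosen.items(), key=lambda kv: kv[1])
                    ],
                )
            )
    return hits
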