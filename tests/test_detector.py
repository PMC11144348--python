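"""Heuristic detector: role tagging, candidate cores, boundary refinement."""

import numpy as np
import pytest

from prophagekit.detector import (
    HALLMARK_ROLES,
    CandidateRegion,
    DetectorParams,
    annotate_gene_roles,
    assign_role,
    detect_prophages,
    find_candidate_cores,
    refine_boundaries,
)
from prophagekit.records import Interval
from prophagekit.simulate import BACTERIAL_PRODUCTS, ROLE_PRODUCTS, generate_scenario

from conftest import FX1_SPECS, make_genome

FX1_PARAMS = DetectorParams(min_run_genes=5, min_region_bp=1)


class TestRoleAssignment:
    @pytest.mark.parametrize(
        "product,role",
        [
            ("phage tail tape measure protein", "tape_measure"),
            ("site-specific integrase", "integrase"),
            ("ABC transporter permease", "bacterial"),
            ("terminase large subunit", "terminase"),
            ("phage tail sheath protein", "tail_sheath"),
            ("hypothetical protein", "hypothetical"),
            ("putative phage protein", "other_phage"),
            ("lysine exporter", "bacterial"),  # 'lysin' must not match inside words
        ],
    )
    def test_lexicon(self, product, role):
        hyp = product == "hypothetical protein"
        assert assign_role(product, hyp) == role

    def test_total_function_one_tag_per_gene(self, fx1):
        tags = annotate_gene_roles(fx1)
        assert len(tags) == len(fx1.genes)
        assert [t.gene_id for t in tags] == [g.feature_id for g in fx1.genes]

    def test_simulator_products_resolve_to_their_roles(self):
        for role, products in ROLE_PRODUCTS.items():
            for product in products:
                hyp = role == "hypothetical"
                assert assign_role(product, hyp) == role, (role, product)
        for product in BACTERIAL_PRODUCTS:
            assert assign_role(product, False) == "bacterial", product


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerate every contiguous gene window,
# test the published predicate from scratch, keep windows not strictly
# contained in another qualifying window.


def oracle_windows(ann, params, roles):
    genes = ann.genes
    n = len(genes)
    qualifying = []
    for i in range(n):
        for j in range(i, n):
            window = list(range(i, j + 1))
            if len(window) < params.min_run_genes:
                continue
            if roles[i] == "bacterial" or roles[j] == "bacterial":
                continue
            gaps_ok = all(
                genes[k + 1].start_bp - genes[k].end_bp - 1 <= 1000
                for k in window[:-1]
            )
            if not gaps_ok:
                continue
            # longest bacterial run inside the window
            run = worst = 0
            for k in window:
                run = run + 1 if roles[k] == "bacterial" else 0
                worst = max(worst, run)
            if worst > params.max_bacterial_gap:
                continue
            hallmarks = sum(1 for k in window if roles[k] in HALLMARK_ROLES)
            hyp_run = best_hyp = 0
            for k in window:
                hyp_run = hyp_run + 1 if roles[k] == "hypothetical" else 0
                best_hyp = max(best_hyp, hyp_run)
            if not (hallmarks >= params.min_hallmarks
                    or best_hyp >= params.min_hypothetical_run):
                continue
            plus = sum(1 for k in window if genes[k].strand == "+")
            if max(plus, len(window) - plus) / len(window) < params.strand_coherence:
                continue
            if genes[j].end_bp - genes[i].start_bp + 1 < params.min_region_bp:
                continue
            qualifying.append((i, j))
    return [
        (i, j)
        for (i, j) in qualifying
        if not any(
            (i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in qualifying
        )
    ]


def random_gene_specs(rng, n_genes):
    specs = []
    pool = (
        [(p, None) for p in BACTERIAL_PRODUCTS] * 2
        + [("hypothetical protein", None)] * 8
        + [(v[0], None) for v in ROLE_PRODUCTS.values()]
    )
    for _ in range(n_genes):
        product = pool[rng.integers(0, len(pool))][0]
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append((product, strand))
    return specs


class TestCandidateCores:
    def test_all_bacterial_genome_empty(self):
        ann = make_genome([("ABC transporter permease", "+")] * 30)
        assert find_candidate_cores(ann, DetectorParams()) == []

    def test_zero_genes_empty(self):
        ann = make_genome([])
        assert find_candidate_cores(ann, DetectorParams()) == []

    def test_fx1_unique_candidate_spans_genes_4_to_10(self, fx1):
        cands = find_candidate_cores(fx1, FX1_PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.gene_ids == [f"FX1_g{i:03d}" for i in range(4, 11)]
        assert c.interval.start_bp == fx1.genes[3].start_bp
        assert c.interval.end_bp == fx1.genes[9].end_bp
        assert "hallmark_gene" in c.evidence

    def test_fx1_matches_oracle(self, fx1):
        roles = [t.role for t in annotate_gene_roles(fx1)]
        expected = oracle_windows(fx1, FX1_PARAMS, roles)
        assert expected == [(3, 9)]

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_genomes(self, seed):
        """Exhaustive window enumeration agrees exactly on small genomes."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 61))
        ann = make_genome(random_gene_specs(rng, n_genes),
                          genome_id=f"rnd{seed}",
                          gap_bp=int(rng.integers(20, 400)))
        params = DetectorParams(min_run_genes=int(rng.integers(3, 8)),
                                min_region_bp=1)
        roles = [t.role for t in annotate_gene_roles(ann)]
        got = [
            (ann.genes.index(next(g for g in ann.genes if g.feature_id == c.gene_ids[0])),
             ann.genes.index(next(g for g in ann.genes if g.feature_id == c.gene_ids[-1])))
            for c in find_candidate_cores(ann, params, roles=roles)
        ]
        assert got == oracle_windows(ann, params, roles)

    def test_determinism(self, fx1):
        a = find_candidate_cores(fx1, FX1_PARAMS)
        b = find_candidate_cores(fx1, FX1_PARAMS)
        assert [c.gene_ids for c in a] == [c.gene_ids for c in b]


class TestRefineBoundaries:
    def test_fx1_fixpoint(self, fx1):
        c = find_candidate_cores(fx1, FX1_PARAMS)[0]
        refined = refine_boundaries(c, fx1, FX1_PARAMS)
        assert refined.gene_ids == c.gene_ids

    def test_integrase_snap_extends(self):
        specs = list(FX1_SPECS)
        specs[10] = ("site-specific integrase", "+")  # gene 11 now an integrase
        ann = make_genome(specs, genome_id="FX1v")
        core = CandidateRegion(
            genome_id="FX1v",
            interval=Interval(ann.genes[3].start_bp, ann.genes[9].end_bp),
            gene_ids=[g.feature_id for g in ann.genes[3:10]],
        )
        refined = refine_boundaries(core, ann, FX1_PARAMS)
        assert refined.gene_ids[-1] == "FX1v_g011"

    def test_clamps_at_genome_start(self):
        specs = FX1_SPECS[3:]  # begins directly with the phage block
        ann = make_genome(specs, genome_id="FX1s")
        core = find_candidate_cores(ann, FX1_PARAMS)[0]
        refined = refine_boundaries(core, ann, FX1_PARAMS)
        assert refined.gene_ids[0] == "FX1s_g001"


class TestFullDetection:
    def test_refined_regions_never_overlap(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            ann = make_genome(random_gene_specs(rng, 50), genome_id=f"ov{seed}")
            regions = detect_prophages(ann, DetectorParams(min_run_genes=3,
                                                           min_region_bp=1))
            for a, b in zip(regions, regions[1:]):
                assert a.interval.end_bp < b.interval.start_bp

    def test_recovers_synthetic_implant(self):
        genomes, truth = generate_scenario(1, seed=1)
        ann = next(iter(genomes.values()))
        regions = detect_prophages(ann)
        assert len(regions) == 1
        entry = truth.entries[0]
        assert regions[0].interval.reciprocal_overlap(entry.interval) >= 0.9
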