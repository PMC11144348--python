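"""Synthetic-data generators: determinism, truth consistency, statistics."""

import numpy as np
import pytest

from prophagekit.consensus import assess_quality, ConsensusRegion
from prophagekit.detector import annotate_gene_roles
from prophagekit.io import gc_content
from prophagekit.morphology import classify_morphology, score_gene_order
from prophagekit.records import AnnotatedGenome
from prophagekit.similarity import pairwise_similarity
from prophagekit.simulate import (
    MethodProfile,
    TruthSet,
    degrade_prophage,
    generate_host_background,
    generate_scenario,
    implant_prophage,
    intact_myoviral_template,
    intact_siphoviral_template,
    mutate_sequence,
    simulate_detector_reports,
)


def region_roles(ann: AnnotatedGenome, entry) -> list:
    gene_map = {g.feature_id: g for g in ann.genes}
    sub = AnnotatedGenome(genome=ann.genome, genes=[])
    sub.genes = [gene_map[fid] for fid in entry.gene_ids if fid in gene_map]
    return [t.role for t in annotate_gene_roles(sub)]


class TestHostBackground:
    def test_length_and_gc(self):
        ann = generate_host_background(100_000, 40.0, seed=7)
        assert ann.genome.length_bp == 100_000
        assert abs(gc_content(ann.genome.sequence) - 40.0) < 1.0

    def test_deterministic(self):
        a = generate_host_background(60_000, 45.0, seed=3)
        b = generate_host_background(60_000, 45.0, seed=3)
        assert a.genome.sequence == b.genome.sequence
        assert [(g.start_bp, g.end_bp, g.strand, g.product) for g in a.genes] == [
            (g.start_bp, g.end_bp, g.strand, g.product) for g in b.genes
        ]

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="background too short"):
            generate_host_background(1000, 40.0, seed=1)

    def test_gc_bounds(self):
        with pytest.raises(ValueError):
            generate_host_background(60_000, 0.0, seed=1)

    def test_gene_tiling(self):
        ann = generate_host_background(100_000, 40.0, seed=2)
        strands = {g.strand for g in ann.genes}
        assert strands == {"+", "-"}
        lengths = [g.length_bp for g in ann.genes]
        assert 700 < np.mean(lengths) < 1300


class TestImplant:
    def test_siphoviral_by_construction(self):
        ann = generate_host_background(100_000, 40.0, seed=5)
        ann2, entry = implant_prophage(ann, intact_siphoviral_template(), 20_000, seed=5)
        assert classify_morphology(region_roles(ann2, entry)).morphology == "Siphoviral"

    def test_myoviral_contains_tail_sheath(self):
        ann = generate_host_background(100_000, 40.0, seed=5)
        ann2, entry = implant_prophage(ann, intact_myoviral_template(), 20_000, seed=5)
        roles = region_roles(ann2, entry)
        assert "tail_sheath" in roles
        assert classify_morphology(roles).morphology == "Myoviral"

    def test_intact_template_scores_intact(self):
        ann = generate_host_background(100_000, 40.0, seed=6)
        ann2, entry = implant_prophage(ann, intact_siphoviral_template(), 30_000, seed=6)
        assert score_gene_order(region_roles(ann2, entry)).intact

    def test_truth_gene_consistency(self):
        """Every truth gene lies inside its truth interval, on one strand."""
        ann = generate_host_background(100_000, 40.0, seed=8)
        ann2, entry = implant_prophage(ann, intact_myoviral_template(), 42_000, seed=8)
        gene_map = {g.feature_id: g for g in ann2.genes}
        strands = set()
        for fid in entry.gene_ids:
            g = gene_map[fid]
            assert entry.interval.start_bp <= g.start_bp <= g.end_bp <= entry.interval.end_bp
            strands.add(g.strand)
        assert len(strands) == 1
        assert ann2.genome.length_bp == ann.genome.length_bp

    def test_overlapping_implant_errors(self):
        ann = generate_host_background(100_000, 40.0, seed=9)
        truth = TruthSet()
        ann, _ = implant_prophage(ann, intact_siphoviral_template(), 20_000,
                                  seed=9, truth=truth)
        with pytest.raises(ValueError, match="overlaps existing truth entry"):
            implant_prophage(ann, intact_siphoviral_template(), 25_000,
                             seed=10, truth=truth)

    def test_does_not_fit_errors(self):
        ann = generate_host_background(50_000, 40.0, seed=9)
        with pytest.raises(ValueError, match="does not fit"):
            implant_prophage(ann, intact_siphoviral_template(), 48_000, seed=9)


class TestDegrade:
    def setup_method(self):
        ann = generate_host_background(100_000, 40.0, seed=11)
        self.ann, self.entry = implant_prophage(
            ann, intact_siphoviral_template(), 30_000, seed=11
        )

    def test_fraction_zero_identity(self):
        ann2, entry2 = degrade_prophage(self.ann, self.entry, 0.0, seed=1)
        assert ann2 is self.ann
        assert not entry2.degraded

    def test_fraction_one_errors(self):
        with pytest.raises(ValueError):
            degrade_prophage(self.ann, self.entry, 1.0, seed=1)

    def test_half_deletion_halves_completeness(self):
        ann2, entry2 = degrade_prophage(self.ann, self.entry, 0.5, seed=2)
        assert entry2.degraded
        n_before = len(self.entry.gene_ids)
        assert len(entry2.gene_ids) == n_before - round(0.5 * n_before)
        region = ConsensusRegion(genome_id=ann2.id, interval=entry2.interval,
                                 support_methods={"m"})
        q = assess_quality(region, ann2)
        assert q.completeness_pct <= 70.0  # contiguous half gone

    def test_terminase_deletion_breaks_intactness(self):
        for seed in range(8):
            ann2, entry2 = degrade_prophage(self.ann, self.entry, 0.4, seed=seed)
            roles = region_roles(ann2, entry2)
            intact = score_gene_order(roles).intact
            if "terminase" in entry2.deleted_roles:
                assert not intact
            assert set(roles).isdisjoint(entry2.deleted_roles - {"hypothetical"})


class TestMutate:
    def test_identity(self):
        seq = "ACGTTGCA" * 100
        assert mutate_sequence(seq, 0.0, 0.0, seed=1) == seq

    def test_substitution_count_concentrates(self):
        rng = np.random.default_rng(1)
        from prophagekit.simulate import random_sequence

        seq = random_sequence(10_000, 50.0, rng)
        mutated = mutate_sequence(seq, 0.05, 0.0, seed=3)
        diffs = sum(1 for a, b in zip(seq, mutated) if a != b)
        assert abs(diffs - 500) <= 3 * np.sqrt(10_000 * 0.05 * 0.95)

    def test_similarity_of_unmutated_copy_is_100(self):
        rng = np.random.default_rng(2)
        from prophagekit.simulate import random_sequence

        seq = random_sequence(3_000, 40.0, rng)
        assert pairwise_similarity(seq, mutate_sequence(seq, 0.0, 0.0, 3))[0] == 100.0

    def test_deterministic(self):
        seq = "ACGT" * 500
        assert mutate_sequence(seq, 0.1, 0.01, 5) == mutate_sequence(seq, 0.1, 0.01, 5)


class TestDetectorReports:
    def make_truth(self, n=10, genome_len=200_000):
        truth = TruthSet()
        from prophagekit.records import Interval
        from prophagekit.simulate import TruthEntry

        lengths = {}
        for i in range(n):
            gid = f"g{i:03d}"
            truth.entries.append(
                TruthEntry(genome_id=gid, interval=Interval(50_000, 80_000),
                           template_name="t", strand="+")
            )
            lengths[gid] = genome_len
        return truth, lengths

    def test_perfect_methods_reproduce_truth(self):
        truth, lengths = self.make_truth()
        profiles = [MethodProfile("m1", sensitivity=1.0, boundary_jitter_sd_bp=0.0),
                    MethodProfile("m2", sensitivity=1.0, boundary_jitter_sd_bp=0.0)]
        reports = simulate_detector_reports(truth, profiles, seed=4,
                                            genome_lengths=lengths)
        for rep in reports:
            assert len(rep) == len(truth)
            got = {(c.genome_id, c.interval.start_bp, c.interval.end_bp)
                   for c in rep.calls}
            want = {(e.genome_id, e.interval.start_bp, e.interval.end_bp)
                    for e in truth.entries}
            assert got == want

    def test_zero_sensitivity_empty(self):
        truth, lengths = self.make_truth()
        reports = simulate_detector_reports(
            truth, [MethodProfile("m", sensitivity=0.0)], seed=4,
            genome_lengths=lengths,
        )
        assert len(reports[0]) == 0

    def test_false_calls_never_overlap_truth(self):
        truth, lengths = self.make_truth(n=5)
        reports = simulate_detector_reports(
            truth,
            [MethodProfile("m", sensitivity=0.0, false_call_rate_per_mb=10.0)],
            seed=9,
            genome_lengths=lengths,
        )
        assert len(reports[0]) > 0
        for c in reports[0].calls:
            for e in truth.for_genome(c.genome_id):
                assert not c.interval.overlaps(e.interval)

    def test_no_profiles_errors(self):
        with pytest.raises(ValueError):
            simulate_detector_reports(TruthSet(), [], seed=1)


class TestScenarioAndSeparability:
    def test_scenario_counts_and_determinism(self):
        g1, t1 = generate_scenario(3, seed=2)
        g2, t2 = generate_scenario(3, seed=2)
        assert len(g1) == 3 and len(t1) == 3
        for gid in g1:
            assert g1[gid].genome.sequence == g2[gid].genome.sequence

    def test_family_separability(self):
        """Close mutants chain above the genus threshold; distant families
        stay far below it."""
        from prophagekit.simulate import random_sequence

        for seed in range(3):
            base_a = random_sequence(6_000, 40.0, np.random.default_rng(1000 + seed))
            base_b = random_sequence(6_000, 40.0, np.random.default_rng(2000 + seed))
            fam_a = [mutate_sequence(base_a, 0.02, 0.0, 10 * seed + k) for k in (1, 2)]
            fam_b = [mutate_sequence(base_b, 0.02, 0.0, 10 * seed + k) for k in (3, 4)]
            within_a = pairwise_similarity(*fam_a)[0]
            within_b = pairwise_similarity(*fam_b)[0]
            between = pairwise_similarity(fam_a[0], fam_b[0])[0]
            assert within_a > 70 > between
            assert within_b > 70 > between
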