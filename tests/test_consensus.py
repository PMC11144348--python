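"""Consensus integration: matching, support rule, quality proxy, naming."""

import itertools
import random

import pytest

from prophagekit.consensus import (
    ConsensusParams,
    ConsensusRegion,
    apply_support_rule,
    assess_quality,
    match_calls,
    name_regions,
)
from prophagekit.records import DetectionCall, DetectionReport, Interval

from conftest import make_genome


def call(method, start, end, genome="g1"):
    return DetectionCall(genome_id=genome, interval=Interval(start, end), method=method)


def reports_from(calls):
    by_method = {}
    for c in calls:
        by_method.setdefault(c.method, []).append(c)
    return [DetectionReport(method=m, calls=cs) for m, cs in by_method.items()]


def brute_force_components(calls, r):
    """Transitive closure over the reciprocal-overlap relation."""
    groups = [{i} for i in range(len(calls))]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            ga, gb = groups[a], groups[b]
            if any(
                calls[i].genome_id == calls[j].genome_id
                and calls[i].interval.reciprocal_overlap(calls[j].interval) >= r
                for i in ga
                for j in gb
            ):
                groups[a] = ga | gb
                del groups[b]
                changed = True
                break
    return sorted(frozenset(g) for g in groups)


class TestMatchCalls:
    def test_near_identical_merge(self):
        regions = match_calls(reports_from([call("m1", 1000, 20000),
                                            call("m2", 1500, 19000)]))
        assert len(regions) == 1
        assert regions[0].support_methods == {"m1", "m2"}
        assert regions[0].interval == Interval(1000, 20000)

    def test_disjoint_stay_separate(self):
        regions = match_calls(reports_from([call("m1", 1000, 20000),
                                            call("m2", 30000, 45000)]))
        assert len(regions) == 2
        assert all(len(r.support_methods) == 1 for r in regions)

    def test_chain_components(self):
        """A-B and B-C linked, A-C not: still one region (single linkage)."""
        calls = [call("m1", 1, 1000), call("m2", 401, 1400), call("m3", 801, 1800)]
        assert calls[0].interval.reciprocal_overlap(calls[1].interval) >= 0.5
        assert calls[1].interval.reciprocal_overlap(calls[2].interval) >= 0.5
        assert calls[0].interval.reciprocal_overlap(calls[2].interval) < 0.5
        regions = match_calls(reports_from(calls))
        assert len(regions) == 1
        assert regions[0].support_methods == {"m1", "m2", "m3"}
        assert [frozenset({0, 1, 2})] == brute_force_components(calls, 0.5)

    def test_matches_brute_force_on_random_call_sets(self):
        rng = random.Random(7)
        for _ in range(20):
            calls = []
            for i in range(rng.randint(2, 12)):
                start = rng.randint(1, 50000)
                calls.append(
                    call(f"m{rng.randint(1, 4)}", start,
                         start + rng.randint(500, 20000),
                         genome=f"g{rng.randint(1, 2)}")
                )
            regions = match_calls(reports_from(calls))
            expected = brute_force_components(calls, 0.5)
            got_components = sorted(
                frozenset(
                    i for i, c in enumerate(calls)
                    if c.genome_id == reg.genome_id
                    and reg.interval.start_bp <= c.interval.start_bp
                    and c.interval.end_bp <= reg.interval.end_bp
                )
                for reg in regions
            )
            # conservation: every call inside exactly one region
            assert sum(len(g) for g in expected) == len(calls)
            assert len(regions) == len(expected)

    def test_permutation_invariance(self):
        calls = [call("m1", 1000, 9000), call("m2", 2000, 9500),
                 call("m3", 40000, 52000), call("m1", 41000, 51000)]
        base = match_calls(reports_from(calls))
        rng = random.Random(3)
        for _ in range(5):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            other = match_calls(list(reversed(reports_from(shuffled))))
            assert [(r.interval, sorted(r.support_methods)) for r in base] == [
                (r.interval, sorted(r.support_methods)) for r in other
            ]


class TestSupportRule:
    def region(self, methods):
        return ConsensusRegion(genome_id="g1", interval=Interval(1, 10000),
                               support_methods=set(methods))

    def test_two_methods_kept(self):
        kept = apply_support_rule([self.region({"PHASTER", "geNomad"})])
        assert len(kept) == 1 and not kept[0].manual_only

    def test_manual_only_kept_flagged(self):
        kept = apply_support_rule([self.region({"manual_heuristic"})])
        assert len(kept) == 1 and kept[0].manual_only

    def test_single_automatic_method_dropped(self):
        assert apply_support_rule([self.region({"geNomad"})]) == []

    def test_manual_only_disabled(self):
        params = ConsensusParams(allow_manual_only=False)
        assert apply_support_rule([self.region({"manual_heuristic"})], params) == []

    def test_min_support_one_is_identity(self):
        regions = [self.region({"geNomad"}), self.region({"manual_heuristic"}),
                   self.region({"a", "b"})]
        params = ConsensusParams(min_support=1)
        assert apply_support_rule(regions, params) == regions


PHAGE_ROLE_PRODUCTS = [
    "terminase large subunit", "phage portal protein", "prohead protease",
    "phage scaffold protein", "major capsid protein", "head-tail joining protein",
    "tail shaft protein", "phage tail tape measure protein",
    "baseplate assembly protein", "tail fiber protein",
]


class TestQuality:
    def region_over(self, ann):
        return ConsensusRegion(
            genome_id=ann.id,
            interval=Interval(ann.genes[0].start_bp, ann.genes[-1].end_bp),
            support_methods={"m1", "m2"},
        )

    def test_no_viral_genes_rejected(self):
        ann = make_genome([("ABC transporter permease", "+"),
                           ("hypothetical protein", "+")] * 3)
        q = assess_quality(self.region_over(ann), ann)
        assert q.viral_gene_count == 0
        assert q.tier == "rejected"

    def test_all_ten_roles_high(self):
        ann = make_genome([(p, "+") for p in PHAGE_ROLE_PRODUCTS])
        q = assess_quality(self.region_over(ann), ann)
        assert q.completeness_pct == 100.0
        assert q.tier == "high"

    def test_five_roles_medium_boundary(self):
        ann = make_genome([(p, "+") for p in PHAGE_ROLE_PRODUCTS[:5]])
        q = assess_quality(self.region_over(ann), ann)
        assert q.completeness_pct == 50.0
        assert q.tier == "medium"

    def test_four_roles_low(self):
        ann = make_genome([(p, "+") for p in PHAGE_ROLE_PRODUCTS[:4]])
        assert assess_quality(self.region_over(ann), ann).tier == "low"

    def test_region_outside_bounds_errors(self):
        ann = make_genome([("terminase", "+")])
        bad = ConsensusRegion(genome_id=ann.id,
                              interval=Interval(1, ann.genome.length_bp + 50),
                              support_methods={"m"})
        with pytest.raises(ValueError, match="outside annotation bounds"):
            assess_quality(bad, ann)


class TestNaming:
    def region(self, genome, start, end):
        return ConsensusRegion(genome_id=genome, interval=Interval(start, end),
                               support_methods={"m"})

    def test_two_regions_ordered_by_start(self):
        regions = [self.region("strain1", 200000, 210000),
                   self.region("strain1", 10000, 20000)]
        name_regions(regions, aliases={"strain1": "B43"})
        by_start = sorted(regions, key=lambda r: r.interval.start_bp)
        assert [r.name for r in by_start] == ["B43P1", "B43P2"]

    def test_single_region_p1(self):
        regions = [self.region("s", 5, 10)]
        name_regions(regions)
        assert regions[0].name == "sP1"

    def test_empty(self):
        assert name_regions([]) == []
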