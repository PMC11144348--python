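"""Simulate annotated genomes with implanted prophages and detect them.

Builds three 100 kb synthetic host genomes, each carrying one intact
prophage cassette at a known location, then runs the annotation-based
heuristic detector and compares its calls against the ground truth.
"""

from prophagekit import detect_prophages, generate_scenario

genomes, truth = generate_scenario(3, seed=42)

print("genome            truth interval        detected interval     recip. overlap")
for gid, ann in genomes.items():
    entry = truth.for_genome(gid)[0]
    calls = detect_prophages(ann)
    for c in calls:
        ov = c.interval.reciprocal_overlap(entry.interval)
        print(
            f"{gid:16s}  {entry.interval.start_bp:>7}-{entry.interval.end_bp:<8}"
            f"  {c.interval.start_bp:>7}-{c.interval.end_bp:<8}  {ov:.3f}"
        )

# A reciprocal overlap of 1.000 means the detector recovered the implanted
# prophage's gene span exactly; values >= 0.9 count as recovered in the
# package's benchmarks.
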