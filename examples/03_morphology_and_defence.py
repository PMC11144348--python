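"""Morphology, gene-order intactness and defence-system screening.

Runs the rule-based classifiers on small hand-written gene lists so each
decision is easy to follow.
"""

from prophagekit import classify_morphology, detect_defence_systems, score_gene_order
from prophagekit.records import GeneFeature

# Morphology: a tail sheath protein implies a contractile (myoviral) tail;
# a tape measure protein without a sheath implies a siphoviral tail.
for roles in (["tail_sheath", "tape_measure", "terminase"],
              ["tape_measure", "terminase"],
              ["integrase", "other_phage"]):
    print(f"{roles} -> {classify_morphology(roles).morphology}")

# Gene order: the canonical head-to-tail cassette in order scores 10/10.
canonical = ["integrase", "terminase", "portal", "protease", "scaffold",
             "major_capsid", "head_tail_joining", "tail_shaft", "tape_measure",
             "baseplate", "tail_fibre"]
score = score_gene_order(canonical)
print(f"\ncanonical cassette: {score.longest_in_order}/10 in order, "
      f"intact={score.intact}")
shuffled = ["tail_fibre", "terminase", "baseplate", "portal", "integrase"]
score = score_gene_order(shuffled)
print(f"scrambled cassette: {score.longest_in_order}/10 in order, "
      f"intact={score.intact}")

# Defence systems: both components must co-occur within 5 genes.
def genes(products):
    return [GeneFeature(feature_id=f"g{i}", start_bp=1 + i * 1000,
                        end_bp=900 + i * 1000, strand="+", product=p)
            for i, p in enumerate(products)]

hits = detect_defence_systems(
    genes(["ThsB TIR-domain protein", "ThsA SIR2-domain NADase",
           "DNA modification methylase", "hypothetical protein",
           "restriction endonuclease"])
)
print("\ndefence hits:", [(h.system, h.component_genes) for h in hits])
print("lone MTase:", detect_defence_systems(genes(["DNA methyltransferase"])))
# The lone methyltransferase correctly produces no call: an R-M system needs
# its restriction endonuclease partner nearby.
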