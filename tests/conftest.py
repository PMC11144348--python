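"""Shared fixtures: toy annotated genomes and the synthetic reference set."""

import pytest

from prophagekit.records import AnnotatedGenome, GeneFeature, GenomeRecord


def make_genome(gene_specs, genome_length=None, genome_id="toy", gap_bp=100,
                gene_len=600):
    """Build an AnnotatedGenome from (product, strand) tuples.

    Genes are tiled left to right with ``gap_bp`` intergenic gaps; the
    sequence itself is a neutral filler (detection operates on annotations).
    """
    genes = []
    pos = 201
    for i, (product, strand) in enumerate(gene_specs, start=1):
        genes.append(
            GeneFeature(
                feature_id=f"{genome_id}_g{i:03d}",
                start_bp=pos,
                end_bp=pos + gene_len - 1,
                strand=strand,
                product=product,
            )
        )
        pos += gene_len + gap_bp
    length = genome_length or (pos + 200)
    seq = ("ACGT" * (length // 4 + 1))[:length]
    return AnnotatedGenome(
        genome=GenomeRecord(id=genome_id, sequence=seq), genes=genes
    )


#: 12-gene toy layout: 3 bacterial (mixed strand), 7 phage genes on '+'
#: (integrase, 3x hypothetical, terminase, portal, major capsid), 2 bacterial.
FX1_SPECS = [
    ("ABC transporter permease", "+"),
    ("DNA gyrase subunit B", "-"),
    ("elongation factor Tu", "-"),
    ("site-specific integrase", "+"),
    ("hypothetical protein", "+"),
    ("hypothetical protein", "+"),
    ("hypothetical protein", "+"),
    ("terminase large subunit", "+"),
    ("phage portal protein", "+"),
    ("major capsid protein", "+"),
    ("MFS transporter", "-"),
    ("sensor histidine kinase", "+"),
]


@pytest.fixture
def fx1():
    return make_genome(FX1_SPECS, genome_id="FX1")


@pytest.fixture(scope="session")
def reference_records():
    from prophagekit.synthetic_reference import build_synthetic_reference_set

    return build_synthetic_reference_set(seed=1)


@pytest.fixture(scope="session")
def reference_matrix(reference_records):
    from prophagekit.similarity import similarity_matrix

    return similarity_matrix(reference_records)
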