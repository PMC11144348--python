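"""Readers and writers for the external formats, plus core sequence utilities.

FASTA and GenBank parsing is delegated to Biopython; GFF3 parsing to gffutils.
All files use 1-based inclusive coordinates.
"""

from __future__ import annotations

from typing import List, Optional

import pandas as pd
from Bio import SeqIO

from .records import (
    AnnotatedGenome,
    DetectionCall,
    DetectionReport,
    GeneFeature,
    GenomeRecord,
    Interval,
)

__all__ = [
    "read_genome_fasta",
    "write_genome_fasta",
    "read_annotations",
    "gc_content",
    "reverse_complement",
    "read_detector_report",
    "write_detector_report",
    "extract_region",
    "write_region_table",
    "read_region_table",
    "REGION_TABLE_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn", "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _normalise_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_genome_fasta(path) -> List[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Sequences are uppercased and RNA U is mapped to T. Raises on an empty
    file, a record with no sequence, or duplicate record ids.
    """
    records: List[GenomeRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalise_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty sequence for {rec.id}")
        records.append(
            GenomeRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_genome_fasta(records: List[GenomeRecord], path, width: int = 70):
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


def _genbank_to_annotated(path) -> AnnotatedGenome:
    rec = next(SeqIO.parse(str(path), "genbank"))
    genome = GenomeRecord(
        id=rec.id, sequence=_normalise_sequence(str(rec.seq)), description=rec.description
    )
    genes = []
    n = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n += 1
        quals = feat.qualifiers
        fid = (
            quals.get("locus_tag", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"{rec.id}_cds{n}"
        )
        product = quals.get("product", [""])[0]
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        if end > genome.length_bp:
            raise ValueError(
                f"feature {fid} extends to {end} beyond sequence end {genome.length_bp}"
            )
        genes.append(
            GeneFeature(feature_id=fid, start_bp=start, end_bp=end, strand=strand,
                        product=product)
        )
    return AnnotatedGenome(genome=genome, genes=genes)


def _gff3_to_annotated(path, sequence: Optional[GenomeRecord]) -> AnnotatedGenome:
    import gffutils

    with open(path) as fh:
        text = fh.read()
    gff_part, fasta_part = text, None
    if "##FASTA" in text:
        gff_part, fasta_part = text.split("##FASTA", 1)
    genome = sequence
    if genome is None:
        if fasta_part is None:
            raise ValueError(
                f"{path}: GFF3 has no embedded ##FASTA section and no sequence "
                "was supplied"
            )
        import io as _io

        fasta_records = list(SeqIO.parse(_io.StringIO(fasta_part.lstrip("\n")), "fasta"))
        if not fasta_records:
            raise ValueError(f"{path}: empty ##FASTA section")
        rec = fasta_records[0]
        genome = GenomeRecord(
            id=rec.id, sequence=_normalise_sequence(str(rec.seq)),
            description=rec.description,
        )
    db = gffutils.create_db(
        gff_part, dbfn=":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start"), start=1):
        fid = feat.id or f"{genome.id}_cds{i}"
        product = (feat.attributes.get("product") or feat.attributes.get("Name") or [""])[0]
        if feat.end > genome.length_bp:
            raise ValueError(
                f"feature {fid} extends to {feat.end} beyond sequence end "
                f"{genome.length_bp}"
            )
        genes.append(
            GeneFeature(feature_id=fid, start_bp=feat.start, end_bp=feat.end,
                        strand="-" if feat.strand == "-" else "+", product=product)
        )
    return AnnotatedGenome(genome=genome, genes=genes)


def read_annotations(path, format: str = "genbank",
                     sequence: Optional[GenomeRecord] = None) -> AnnotatedGenome:
    """Read gene annotations into an AnnotatedGenome.

    Only CDS features are retained. ``format`` is ``"genbank"`` or ``"gff3"``;
    for GFF3 the sequence comes from an embedded ``##FASTA`` section or the
    ``sequence`` argument.
    """
    fmt = format.lower()
    if fmt == "genbank":
        return _genbank_to_annotated(path)
    if fmt == "gff3":
        return _gff3_to_annotated(path, sequence)
    raise ValueError(f"unknown annotation format {format!r}")


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases only.

    Ambiguity codes (including N) are excluded from both numerator and
    denominator. Raises when no unambiguous base is present. The return value
    is unrounded; round at display time.
    """
    if not sequence:
        raise ValueError("undefined GC for empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("undefined GC: sequence has no unambiguous bases")
    return 100.0 * gc / (gc + at)


def read_detector_report(path, method_name: str) -> DetectionReport:
    """Read a normalized detector-report TSV (genome_id, start_bp, end_bp[, score])."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    for col in ("genome_id", "start_bp", "end_bp"):
        if col not in df.columns:
            raise ValueError(f"detector report {path} missing required column {col!r}")
    calls = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.start_bp > row.end_bp:
            raise ValueError(f"inverted interval at line {row_idx} of {path}")
        score = None
        if "score" in df.columns:
            val = getattr(row, "score")
            score = None if pd.isna(val) else float(val)
        calls.append(
            DetectionCall(
                genome_id=str(row.genome_id),
                interval=Interval(int(row.start_bp), int(row.end_bp)),
                method=method_name,
                score=score,
            )
        )
    return DetectionReport(method=method_name, calls=calls)


def write_detector_report(report: DetectionReport, path):
    rows = [
        {
            "genome_id": c.genome_id,
            "start_bp": c.interval.start_bp,
            "end_bp": c.interval.end_bp,
            "score": "" if c.score is None else c.score,
        }
        for c in report.calls
    ]
    pd.DataFrame(rows, columns=["genome_id", "start_bp", "end_bp", "score"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def extract_region(genome: GenomeRecord, interval: Interval) -> GenomeRecord:
    """Extract the inclusive subsequence [start_bp, end_bp] as a new record."""
    if interval.start_bp < 1 or interval.end_bp > genome.length_bp:
        raise ValueError(
            f"interval {interval.start_bp}-{interval.end_bp} out of bounds for "
            f"{genome.id} (length {genome.length_bp}; coordinates are 1-based)"
        )
    sub = genome.sequence[interval.start_bp - 1 : interval.end_bp]
    return GenomeRecord(
        id=f"{genome.id}:{interval.start_bp}-{interval.end_bp}",
        sequence=sub,
        description=f"region of {genome.id}",
    )


def write_gff3(annotated_genome: AnnotatedGenome, path, embed_fasta: bool = True):
    """Write CDS features as GFF3, with the sequence in a ##FASTA section."""
    g = annotated_genome
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.genome.length_bp}\n")
        for feat in g.genes:
            attrs = f"ID={feat.feature_id};product={feat.product}"
            fh.write(
                "\t".join(
                    [
                        g.id, "prophagekit", "CDS",
                        str(feat.start_bp), str(feat.end_bp),
                        ".", feat.strand, "0", attrs,
                    ]
                )
                + "\n"
            )
        if embed_fasta:
            fh.write("##FASTA\n")
            fh.write(f">{g.id}\n")
            seq = g.genome.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path


REGION_TABLE_COLUMNS = [
    "name",
    "quality_tier",
    "completeness_pct",
    "length_kb",
    "cds_count",
    "gc_pct",
    "morphology",
    "intact_flag",
    "defence_systems",
    "support_methods",
]


def write_region_table(regions, path):
    """Write consensus regions as the Table-1-style TSV report.

    length_kb and gc_pct are rendered at 1 decimal place; a region with no
    defence hits prints "None found".
    """
    rows = []
    for r in regions:
        defence = getattr(r, "defence_systems", None) or []
        defence_str = ";".join(defence) if defence else "None found"
        rows.append(
            {
                "name": r.name,
                "quality_tier": r.quality.tier if r.quality else "",
                "completeness_pct": r.quality.completeness_pct if r.quality else "",
                "length_kb": f"{r.length_kb:.1f}",
                "cds_count": r.cds_count,
                "gc_pct": f"{r.gc_pct:.1f}",
                "morphology": getattr(r, "morphology", "") or "",
                "intact_flag": bool(getattr(r, "intact", False)),
                "defence_systems": defence_str,
                "support_methods": ",".join(sorted(r.support_methods)),
            }
        )
    pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REGION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table {path} missing columns {missing}")
    return df
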