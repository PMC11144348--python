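# Methods

This note documents the models, rules and numerical choices behind
`prophagekit`, in the spirit of the methods documentation of mature
scientific packages: what each stage assumes, which knobs matter, and what a
passing test does — and does not — establish.

## 1. Heuristic prophage detection

### Role tagging

Every CDS receives exactly one role from an ordered keyword lexicon
(`data/phage_lexicon.yaml`; case-insensitive regular expressions, first
match wins, most specific patterns first). Sixteen roles are distinguished:
the ten canonical structural roles (terminase, portal, protease, scaffold,
major capsid, head/tail joining, tail shaft, tape measure, baseplate, tail
fibre), plus integrase, tail sheath, lysis, a catch-all `other_phage`,
`hypothetical` (product matches "hypothetical protein", "uncharacterized
protein" or "DUF"), and `bacterial` for everything else. The lexicon is a
plain editable file because no published keyword set exists for these
genomes; users with organism-specific vocabularies should extend it.
"Hallmark" roles — the conserved, recognisable phage genes — are all roles
except `other_phage`, `hypothetical` and `bacterial`.

### Candidate cores

A window of consecutive genes qualifies as a candidate prophage core when:

| condition | default | rationale |
|---|---|---|
| gene count ≥ `min_run_genes` | 15 | real prophages here carry ≥ 27 CDS; 15 leaves margin |
| every intergenic gap ≤ 1 kb | fixed | operationalises "co-transcribed and contiguous" |
| no internal run of > `max_bacterial_gap` consecutive bacterial genes | 2 | a longer bacterial stretch separates two candidates |
| terminal genes non-bacterial | fixed | candidates must not begin/end on host genes |
| ≥ `min_hallmarks` hallmark genes OR a hypothetical run ≥ `min_hypothetical_run` | 1 / 5 | either recognisable phage genes or the anonymous-gene desert typical of prophages |
| ≥ `strand_coherence` of genes on one strand | 0.70 | phage operons are co-oriented, but real prophages carry a few reverse genes; 100% would be too strict |
| span ≥ `min_region_bp` | 10 kb | smallest credible prophage regions are ~12 kb |

The detector returns the *maximal* qualifying windows (those not contained
in a larger qualifying window). An exhaustive-enumeration oracle in the test
suite checks exact agreement on random small genomes; because strand
coherence is non-monotone, maximality is decided against the full window
set, not greedily.

### Boundary refinement

Boundaries extend outward gene-by-gene over phage-role or hypothetical
genes while overall strand coherence stays ≥ 0.70. Extension stops at the
first of: `max_bacterial_gap` consecutive bacterial genes (annotation turns
host-like again), or a strand switch immediately following a bacterial gene
(genes "cross strands" again). If an integrase lies within five genes beyond
a final edge, the boundary snaps outward to include it (integrases sit at
prophage termini, adjacent to the attachment site); extension then resumes
until a fixpoint. Refined regions that overlap are merged (union), so final
calls never overlap. Intervals always span whole genes.

## 2. Multi-detector consensus

Calls from different methods are matched by reciprocal overlap:
`overlap/len(A) ≥ r` **and** `overlap/len(B) ≥ r`, with `r = 0.5` — the
common genomics convention; no published matching rule exists for this
workflow. Connected components of the match graph become consensus regions
(single linkage, so A–B and B–C chains merge even when A–C falls below
`r`); the region interval is the union span of its members, optionally
re-refined against the annotation (mirroring the practice of manually
re-estimating automated boundaries).

The support rule keeps regions identified by ≥ 2 distinct methods. A region
supported only by the manual heuristic is kept but flagged `manual_only`
rather than silently accepted or dropped: precedent exists for accepting
such regions case by case, so the report preserves the flag for downstream
judgement.

### Quality proxy

Real pipelines gate candidate prophages with CheckV, whose database-driven
completeness estimate is out of scope here. The proxy: a region whose genes
include *no* viral role (nothing beyond bacterial/hypothetical) is
**rejected** outright; otherwise completeness is
`100 × (distinct canonical structural roles present) / 10`, tiered
**high** (> 90), **medium** (50–90) or **low** (< 50), matching the tier
vocabulary of CheckV-style reports. The proxy is deliberately
annotation-only: it measures structural-module representation, not genome
completeness against a reference database.

Regions are named `{alias}P{k}` with `k` ordered by start coordinate within
each genome; the genome→alias table is user configuration (aliases are
editorial, not derivable).

## 3. Morphology, intactness, defence

- **Morphology** (integrated phages cannot be imaged, so tail genes stand
  in): any tail sheath ⇒ `Myoviral` (contractile tail); else any tape
  measure ⇒ `Siphoviral`; else `Unclassified`. Order-invariant.
- **Intactness**: the region's role sequence is scored against the
  canonical 10-role head-to-tail order as the longest strictly in-order
  subsequence with each role credited once (computed as a longest strictly
  increasing subsequence over canonical indices — tandem paralogs cannot
  inflate it, and adding genes can never lower it). `intact` requires an
  integrase, a terminase and ≥ 7/10 roles in order. The 7/10 cutoff is a
  package choice: curators call prophages "potentially intact" on order +
  integrase + terminase without a printed threshold; 7 is configurable.
  Interleaved non-structural genes are ignored — order is scored on the
  role subsequence only.
- **Defence systems** (`data/defence_rules.yaml`): Thoeris type 1 needs a
  ThsA-like (ThsA/SIR2/NAD) and a ThsB-like (ThsB/TIR) gene within 5 genes;
  R-M type II needs an MTase-like and an REase-like gene within 5 genes.
  Components are consumed greedily so a lone component (e.g. an orphan
  methyltransferase) never fires. This is a keyword screen; PADLOC remains
  the authoritative profile-based tool.

## 4. Intergenomic similarity

The pairwise score is identity-weighted and length-normalised:

    S(A,B) = 100 · 2I / (L_A + L_B)

where `I` is the number of identical aligned base pairs over the accepted
alignment tiling. This is the aggregation that coverage-times-identity
heat-map calculators reduce to when both genomes' coverages are pooled over
their summed lengths; it gives S = 100 for identical genomes and S ≈ 0 for
unrelated ones, and S falls with both divergence and length difference
(a deleted/truncated variant cannot reach 100 against its parent).

Search is seed-and-extend over both strands:

1. shared 11-mers (ambiguity-free) seed diagonals; k-mers occurring > 100
   times are skipped; a diagonal cluster needs ≥ 2 seeds (BLAST's two-hit
   rule) except on inputs shorter than 4k;
2. around the seeds of each diagonal (±120 bp padding, clusters split at
   240 bp seed gaps) all maximal-scoring ungapped segments are extracted by
   the Ruzzo–Tompa algorithm under the BLASTN-default +1/−2
   reward/penalty, dropping segments scoring below the seed length;
3. segments are chained collinearly across nearby diagonals (≤ 200 bp
   unaligned, ≤ 50 bp diagonal shift); each bridge is charged the affine
   gap cost `gap_open + gap_extend·shift` (2 + 2·shift — the conventional
   companions to +1/−2 scoring) plus the mismatch penalty for skipped
   bases, so chaining can never undo the maximal-segment decomposition;
4. chains scoring < `min_hsp_score` (50) are discarded; survivors are
   accepted greedily by descending score with deterministic,
   strand-symmetric tie-breaks, trimming any overlap with previously
   accepted alignments on either genome before counting identities.

On 2 kb pairs the tiled score agrees with a full dynamic-programming local
alignment (Biopython's `PairwiseAligner`, same scoring) to well under one
percentage point, and the score is exactly invariant to
reverse-complementing one input. Known behaviour at high divergence:
beyond ~25–30% substitutions the per-segment score drift turns negative,
fragments fall below `min_hsp_score`, and S collapses toward 0 faster than
percent identity — published similarity values are therefore only compared
within a declared ±1.5 pp tolerance, and the package should not be used to
quantify similarity below roughly 50%.

Clustering at a threshold is single linkage — connected components of the
graph with edges `S ≥ t` — at the ICTV conventions t = 70 (genus) and
t = 95 (species). Labels are assigned by ascending smallest member id, so
clusterings are independent of input order and of any monotone rescaling of
S that preserves threshold sides.

## 5. Synthetic data

The generators are pure functions of (arguments, seed); independent streams
are derived by hashing (seed, operation, index), so outputs are
byte-identical across runs and machines.

- **Host background**: i.i.d. bases at a target GC (not a Markov model —
  sufficient for testing annotation-driven detection and alignment-based
  similarity), tiled with ~1 kb mixed-strand genes carrying housekeeping
  products that never match the phage lexicon.
- **Implants**: a template (role order, gene-length distribution, GC
  offset) is written over the host at a chosen position on one strand with
  short gaps; products are drawn from the lexicon vocabulary for each role,
  so role recovery is exact by construction. Truth intervals are recorded
  exactly. Tape measure genes are tripled in length (they are
  characteristically long).
- **Degradation**: a contiguous block of phage genes is deleted and
  overwritten with host-composition sequence, emulating cryptic prophages;
  deleted roles are recorded on the truth entry.
- **Detector reports**: per method, each truth entry is detected with
  probability `sensitivity`, boundaries jittered with Gaussian noise, and
  false calls arrive Poisson per Mb — never overlapping truth, so
  recall/false-call accounting stays unambiguous.

What green tests on this substrate establish: algorithmic correctness of
detection, integration, scoring and clustering under the stated model. What
they do not establish: performance on real annotation noise (mis-called
ORFs, inconsistent product vocabularies, partial annotations), real base
composition, or origin-spanning prophages.

### The 38-record reference surrogate

`synthetic_reference.build_synthetic_reference_set` rebuilds a stand-in for
a published 38-prophage sequence set that cannot be redistributed: per
record it reproduces the printed name, length (exactly, at 0.1 kb
resolution) and GC content (exact G+C counts, matching at 0.1%), and the
printed mean GC of 41.6% across the set. The three published sequence
clusters are emulated as substitution-mutation families sharing a
per-cluster ancestor, with per-member divergence chosen once from the
published similarity range (the most similar pair at 1.9% divergence each,
giving ≈ 96% pairwise similarity; other members at 3–6.5%); the 14
unclustered records are independent random sequences. Member lengths are
ancestor prefixes, so shorter members behave like truncated (cryptic)
variants. For the 14 records whose individual statistics are not printed,
values were chosen once to be consistent with the set-level marginals and
plausible host GC, and are labelled synthetic in the source. Acceptance
tests against this surrogate therefore verify the package's own parsing,
GC computation and similarity/clustering machinery; they cannot verify
agreement with the original sequences themselves.

## 6. Numerical and interface conventions

- Coordinates are 1-based inclusive everywhere on the public surface
  (GenBank/GFF3 convention); internal half-open arithmetic is never
  exposed.
- GC content excludes ambiguity codes (including N) from numerator and
  denominator, and is rounded only at display time (1 d.p.).
- Circular genomes are treated as linear; origin-spanning prophages are a
  documented blind spot.
- Region tables, detector reports, similarity matrices and cluster
  assignments are all TSV; prophage sequence sets are multi-FASTA.
- Ties in greedy alignment acceptance break by (score, A-start,
  strand-symmetric B-position); overlapping refined detector regions merge
  by union; cluster labels order by smallest member id. All stages are
  deterministic given inputs and seed.
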