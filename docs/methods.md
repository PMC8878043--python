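# Methods

`phagetax` classifies a set of phage genomes with the genome-based,
two-tier scheme used in comparative phage genomics: genera ("sub-clusters")
from reciprocal intergenomic nucleotide similarity, subfamilies ("clusters")
from shared protein content, plus a core/accessory/unique pangenome
partition per cluster and a gene-content distance matrix for splits-network
visualisation.  This note records the models, conventions and numerical
choices behind each stage, and what the synthetic validation does and does
not establish.

## Intergenomic nucleotide similarity

For an ordered pair (query *a*, subject *b*) the query is locally aligned
against both strands of the subject and the resulting HSPs are projected
onto the query axis.  Overlaps are resolved deterministically: HSPs are
ranked by score (ties: smaller start, smaller end, more identities), kept
intact in rank order, and lower-ranked HSPs are trimmed to the uncovered
part of the axis with identity counts reduced proportionally (rounded
down).  This guarantees no base is counted twice.  With `id_ab` the merged
identity count for *a* as query, the pair statistic is

    sim% = 100 · (id_ab + id_ba) / (len_a + len_b)

It is symmetric, length-normalised, and exactly 100 for identical genomes
(the full-length self-HSP outranks every partial hit).  Demarcation
thresholds are the standard ones: species at ≥95%, genus at ≥65%.

The built-in aligner is a seed-and-extend design: exact 7-mer seed matches
(word size 7, the scoring regime also used by the similarity tools this
reproduces: match +2, mismatch −3) are grouped by diagonal, seeds closer
than 250 bp on a diagonal define an extension window padded by 100 bp, and
every maximal-scoring *ungapped* segment with score ≥50 (equivalent to a
25 bp exact match) inside a window is reported as an HSP.  Windows on the
same diagonal never overlap (padding < half the gap), so no segment is
reported twice.  The scan is a single numba-compiled pass.  The choice of
ungapped extension is deliberate: the synthetic generator is
substitution-only, identities are aggregated across merged HSPs anyway, and
on indel-containing real genomes the statistic degrades gracefully because
an indel merely splits one HSP into two that the merge step re-aggregates.
An external `blastn` wrapper (same word size and scoring, gap open 5 /
extend 2) satisfies the same HSP contract and agrees with the internal
backend within ±2 similarity points on the synthetic suite; on short
sequences the merged identity counts are checked against an exhaustive
Smith–Waterman oracle to within ±2 identities.  N never counts as an
identity and never seeds a match.

The score floor of 50 suppresses the background of spurious micro-hits:
on 100 independent random 200 bp pairs, no HSP passes the floor.

## Protein grouping (phams)

Translated CDSs are compared by optimal local alignment (BLOSUM62, gap
open 11, extension 1, via Biopython's `PairwiseAligner`).  A pair matches
when alignment identity (identical residues / alignment columns, gap
columns included) is ≥0.35 and the aligned span covers ≥0.50 of *both*
sequences.  The 0.35 default is the midpoint of the 30–40% range customary
for phage pangenome tools and is exposed as a parameter; coverage on both
sequences (rather than on the HSP only) is the stricter reading and
prevents domain-level chaining of multi-domain proteins.

Groups are connected components of the match graph — single linkage, the
same transitivity rule as pham construction — so groups partition the
proteome; a single-member group is an orpham.  Group ids are assigned from
the lexicographically smallest member, making output independent of input
order.  Two provably safe shortcuts keep the quadratic pair scan
affordable: identical sequences are collapsed to one representative, and a
pair already connected through earlier matches is skipped (redundant edges
cannot change components).  A pair whose lengths differ by more than 4× is
skipped too: the aligned span on the longer sequence is at most the full
shorter sequence, so its coverage is below 0.25 and the pair can never
match.  On proteomes of ≤50 proteins the whole construction is verified
against brute-force all-pairs alignment with an independent aligner.

The genome-level summary is the pooled shared-content percentage

    shared%(a,b) = 100 · (s_a + s_b) / (n_a + n_b)

with `s_a` the number of *a*'s proteins whose group also contains a protein
of *b*.  Pooling (rather than min- or max-normalising) makes the heatmap
symmetric by construction and weighs both proteomes by size.

## Two-tier taxonomy

Sub-clusters (genera) are connected components of the similarity graph
thresholded at 65%, species the components at 95% within each sub-cluster —
single linkage, matching the behaviour of clustered-similarity-heatmap
tools.  Clusters (subfamilies) come from complete-linkage hierarchical
clustering on distance = 100 − shared%, cut at 70 (= minimum 30% shared
proteins).  The two framings can disagree: a complete-linkage cut may split
a sub-cluster that single-linkage similarity had joined.  Sub-clusters are
therefore atomic: clusters that would split one are merged back and a
warning is logged.  Labels are fully deterministic — cluster letters by
size (descending) then smallest member genome id, sub-cluster numbers
within each cluster likewise — so reruns produce identical reports.  A
genome is a singleton exactly when it is alone in its sub-cluster and
joins no multi-genome cluster; singletons are labelled separately
(`SGL1`, …), so both the "genera including singletons" and the
"multi-genome sub-clusters only" accountings can be read off the report.

Within each cluster, a protein group is **core** when it has a member in
every cluster genome, **accessory** when in two or more but not all, and
**unique** (counted in proteins, not groups) when confined to a single
genome.  Genomes flagged `partial` are excluded from the core denominator
but keep contributing members.  For single-genome clusters core/accessory
are undefined (reported `N/A`) and the proteins split into unique
(group confined to that genome) versus shared with other genomes in the
dataset — mirroring how published per-cluster tables handle singleton rows.
`n_core_exclusive` counts core groups with no members outside the cluster.

## Gene-content network export

The binary presence/absence matrix feeds a Jaccard-style distance,
d(a,b) = (groups in exactly one) / (groups in at least one).  The
alternative reading of "gene differences per gene site" — dividing by the
total number of groups — is available via `denominator="all"`; the union
denominator is the default because groups absent from both genomes carry
no signal about the pair.  Distances are serialised as a NEXUS
TAXA + DISTANCES file (lower triangle with diagonal, labels quoted when
they contain reserved characters) with byte-deterministic output, plus a
TSV of the shared-content matrix permuted to complete-linkage leaf order
with a cluster colour-key column.

## Synthetic populations

The generator plants a known taxonomy on a three-level tree.  Ancestral
gene families are random codon sequences (ATG + non-stop codons + TAA;
length uniform in ±30% of the 600 nt default, i.e. ~200-residue proteins,
typical for phage ORFs).  Each cluster draws a core family set (a
configurable fraction shared with other clusters), each genus adds its own
accessory families, and each genome may append private families — the
subsetting directly exercises the core/accessory/unique logic without a
birth–death model.  Genus ancestors diverge from cluster ancestors, and
genomes from genus ancestors, by uniform random point substitutions that
are rejected whenever they would create an in-frame stop; start and stop
codons are never touched, so every CDS stays translatable and the protein
stage sees realistic orthologs.  About 30% of families are placed on the
minus strand.  Intergenic spacers (20–120 bp) are drawn at genus level and
mutated per genome, so the zero-divergence, no-private-genes limit yields
byte-identical genomes.  One seeded generator drives everything: a fixed
config regenerates byte-identical FASTA/GFF3/TSV fixtures.

Two sequences that each diverged from their ancestor with per-site
substitution probability *d* match at a site with probability
i = (1−d)² + d²/3; the package inverts this to estimate *d* from merged
alignment identities, and the generator records the predicted within-genus
similarity (identity × shared-sequence fraction) in the truth file.  The
planted species partition follows the same prediction against the 95%
threshold.

**Default study conditions** (the demo population): 3 clusters × 2 genera ×
3 genomes + 2 singletons, 12 genes per genome (50% cluster core, 1 private
gene), intra-genus divergence 0.02, inter-genus divergence 0.12,
inter-cluster core sharing 0.1.  These sit comfortably away from every
threshold: within-genus similarity ≈88% (genus cut 65), between-genus ≈33%,
between-genus shared content ≈50% (cluster cut 30), cross-cluster shared
content ≈8%.  Genomes are ~8 kb — an order of magnitude below real phage
genomes (30–380 kb) — which keeps the full pipeline run around a minute on
one CPU; the generator scales to realistic sizes by raising
`genes_per_genome` and `mean_gene_len_nt`.

**What synthetic validation does not show.**  The generator has no indels,
no recombination or horizontal transfer, no codon-usage or GC structure, no
terminal repeats or genome re-opening, and gene gain/loss is subsetting
rather than an evolutionary process.  Passing the recovery suite therefore
demonstrates the correctness of the statistics and the clustering logic
under the stated model, not annotation robustness on real data — where ORF
calling differences and indel-rich alignments move both similarity and
shared-content percentages by a few points.  Real-data comparisons (e.g.
reproducing published pairwise similarities from INSDC records) are
supported by `scripts/pairwise_compare.py` on locally downloaded files.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally, 1-based inclusive in
  written reports.
- Genomes are never re-oriented: both subject strands are searched, and all
  statistics are orientation-invariant by construction.
- ORF calling (for FASTA inputs and synthetic genomes) scans six frames for
  ATG/GTG/TTG → next in-frame stop, translation table 11, minimum 120 nt
  including the stop; ORFs sharing a stop keep only the longest; initial
  residue is written as M.  It is deliberately naive — no RBS scoring, no
  overlap resolution across frames — and is not a re-annotation tool.
- A genome shorter than the ORF minimum yields an empty CDS set, not an
  error; an all-N genome aligns to nothing and has GC computed over the
  ACGT denominator only.
- Ambiguity codes other than N are collapsed to N with a logged warning;
  U is mapped to T; anything outside the IUPAC alphabet is an error.
- Similarity matrices are written with one decimal; ties in every ordering
  are broken lexicographically by genome id, making all outputs
  byte-reproducible.
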