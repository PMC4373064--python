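# Methods

`wildtx` re-implements, as a tested library, the post-assembly
characterization of a stranded de novo transcriptome from a wild accession
against an annotated reference genome: strand-artifact filtering, spliced
transcript-to-genome mapping with category classification, redundancy
clustering and distinct-gene discovery with a coding-potential split,
homozygous SNP/indel calling with functional effect annotation, cis-natural
antisense transcript (cis-NAT) detection, and GO-term over-representation
testing. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not emulate.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GFF3, VCF and the pileup
TSV are 1-based at the file boundary and converted exactly once, in
`io_formats`. Indels are left-anchored on the preceding reference base
(VCF-style) everywhere, including the internal `Variant` type, so no
re-anchoring ever happens downstream.

## Strand-artifact filter

Strand-specific libraries with incomplete second-strand digestion produce
mirror contigs written in the antisense direction. A contig is discarded
iff `sense_reads < 0.1 x antisense_reads`, with strict inequality: a contig
whose sense count is exactly a tenth of its antisense count survives.
Contigs missing from the count table are kept with a warning. Reads are
assumed counted once each (a multi-mapped read contributes to its
best-scoring contig only); the tallying itself is an input, not part of
this package.

polyA trimming removes one maximal terminal run per call — a 3' A-run
first, else a 5' T-run — of at least `min_run = 10` bases (configurable; a
conservative default for a step usually delegated to seqclean-style
cleaners without parameters). A contig trimmed to nothing is
dropped with a warning.

## Spliced transcript-to-genome alignment

The aligner is intentionally simple and desk-scale; externally produced
spliced alignments can be imported through the PSL-inspired TSV instead.

1. **Seeding.** Exact 31-mer index over the forward strand of every
   chromosome; k-mers occurring more than 10 times are dropped as
   uninformative. Both contig orientations are tried (minus-strand hits are
   reported with `strand = "-"` and contig coordinates in the
   reverse-complemented frame).
2. **Run merging and chaining.** Same-diagonal seeds merge into maximal
   exact runs; runs are chained per locus by a quadratic DP maximizing
   covered contig bases. Runs may overlap by up to one seed length (31 bp)
   on either sequence — a seed spanning an exon junction can extend into an
   intron whose boundary bases mimic the next exon — and the overlap is
   trimmed off the later run. Loci are seed groups separated by more than
   10 kb; because a tandem duplication can sit closer than that, chaining
   is repeated on leftover runs (up to 4 rounds) so near-tandem duplicated
   loci still yield separate alignments.
3. **Gap resolution.** Gaps between chained runs are resolved by a global
   affine alignment of the two gap sequences (match +1, mismatch -2, open
   -2.5, extend -0.5); affine costs park an intron-sized genomic gap in one
   piece, and small indels fall out of the same alignment. Genomic gaps
   above 2 kb skip the DP and use a mismatch-minimizing two-sided split
   instead. Contig ends beyond the outermost runs are placed by an
   anchored ungapped comparison, re-done as a local alignment within a
   600 bp genome window when more than 2 mismatches appear (this rescues
   ends broken by indels or by a terminal exon too mutated to seed).
4. **Qualification.** An alignment qualifies iff identity
   (matches / aligned columns) >= 0.97 **and** contig coverage (aligned
   contig bases / contig length) >= 0.90. The coverage floor is this
   package's choice: with an identity rule alone, "uniquely aligned" is
   ill-defined for fragmentary hits. Both thresholds are exposed.

**Mapping categories.** Per contig: no qualifying alignment -> `unmapped`;
two or more -> `multiple`; exactly one -> the overlap fraction is the
share of aligned contig bases whose genomic images fall inside any
annotated gene span (introns included, matching the convention that
intron-contained bases are genic). Zero -> `intergenic`; in (0, 0.90) ->
`small_overlap`; >= 0.90 -> `sense_gene` or `antisense_gene` by strand
agreement with the best-overlapping gene (ties toward the smaller gene
id). The denominator is aligned bases rather than contig length, which is
robust to soft ends; on data meeting the 0.90 coverage floor the two
definitions differ by at most 10% of the contig and agree on all synthetic
checks.

## Redundancy clustering and distinct genes

Contigs sharing a same-orientation best local alignment of >= 100 aligned
columns at >= 97% identity are joined; clusters are single-linkage
connected components (the clustering criterion is pairwise and implies no
linkage rule; single linkage is the weakest consistent choice and is tested
against an all-pairs + transitive-closure oracle). Candidate pairs are
restricted to contigs sharing a 15-mer; the suite verifies this pruning is
lossless against the oracle. The representative is the longest member,
ties broken toward the lexicographically smallest id.

Distinct transcripts are unmapped cluster representatives. Coding potential
is a transparent surrogate for SVM-based classifiers (CPC-style tools):
`score = L/300 - 1` with L the longest sense-strand ATG-to-stop ORF in
nucleotides (stop codon included; an ORF running off the 3' end counts
through its last complete codon), and `label = coding iff score > 0`. The
score is monotone in ORF length and keeps the positive-score = coding
convention; only the sign is consumed downstream. The 300 nt reference
length follows the common long-ORF convention for distinguishing coding
from non-coding transcripts. This substitution is deliberate and
prominent: the surrogate reproduces the decision boundary role of a
coding-potential classifier, not its scores.

## Variant calling and effect annotation

Input is a deduplicated, uniquely-mapped pileup (chrom, 1-based pos, ref,
read:allele tokens; `+SEQ` insertion after the site, `-N` deletion of the
next N bases). PCR duplicates are reads sharing (chrom, start, strand,
block structure); the lexicographically smallest read id survives,
consistently across columns.

Per column the most frequent non-reference allele is evaluated; a variant
is emitted iff it is carried by >= 4 distinct reads **and** its frequency
among distinct reads is > 0.70, both strict in the stated direction. Ties
between non-reference alleles yield no call. The support rule counts reads
carrying the variant allele (the stricter reading of "supported by at
least four distinct reads"); homozygosity rests on the frequency rule
alone, with no genotype likelihoods.

Effects: the region is located by precedence splice (2 bp canonical GT/AG
intron ends, strand-aware donor/acceptor) > CDS > UTR exon > intron >
intergenic, over all overlapping genes; one effect per variant is kept by
severity start_lost > stop_gained > stop_lost > frameshift >
splice_disruption > inframe_indel > nonsynonymous > synonymous >
noncoding. CDS SNPs rebuild the affected codon in coding orientation under
the standard nuclear table (alternative starts not honored); CDS indels
classify by length mod 3. The annotator is validated against an
independent oracle that substitutes the allele into the chromosome,
shifts coordinates, re-extracts and translates the whole CDS and diffs the
proteins; the generator labels planted variants with the same oracle, so
the annotator is never tested against itself.

`ns_ratio` is the nonsynonymous/synonymous **variant count** ratio
(undefined when no synonymous variants exist), optionally over a gene
subset. A per-site normalized dN/dS is not implemented; the phrase "ratio
of nonsynonymous to synonymous sites" admits both readings and the count
ratio is the one computed here, as flagged in the API docs.

## cis-NAT detection

Candidates come from a reverse-orientation self-comparison: pairs whose
best local alignment of one contig against the reverse complement of the
other spans **more than 50** columns (strict) at >= 97% identity. The 97%
is this package's choice, mirroring the genome-mapping threshold (the
self-comparison step's original threshold is unstated); it is exposed as a
parameter. Confirmation requires each member to hold exactly one
qualifying genome alignment, same chromosome, opposite strands,
intersecting spans. "Distinct splicing patterns" is operationalized as
non-identical genomic block sets: a pair aligning to identical blocks on
opposite strands is an assembly strand artifact, not two transcripts, and
is discarded (this interpretation is a judgment call and is documented as
such).

Geometry on genomic spans only, with strand-aware termini (a minus-strand
alignment's 3' end is its smaller genomic coordinate): containment ->
`contained` (including exact-boundary containment); otherwise an overlap
touching both 3' termini -> `tail_to_tail`, both 5' termini ->
`head_to_head`. Pairing labels (`coding_coding`, `coding_noncoding`,
`noncoding_noncoding`) come from the members' coding-potential calls.

## Enrichment

Upper-tail hypergeometric test per term with at least one study hit:
p = P(X >= k | N, K, n), Bonferroni-corrected over the number of tested
terms (the documented default of GO::TermFinder-style tools);
Benjamini-Hochberg is available but not default. Terms with corrected
p <= 0.05 are flagged. Annotation maps are expected pre-propagated to
ancestor terms by the caller — the module is ontology-agnostic and does no
OBO/DAG parsing. The implementation delegates to `scipy.stats.hypergeom`;
tests compare it to exact integer enumeration at 1e-12 (exhaustively for
N <= 32, densely sampled to N = 60).

## Synthetic data: what it emulates, and what it does not

`synthdata` generates, from one seeded NumPy generator (byte-identical
outputs per seed):

* a reference genome (default 2 chromosomes x 60 kb) hosting 60 genes with
  1-4 exons (>= 120 bp), GT-AG introns of 60-200 bp, ATG-initiated
  stop-terminated CDSs of >= 321 nt, and >= 500 bp intergenic spacing;
  mRNA ends are forced non-A/non-T so planted polyA tails trim exactly;
* accession transcripts carrying planted SNPs (rate 0.010/bp) and 1-3 bp
  indels (rate 0.002/bp), spaced >= 6 bp apart and >= 4 bp from exon
  junctions, keeping identity >= 97% (rates implying more divergence are
  rejected); a configurable fraction (0.3) carries a 12-20 bp polyA tail;
* distinct contigs sharing no 31-mer with either genome strand: coding
  (planted ORF >= 333 nt) and noncoding (all ORFs < 150 nt);
* antisense partners overlapping a gene by a planted geometry (contained /
  tail-to-tail / head-to-head, cycled), each sharing >= 80 bp of exon
  sequence in reverse orientation;
* mirror artifacts (reverse complements of genuine contigs) with sense
  counts strictly below a tenth of antisense, plus one genuine contig
  planted exactly at the boundary;
* truncated redundant copies (>= 130 bp, substrings of the mutated
  transcript) for clustering;
* two genes whose genomic spans are copied verbatim to a second locus
  (their transcripts carry no variants) to populate the multiple-hit
  category, plus intergenic and small-overlap genome windows;
* pileups with depth 10 at every planted site (support drawn from
  {8, 9, 10}) plus decoys pinning the strict boundaries: allele frequency
  exactly 0.70 (support 7/10) or support exactly 3 (3/4), each violating
  exactly one calling rule; decoy count is 0.3 x planted count;
* a GO map with one term planted in ~75% of distinct-coding contigs and
  5% of the background, among random background terms.

Splice-site, intron and intergenic variants are planted in the pileups
only (read-to-genome pileups cover non-exonic transcribed sequence);
altered splicing of the accession transcript is not modelled. Not emulated
at all: read-level errors and quality, expression levels, heterozygosity,
alternative isoforms beyond truncation, chimeric contigs, contamination.
Passing tests therefore demonstrate the correctness of the decision rules
and their boundary behavior under the stated statistical structure — not
robustness to assembler fragmentation, sequencing error or mapping
ambiguity in real libraries.

Default problem sizes (60 genes, ~110 contigs, ~450-550 planted variants
plus ~150 decoys, 6 antisense pairs) keep an end-to-end run around a
second while exercising every category and boundary; the focused harnesses
use 1000 random CDS variants for oracle equivalence, a 200-contig set for
the clustering oracle, and 100 seeded replicates for the planted
enrichment. These sizes are the package's study conditions, fixed in the
defaults.

## Known limitations

* The spliced aligner assumes well-separated loci and modest intron sizes;
  it is not a replacement for BLAT/minimap2 on real genomes and does not
  model chimeras or split-chromosome alignments.
* The coding-potential surrogate ignores homology and nucleotide
  composition features; transcripts with long spurious ORFs are labelled
  coding.
* Deletions spanning a CDS/UTR boundary within one exon are classified by
  overlap precedence, not by partial-codon semantics; the generator never
  plants such variants and the oracle contract excludes them.
* One transcript per gene (the first mRNA in file order) is used from
  GFF3; isoform-aware effect annotation is out of scope.
* `ns_ratio` is a count ratio; site-normalized dN/dS is not provided.
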