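# wildtx

Post-assembly characterization of a stranded de novo transcriptome against
an annotated reference genome.

When a wild accession's transcriptome is assembled de novo and compared
with the reference genotype of its species, a handful of recurring
questions follow: which contigs are strand-flip assembly artifacts; where
does each transcript land on the genome and how does it relate to the
annotated genes; which transcripts are *distinct* — absent or highly
diverged from the reference — and are they protein-coding; which
homozygous SNPs and small indels separate the accession from the
reference, and what do they do to genes; which transcript pairs are
cis-natural antisense transcripts (cis-NATs); and which functional terms
are over-represented among the distinct genes. `wildtx` implements that
whole post-assembly pipeline as a tested Python library with a thin CLI,
for researchers working at desk scale or prototyping the analysis before
scaling out.

## The rules it implements

* **Strand filter** — discard a contig iff
  `sense_reads < antisense_reads / 10` (strict); trim one terminal polyA
  (or leading polyT) run of ≥ 10 bases.
* **Mapping** — spliced alignment qualifies at identity ≥ 97% and contig
  coverage ≥ 90%; categories: unmapped, multiple, intergenic,
  small overlap, sense gene and antisense gene, split at ≥ 90% of aligned
  bases inside a gene span and by strand agreement.
* **Distinct genes** — single-linkage clustering over pairs with ≥ 100
  aligned columns at ≥ 97% identity, longest representative; unmapped
  representatives are distinct, split coding/non-coding by the ORF score
  `L/300 − 1` (positive = coding, with `L` the longest sense-strand ORF).
* **Variants** — a site is called iff ≥ 4 distinct reads carry the
  alternate allele *and* its allele frequency is > 70% (both strict);
  effects per the standard taxonomy (synonymous/nonsynonymous, start/stop
  lost, stop gained, frameshift, in-frame indel, splice donor/acceptor
  disruption, noncoding), one per variant by severity; the NS/S count
  ratio is reported.
* **cis-NATs** — reverse-orientation self-comparison with overlap > 50 bp
  (strict), confirmed by opposite-strand co-location on the genome with
  distinct splicing patterns; geometry head-to-head / tail-to-tail /
  contained; pairing from coding potential.
* **Enrichment** — upper-tail hypergeometric `P(X ≥ k | N, K, n)` per
  term, Bonferroni-corrected, flagged at corrected P ≤ 0.05.

A seeded synthetic-data generator (`wildtx.synthdata`) builds a toy
genome, an accession transcriptome with planted variants, artifacts,
antisense pairs and redundant copies, plus machine-readable truth tables —
every rule above is exercised against planted truth, with boundary decoys
pinned exactly at the strict thresholds. See `docs/methods.md` for the
model details and the generator's scope.

## Worked example

Run the whole pipeline on generated data (one seed controls everything):

```sh
wildtx run --synth --seed 1 --out wildtx_out
```

Output (abridged):

```
## Assembly
n_contigs       110
n50             591
gc_percent      50.84

## Stage counts
strand_artifacts_discarded  6
contigs_clean               104
distinct_coding             12
distinct_noncoding          8
variants_called             435
cisnat_pairs                6

## Mapping categories
unmapped        20
multiple        2
intergenic      4
small_overlap   8
sense_gene      68
antisense_gene  2

## Variant effects
effect:nonsynonymous  197
effect:synonymous     72
effect:frameshift     35
effect:stop_gained    14
ns_ratio              2.736

## cis-NAT pairs
contained     2
head_to_head  2
tail_to_tail  2

## Enriched terms (corrected P <= alpha)
GO:0000001
```

Reading it: of 110 assembled contigs, 6 were discarded as strand-flip
artifacts. Of the cleaned contigs, 68 map to genes in sense orientation,
2 hit two genomic loci (a duplicated gene), and 20 have no qualifying
alignment — the distinct transcripts, which split 12 coding / 8 non-coding.
435 homozygous variants pass the 4-read / 70% rules; 197 are
nonsynonymous against 72 synonymous (NS/S ≈ 2.7 — random planted
substitutions are not purifying-selected, so this ratio is high by
construction). All 6 planted cis-NAT pairs are recovered with their
geometries, and the planted GO term is the one enriched term. In
synth-mode the report ends with a truth-comparison section; the run above
reports zero discrepancies.

The same stages run from files (`wildtx run --transcripts ... --genome
... --annotation ... --strand-counts ... --pileup ... --go-map ...`), and
individually via `wildtx qc|simulate` or the library API
(`wildtx.pipeline.run_pipeline`, or the per-stage modules).

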