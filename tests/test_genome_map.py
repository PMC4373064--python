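"""Spliced alignment and mapping-category classification."""

import numpy as np
import pytest

from wildtx import genome_map
from wildtx.assembly_qc import trim_polya
from wildtx.io_formats import GeneModel, SequenceRecord, revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(11)
    seq = _rand(rng, 6000)
    # a two-exon gene: exons (1000,1400) and (1600,2000), GT..AG intron
    seq = seq[:1400] + "GT" + seq[1402:1598] + "AG" + seq[1600:]
    return [SequenceRecord("chrA", seq)]


@pytest.fixture(scope="module")
def toy_gene():
    return GeneModel("gX", "chrA", "+", 1000, 2000,
                     exons=[(1000, 1400), (1600, 2000)], cds=[])


def test_exact_exon_concatenation_aligns_in_two_blocks(toy_genome, toy_gene):
    gseq = toy_genome[0].seq
    contig = SequenceRecord("t1", gseq[1000:1400] + gseq[1600:2000])
    (aln,) = genome_map.align_transcripts([contig], toy_genome)
    assert aln.identity == 1.0
    assert len(aln.blocks) == 2
    assert aln.blocks[0][1] == (1000, 1400) and aln.blocks[1][1] == (1600, 2000)


def test_minus_strand_contig_aligns_with_minus_strand(toy_genome):
    gseq = toy_genome[0].seq
    contig = SequenceRecord("t2", revcomp(gseq[3000:3500]))
    (aln,) = genome_map.align_transcripts([contig], toy_genome)
    assert aln.strand == "-"
    assert aln.genomic_span == (3000, 3500)


def test_contig_without_seeds_yields_no_alignment(toy_genome):
    rng = np.random.default_rng(5)
    contig = SequenceRecord("t3", _rand(rng, 400))
    assert genome_map.align_transcripts([contig], toy_genome) == []


def test_duplicated_contig_gets_two_alignments(reference, accession):
    dup = reference.dup_gene_ids[0]
    tx = next(t for t in accession.transcripts if t.id == f"tx_{dup}")
    alns = genome_map.align_transcripts([trim_polya(tx)], reference.genome)
    assert len(alns) == 2
    assert all(a.identity == 1.0 for a in alns)


def test_alignment_tolerates_planted_divergence(reference, accession):
    kept = [
        trim_polya(t) for t in accession.transcripts
        if t.id.startswith("tx_") and "_r" not in t.id
    ]
    alns = genome_map.align_transcripts(kept, reference.genome)
    by_contig = {}
    for a in alns:
        by_contig.setdefault(a.contig_id, []).append(a)
    assert set(by_contig) == {c.id for c in kept}
    for c in kept:
        for a in by_contig[c.id]:
            assert a.identity >= 0.97
            assert a.aligned_bases / len(c) >= 0.90


@pytest.mark.parametrize("shuffle_seed", [0, 1])
def test_classification_invariant_to_alignment_order(reference, accession, shuffle_seed):
    contigs = [trim_polya(t) for t in accession.transcripts[:30]]
    contigs = [c for c in contigs if c]
    alns = genome_map.align_transcripts(contigs, reference.genome)
    rng = np.random.default_rng(shuffle_seed)
    perm = [alns[i] for i in rng.permutation(len(alns))]
    a = genome_map.classify_transcripts(alns, reference.genes,
                                        contig_ids=[c.id for c in contigs])
    b = genome_map.classify_transcripts(perm, reference.genes,
                                        contig_ids=[c.id for c in contigs])
    assert sorted(a, key=lambda m: m.contig_id) == sorted(b, key=lambda m: m.contig_id)


def test_every_contig_gets_exactly_one_category(reference, accession):
    contigs = [trim_polya(t) for t in accession.transcripts]
    contigs = [c for c in contigs if c]
    alns = genome_map.align_transcripts(contigs, reference.genome)
    classes = genome_map.classify_transcripts(
        alns, reference.genes, contig_ids=[c.id for c in contigs]
    )
    assert len(classes) == len(contigs)
    assert all(m.category in genome_map.CATEGORIES for m in classes)


def test_unknown_chromosome_errors(toy_gene):
    aln = genome_map.TranscriptAlignment(
        "t", "chrZ", "+", (((0, 100), (0, 100)),), 100, 0
    )
    with pytest.raises(ValueError, match="unknown chrom"):
        genome_map.classify_transcripts([aln], [toy_gene], chrom_names={"chrA"})


def _unique_aln(span, strand="+"):
    return genome_map.TranscriptAlignment(
        "t", "chrA", strand, (((0, span[1] - span[0]), span),),
        span[1] - span[0], 0,
    )


@pytest.mark.parametrize(
    "span, expected",
    [
        ((1050, 1950), "sense_gene"),     # fully inside the gene span
        ((4000, 4400), "intergenic"),
        ((1800, 2400), "small_overlap"),  # 200/600 in gene
    ],
)
def test_single_alignment_categories(toy_gene, span, expected):
    (m,) = genome_map.classify_transcripts([_unique_aln(span)], [toy_gene])
    assert m.category == expected


def test_antisense_category_needs_opposite_strand(toy_gene):
    (m,) = genome_map.classify_transcripts([_unique_aln((1050, 1950), "-")], [toy_gene])
    assert m.category == "antisense_gene"
    assert m.best_gene == "gX"
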