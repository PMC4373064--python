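"""Variant calling thresholds, deduplication and effect annotation."""

import numpy as np
import pytest

from wildtx import effect_oracle, variant_annot
from wildtx.io_formats import GeneModel, PileupColumn, SequenceRecord, revcomp
from wildtx.variant_annot import (
    Variant, annotate_effects, call_variants, deduplicate_reads, ns_ratio,
)


def _col(chrom, pos, ref, alleles):
    return PileupColumn(chrom, pos, ref, [(f"r{i}", a) for i, a in enumerate(alleles)])


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "alleles, called",
    [
        (["G"] * 8 + ["A"] * 2, True),    # af 0.8, support 8
        (["G"] * 3, False),               # support < 4
        (["G"] * 7 + ["A"] * 3, False),   # af 0.70 not > 0.70
        (["G"] * 4 + ["A"] * 1, True),    # af 0.8, support 4
    ],
)
def test_calling_thresholds_are_strict(alleles, called):
    variants = call_variants([_col("c1", 10, "A", alleles)])
    assert bool(variants) is called
    if called:
        v = variants[0]
        assert (v.ref, v.alt, v.vtype) == ("A", "G", "snp")


def test_tied_alt_alleles_yield_no_call():
    variants = call_variants([_col("c1", 10, "A", ["G"] * 5 + ["T"] * 5)])
    assert variants == []


def test_insertion_call_is_anchored():
    (v,) = call_variants([_col("c1", 10, "A", ["+GG"] * 9 + ["A"])])
    assert (v.pos, v.ref, v.alt, v.vtype) == (10, "A", "AGG", "ins")


def test_deletion_call_uses_reference_run():
    (v,) = call_variants([_col("c1", 10, "ATT", ["-2"] * 9 + ["A"])])
    assert (v.pos, v.ref, v.alt, v.vtype) == (10, "ATT", "A", "del")


def test_zero_depth_column_skipped():
    assert call_variants([PileupColumn("c1", 5, "A", [])]) == []


def test_caller_recovers_planted_and_rejects_decoys(accession):
    variants = call_variants(accession.pileup)
    called = {v.key() for v in variants}
    planted = {(p.chrom, p.pos, p.ref, p.alt) for p in accession.truth.planted_variants}
    assert called == planted  # precision = recall = 1
    decoy_sites = {(d.chrom, d.pos) for d in accession.truth.decoys}
    assert not {k for k in called if (k[0], k[1]) in decoy_sites}


def test_each_decoy_violates_exactly_one_rule(accession):
    by_site = {(c.chrom, c.pos): c for c in accession.pileup}
    for d in accession.truth.decoys:
        col = by_site[(d.chrom, d.pos)]
        support = sum(1 for _, a in col.observations if a == d.alt)
        depth = len(col.observations)
        if d.violated_rule == "af":
            assert support >= 4 and not support / depth > 0.70
        else:
            assert support < 4 and support / depth > 0.70


def test_relaxed_af_calls_at_least_as_many(accession):
    strict = call_variants(accession.pileup, min_af=0.70)
    relaxed = call_variants(accession.pileup, min_af=0.50)
    assert {v.key() for v in strict} <= {v.key() for v in relaxed}
    assert len(relaxed) > len(strict)  # af-boundary decoys now pass


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_duplicates_collapse_to_lexicographically_smallest():
    cols = [_col("c1", 9, "A", ["G", "G", "G"])]
    meta = {f"r{i}": ("c1", 100, "+", "50M") for i in range(3)}
    (out,) = deduplicate_reads(cols, meta)
    assert [r for r, _ in out.observations] == ["r0"]


def test_opposite_strand_duplicates_both_survive():
    cols = [_col("c1", 9, "A", ["G", "G"])]
    meta = {"r0": ("c1", 100, "+", "50M"), "r1": ("c1", 100, "-", "50M")}
    (out,) = deduplicate_reads(cols, meta)
    assert len(out.observations) == 2


def test_dedup_is_identity_without_duplicates():
    cols = [_col("c1", 9, "A", ["G", "T"])]
    meta = {"r0": ("c1", 100, "+", "50M"), "r1": ("c1", 130, "+", "50M")}
    (out,) = deduplicate_reads(cols, meta)
    assert out.observations == cols[0].observations


def test_dedup_missing_metadata_errors():
    with pytest.raises(ValueError, match="r1"):
        deduplicate_reads([_col("c1", 9, "A", ["G", "G"])],
                          {"r0": ("c1", 100, "+", "50M")})


# ---------------------------------------------------------------------------
# effect annotation on a hand-built gene
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy():
    # + strand gene: 10 nt UTR, CDS ATG AAA TGG GAA TAA split over 2 exons,
    # intron GT..AG of 20 nt between codons 2 and 3
    utr5 = "CCCCCCCCCC"
    exon1 = utr5 + "ATGAAA"
    intron = "GT" + "C" * 16 + "AG"
    exon2 = "TGGGAATAA" + "CCCCC"
    seq = "G" * 50 + exon1 + intron + exon2 + "G" * 50
    g0 = 50
    gene = GeneModel(
        "gT", "cT", "+", g0, g0 + len(exon1) + len(intron) + len(exon2),
        exons=[(g0, g0 + 16), (g0 + 36, g0 + 50)],
        cds=[(g0 + 10, g0 + 16), (g0 + 36, g0 + 45)],
    )
    return [SequenceRecord("cT", seq)], [gene]


def _variant(pos, ref, alt, vtype="snp"):
    return Variant("cT", pos, ref, alt, vtype, 8, 10)


@pytest.mark.parametrize(
    "pos, alt, region, effect",
    [
        (60, "G", "cds", "start_lost"),          # ATG -> GTG
        (88, "A", "cds", "stop_gained"),         # TGG -> TGA
        (63, "G", "cds", "nonsynonymous"),       # AAA(K) -> GAA(E)
        (91, "G", "cds", "synonymous"),          # GAA -> GAG
        (94, "C", "cds", "stop_lost"),           # TAA -> CAA
        (66, "A", "splice_donor", "splice_disruption"),    # G of GT
        (85, "C", "splice_acceptor", "splice_disruption"), # G of AG
        (55, "A", "utr_exon", "noncoding"),
        (75, "A", "intron", "noncoding"),
        (20, "A", "intergenic", "noncoding"),
    ],
)
def test_snp_effect_classes(toy, pos, alt, region, effect):
    genome, genes = toy
    ref = genome[0].seq[pos]
    assert ref != alt
    (e,) = annotate_effects([_variant(pos, ref, alt)], genes, genome)
    assert (e.region, e.effect) == (region, effect)


def test_cds_deletion_frameshift_vs_inframe(toy):
    genome, genes = toy
    seq = genome[0].seq
    (fs,) = annotate_effects(
        [_variant(87, seq[87:89], seq[87], "del")], genes, genome
    )
    assert (fs.region, fs.effect) == ("cds", "frameshift")
    (inf,) = annotate_effects(
        [_variant(86, seq[86:90], seq[86], "del")], genes, genome
    )
    assert (inf.region, inf.effect) == ("cds", "inframe_indel")


def test_cds_insertion_frameshift(toy):
    genome, genes = toy
    seq = genome[0].seq
    (e,) = annotate_effects(
        [_variant(62, seq[62], seq[62] + "T", "ins")], genes, genome
    )
    assert (e.region, e.effect) == ("cds", "frameshift")


def test_ns_ratio_examples():
    def eff(effect):
        v = _variant(60, "A", "G")
        return variant_annot.VariantEffect(v, "cds", effect, "g")

    effects = [eff("nonsynonymous")] * 7 + [eff("synonymous")] * 10
    assert ns_ratio(effects) == pytest.approx(0.7)
    assert ns_ratio([eff("nonsynonymous")] * 5) is None
    assert ns_ratio([]) is None


def test_variant_outside_chromosomes_errors(toy):
    genome, genes = toy
    with pytest.raises(ValueError, match="unknown chromosome"):
        annotate_effects([Variant("cZ", 5, "A", "G", "snp", 8, 10)], genes, genome)


# ---------------------------------------------------------------------------
# oracle equivalence and strand symmetry
# ---------------------------------------------------------------------------

def _oracle_check(ref, variants):
    genome = {r.id: r.seq for r in ref.genome}
    effects = annotate_effects(variants, ref.genes, ref.genome)
    for v, e in zip(variants, effects):
        gene = next(
            g for g in ref.genes if g.chrom == v.chrom and g.start <= v.pos < g.end
        )
        want = effect_oracle.classify_cds_variant(genome[v.chrom], gene, v)
        assert (e.region, e.effect) == ("cds", want), (v, e.effect, want)


def test_effects_match_translate_diff_oracle(reference):
    from wildtx.synthdata import sample_cds_variants

    _oracle_check(reference, sample_cds_variants(reference, 300, seed=5))


def test_effects_invariant_under_genome_reverse_complement(reference):
    from wildtx.synthdata import sample_cds_variants

    variants = sample_cds_variants(reference, 150, seed=6)
    effects = annotate_effects(variants, reference.genes, reference.genome)

    flipped_genome = [r.reverse_complement() for r in reference.genome]
    length = {r.id: len(r.seq) for r in reference.genome}
    flipped_genes = [
        GeneModel(
            g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
            length[g.chrom] - g.end, length[g.chrom] - g.start,
            exons=[(length[g.chrom] - e, length[g.chrom] - s) for s, e in g.exons],
            cds=[(length[g.chrom] - e, length[g.chrom] - s) for s, e in g.cds],
        )
        for g in reference.genes
    ]
    flipped_variants = []
    for v in variants:
        L = length[v.chrom]
        if v.vtype == "snp":
            fv = Variant(v.chrom, L - v.pos - 1, revcomp(v.ref), revcomp(v.alt),
                         "snp", v.support, v.depth)
        else:
            # anchor moves to the other side of the edited run
            span = len(v.ref) if v.vtype == "del" else len(v.alt)
            pos = L - (v.pos + span)
            gseq = dict((r.id, r.seq) for r in flipped_genome)[v.chrom]
            if v.vtype == "del":
                fv = Variant(v.chrom, pos, gseq[pos:pos + span], gseq[pos],
                             "del", v.support, v.depth)
            else:
                fv = Variant(v.chrom, pos, gseq[pos],
                             gseq[pos] + revcomp(v.alt[1:]), "ins",
                             v.support, v.depth)
        flipped_variants.append(fv)
    flipped_effects = annotate_effects(flipped_variants, flipped_genes, flipped_genome)
    for e, fe in zip(effects, flipped_effects):
        assert e.effect == fe.effect, (e.variant, e.effect, fe.effect)
        assert e.region == fe.region
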