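"""Properties of the synthetic-data generator and its truth tables."""

import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from wildtx.synthdata import (
    SynthConfig, generate, generate_reference, write_outputs,
)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SynthConfig(n_genes=-1)
    with pytest.raises(ValueError):
        SynthConfig(snp_rate=1.5)
    with pytest.raises(ValueError, match="identity below 97%"):
        SynthConfig(snp_rate=0.04)


def test_generation_is_byte_identical_for_fixed_seed(tmp_path):
    for d in ("a", "b"):
        ref, acc = generate(SynthConfig(seed=7))
        write_outputs(ref, acc, tmp_path / d)
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b",
        [p.name for p in (tmp_path / "a").iterdir()], shallow=False,
    )
    assert not mismatch and not errors


def test_gene_count_matches_config():
    ref = generate_reference(SynthConfig(seed=2, n_genes=20, n_multi_locus_genes=1))
    assert len(ref.genes) == 20


def test_every_cds_translates_clean(reference, genome_dict):
    """Direct translation oracle: M start, single terminal stop, GT-AG introns."""
    for g in reference.genes:
        cds = "".join(genome_dict[g.chrom][s:e] for s, e in g.cds)
        if g.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        prot = str(Seq(cds).translate())
        assert prot.startswith("M")
        assert prot.endswith("*") and "*" not in prot[:-1]
        for i1, i2 in g.introns():
            intron = genome_dict[g.chrom][i1:i2]
            if g.strand == "-":
                intron = str(Seq(intron).reverse_complement())
            assert intron.startswith("GT") and intron.endswith("AG")


def test_null_planting_gives_exact_exon_concatenation():
    cfg = SynthConfig(seed=3, snp_rate=0.0, indel_rate=0.0, polya_fraction=0.0)
    ref, acc = generate(cfg)
    genome = {r.id: r.seq for r in ref.genome}
    tx = {t.id: t.seq for t in acc.transcripts}
    for g in ref.genes:
        mrna = "".join(genome[g.chrom][s:e] for s, e in g.exons)
        if g.strand == "-":
            mrna = str(Seq(mrna).reverse_complement())
        assert tx[f"tx_{g.gene_id}"] == mrna


def test_planted_pileups_recount_to_thresholds(accession):
    """Recount oracle: every planted site passes both rules, decoys one."""
    cols = {(c.chrom, c.pos): c for c in accession.pileup}
    for pv in accession.truth.planted_variants:
        col = cols[(pv.chrom, pv.pos)]
        if pv.vtype == "snp":
            token = pv.alt
        elif pv.vtype == "ins":
            token = "+" + pv.alt[1:]
        else:
            token = f"-{len(pv.ref) - 1}"
        support = sum(1 for _, a in col.observations if a == token)
        depth = len(col.observations)
        assert support >= 4
        assert support / depth > 0.70
    assert len(accession.truth.decoys) == round(
        0.3 * len(accession.truth.planted_variants)
    )


def test_truth_ids_exist_in_fasta(accession):
    ids = {t.id for t in accession.transcripts}
    t = accession.truth
    referenced = (
        set(t.distinct_truth) | t.artifact_truth | set(t.mapping_truth)
        | {x for pair in t.antisense_truth for x in pair[:2]}
        | {m for cluster in t.cluster_truth for m in cluster}
    )
    assert referenced <= ids


def test_antisense_geometries_follow_config():
    cfg = SynthConfig(seed=4, n_antisense_pairs=3)
    _, acc = generate(cfg)
    geoms = [g for _, _, g, _ in acc.truth.antisense_truth]
    assert sorted(geoms) == ["contained", "head_to_head", "tail_to_tail"]


def test_distinct_contigs_share_no_31mer_with_genome(reference, accession):
    from wildtx.synthdata import _genome_kmers, _shares_kmer

    kmers = _genome_kmers(reference.genome)
    for cid in accession.truth.distinct_truth:
        seq = next(t.seq for t in accession.transcripts if t.id == cid)
        assert not _shares_kmer(seq, kmers)


def test_distinct_contigs_unmapped_by_aligner(reference, accession):
    from wildtx import genome_map

    distinct = [t for t in accession.transcripts
                if t.id in accession.truth.distinct_truth]
    assert genome_map.align_transcripts(distinct, reference.genome) == []


def test_mapping_truth_covers_every_category(accession):
    from wildtx.genome_map import CATEGORIES

    seen = set(accession.truth.mapping_truth.values())
    assert seen == set(CATEGORIES)


def test_truth_effects_computed_by_oracle(reference, accession, genes_by_id, genome_dict):
    from wildtx import effect_oracle
    from wildtx.variant_annot import Variant

    cds_planted = [p for p in accession.truth.planted_variants if p.region == "cds"]
    assert cds_planted
    rng = np.random.default_rng(0)
    for p in (cds_planted[i] for i in rng.choice(len(cds_planted), 50, replace=False)):
        v = Variant(p.chrom, p.pos, p.ref, p.alt, p.vtype, 8, 10)
        g = genes_by_id[p.gene_id]
        assert effect_oracle.classify_cds_variant(genome_dict[p.chrom], g, v) == p.effect
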