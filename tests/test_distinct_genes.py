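"""Redundancy clustering, coding score and distinct-gene identification."""

import numpy as np
import pytest
from oracles import brute_single_linkage

from wildtx._align import best_local_alignment
from wildtx.distinct_genes import (
    cluster_transcripts, identify_distinct, longest_orf, score_coding_potential,
)
from wildtx.io_formats import SequenceRecord


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_identical_contigs_tie_breaks_to_smaller_id():
    rng = np.random.default_rng(3)
    seq = _rand(rng, 500)
    (c,) = cluster_transcripts([SequenceRecord("b", seq), SequenceRecord("a", seq)])
    assert c.representative == "a"
    assert c.member_ids == frozenset({"a", "b"})


def test_short_overlap_stays_separate():
    rng = np.random.default_rng(4)
    shared = _rand(rng, 80)
    a = SequenceRecord("a", _rand(rng, 200) + shared)
    b = SequenceRecord("b", shared + _rand(rng, 200))
    clusters = cluster_transcripts([a, b])
    assert {c.member_ids for c in clusters} == {frozenset({"a"}), frozenset({"b"})}


def test_transitive_chain_merges_into_one_cluster():
    rng = np.random.default_rng(5)
    src = _rand(rng, 600)
    a = SequenceRecord("a", src[:350])
    b = SequenceRecord("b", src[150:500])   # overlaps a by 200, c by 150
    c = SequenceRecord("c", src[300:600] + _rand(rng, 150))  # 450 nt, longest
    clusters = cluster_transcripts([a, b, c])
    # a~b and b~c but a and c share nothing
    assert best_local_alignment(a.seq, c.seq) is None or \
        best_local_alignment(a.seq, c.seq).columns < 100
    assert {cl.member_ids for cl in clusters} == {frozenset({"a", "b", "c"})}
    (cl,) = clusters
    assert cl.representative == "c"  # longest member


def test_clustering_matches_brute_force_oracle_small():
    from wildtx.synthdata import generate_clustering_set

    contigs = generate_clustering_set(9, n_sources=12, n_copies=30, n_singletons=12)
    got = {c.member_ids for c in cluster_transcripts(contigs)}
    assert got == brute_single_linkage(contigs)


def test_redundant_copies_cocluster_with_source(accession):
    from wildtx.assembly_qc import trim_polya

    clean = [trim_polya(t) for t in accession.transcripts
             if t.id not in accession.truth.artifact_truth]
    clean = [c for c in clean if c]
    clusters = cluster_transcripts(clean)
    assert {c.member_ids for c in clusters} == set(accession.truth.cluster_truth)
    length_of = {c.id: len(c.seq) for c in clean}
    for c in clusters:
        assert length_of[c.representative] == max(length_of[m] for m in c.member_ids)


@pytest.mark.parametrize(
    "orf_len, score, label",
    [(600, 1.0, "coding"), (90, -0.7, "noncoding")],
)
def test_coding_score_from_orf_length(orf_len, score, label):
    rng = np.random.default_rng(6)
    nonstop = [c for c in
               ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
               if c not in {"TAA", "TAG", "TGA"} and c != "ATG"]
    orf = "ATG" + "".join(rng.choice(nonstop, size=orf_len // 3 - 2)) + "TAA"
    assert len(orf) == orf_len
    pad = "C" * 150  # no ATG, no ORF contribution
    call = score_coding_potential(SequenceRecord("c", pad + orf + pad))
    assert call.longest_orf_len == orf_len
    assert call.score == pytest.approx(score)
    assert call.label == label


def test_no_atg_scores_minus_one():
    call = score_coding_potential(SequenceRecord("c", "CCCGGGTTT" * 30))
    assert (call.longest_orf_len, call.score, call.label) == (0, -1.0, "noncoding")


def test_orf_reaching_end_counts_complete_codons():
    seq = "ATG" + "GGC" * 20 + "GG"  # no stop; runs off the 3' end
    assert longest_orf(seq) == 63


def test_identify_distinct_matches_truth(reference, accession):
    from wildtx import genome_map
    from wildtx.assembly_qc import trim_polya

    clean = [trim_polya(t) for t in accession.transcripts
             if t.id not in accession.truth.artifact_truth]
    clean = [c for c in clean if c]
    clusters = cluster_transcripts(clean)
    alns = genome_map.align_transcripts(clean, reference.genome)
    classes = genome_map.classify_transcripts(
        alns, reference.genes, contig_ids=[c.id for c in clean]
    )
    class_of = {m.contig_id: m.category for m in classes}
    coding, noncoding = identify_distinct(clusters, class_of, {c.id: c for c in clean})
    want_coding = {c for c, l in accession.truth.distinct_truth.items() if l == "coding"}
    want_nc = {c for c, l in accession.truth.distinct_truth.items() if l == "noncoding"}
    assert coding == want_coding
    assert noncoding == want_nc


def test_identify_distinct_missing_class_errors():
    rng = np.random.default_rng(8)
    contig = SequenceRecord("x", _rand(rng, 300))
    (cluster,) = cluster_transcripts([contig])
    with pytest.raises(ValueError, match="no mapping classification"):
        identify_distinct([cluster], {}, {"x": contig})


def test_no_unmapped_representatives_gives_empty_sets():
    rng = np.random.default_rng(9)
    contig = SequenceRecord("x", _rand(rng, 300))
    (cluster,) = cluster_transcripts([contig])
    coding, noncoding = identify_distinct([cluster], {"x": "sense_gene"}, {"x": contig})
    assert coding == set() and noncoding == set()
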