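"""cis-NAT candidate search, genomic confirmation and geometry classes."""

import numpy as np
import pytest

from wildtx import cisnat
from wildtx.genome_map import TranscriptAlignment
from wildtx.io_formats import SequenceRecord, revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_planted_antisense_overlap_is_candidate():
    rng = np.random.default_rng(1)
    a = SequenceRecord("a", _rand(rng, 400))
    b = SequenceRecord("b", revcomp(a.seq[100:300]) + _rand(rng, 150))
    cands = cisnat.find_antisense_overlaps([a, b])
    assert [(x, y) for x, y, _ in cands] == [("a", "b")]
    assert cands[0][2] >= 200


@pytest.mark.parametrize("overlap, expected", [(50, 0), (51, 1), (80, 1)])
def test_overlap_boundary_is_strictly_greater_than_50(overlap, expected):
    rng = np.random.default_rng(2)
    a = SequenceRecord("a", _rand(rng, 300))
    b = SequenceRecord("b", revcomp(a.seq[-overlap:]) + _rand(rng, 200))
    cands = cisnat.find_antisense_overlaps([a, b])
    assert len(cands) == expected


def test_sense_identical_contigs_are_not_candidates():
    rng = np.random.default_rng(3)
    seq = _rand(rng, 400)
    a, b = SequenceRecord("a", seq), SequenceRecord("b", seq[:350])
    assert cisnat.find_antisense_overlaps([a, b]) == []


def _aln(cid, span, strand, blocks=None):
    if blocks is None:
        blocks = (((0, span[1] - span[0]), span),)
    return TranscriptAlignment(cid, "c1", strand, blocks, span[1] - span[0], 0)


LABELS = {"a": "coding", "b": "noncoding"}


@pytest.mark.parametrize(
    "span_a, strand_a, span_b, strand_b, geometry",
    [
        ((100, 1000), "+", (300, 700), "-", "contained"),
        ((100, 1000), "+", (800, 1500), "-", "tail_to_tail"),
        ((800, 1500), "+", (100, 1000), "-", "head_to_head"),
        ((100, 1000), "-", (800, 1500), "+", "head_to_head"),
        ((800, 1500), "-", (100, 1000), "+", "tail_to_tail"),
        ((100, 1000), "-", (100, 700), "+", "contained"),  # shared boundary
    ],
)
def test_geometry_classification(span_a, strand_a, span_b, strand_b, geometry):
    pairs = cisnat.confirm_and_classify(
        [("a", "b", 120)],
        [_aln("a", span_a, strand_a), _aln("b", span_b, strand_b)],
        LABELS,
    )
    assert [p.geometry for p in pairs] == [geometry]
    assert pairs[0].pairing == "coding_noncoding"


def test_geometry_is_symmetric():
    alns = [_aln("a", (100, 1000), "+"), _aln("b", (800, 1500), "-")]
    (p1,) = cisnat.confirm_and_classify([("a", "b", 120)], alns, LABELS)
    (p2,) = cisnat.confirm_and_classify([("b", "a", 120)], alns, LABELS)
    assert p1.geometry == p2.geometry == "tail_to_tail"
    assert (p1.contig_a, p1.contig_b) == (p2.contig_a, p2.contig_b)


def test_mirror_artifact_discarded():
    blocks = (((0, 200), (100, 300)), ((200, 400), (350, 550)))
    alns = [
        TranscriptAlignment("a", "c1", "+", blocks, 400, 0),
        TranscriptAlignment("b", "c1", "-", blocks, 400, 0),
    ]
    assert cisnat.confirm_and_classify([("a", "b", 400)], alns, LABELS) == []


def test_same_strand_pair_rejected():
    alns = [_aln("a", (100, 1000), "+"), _aln("b", (300, 700), "+")]
    assert cisnat.confirm_and_classify([("a", "b", 120)], alns, LABELS) == []


def test_member_without_unique_alignment_dropped(caplog):
    alns = [
        _aln("a", (100, 1000), "+"),
        _aln("b", (300, 700), "-"),
        _aln("b", (5000, 5400), "-"),
    ]
    assert cisnat.confirm_and_classify([("a", "b", 120)], alns, LABELS) == []


def test_disjoint_spans_rejected():
    alns = [_aln("a", (100, 400), "+"), _aln("b", (700, 1000), "-")]
    assert cisnat.confirm_and_classify([("a", "b", 120)], alns, LABELS) == []


def test_recovers_planted_pairs_exactly(reference, accession):
    from wildtx import genome_map
    from wildtx.assembly_qc import trim_polya
    from wildtx.distinct_genes import score_coding_potential

    clean = [trim_polya(t) for t in accession.transcripts
             if t.id not in accession.truth.artifact_truth]
    clean = [c for c in clean if c]
    cands = cisnat.find_antisense_overlaps(clean)
    alns = genome_map.align_transcripts(clean, reference.genome)
    labels = {c.id: score_coding_potential(c).label for c in clean}
    pairs = cisnat.confirm_and_classify(cands, alns, labels)
    got = {(p.contig_a, p.contig_b, p.geometry, p.pairing) for p in pairs}
    want = {(min(a, b), max(a, b), g, pr)
            for a, b, g, pr in accession.truth.antisense_truth}
    assert got == want
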