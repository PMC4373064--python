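"""cis-natural antisense transcript (cis-NAT) discovery and classification.

Candidate pairs come from a reverse-orientation self-comparison of the
stranded contig set: a pair qualifies when the best local alignment of one
contig against the reverse complement of the other spans more than 50
columns (strict) at >= 97% identity. Candidates are confirmed on the
genome: both members must have a unique qualifying alignment, on the same
chromosome, on opposite strands, with intersecting genomic spans and
non-identical genomic block sets (identical blocks on opposite strands are
the signature of a strand-flip assembly artifact, not of two transcripts).

Overlap geometry follows the usual taxonomy: one span containing the other
is "contained"; otherwise an overlap involving both strand-aware 3' termini
is "tail_to_tail" and one involving both 5' termini is "head_to_head".
Pairs are labelled coding_coding / coding_noncoding / noncoding_noncoding
from the members' coding-potential calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._align import best_local_alignment, seeded_pairs
from .genome_map import TranscriptAlignment
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

GEOMETRIES = ("head_to_head", "tail_to_tail", "contained")


@dataclass(frozen=True)
class CisNatPair:
    contig_a: str
    contig_b: str
    seq_overlap: int
    genomic_overlap: int
    geometry: str
    pairing: str


def find_antisense_overlaps(
    contigs: Sequence[SequenceRecord],
    min_overlap: int = 50,
    min_identity: float = 0.97,
) -> list[tuple[str, str, int]]:
    """Reverse-orientation self-comparison of the contig set.

    Returns (id_a, id_b, overlap_columns) for pairs whose best local
    alignment of a against revcomp(b) spans strictly more than
    ``min_overlap`` columns at >= ``min_identity`` identity.
    """
    rc = [c.reverse_complement() for c in contigs]
    candidates: list[tuple[str, str, int]] = []
    seen: set[frozenset[str]] = set()
    for i, j in sorted(seeded_pairs(contigs, others=rc)):
        if i == j:
            continue
        key = frozenset((contigs[i].id, contigs[j].id))
        if key in seen:
            continue
        seen.add(key)
        hit = best_local_alignment(contigs[i].seq, rc[j].seq)
        if hit is None:
            continue
        if hit.columns > min_overlap and hit.identity >= min_identity:
            a, b = sorted((contigs[i].id, contigs[j].id))
            candidates.append((a, b, hit.columns))
    candidates.sort()
    return candidates


def _three_prime(span: tuple[int, int], strand: str) -> int:
    return span[1] if strand == "+" else span[0]


def _five_prime(span: tuple[int, int], strand: str) -> int:
    return span[0] if strand == "+" else span[1]


def _classify_geometry(a: TranscriptAlignment, b: TranscriptAlignment) -> str:
    sa, sb = a.genomic_span, b.genomic_span
    if (sa[0] <= sb[0] and sb[1] <= sa[1]) or (sb[0] <= sa[0] and sa[1] <= sb[1]):
        return "contained"
    o1, o2 = max(sa[0], sb[0]), min(sa[1], sb[1])

    def touched(end: int) -> bool:
        return o1 <= end <= o2

    if touched(_three_prime(sa, a.strand)) and touched(_three_prime(sb, b.strand)):
        return "tail_to_tail"
    if touched(_five_prime(sa, a.strand)) and touched(_five_prime(sb, b.strand)):
        return "head_to_head"
    # opposite-strand partial overlaps always hit one of the two cases;
    # reachable only with degenerate spans
    return "contained"


def confirm_and_classify(
    pairs: Sequence[tuple[str, str, int]],
    alignments: Sequence[TranscriptAlignment],
    coding_labels: Mapping[str, str],
) -> list[CisNatPair]:
    """Confirm sequence-level candidates on the genome and classify them.

    ``coding_labels`` maps contig id -> coding|noncoding. Pairs whose
    members lack a unique qualifying alignment are dropped with a warning;
    mirror artifacts (identical genomic block sets on opposite strands) are
    discarded.
    """
    by_contig: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)

    out: list[CisNatPair] = []
    for ida, idb, seq_overlap in pairs:
        if ida == idb:
            continue
        ida, idb = sorted((ida, idb))  # canonical pair order: classify(a,b) == classify(b,a)
        alns_a, alns_b = by_contig.get(ida, []), by_contig.get(idb, [])
        if len(alns_a) != 1 or len(alns_b) != 1:
            logger.warning(
                "cis-NAT candidate (%s, %s) dropped: members need exactly one "
                "qualifying alignment (%d, %d found)",
                ida, idb, len(alns_a), len(alns_b),
            )
            continue
        a, b = alns_a[0], alns_b[0]
        if a.chrom != b.chrom or a.strand == b.strand:
            continue
        sa, sb = a.genomic_span, b.genomic_span
        genomic_overlap = min(sa[1], sb[1]) - max(sa[0], sb[0])
        if genomic_overlap < 1:
            continue
        if a.block_set == b.block_set:
            continue  # mirror artifact, not two transcripts
        labels = sorted((coding_labels[ida], coding_labels[idb]))
        out.append(CisNatPair(
            contig_a=ida, contig_b=idb,
            seq_overlap=seq_overlap,
            genomic_overlap=genomic_overlap,
            geometry=_classify_geometry(a, b),
            pairing="_".join(labels),
        ))
    out.sort(key=lambda p: (p.contig_a, p.contig_b))
    return out


def write_cisnat_tsv(pairs: Sequence[CisNatPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\tgeometry\tpairing\tseq_overlap\tgenomic_overlap\n")
        for p in pairs:
            fh.write(f"{p.contig_a}\t{p.contig_b}\t{p.geometry}\t{p.pairing}\t"
                     f"{p.seq_overlap}\t{p.genomic_overlap}\n")
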