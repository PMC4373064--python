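"""Redundancy clustering, distinct-gene identification and coding potential.

Contigs sharing a same-orientation local alignment of >= 100 aligned columns
at >= 97% identity are merged by single linkage; the longest member
represents each cluster. Representatives with no qualifying genome
alignment are the "distinct" transcripts, split into protein-coding and
non-coding by a transparent ORF-length score: score = L/300 - 1 where L is
the longest sense-strand ORF in nucleotides, positive score = coding. The
score is a deliberate, documented surrogate for SVM-based coding-potential
classifiers; only the sign of the score is consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._align import best_local_alignment, seeded_pairs
from .io_formats import SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptCluster:
    member_ids: frozenset[str]
    representative: str


@dataclass(frozen=True)
class CodingCall:
    contig_id: str
    longest_orf_len: int
    score: float
    label: str  # coding | noncoding


def longest_orf(seq: str) -> int:
    """Longest ATG..stop ORF on the sense strand, in nt, across 3 frames.

    Length runs from the ATG through the stop codon inclusive; an ORF
    reaching the 3' end without a stop counts through its last complete
    codon.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        open_start: int | None = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - open_start)
                open_start = None
            i += 3
        if open_start is not None:  # ran off the 3' end
            best = max(best, i - open_start)
    return best


def score_coding_potential(contig: SequenceRecord, orf_ref_len: int = 300) -> CodingCall:
    """ORF-length coding score; positive score = coding."""
    L = longest_orf(contig.seq)
    score = L / orf_ref_len - 1.0
    return CodingCall(
        contig_id=contig.id,
        longest_orf_len=L,
        score=score,
        label="coding" if score > 0 else "noncoding",
    )


def _pair_linked(a: str, b: str, min_identity: float, min_overlap: int) -> bool:
    hit = best_local_alignment(a, b)
    return (
        hit is not None
        and hit.columns >= min_overlap
        and hit.identity >= min_identity
    )


def cluster_transcripts(
    contigs: Sequence[SequenceRecord],
    min_identity: float = 0.97,
    min_overlap: int = 100,
) -> list[TranscriptCluster]:
    """Single-linkage clusters over qualifying same-orientation overlaps.

    Candidate edges are limited to contig pairs sharing a 15-mer; each
    candidate is confirmed by its best local alignment (>= min_overlap
    aligned columns at >= min_identity identity). Clusters are the
    connected components; the representative is the longest member, ties
    broken toward the lexicographically smallest id.
    """
    n = len(contigs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i, j in sorted(seeded_pairs(contigs)):
        if find(i) == find(j):
            continue
        if _pair_linked(contigs[i].seq, contigs[j].seq, min_identity, min_overlap):
            union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    length_of = {c.id: len(c.seq) for c in contigs}
    clusters = []
    for members in groups.values():
        ids = [contigs[i].id for i in members]
        rep = min(ids, key=lambda cid: (-length_of[cid], cid))
        clusters.append(TranscriptCluster(member_ids=frozenset(ids), representative=rep))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def identify_distinct(
    clusters: Sequence[TranscriptCluster],
    classes: Mapping[str, str],
    contigs_by_id: Mapping[str, SequenceRecord],
    orf_ref_len: int = 300,
) -> tuple[set[str], set[str]]:
    """Split unmapped cluster representatives into coding / noncoding sets.

    ``classes`` maps representative id -> mapping category (genome_map
    output). Raises if a representative has no category.
    """
    coding: set[str] = set()
    noncoding: set[str] = set()
    for cluster in clusters:
        rep = cluster.representative
        if rep not in classes:
            raise ValueError(f"representative {rep} has no mapping classification")
        if classes[rep] != "unmapped":
            continue
        call = score_coding_potential(contigs_by_id[rep], orf_ref_len=orf_ref_len)
        (coding if call.label == "coding" else noncoding).add(rep)
    return coding, noncoding


def write_cluster_tsv(clusters: Sequence[TranscriptCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmember_id\n")
        for c in clusters:
            for m in sorted(c.member_ids):
                fh.write(f"{c.representative}\t{m}\n")
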