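"""Seeded pairwise local alignment shared by clustering and cis-NAT search.

Candidate pairs are restricted to sequences sharing at least one exact
15-mer (in the requested relative orientation); surviving pairs are aligned
with Biopython's Smith-Waterman PairwiseAligner and summarized as aligned
columns and identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .io_formats import SequenceRecord, revcomp

SEED_K = 15


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment between two sequences."""

    columns: int      # alignment length incl. internal gap columns
    matches: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -2.5
    a.extend_gap_score = -0.5
    return a


def best_local_alignment(a: str, b: str) -> LocalHit | None:
    """Best Smith-Waterman local alignment of a vs b (given orientations)."""
    aligner = _aligner()
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = aln.shape[1]
    return LocalHit(columns=columns, matches=counts.identities)


def _kmer_set(seq: str, k: int = SEED_K) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i:i + k]}


def seeded_pairs(
    records: Sequence[SequenceRecord],
    others: Sequence[SequenceRecord] | None = None,
    k: int = SEED_K,
) -> set[tuple[int, int]]:
    """Index pairs (i, j) sharing at least one k-mer.

    With ``others`` None, pairs are within ``records`` (i < j); otherwise
    pairs are (i in records, j in others) — used for the reverse-orientation
    self-comparison, where ``others`` holds reverse complements.
    """
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        for kmer in _kmer_set(rec.seq, k):
            index.setdefault(kmer, []).append(i)
    pairs: set[tuple[int, int]] = set()
    if others is None:
        for hits in index.values():
            for x in range(len(hits)):
                for y in range(x + 1, len(hits)):
                    pairs.add((hits[x], hits[y]))
    else:
        for j, rec in enumerate(others):
            seen: set[int] = set()
            for kmer in _kmer_set(rec.seq, k):
                seen.update(index.get(kmer, ()))
            pairs.update((i, j) for i in seen)
    return pairs
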