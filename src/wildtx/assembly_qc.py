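"""Assembly summary statistics, polyA trimming and the strand-artifact filter.

Strand-specific libraries with incomplete second-strand digestion yield
mirror contigs written in the antisense direction; a contig whose sense read
support is under one tenth of its antisense support is discarded as such an
artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bases: int
    n50: int
    mean_length: float
    gc_percent: float


@dataclass(frozen=True)
class StrandCount:
    contig_id: str
    sense_reads: int
    antisense_reads: int

    def __post_init__(self) -> None:
        if self.sense_reads < 0 or self.antisense_reads < 0:
            raise ValueError(f"negative read count for {self.contig_id}")


def compute_assembly_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    """N50, mean length and GC% of an assembly.

    N50 is the length at which the cumulative length of descending-sorted
    contigs first reaches half the total. GC% excludes N from the
    denominator.
    """
    if not contigs:
        raise ValueError("empty assembly")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for ln in lengths:
        cum += ln
        if cum * 2 >= total:
            n50 = ln
            break
    gc = at = 0
    for c in contigs:
        gc += c.seq.count("G") + c.seq.count("C")
        at += c.seq.count("A") + c.seq.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bases=total,
        n50=n50,
        mean_length=total / len(contigs),
        gc_percent=gc_percent,
    )


def trim_polya(contig: SequenceRecord, min_run: int = 10) -> SequenceRecord | None:
    """Trim one polyA tail (or leading polyT, for antisense-written contigs).

    The 3' end is checked first; at most one end is trimmed per call. A
    contig trimmed to nothing is dropped (None) with a warning.
    """
    seq = contig.seq
    n_a = len(seq) - len(seq.rstrip("A"))
    if n_a >= min_run:
        trimmed = seq[: len(seq) - n_a]
    else:
        n_t = len(seq) - len(seq.lstrip("T"))
        trimmed = seq[n_t:] if n_t >= min_run else seq
    if not trimmed:
        logger.warning("contig %s trimmed to length 0; dropped", contig.id)
        return None
    return SequenceRecord(contig.id, trimmed)


def filter_strand_artifacts(
    counts: Iterable[StrandCount],
    contig_ids: Iterable[str] | None = None,
    ratio: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Discard contigs whose sense reads are strictly < ratio x antisense reads.

    Returns (kept ids, discarded ids). Contigs listed in ``contig_ids`` but
    absent from the counts are kept with a warning; equality at the boundary
    keeps the contig.
    """
    counts = list(counts)
    kept: list[str] = []
    discarded: list[str] = []
    counted = set()
    for c in counts:
        counted.add(c.contig_id)
        if c.sense_reads < ratio * c.antisense_reads:
            discarded.append(c.contig_id)
        else:
            kept.append(c.contig_id)
    if contig_ids is not None:
        for cid in contig_ids:
            if cid not in counted:
                logger.warning("contig %s has no strand counts; kept", cid)
                kept.append(cid)
    return kept, discarded
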