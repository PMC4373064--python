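"""Spliced placement of transcripts on the reference genome and mapping
classification.

The aligner is a deliberately simple seed-chain-extend spliced aligner for
desk-scale genomes: exact 31-mer seeds are merged into maximal runs,
chained colinearly per locus by dynamic programming, and the gaps between
runs are resolved by small global alignments whose affine gap costs place
intron-sized genomic gaps in one piece and small indels in another. Qualifying
alignments require identity >= 97% and contig coverage >= 90%; externally
produced alignments can be imported through the alignment TSV instead.

Each transcript is then binned into one of the mapping categories:
unmapped, multiple (several qualifying loci), intergenic, small_overlap,
sense_gene or antisense_gene, based on the fraction of aligned bases whose
genomic images fall inside annotated gene spans (introns included) and on
strand agreement with the overlapping gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from intervaltree import IntervalTree

from .io_formats import GeneModel, SequenceRecord, revcomp

SEED_K = 31
MIN_INTRON = 4
LOCUS_GAP = 10_000

CATEGORIES = (
    "unmapped", "multiple", "intergenic", "small_overlap", "sense_gene", "antisense_gene",
)


@dataclass(frozen=True)
class TranscriptAlignment:
    """Block-structured placement of one contig on the genome.

    ``blocks`` pair equal-sized contig and genomic intervals (0-based
    half-open). For minus-strand alignments the contig intervals refer to
    the reverse-complemented contig.
    """

    contig_id: str
    chrom: str
    strand: str
    blocks: tuple
    matches: int
    mismatches: int

    @property
    def identity(self) -> float:
        total = self.matches + self.mismatches
        return self.matches / total if total else 0.0

    @property
    def aligned_bases(self) -> int:
        return sum(ce - cs for (cs, ce), _ in self.blocks)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.blocks[0][1][0], self.blocks[-1][1][1]

    @property
    def block_set(self) -> frozenset:
        return frozenset(g for _, g in self.blocks)


@dataclass(frozen=True)
class MappingClass:
    contig_id: str
    category: str
    best_gene: str | None
    overlap_fraction: float


class GenomeIndex:
    """Exact 31-mer index over the forward strand of every chromosome."""

    def __init__(self, genome: Sequence[SequenceRecord], k: int = SEED_K,
                 max_hits: int = 10) -> None:
        self.k = k
        self.seqs: dict[str, str] = {r.id: r.seq for r in genome}
        index: dict[str, list[tuple[str, int]]] = {}
        for rec in genome:
            s = rec.seq
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                if "N" in kmer:
                    continue
                hits = index.setdefault(kmer, [])
                if len(hits) <= max_hits:
                    hits.append((rec.id, i))
        # kmers with pathological multiplicity are uninformative as seeds
        self.index = {km: h for km, h in index.items() if len(h) <= max_hits}

    def seeds(self, seq: str) -> list[tuple[str, int, int]]:
        """(chrom, genome_pos, contig_pos) for every exact k-mer hit."""
        out = []
        for i in range(len(seq) - self.k + 1):
            for chrom, g in self.index.get(seq[i:i + self.k], ()):
                out.append((chrom, g, i))
        return out


def _merge_runs(seeds: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge same-diagonal seeds into maximal exact runs (c_start, c_end, g_start)."""
    by_diag: dict[int, list[int]] = {}
    for g, c in seeds:
        by_diag.setdefault(g - c, []).append(c)
    runs = []
    for diag, cs in by_diag.items():
        cs.sort()
        start = prev = cs[0]
        for c in cs[1:]:
            if c <= prev + k:  # overlapping/contiguous kmers
                prev = c
            else:
                runs.append((start, prev + k, start + diag))
                start = prev = c
        runs.append((start, prev + k, start + diag))
    return runs


CHAIN_SLACK = 31  # runs may overlap by up to one seed (splice-junction k-mers)


def _chain_runs(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Colinear chain maximizing covered contig bases (DP over runs).

    Runs may overlap by up to CHAIN_SLACK on either sequence — seeds
    spanning an exon junction can extend into an intron whose boundary
    bases mimic the next exon — and overlaps are trimmed off the later run.
    """
    runs = sorted(runs)
    n = len(runs)
    score = [re - rs for rs, re, _ in runs]
    back = [-1] * n
    for i in range(n):
        cs_i, ce_i, gs_i = runs[i]
        for j in range(i):
            cs_j, ce_j, gs_j = runs[j]
            ge_j = gs_j + (ce_j - cs_j)
            if (cs_j <= cs_i and ce_j - cs_i <= CHAIN_SLACK
                    and gs_j <= gs_i and ge_j - gs_i <= CHAIN_SLACK
                    and gs_i - ge_j <= LOCUS_GAP):
                overlap = max(0, ce_j - cs_i, ge_j - gs_i)
                cand = score[j] + (ce_i - cs_i) - overlap
                if cand > score[i]:
                    score[i] = cand
                    back[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(runs[best])
        best = back[best]
    chain.reverse()
    # trim overlaps off the later run (keeps runs exact: same diagonal)
    out: list[tuple[int, int, int]] = []
    for cs, ce, gs in chain:
        if out:
            pcs, pce, pgs = out[-1]
            pge = pgs + (pce - pcs)
            delta = max(0, pce - cs, pge - gs)
            cs, gs = cs + delta, gs + delta
        if ce > cs:
            out.append((cs, ce, gs))
    return out


def _compare(a: str, b: str) -> tuple[int, int]:
    m = sum(1 for x, y in zip(a, b) if x == y)
    return m, len(a) - m


def _gap_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -2.5
    a.extend_gap_score = -0.5
    return a


END_PAD = 600  # window slack for re-aligned contig ends (indels or a skipped intron)


def _align_locus(oseq: str, gseq: str, chain: list[tuple[int, int, int]]
                 ) -> tuple[list, int, int]:
    """Fill inter-run gaps and extend ends; return (blocks, matches, mismatches)."""
    from ._align import _aligner  # same local scorer as the pairwise modules

    matches = mismatches = 0
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []

    def emit(cs: int, ce: int, gs: int) -> None:
        nonlocal matches, mismatches
        if ce <= cs:
            return
        if blocks and blocks[-1][0][1] == cs and blocks[-1][1][1] == gs:
            (pcs, _), (pgs, _) = blocks[-1]
            blocks[-1] = ((pcs, ce), (pgs, gs + (ce - cs)))
        else:
            blocks.append(((cs, ce), (gs, gs + (ce - cs))))

    def extend_end(c_start: int, a: str, g_start: int, b: str,
                   anchored_left: bool) -> None:
        """Place contig end segment ``a`` within genome window ``b``.

        ``anchored_left`` is True for the 3' extension (a begins at the last
        chained run) and False for the 5' extension (a ends at the first).
        An ungapped comparison at the anchored diagonal is tried first; if
        it looks indel-broken, the segment is re-aligned locally (terminal
        bases may then stay unaligned).
        """
        nonlocal matches, mismatches
        if not a or not b:
            return
        if len(b) >= len(a):
            # anchored-diagonal fast path (ungapped, no intron)
            off = 0 if anchored_left else len(b) - len(a)
            m, mm = _compare(a, b[off:off + len(a)])
            if mm <= 2 or len(a) < 12:
                matches += m
                mismatches += mm
                emit(c_start, c_start + len(a), g_start + off)
                return
        alns = _aligner().align(a, b)
        if len(alns) == 0 or alns.score <= 0:
            return
        for (ts, te), (qs, qe) in zip(*alns[0].aligned):
            m, mm = _compare(a[ts:te], b[qs:qe])
            matches += m
            mismatches += mm
            emit(c_start + ts, c_start + te, g_start + qs)

    # left extension to the contig 5' end, clamped at the chromosome start
    cs0, _, gs0 = chain[0]
    if cs0:
        wstart = max(0, gs0 - cs0 - END_PAD)
        extend_end(0, oseq[:cs0], wstart, gseq[wstart:gs0], anchored_left=False)

    prev_ce = prev_ge = None
    for cs, ce, gs in chain:
        if prev_ce is not None:
            gap_c, gap_g = cs - prev_ce, gs - prev_ge
            fill = min(gap_c, gap_g)
            if fill and gap_g > 2000:
                # intron: split the fillable contig bases between the two exon
                # sides minimizing mismatches, so junction-adjacent
                # substitutions do not smear across the intron
                left_c, left_g = oseq[prev_ce:prev_ce + fill], gseq[prev_ge:prev_ge + fill]
                right_c, right_g = oseq[cs - fill:cs], gseq[gs - fill:gs]
                left_mm = [0] * (fill + 1)
                for i in range(fill):
                    left_mm[i + 1] = left_mm[i] + (left_c[i] != left_g[i])
                right_mm = [0] * (fill + 1)  # right_mm[i]: suffix starting at i
                for i in range(fill - 1, -1, -1):
                    right_mm[i] = right_mm[i + 1] + (right_c[i] != right_g[i])
                split = max(
                    range(fill + 1),
                    key=lambda s: (-(left_mm[s] + right_mm[s]), s),
                )
                mm = left_mm[split] + right_mm[split]
                matches += fill - mm
                mismatches += mm
                if split:
                    emit(prev_ce, prev_ce + split, prev_ge)
                if split < fill:
                    emit(cs - (fill - split), cs, gs - (fill - split))
            elif fill:
                # resolve the gap (substitutions, small indels and/or an
                # intron) with a global alignment of the two gap sequences;
                # affine gap costs park intron-sized gaps in one piece
                a, b = oseq[prev_ce:cs], gseq[prev_ge:gs]
                aln = _gap_aligner().align(a, b)[0]
                for (ts, te), (qs, qe) in zip(*aln.aligned):
                    m, mm = _compare(a[ts:te], b[qs:qe])
                    matches += m
                    mismatches += mm
                    emit(prev_ce + ts, prev_ce + te, prev_ge + qs)
        matches += ce - cs
        emit(cs, ce, gs)
        prev_ce, prev_ge = ce, gs + (ce - cs)

    # right extension to the contig 3' end, clamped at the chromosome end
    rem = len(oseq) - prev_ce
    if rem:
        wend = min(len(gseq), prev_ge + rem + END_PAD)
        extend_end(prev_ce, oseq[prev_ce:], prev_ge, gseq[prev_ge:wend],
                   anchored_left=True)

    return blocks, matches, mismatches


def align_transcripts(
    contigs: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord] | GenomeIndex,
    min_identity: float = 0.97,
    min_coverage: float = 0.90,
) -> list[TranscriptAlignment]:
    """Qualifying spliced alignments of each contig on both strands.

    A contig seeding at several well-separated loci yields one alignment
    per qualifying locus; a contig with no seeds yields none.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: list[TranscriptAlignment] = []
    for contig in contigs:
        per_contig: list[TranscriptAlignment] = []
        for strand in "+-":
            oseq = contig.seq if strand == "+" else revcomp(contig.seq)
            seeds = index.seeds(oseq)
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, g, c in seeds:
                by_chrom.setdefault(chrom, []).append((g, c))
            for chrom, chrom_seeds in by_chrom.items():
                runs = _merge_runs(chrom_seeds, index.k)
                # split runs into loci by genomic position
                runs.sort(key=lambda r: r[2])
                loci: list[list[tuple[int, int, int]]] = []
                for run in runs:
                    if loci and run[2] - loci[-1][-1][2] <= LOCUS_GAP:
                        loci[-1].append(run)
                    else:
                        loci.append([run])
                for locus_runs in loci:
                    # a locus group may hold several true placements (e.g. a
                    # nearby tandem duplication): re-chain the leftover runs
                    remaining = locus_runs
                    for _ in range(4):
                        if not remaining:
                            break
                        chain = _chain_runs(remaining)
                        blocks, m, mm = _align_locus(oseq, index.seqs[chrom], chain)
                        aln = TranscriptAlignment(
                            contig_id=contig.id, chrom=chrom, strand=strand,
                            blocks=tuple(blocks), matches=m, mismatches=mm,
                        )
                        if (aln.identity >= min_identity
                                and aln.aligned_bases / len(contig) >= min_coverage):
                            per_contig.append(aln)
                        s, e = aln.genomic_span
                        rest = [
                            r for r in remaining
                            if not (r[2] < e and s < r[2] + (r[1] - r[0]))
                        ]
                        if len(rest) == len(remaining):
                            break
                        remaining = rest
        # collapse overlapping-locus duplicates (e.g. palindromic double hits)
        per_contig.sort(key=lambda a: -a.matches)
        kept: list[TranscriptAlignment] = []
        for aln in per_contig:
            s, e = aln.genomic_span
            if any(k.chrom == aln.chrom and s < k.genomic_span[1] and k.genomic_span[0] < e
                   for k in kept):
                continue
            kept.append(aln)
        out.extend(sorted(kept, key=lambda a: (a.chrom, a.genomic_span)))
    return out


def _gene_trees(annotation: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    return trees


def classify_transcripts(
    alignments: Sequence[TranscriptAlignment],
    annotation: Sequence[GeneModel],
    overlap_threshold: float = 0.90,
    contig_ids: Sequence[str] | None = None,
    chrom_names: set[str] | None = None,
) -> list[MappingClass]:
    """Assign each contig exactly one mapping category.

    ``contig_ids``, when given, supplies the full contig roster so that
    contigs without any qualifying alignment are reported as unmapped.
    The overlap fraction is (aligned contig bases whose genomic images fall
    inside any gene span) / (aligned contig bases).
    """
    trees = _gene_trees(annotation)
    if chrom_names is not None:
        for a in alignments:
            if a.chrom not in chrom_names:
                raise ValueError(f"alignment of {a.contig_id} references unknown chrom {a.chrom}")
    by_contig: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)
    roster = list(contig_ids) if contig_ids is not None else sorted(by_contig)

    out: list[MappingClass] = []
    for cid in roster:
        alns = by_contig.get(cid, [])
        if not alns:
            out.append(MappingClass(cid, "unmapped", None, 0.0))
            continue
        if len(alns) > 1:
            out.append(MappingClass(cid, "multiple", None, 0.0))
            continue
        aln = alns[0]
        tree = trees.get(aln.chrom, IntervalTree())
        in_gene = 0
        per_gene: dict[str, int] = {}
        for (cs, ce), (gs, ge) in aln.blocks:
            covered: set[int] = set()
            for iv in tree.overlap(gs, ge):
                ov_s, ov_e = max(gs, iv.begin), min(ge, iv.end)
                if ov_e > ov_s:
                    per_gene[iv.data.gene_id] = per_gene.get(iv.data.gene_id, 0) + (ov_e - ov_s)
                    covered.update(range(ov_s, ov_e))
            in_gene += len(covered)
        frac = in_gene / aln.aligned_bases if aln.aligned_bases else 0.0
        if frac == 0.0:
            out.append(MappingClass(cid, "intergenic", None, 0.0))
            continue
        best_gene = min(per_gene, key=lambda gid: (-per_gene[gid], gid))
        if frac < overlap_threshold:
            out.append(MappingClass(cid, "small_overlap", best_gene, frac))
            continue
        gene = next(g for g in annotation if g.gene_id == best_gene)
        category = "sense_gene" if gene.strand == aln.strand else "antisense_gene"
        out.append(MappingClass(cid, category, best_gene, frac))
    return out


def write_classification_tsv(classes: Sequence[MappingClass], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tcategory\tbest_gene\toverlap_fraction\n")
        for c in classes:
            fh.write(f"{c.contig_id}\t{c.category}\t{c.best_gene or '.'}\t{c.overlap_fraction:.4f}\n")
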