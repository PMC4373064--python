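"""Readers and writers for every external format the pipeline touches.

All coordinates held in memory are 0-based half-open; 1-based inclusive
conventions (GFF3, VCF, pileup TSV) are converted at the file boundary and
nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import gffutils

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(new_id or self.id, revcomp(self.seq))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneModel:
    """A reference gene: strand, exon chain and CDS chain in genomic coordinates.

    ``exons`` and ``cds`` are sorted, disjoint 0-based half-open intervals on
    the forward genomic strand regardless of ``strand``; for minus-strand
    genes the coding order is the reverse of the genomic order.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None:
                if s < prev_end:
                    raise ValueError(f"gene {self.gene_id}: overlapping exons")
                if s - prev_end < 4:
                    raise ValueError(f"gene {self.gene_id}: intron shorter than 4 bp")
            prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS ({s},{e}) not within an exon")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, genomic order."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def splice_sites(self) -> list[tuple[Interval, str]]:
        """2-bp donor/acceptor windows per intron, labelled strand-aware.

        For a plus-strand gene the donor (GT) is at the intron's genomic
        start and the acceptor (AG) at its genomic end; reversed on minus.
        """
        sites: list[tuple[Interval, str]] = []
        for i1, i2 in self.introns():
            left, right = (i1, i1 + 2), (i2 - 2, i2)
            if self.strand == "+":
                sites.append((left, "splice_donor"))
                sites.append((right, "splice_acceptor"))
            else:
                sites.append((left, "splice_acceptor"))
                sites.append((right, "splice_donor"))
        return sites


@dataclass
class PileupColumn:
    """Deduplicated per-site observations from read-to-genome alignment.

    ``pos`` is 0-based. ``ref_allele`` is the reference base at ``pos``; for
    columns where deletions are observed it carries the anchor base followed
    by the deleted reference bases. Alleles are a base, ``+SEQ`` (insertion
    after ``pos``) or ``-N`` (deletion of the next N bases).
    """

    chrom: str
    pos: int
    ref_allele: str
    observations: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.observations]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in pileup column {self.chrom}:{self.pos + 1}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; uppercase, U mapped to T.

    Raises on duplicate ids and on an empty file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")  # Biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, genome: Sequence[SequenceRecord]) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS rows into GeneModels (first mRNA per gene).

    GFF3 coordinates are 1-based inclusive; the returned models are 0-based
    half-open. Features extending beyond their chromosome raise.
    """
    chrom_len = {r.id: len(r.seq) for r in genome}
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in chrom_len:
            raise ValueError(f"gene {gene.id}: unknown chromosome {gene.seqid}")
        if gene.end > chrom_len[gene.seqid]:
            raise ValueError(f"gene {gene.id}: feature beyond chromosome end")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            raise ValueError(f"gene {gene.id}: no mRNA feature")
        if len(mrnas) > 1:
            logger.warning("gene %s has %d mRNAs; keeping the first by file order",
                           gene.id, len(mrnas))
        mrna = mrnas[0]
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        for s, e in exons + cds:
            if e > chrom_len[gene.seqid] or s < 0:
                raise ValueError(f"gene {gene.id}: feature beyond chromosome end")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                cds=cds,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialize GeneModels as gene/mRNA/exon/CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            row = lambda ftype, s, e, attrs: fh.write(
                f"{g.chrom}\twildtx\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            row("gene", g.start, g.end, f"ID={g.gene_id}")
            mrna_id = f"{g.gene_id}.1"
            row("mRNA", g.start, g.end, f"ID={mrna_id};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.exons, 1):
                row("exon", s, e, f"ID={mrna_id}.exon{i};Parent={mrna_id}")
            for i, (s, e) in enumerate(g.cds, 1):
                row("CDS", s, e, f"ID={mrna_id}.cds{i};Parent={mrna_id}")


# ---------------------------------------------------------------------------
# alignment TSV (PSL-inspired)
# ---------------------------------------------------------------------------

ALIGNMENT_TSV_HEADER = (
    "contig\tchrom\tstrand\tmatches\tmismatches\tblock_count\t"
    "contig_starts\tgenome_starts\tblock_sizes"
)


def write_alignment_tsv(alignments, path: str | Path) -> None:
    """Write TranscriptAlignments in the PSL-inspired TSV dialect."""
    with open(path, "w") as fh:
        fh.write(ALIGNMENT_TSV_HEADER + "\n")
        for a in alignments:
            cstarts = ",".join(str(b[0][0]) for b in a.blocks)
            gstarts = ",".join(str(b[1][0]) for b in a.blocks)
            sizes = ",".join(str(b[0][1] - b[0][0]) for b in a.blocks)
            fh.write(
                f"{a.contig_id}\t{a.chrom}\t{a.strand}\t{a.matches}\t{a.mismatches}\t"
                f"{len(a.blocks)}\t{cstarts}\t{gstarts}\t{sizes}\n"
            )


def read_alignment_tsv(path: str | Path):
    """Read the alignment TSV back into TranscriptAlignments."""
    from .genome_map import TranscriptAlignment  # local import: avoid cycle

    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != ALIGNMENT_TSV_HEADER.strip():
            raise ValueError(f"unexpected alignment TSV header in {path}")
        for line in fh:
            c, chrom, strand, m, mm, _n, cs, gs, sz = line.rstrip("\n").split("\t")
            cstarts = [int(x) for x in cs.split(",")]
            gstarts = [int(x) for x in gs.split(",")]
            sizes = [int(x) for x in sz.split(",")]
            blocks = [
                ((a, a + s), (b, b + s)) for a, b, s in zip(cstarts, gstarts, sizes)
            ]
            out.append(
                TranscriptAlignment(
                    contig_id=c, chrom=chrom, strand=strand,
                    blocks=blocks, matches=int(m), mismatches=int(mm),
                )
            )
    return out


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup_tsv(columns: Sequence[PileupColumn], path: str | Path) -> None:
    """chrom, 1-based pos, ref, semicolon-separated read_id:allele tokens."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\tobservations\n")
        for col in columns:
            obs = ";".join(f"{r}:{a}" for r, a in col.observations)
            fh.write(f"{col.chrom}\t{col.pos + 1}\t{col.ref_allele}\t{obs}\n")


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, ref, obs = line.rstrip("\n").split("\t")
            observations = []
            if obs:
                for token in obs.split(";"):
                    rid, allele = token.split(":", 1)
                    observations.append((rid, allele))
            out.append(PileupColumn(chrom, int(pos) - 1, ref, observations))
    return out


def convert_mpileup_bases(chrom: str, pos1: int, ref: str, bases: str) -> PileupColumn:
    """Best-effort conversion of a samtools-mpileup base string to a column.

    Handles ``.``/``,`` (reference match), ACGT (substitution), ``+n SEQ`` /
    ``-n SEQ`` (indels), ``*`` (deleted base placeholder, dropped), ``^q``
    read starts and ``$`` read ends. Read identities are not present in
    mpileup text, so synthetic ids r1..rn are assigned.
    """
    observations: list[tuple[str, str]] = []
    i, n = 0, 0
    s = bases
    while i < len(s):
        ch = s[i]
        if ch == "^":
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch == "*":
            i += 1
            continue
        if ch in ".,":
            allele = ref[0]
            i += 1
        elif ch.upper() in "ACGTN":
            allele = ch.upper()
            i += 1
        elif ch in "+-":
            j = i + 1
            while j < len(s) and s[j].isdigit():
                j += 1
            ln = int(s[i + 1:j])
            seq = s[j:j + ln].upper()
            allele = f"+{seq}" if ch == "+" else f"-{ln}"
            i = j + ln
            # the indel annotates the preceding read observation
            if observations:
                n_prev = observations.pop()
                observations.append((n_prev[0], allele))
                continue
        else:
            raise ValueError(f"unsupported mpileup token {ch!r}")
        n += 1
        observations.append((f"r{n}", allele))
    return PileupColumn(chrom, pos1 - 1, ref, observations)


# ---------------------------------------------------------------------------
# strand counts / GO map / generic TSVs
# ---------------------------------------------------------------------------

def read_strand_counts(path: str | Path):
    from .assembly_qc import StrandCount

    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, sense, anti = line.rstrip("\n").split("\t")
            out.append(StrandCount(cid, int(sense), int(anti)))
    return out


def write_strand_counts(counts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tsense_reads\tantisense_reads\n")
        for c in counts:
            fh.write(f"{c.contig_id}\t{c.sense_reads}\t{c.antisense_reads}\n")


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """GO map TSV: one (element_id, term_id) pair per row."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            eid, term = line.split("\t")
            out.setdefault(eid, set()).add(term)
    return out


def write_go_map(term_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for eid in sorted(term_map):
            for term in sorted(term_map[eid]):
                fh.write(f"{eid}\t{term}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=EFF,Number=1,Type=String,Description="Effect annotation: region|effect|gene_id">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Distinct-read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(effects, path: str | Path) -> None:
    """Write annotated variants as VCF v4.2 with an EFF INFO tag.

    Input must be sorted by (chrom, pos); indels are expected already
    left-anchored on the preceding reference base (the caller's native
    representation).
    """
    keys = [(e.variant.chrom, e.variant.pos) for e in effects]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for e in effects:
            v = e.variant
            info = (
                f"EFF={e.region}|{e.effect}|{e.gene_id or '.'};"
                f"DP={v.depth};AF={v.af:.4f}"
            )
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
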