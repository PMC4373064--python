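"""Homozygous SNP/indel calling from pileups and functional effect annotation.

Calling follows two rules: a variant must be supported by at least four
distinct reads carrying the alternate allele, and its allele frequency
(alt reads / distinct reads at the site) must exceed 0.70 strictly —
homozygosity is enforced solely by the frequency rule, with no genotype
likelihoods.

Effects are assigned one per variant by severity: start_lost > stop_gained
> stop_lost > frameshift > splice_disruption > nonsynonymous > synonymous >
noncoding, after locating the variant by region precedence splice (the 2-bp
canonical GT/AG intron ends) > CDS > UTR exon > intron > intergenic. CDS
SNPs are resolved by rebuilding the affected codon in coding orientation
under the standard nuclear codon table; alternative start codons are not
honored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import GeneModel, PileupColumn, SequenceRecord

logger = logging.getLogger(__name__)

STOPS = {"TAA", "TAG", "TGA"}

SEVERITY = [
    "start_lost", "stop_gained", "stop_lost", "frameshift",
    "splice_disruption", "inframe_indel", "nonsynonymous", "synonymous",
    "noncoding",
]
_RANK = {e: i for i, e in enumerate(SEVERITY)}

REGION_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class Variant:
    """A called homozygous substitution or small indel, VCF-style anchored.

    ``pos`` is 0-based. For indels ``ref``/``alt`` include the anchor base
    preceding the inserted/deleted sequence.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # snp | ins | del
    support: int
    depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.support < 1 or self.depth < self.support:
            raise ValueError("bad support/depth")

    @property
    def af(self) -> float:
        return self.support / self.depth

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantEffect:
    variant: Variant
    region: str
    effect: str
    gene_id: str | None


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate_reads(
    columns: Sequence[PileupColumn],
    read_meta: Mapping[str, tuple],
) -> list[PileupColumn]:
    """Drop PCR duplicates: among reads sharing (chrom, start, strand, block
    structure), only the lexicographically smallest read id survives,
    consistently across every column."""
    all_reads = {rid for col in columns for rid, _ in col.observations}
    missing = sorted(all_reads - set(read_meta))
    if missing:
        raise ValueError(f"missing read metadata for {missing[0]}")
    keep: dict[tuple, str] = {}
    for rid in sorted(all_reads):
        sig = tuple(read_meta[rid])
        keep.setdefault(sig, rid)
    survivors = set(keep.values())
    out = []
    for col in columns:
        obs = [(r, a) for r, a in col.observations if r in survivors]
        out.append(PileupColumn(col.chrom, col.pos, col.ref_allele, obs))
    return out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_variants(
    pileup: Sequence[PileupColumn],
    min_support: int = 4,
    min_af: float = 0.70,
) -> list[Variant]:
    """Call the most frequent non-reference allele per column.

    Emitted iff alt support >= min_support and support/depth > min_af
    (strict). A tie between distinct non-reference alleles yields no call.
    Input observations are assumed deduplicated and uniquely mapped.
    """
    out: list[Variant] = []
    for col in sorted(pileup, key=lambda c: (c.chrom, c.pos)):
        depth = len(col.observations)
        if depth == 0:
            logger.debug("zero-depth column %s:%d skipped", col.chrom, col.pos + 1)
            continue
        ref_base = col.ref_allele[0]
        tally: dict[str, int] = {}
        for _rid, allele in col.observations:
            if allele != ref_base:
                tally[allele] = tally.get(allele, 0) + 1
        if not tally:
            continue
        best = max(tally.values())
        top = [a for a, n in tally.items() if n == best]
        if len(top) > 1:
            continue
        allele = top[0]
        if best < min_support or best / depth <= min_af:
            continue
        if allele.startswith("+"):
            ref, alt, vtype = ref_base, ref_base + allele[1:], "ins"
        elif allele.startswith("-"):
            dlen = int(allele[1:])
            if len(col.ref_allele) < dlen + 1:
                raise ValueError(
                    f"column {col.chrom}:{col.pos + 1} lacks reference sequence "
                    f"for a {dlen} bp deletion"
                )
            ref, alt, vtype = col.ref_allele[: dlen + 1], ref_base, "del"
        else:
            ref, alt, vtype = ref_base, allele, "snp"
        out.append(Variant(col.chrom, col.pos, ref, alt, vtype, best, depth))
    return out


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------

def _affected_interval(v: Variant) -> tuple[int, int]:
    if v.vtype == "snp":
        return v.pos, v.pos + 1
    if v.vtype == "del":
        return v.pos + 1, v.pos + 1 + v.indel_length
    return v.pos, v.pos + 2  # insertion point between pos and pos+1


def _in_intervals(s: int, e: int, ivs: Sequence[tuple[int, int]]) -> bool:
    return any(xs <= s and e <= xe for xs, xe in ivs)


def _overlaps_intervals(s: int, e: int, ivs: Sequence[tuple[int, int]]) -> bool:
    return any(s < xe and xs < e for xs, xe in ivs)


def _coding_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of genomic position ``pos`` within the spliced CDS,
    in coding orientation."""
    fwd = 0
    for s, e in gene.cds:
        if s <= pos < e:
            fwd += pos - s
            break
        fwd += e - s
    else:
        raise ValueError("position not in CDS")
    return fwd if gene.strand == "+" else gene.cds_length - 1 - fwd


def _cds_base(gene: GeneModel, chrom_seq: str, coding_offset: int,
              override: tuple[int, str] | None = None) -> str:
    """Base at a coding offset, optionally overriding one genomic base."""
    fwd = coding_offset if gene.strand == "+" else gene.cds_length - 1 - coding_offset
    acc = 0
    for s, e in gene.cds:
        if acc + (e - s) > fwd:
            gpos = s + (fwd - acc)
            base = override[1] if override and override[0] == gpos else chrom_seq[gpos]
            return base if gene.strand == "+" else str(Seq(base).complement())
        acc += e - s
    raise ValueError("coding offset out of range")


def _snp_cds_effect(gene: GeneModel, chrom_seq: str, v: Variant) -> str:
    off = _coding_offset(gene, v.pos)
    codon_idx = off // 3
    n_codons = gene.cds_length // 3
    base0 = codon_idx * 3
    ref_codon = "".join(_cds_base(gene, chrom_seq, base0 + i) for i in range(3))
    alt_codon = "".join(
        _cds_base(gene, chrom_seq, base0 + i, override=(v.pos, v.alt)) for i in range(3)
    )
    if codon_idx == 0:
        return "start_lost" if alt_codon != "ATG" else "synonymous"
    if codon_idx == n_codons - 1 and ref_codon in STOPS:
        return "synonymous" if alt_codon in STOPS else "stop_lost"
    if alt_codon in STOPS and ref_codon not in STOPS:
        return "stop_gained"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "nonsynonymous" if ref_aa != alt_aa else "synonymous"


def _classify_in_gene(gene: GeneModel, chrom_seq: str, v: Variant
                      ) -> tuple[str, str] | None:
    """(region, effect) of a variant within one gene, or None if outside."""
    s, e = _affected_interval(v)
    if not (s < gene.end and gene.start < e):
        return None
    for (ws, we), site in gene.splice_sites():
        if v.vtype == "ins":
            # an insertion disrupts the window only when it splits the dinucleotide
            if v.pos == ws:
                return site, "splice_disruption"
        elif s < we and ws < e:
            return site, "splice_disruption"
    if v.vtype == "snp":
        if _in_intervals(s, e, gene.cds):
            return "cds", _snp_cds_effect(gene, chrom_seq, v)
        if _in_intervals(s, e, gene.exons):
            return "utr_exon", "noncoding"
        return "intron", "noncoding"
    # indels
    in_cds = (
        _in_intervals(s, e, gene.cds) if v.vtype == "del"
        else any(xs <= v.pos and v.pos + 1 < xe for xs, xe in gene.cds)
    )
    if in_cds:
        effect = "frameshift" if v.indel_length % 3 else "inframe_indel"
        return "cds", effect
    in_exon = (
        _overlaps_intervals(s, e, gene.exons) if v.vtype == "del"
        else any(xs <= v.pos and v.pos + 1 < xe for xs, xe in gene.exons)
    )
    return ("utr_exon" if in_exon else "intron"), "noncoding"


def annotate_effects(
    variants: Sequence[Variant],
    annotation: Sequence[GeneModel],
    genome: Sequence[SequenceRecord],
) -> list[VariantEffect]:
    """Annotate region and functional effect per variant.

    Over all overlapping genes the most severe candidate effect is retained;
    variants outside every gene are intergenic/noncoding.
    """
    seqs = {r.id: r.seq for r in genome}
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: list[VariantEffect] = []
    for v in variants:
        if v.chrom not in seqs:
            raise ValueError(f"variant at {v.chrom}:{v.pos + 1} on unknown chromosome")
        s, e = _affected_interval(v)
        candidates: list[tuple[str, str, str]] = []
        for iv in trees.get(v.chrom, IntervalTree()).overlap(s, max(e, s + 1)):
            hit = _classify_in_gene(iv.data, seqs[v.chrom], v)
            if hit is not None:
                candidates.append((hit[0], hit[1], iv.data.gene_id))
        if not candidates:
            out.append(VariantEffect(v, REGION_INTERGENIC, "noncoding", None))
        else:
            region, effect, gid = min(candidates, key=lambda c: (_RANK[c[1]], c[2]))
            out.append(VariantEffect(v, region, effect, gid))
    return out


def ns_ratio(effects: Sequence[VariantEffect],
             gene_subset: set[str] | None = None) -> float | None:
    """Nonsynonymous/synonymous variant count ratio; None when undefined.

    This is a ratio of variant counts, not a per-site normalized dN/dS.
    """
    pool = [
        e for e in effects
        if gene_subset is None or (e.gene_id in gene_subset)
    ]
    ns = sum(1 for e in pool if e.effect == "nonsynonymous")
    syn = sum(1 for e in pool if e.effect == "synonymous")
    if syn == 0:
        return None
    return ns / syn


def effect_counts(effects: Sequence[VariantEffect]) -> dict[str, dict[str, int]]:
    """Per-region and per-effect tallies for the report."""
    by_region: dict[str, int] = {}
    by_effect: dict[str, int] = {}
    for e in effects:
        by_region[e.region] = by_region.get(e.region, 0) + 1
        by_effect[e.effect] = by_effect.get(e.effect, 0) + 1
    return {"region": by_region, "effect": by_effect}
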