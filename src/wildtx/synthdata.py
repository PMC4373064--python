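"""Seeded generator of a toy reference genome, a diverged "accession"
transcriptome with planted features, stranded counts, pileups and
machine-readable truth tables.

The generator emulates the statistical structure the pipeline assumes when
comparing a wild accession against a sequenced reference genotype:

* multi-exon GT-AG gene models with ATG-initiated, stop-terminated CDSs;
* accession transcripts diverged from the reference by planted SNPs and
  small indels, with identity kept >= 97%;
* "distinct" contigs absent from the genome (31-mer screened), with and
  without long ORFs;
* genuine antisense partners overlapping a gene by a configured geometry;
* strand-flip assembly artifacts (mirror contigs with sense read support
  below a tenth of antisense);
* truncated redundant copies for clustering;
* pileups carrying every planted variant at configured depth and allele
  frequency, plus decoy sites each violating exactly one calling rule
  (allele frequency exactly 0.70, or support exactly 3).

Everything derives from one seeded NumPy generator; outputs are
byte-identical for a fixed seed. Planted CDS variant effects are labelled
with the substitute-translate-diff oracle, not with the annotator under
test.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import effect_oracle
from .assembly_qc import StrandCount
from .io_formats import (
    GeneModel, PileupColumn, SequenceRecord, revcomp,
    write_fasta, write_gff3, write_go_map, write_pileup_tsv, write_strand_counts,
)
from .variant_annot import Variant

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS
)
SCREEN_K = 31
MIN_EXON = 120
EDIT_SPACING = 6
JUNCTION_MARGIN = 4


@dataclass
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 60_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (1, 4)
    snp_rate: float = 0.010
    indel_rate: float = 0.002
    n_distinct_coding: int = 12
    n_distinct_noncoding: int = 8
    n_antisense_pairs: int = 6
    n_artifact_contigs: int = 6
    n_redundant_copies: int = 10
    depth: int = 10
    decoy_fraction: float = 0.3
    # extensions needed to plant every mapping category and variant region
    n_multi_locus_genes: int = 2
    n_intergenic_contigs: int = 4
    n_small_overlap_contigs: int = 4
    n_splice_variants: int = 4
    n_intron_variants: int = 10
    n_intergenic_variants: int = 10
    polya_fraction: float = 0.3
    min_support: int = 4
    min_af: float = 0.70

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.chrom_len, self.n_genes, self.n_distinct_coding,
            self.n_distinct_noncoding, self.n_antisense_pairs,
            self.n_artifact_contigs, self.n_redundant_copies, self.depth,
            self.n_multi_locus_genes, self.n_intergenic_contigs,
            self.n_small_overlap_contigs,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for rate in (self.snp_rate, self.indel_rate, self.decoy_fraction):
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0, 1)")
        self.exons_per_gene = tuple(self.exons_per_gene)
        # expected divergence must respect the 97% identity floor
        if self.snp_rate + 4 * self.indel_rate > 0.03:
            raise ValueError(
                "snp_rate/indel_rate would push accession identity below 97%"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["exons_per_gene"] = list(self.exons_per_gene)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vtype: str
    region: str
    effect: str
    gene_id: str | None


@dataclass(frozen=True)
class DecoySite:
    chrom: str
    pos: int
    ref: str
    alt: str
    violated_rule: str  # "af" | "support"


@dataclass
class TruthTables:
    planted_variants: list[PlantedVariant]
    decoys: list[DecoySite]
    distinct_truth: dict[str, str]           # contig -> coding|noncoding
    antisense_truth: list[tuple[str, str, str, str]]  # a, b, geometry, pairing
    artifact_truth: set[str]
    cluster_truth: list[frozenset[str]]
    mapping_truth: dict[str, str]            # post-filter contig -> category
    enriched_term: str


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _longest_orf_scan(seq: str) -> int:
    """Independent longest-ORF scan (ATG..stop inclusive; to-end ORFs count
    through the last complete codon). Used only for truth labelling."""
    best = 0
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for idx, codon in enumerate(codons):
            if start is None and codon == "ATG":
                start = idx
            elif start is not None and codon in STOPS:
                best = max(best, 3 * (idx - start + 1))
                start = None
        if start is not None:
            best = max(best, 3 * (len(codons) - start))
    return best


@dataclass
class _GeneLayout:
    """Bookkeeping for one generated gene (transcription-order geometry)."""

    gene: GeneModel
    mrna_len: int
    utr5: int
    cds_len: int


def _build_gene(rng: np.random.Generator, config: SynthConfig, gene_id: str,
                chrom: str, strand: str, start: int
                ) -> tuple[_GeneLayout, str]:
    """Construct one gene; returns layout and the genomic region string."""
    utr5 = int(rng.integers(20, 80))
    n_codons = int(rng.integers(110, 240))
    cds = "ATG" + "".join(
        NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    ) + STOPS[int(rng.integers(0, 3))]
    utr3 = int(rng.integers(30, 120))
    mrna = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
    # clean ends so polyA trimming is exact and strand-safe
    if mrna[0] == "T":
        mrna = "C" + mrna[1:]
    if mrna[-1] == "A":
        mrna = mrna[:-1] + "C"
    L = len(mrna)

    lo, hi = config.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    n_exons = max(1, min(n_exons, L // MIN_EXON))
    # random composition with every exon >= MIN_EXON
    extra = L - n_exons * MIN_EXON
    cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1)) if n_exons > 1 else []
    sizes = []
    prev = 0
    for c in list(cuts) + [extra]:
        sizes.append(MIN_EXON + int(c) - prev)
        prev = int(c)

    pieces = []
    off = 0
    for sz in sizes:
        pieces.append(mrna[off:off + sz])
        off += sz
    introns = [
        "GT" + _rand_seq(rng, int(rng.integers(60, 200)) - 4) + "AG"
        for _ in range(n_exons - 1)
    ]
    region_parts = []
    for i, piece in enumerate(pieces):
        region_parts.append(piece)
        if i < len(introns):
            region_parts.append(introns[i])
    region = "".join(region_parts)

    # exon intervals in transcription-order region coordinates
    tx_exons = []
    off = 0
    for i, piece in enumerate(pieces):
        tx_exons.append((off, off + len(piece)))
        off += len(piece)
        if i < len(introns):
            off += len(introns[i])
    Lr = len(region)

    if strand == "+":
        exons = [(start + s, start + e) for s, e in tx_exons]
        region_out = region
    else:
        exons = sorted((start + Lr - e, start + Lr - s) for s, e in tx_exons)
        region_out = revcomp(region)

    # CDS mRNA range -> genomic intervals
    c0, c1 = utr5, utr5 + len(cds)
    cds_ivs = []
    m0 = 0
    for i, (ts, te) in enumerate(tx_exons):
        m1 = m0 + (te - ts)
        o0, o1 = max(m0, c0), min(m1, c1)
        if o1 > o0:
            rs, re = ts + (o0 - m0), ts + (o1 - m0)
            if strand == "+":
                cds_ivs.append((start + rs, start + re))
            else:
                cds_ivs.append((start + Lr - re, start + Lr - rs))
        m0 = m1
    cds_ivs.sort()

    gene = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        start=start, end=start + Lr, exons=exons, cds=cds_ivs,
    )
    return _GeneLayout(gene=gene, mrna_len=L, utr5=utr5, cds_len=len(cds)), region_out


@dataclass
class Reference:
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    layouts: dict[str, _GeneLayout]
    dup_gene_ids: list[str]
    dup_regions: list[tuple[str, int, int]]  # extra copies (chrom, start, end)


def generate_reference(config: SynthConfig) -> Reference:
    """Toy genome + annotation; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_seqs = {c: list(_rand_seq(rng, config.chrom_len)) for c in chrom_names}

    genes: list[GeneModel] = []
    layouts: dict[str, _GeneLayout] = {}
    ci, pos = 0, 600
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        while ci < len(chrom_names):
            chrom = chrom_names[ci]
            layout, region = _build_gene(rng, config, gene_id, chrom, strand, pos)
            if pos + len(region) + 600 <= config.chrom_len:
                chrom_seqs[chrom][pos:pos + len(region)] = list(region)
                genes.append(layout.gene)
                layouts[gene_id] = layout
                pos += len(region) + 500 + int(rng.integers(0, 300))
                placed = True
                break
            ci += 1
            pos = 600
        if not placed:
            raise ValueError(
                "infeasible packing: increase chrom_len or n_chroms, or reduce n_genes"
            )

    # duplicate whole gene regions into remaining space -> multi-locus genes
    dup_ids: list[str] = []
    dup_regions: list[tuple[str, int, int]] = []
    candidates = [g for g in genes]
    for di in range(config.n_multi_locus_genes):
        gene = candidates[int(rng.integers(0, len(candidates)))]
        while gene.gene_id in dup_ids:
            gene = candidates[int(rng.integers(0, len(candidates)))]
        L = gene.end - gene.start
        placed = False
        while ci < len(chrom_names):
            chrom = chrom_names[ci]
            if pos + L + 600 <= config.chrom_len:
                src = chrom_seqs[gene.chrom][gene.start:gene.end]
                chrom_seqs[chrom][pos:pos + L] = src
                dup_regions.append((chrom, pos, pos + L))
                dup_ids.append(gene.gene_id)
                pos += L + 500 + int(rng.integers(0, 300))
                placed = True
                break
            ci += 1
            pos = 600
        if not placed:
            raise ValueError("infeasible packing for duplicated loci; increase chrom_len")

    genome = [SequenceRecord(c, "".join(chrom_seqs[c])) for c in chrom_names]
    return Reference(genome=genome, genes=genes, layouts=layouts,
                     dup_gene_ids=dup_ids, dup_regions=dup_regions)


# ---------------------------------------------------------------------------
# accession transcriptome + pileups + truth
# ---------------------------------------------------------------------------

def _genome_kmers(genome: Sequence[SequenceRecord], k: int = SCREEN_K) -> set[str]:
    kmers: set[str] = set()
    for rec in genome:
        for s in (rec.seq, revcomp(rec.seq)):
            for i in range(len(s) - k + 1):
                kmers.add(s[i:i + k])
    return kmers


def _shares_kmer(seq: str, kmers: set[str], k: int = SCREEN_K) -> bool:
    return any(seq[i:i + k] in kmers for i in range(len(seq) - k + 1))


def _mutated_transcript(chrom_seq: str, gene: GeneModel,
                        edits: list[Variant]) -> str:
    """Splice the accession transcript carrying the planted genomic edits.

    Every edit lies strictly inside one exon with margin, so exon boundaries
    shift unambiguously.
    """
    deltas = []  # (position_from_which_coords_shift, delta)
    region = chrom_seq
    for v in sorted(edits, key=lambda v: -v.pos):
        if v.vtype == "snp":
            region = region[:v.pos] + v.alt + region[v.pos + 1:]
        elif v.vtype == "ins":
            region = region[:v.pos + 1] + v.alt[1:] + region[v.pos + 1:]
            deltas.append((v.pos + 1, len(v.alt) - 1))
        else:
            d = len(v.ref) - 1
            region = region[:v.pos + 1] + region[v.pos + 1 + d:]
            deltas.append((v.pos + 1, -d))

    def shift(x: int) -> int:
        return x + sum(d for p, d in deltas if x > p)

    parts = [region[shift(s):shift(e)] for s, e in gene.exons]
    tx = "".join(parts)
    return tx if gene.strand == "+" else revcomp(tx)


def _exonic_positions(gene: GeneModel) -> list[int]:
    """Genomic exon positions eligible for edits (junction margins applied)."""
    out = []
    for s, e in gene.exons:
        out.extend(range(s + JUNCTION_MARGIN, e - JUNCTION_MARGIN))
    return out


def _interval_containing(pos: int, ivs: Sequence[tuple[int, int]]) -> tuple[int, int] | None:
    for s, e in ivs:
        if s <= pos < e:
            return (s, e)
    return None


@dataclass
class Accession:
    transcripts: list[SequenceRecord]
    strand_counts: list[StrandCount]
    pileup: list[PileupColumn]
    go_map: dict[str, set[str]]
    go_background: list[str]
    truth: TruthTables


def generate_accession(config: SynthConfig, ref: Reference) -> Accession:
    rng = np.random.default_rng(config.seed + 1)
    genome = {r.id: r.seq for r in ref.genome}
    genes = {g.gene_id: g for g in ref.genes}
    gene_order = [g.gene_id for g in ref.genes]
    dup = set(ref.dup_gene_ids)

    # ---- role assignment (disjoint where interference matters) ----------
    pool = [gid for gid in gene_order if gid not in dup]
    multi_exon_pool = [gid for gid in pool if len(genes[gid].exons) > 1]
    if (len(pool) < config.n_antisense_pairs + config.n_small_overlap_contigs
            + config.n_artifact_contigs):
        raise ValueError("not enough genes for the requested planted features")
    nat_genes = pool[: config.n_antisense_pairs]
    rest = pool[config.n_antisense_pairs:]
    so_genes = rest[: config.n_small_overlap_contigs]
    rest = rest[config.n_small_overlap_contigs:]
    art_genes = rest[: config.n_artifact_contigs]
    redund_genes = rest[config.n_artifact_contigs:]
    if config.n_redundant_copies and not redund_genes:
        raise ValueError("not enough genes left for redundant copies")

    # ---- antisense partner windows (chosen before variant planting) -----
    geometries = ["contained", "tail_to_tail", "head_to_head"]
    nat_windows: dict[str, tuple[int, int, str]] = {}  # gene -> (w1, w2, geometry)
    for i, gid in enumerate(nat_genes):
        g = genes[gid]
        geom = geometries[i % 3]
        s, e = g.start, g.end
        if geom == "contained":
            xs, xe = max(g.exons, key=lambda iv: iv[1] - iv[0])
            w1 = xs + 5
            w2 = w1 + min(200, (xe - xs) - 10)
        elif geom == "tail_to_tail":
            if g.strand == "+":
                w1, w2 = e - 100, e + int(rng.integers(60, 160))
            else:
                w1, w2 = s - int(rng.integers(60, 160)), s + 100
        else:  # head_to_head
            if g.strand == "+":
                w1, w2 = s - int(rng.integers(60, 160)), s + 100
            else:
                w1, w2 = e - 100, e + int(rng.integers(60, 160))
        nat_windows[gid] = (w1, w2, geom)

    # ---- plant variants in accession transcripts -------------------------
    planted: list[PlantedVariant] = []
    edits_by_gene: dict[str, list[Variant]] = {gid: [] for gid in gene_order}
    used_positions: dict[str, set[int]] = {c: set() for c in genome}

    def reserve(chrom: str, pos: int, width: int = EDIT_SPACING) -> bool:
        cells = set(range(pos - width, pos + width + 1))
        if cells & used_positions[chrom]:
            return False
        used_positions[chrom].update(cells)
        return True

    for gid in gene_order:
        if gid in dup:
            continue
        g = genes[gid]
        chrom_seq = genome[g.chrom]
        L = sum(e - s for s, e in g.exons)
        budget = math.floor(0.03 * L)
        n_snp = int(rng.binomial(L, config.snp_rate))
        n_indel = int(rng.binomial(L, config.indel_rate))
        candidates = _exonic_positions(g)
        if gid in nat_windows:
            w1, w2, _ = nat_windows[gid]
            candidates = [p for p in candidates if not (w1 - 2 <= p < w2 + 2)]
        candidates = [candidates[j] for j in rng.permutation(len(candidates))]
        edit_cost = 0
        it = iter(candidates)
        placed_snp = placed_indel = 0
        for pos in it:
            if placed_indel < n_indel:
                dlen = int(rng.integers(1, 4))
                if edit_cost + 4 > budget:
                    break
                is_del = rng.random() < 0.5
                cds_iv = _interval_containing(pos, g.cds)
                exon_iv = _interval_containing(pos, g.exons)
                if is_del:
                    span = (pos + 1, pos + 1 + dlen)
                    home = cds_iv if (cds_iv and span[1] <= cds_iv[1]) else None
                    if home is None:
                        in_utr = (
                            exon_iv and span[1] <= exon_iv[1]
                            and not any(cs < span[1] and span[0] < ce for cs, ce in g.cds)
                            and not (cds_iv and pos + 1 > cds_iv[0])
                        )
                        if not in_utr:
                            continue
                    if not reserve(g.chrom, pos, EDIT_SPACING + dlen):
                        continue
                    ref_allele = chrom_seq[pos:pos + 1 + dlen]
                    v = Variant(g.chrom, pos, ref_allele, ref_allele[0], "del",
                                config.depth, config.depth)
                else:
                    in_cds = cds_iv is not None and cds_iv[0] + 1 <= pos <= cds_iv[1] - 3
                    in_utr = (
                        cds_iv is None and exon_iv is not None
                        and exon_iv[0] + 1 <= pos <= exon_iv[1] - 3
                        and _interval_containing(pos + 1, g.cds) is None
                    )
                    if not (in_cds or in_utr):
                        continue
                    if not reserve(g.chrom, pos, EDIT_SPACING + dlen):
                        continue
                    ins = _rand_seq(rng, dlen)
                    v = Variant(g.chrom, pos, chrom_seq[pos],
                                chrom_seq[pos] + ins, "ins",
                                config.depth, config.depth)
                placed_indel += 1
                edit_cost += 4
            elif placed_snp < n_snp:
                if edit_cost + 1 > budget:
                    break
                if not reserve(g.chrom, pos):
                    continue
                ref_b = chrom_seq[pos]
                alt_b = BASES[int(rng.integers(0, 4))]
                while alt_b == ref_b:
                    alt_b = BASES[int(rng.integers(0, 4))]
                v = Variant(g.chrom, pos, ref_b, alt_b, "snp",
                            config.depth, config.depth)
                placed_snp += 1
                edit_cost += 1
            else:
                break
            edits_by_gene[gid].append(v)
            in_cds = (
                _interval_containing(v.pos, g.cds) is not None if v.vtype != "del"
                else _interval_containing(v.pos + 1, g.cds) is not None
            )
            if in_cds:
                region = "cds"
                effect = effect_oracle.classify_cds_variant(chrom_seq, g, v)
            else:
                region, effect = "utr_exon", "noncoding"
            planted.append(PlantedVariant(
                v.chrom, v.pos, v.ref, v.alt, v.vtype, region, effect, gid,
            ))

    # ---- splice / intron / intergenic variants (pileup-only) -------------
    def random_alt(ref_b: str) -> str:
        alt_b = BASES[int(rng.integers(0, 4))]
        while alt_b == ref_b:
            alt_b = BASES[int(rng.integers(0, 4))]
        return alt_b

    splice_pool = [gid for gid in multi_exon_pool if gid not in dup]
    for i in range(config.n_splice_variants):
        gid = splice_pool[i % len(splice_pool)]
        g = genes[gid]
        sites = g.splice_sites()
        (ws, we), site = sites[i % len(sites)]
        pos = ws if i % 2 == 0 else we - 1
        if not reserve(g.chrom, pos):
            continue
        ref_b = genome[g.chrom][pos]
        planted.append(PlantedVariant(
            g.chrom, pos, ref_b, random_alt(ref_b), "snp", site,
            "splice_disruption", gid,
        ))

    intron_pool = [gid for gid in multi_exon_pool]
    for i in range(config.n_intron_variants):
        gid = intron_pool[i % len(intron_pool)]
        g = genes[gid]
        introns = g.introns()
        i1, i2 = introns[i % len(introns)]
        if i2 - i1 <= 8:
            continue
        pos = int(rng.integers(i1 + 3, i2 - 3))
        if not reserve(g.chrom, pos):
            continue
        ref_b = genome[g.chrom][pos]
        planted.append(PlantedVariant(
            g.chrom, pos, ref_b, random_alt(ref_b), "snp", "intron",
            "noncoding", gid,
        ))

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for g in ref.genes:
        occupied[g.chrom].append((g.start - 250, g.end + 250))
    for chrom, s, e in ref.dup_regions:
        occupied[chrom].append((s - 250, e + 250))

    def sample_intergenic(width: int) -> tuple[str, int]:
        for _ in range(200):
            chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
            pos = int(rng.integers(50, config.chrom_len - width - 50))
            if not any(s < pos + width and pos < e for s, e in occupied[chrom]):
                return chrom, pos
        raise ValueError("could not place an intergenic feature; genome too crowded")

    for _ in range(config.n_intergenic_variants):
        chrom, pos = sample_intergenic(1)
        if not reserve(chrom, pos):
            continue
        ref_b = genome[chrom][pos]
        planted.append(PlantedVariant(
            chrom, pos, ref_b, random_alt(ref_b), "snp", "intergenic",
            "noncoding", None,
        ))

    # ---- contigs ---------------------------------------------------------
    transcripts: list[SequenceRecord] = []
    mapping_truth: dict[str, str] = {}
    cluster_truth: list[set[str]] = []
    coding_label: dict[str, str] = {}

    base_tx: dict[str, str] = {}
    for gid in gene_order:
        g = genes[gid]
        region = genome[g.chrom]
        tx = _mutated_transcript(region, g, edits_by_gene[gid])
        base_tx[gid] = tx
        seq = tx
        if rng.random() < config.polya_fraction:
            seq = seq + "A" * int(rng.integers(12, 21))
        tid = f"tx_{gid}"
        transcripts.append(SequenceRecord(tid, seq))
        mapping_truth[tid] = "multiple" if gid in dup else "sense_gene"
        coding_label[tid] = "coding" if _longest_orf_scan(tx) > 300 else "noncoding"

    for gid in gene_order:
        cluster_truth.append({f"tx_{gid}"})

    # redundant truncated copies
    copy_counter: dict[str, int] = {}
    for i in range(config.n_redundant_copies):
        gid = redund_genes[i % len(redund_genes)]
        tx = base_tx[gid]
        L = len(tx)
        k = copy_counter.get(gid, 0) + 1
        copy_counter[gid] = k
        clen = int(rng.integers(max(150, L // 2), L - 20))
        seq = tx[:clen] if rng.random() < 0.5 else tx[L - clen:]
        tid = f"tx_{gid}_r{k}"
        transcripts.append(SequenceRecord(tid, seq))
        mapping_truth[tid] = "sense_gene"
        next(c for c in cluster_truth if f"tx_{gid}" in c).add(tid)

    # distinct contigs (31-mer screened against the genome)
    kmers = _genome_kmers(ref.genome)
    distinct_truth: dict[str, str] = {}

    def fresh_random(n: int) -> str:
        for _ in range(100):
            s = _rand_seq(rng, n)
            if not _shares_kmer(s, kmers):
                return s
        raise ValueError("could not generate a genome-free random sequence")

    for i in range(config.n_distinct_coding):
        for _ in range(100):
            n_codons = int(rng.integers(110, 200))
            orf = "ATG" + "".join(
                NONSTOP_CODONS[j]
                for j in rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
            ) + STOPS[int(rng.integers(0, 3))]
            pad = int(rng.integers(40, 260))
            left = int(rng.integers(0, pad + 1))
            seq = _rand_seq(rng, left) + orf + _rand_seq(rng, pad - left)
            if not _shares_kmer(seq, kmers):
                break
        else:
            raise ValueError("could not generate a genome-free coding contig")
        tid = f"dc_{i + 1:02d}"
        transcripts.append(SequenceRecord(tid, seq))
        mapping_truth[tid] = "unmapped"
        distinct_truth[tid] = "coding"
        coding_label[tid] = "coding"
        cluster_truth.append({tid})

    for i in range(config.n_distinct_noncoding):
        n = int(rng.integers(400, 800))
        seq = fresh_random(n)
        while _longest_orf_scan(seq) >= 150:
            seq = fresh_random(n)
        tid = f"dn_{i + 1:02d}"
        transcripts.append(SequenceRecord(tid, seq))
        mapping_truth[tid] = "unmapped"
        distinct_truth[tid] = "noncoding"
        coding_label[tid] = "noncoding"
        cluster_truth.append({tid})

    # antisense partners
    antisense_truth: list[tuple[str, str, str, str]] = []
    for gid, (w1, w2, geom) in nat_windows.items():
        g = genes[gid]
        window = genome[g.chrom][w1:w2]
        seq = revcomp(window) if g.strand == "+" else window
        tid = f"nat_{gid}"
        transcripts.append(SequenceRecord(tid, seq))
        in_gene = max(0, min(w2, g.end) - max(w1, g.start))
        frac = in_gene / (w2 - w1)
        if frac >= 0.90:
            mapping_truth[tid] = "antisense_gene"
        elif frac > 0:
            mapping_truth[tid] = "small_overlap"
        else:
            mapping_truth[tid] = "intergenic"
        coding_label[tid] = "coding" if _longest_orf_scan(seq) > 300 else "noncoding"
        cluster_truth.append({tid})
        a, b = f"tx_{gid}", tid
        pairing = "_".join(sorted([coding_label[a], coding_label[b]]))
        antisense_truth.append((a, b, geom, pairing))

    # intergenic and small-overlap windows
    for i in range(config.n_intergenic_contigs):
        width = int(rng.integers(300, 500))
        chrom, pos = sample_intergenic(width)
        occupied[chrom].append((pos - 100, pos + width + 100))
        tid = f"ig_{i + 1:02d}"
        transcripts.append(SequenceRecord(tid, genome[chrom][pos:pos + width]))
        mapping_truth[tid] = "intergenic"
        coding_label[tid] = (
            "coding" if _longest_orf_scan(genome[chrom][pos:pos + width]) > 300
            else "noncoding"
        )
        cluster_truth.append({tid})

    for i in range(config.n_small_overlap_contigs):
        gid = so_genes[i % len(so_genes)]
        g = genes[gid]
        w1, w2 = g.end - 80, g.end + 220
        tid = f"so_{gid}"
        # sense-strand fragment: an antisense window would be a genuine cis-NAT
        seq = genome[g.chrom][w1:w2]
        if g.strand == "-":
            seq = revcomp(seq)
        transcripts.append(SequenceRecord(tid, seq))
        mapping_truth[tid] = "small_overlap"
        coding_label[tid] = "coding" if _longest_orf_scan(seq) > 300 else "noncoding"
        cluster_truth.append({tid})

    # strand-flip artifacts (mirror contigs)
    artifact_truth: set[str] = set()
    tx_by_id = {t.id: t for t in transcripts}
    for i, gid in enumerate(art_genes[: config.n_artifact_contigs]):
        src = tx_by_id[f"tx_{gid}"]
        tid = f"art_{i + 1:02d}"
        transcripts.append(SequenceRecord(tid, revcomp(src.seq)))
        artifact_truth.add(tid)

    # ---- strand counts ---------------------------------------------------
    strand_counts: list[StrandCount] = []
    genuine = [t.id for t in transcripts if t.id not in artifact_truth]
    for j, tid in enumerate(genuine):
        if j == 0:
            strand_counts.append(StrandCount(tid, 5, 50))  # boundary: kept
        else:
            strand_counts.append(StrandCount(
                tid, int(rng.integers(50, 200)), int(rng.integers(0, 6))
            ))
    for tid in sorted(artifact_truth):
        anti = int(rng.integers(60, 150))
        sense = int(rng.integers(0, (anti - 1) // 10 + 1))
        strand_counts.append(StrandCount(tid, sense, anti))

    # ---- pileup columns --------------------------------------------------
    columns: list[PileupColumn] = []
    for pv in planted:
        depth = config.depth
        lower = max(config.min_support, math.floor(config.min_af * depth) + 1)
        support = int(rng.integers(lower, depth + 1))
        if pv.vtype == "snp":
            alt_token = pv.alt
            ref_field = pv.ref
        elif pv.vtype == "ins":
            alt_token = "+" + pv.alt[1:]
            ref_field = pv.ref
        else:
            alt_token = f"-{len(pv.ref) - 1}"
            ref_field = pv.ref
        obs = []
        for k in range(depth):
            rid = f"{pv.chrom}_{pv.pos}_{k}"
            obs.append((rid, alt_token if k < support else ref_field[0]))
        columns.append(PileupColumn(pv.chrom, pv.pos, ref_field, obs))

    decoys: list[DecoySite] = []
    n_decoys = round(config.decoy_fraction * len(planted))
    exonic_all: list[tuple[str, int]] = []
    for gid in gene_order:
        g = genes[gid]
        exonic_all.extend((g.chrom, p) for p in _exonic_positions(g))
    exonic_all = [exonic_all[j] for j in rng.permutation(len(exonic_all))]
    it = iter(exonic_all)
    for j in range(n_decoys):
        for chrom, pos in it:
            if reserve(chrom, pos):
                break
        else:
            raise ValueError("not enough exonic space for decoys")
        ref_b = genome[chrom][pos]
        alt_b = random_alt(ref_b)
        if j % 2 == 0:  # allele frequency exactly at the 0.70 boundary
            depth, support, rule = 10, 7, "af"
        else:           # support exactly at the 4-read boundary
            depth, support, rule = 4, 3, "support"
        obs = [
            (f"{chrom}_{pos}_{k}", alt_b if k < support else ref_b)
            for k in range(depth)
        ]
        columns.append(PileupColumn(chrom, pos, ref_b, obs))
        decoys.append(DecoySite(chrom, pos, ref_b, alt_b, rule))

    columns.sort(key=lambda c: (c.chrom, c.pos))

    # ---- GO annotation map ----------------------------------------------
    enriched_term = "GO:0000001"
    background = sorted(
        t.id for t in transcripts
        if t.id not in artifact_truth and not t.id.split("_")[-1].startswith("r")
    )
    go_map: dict[str, set[str]] = {eid: set() for eid in background}
    dc_ids = sorted(distinct_truth)
    dc_coding = [i for i in dc_ids if distinct_truth[i] == "coding"]
    for j, eid in enumerate(dc_coding):
        if j < max(1, round(0.75 * len(dc_coding))):
            go_map[eid].add(enriched_term)
    for eid in background:
        if eid not in dc_coding and rng.random() < 0.05:
            go_map[eid].add(enriched_term)
        for t in range(2, 10):
            if rng.random() < 0.15:
                go_map[eid].add(f"GO:{t:07d}")
    go_map = {k: v for k, v in go_map.items() if v}

    truth = TruthTables(
        planted_variants=planted,
        decoys=decoys,
        distinct_truth=distinct_truth,
        antisense_truth=antisense_truth,
        artifact_truth=artifact_truth,
        cluster_truth=[frozenset(c) for c in cluster_truth],
        mapping_truth=mapping_truth,
        enriched_term=enriched_term,
    )
    return Accession(
        transcripts=transcripts,
        strand_counts=strand_counts,
        pileup=columns,
        go_map=go_map,
        go_background=background,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# focused harnesses: clustering set and random CDS variants
# ---------------------------------------------------------------------------

def generate_clustering_set(
    seed: int,
    n_sources: int = 40,
    n_copies: int = 120,
    n_singletons: int = 40,
    snp_rate: float = 0.01,
) -> list[SequenceRecord]:
    """Contigs for redundancy-clustering checks: random source sequences,
    mutated/truncated copies of them (>= 100 bp overlap at >= 97% identity,
    forming transitive chains), and unrelated singletons.

    Cluster membership is *not* returned: the ground truth for these sets is
    the brute-force single-linkage oracle.
    """
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    sources: list[str] = []
    for i in range(n_sources):
        seq = _rand_seq(rng, int(rng.integers(220, 420)))
        sources.append(seq)
        out.append(SequenceRecord(f"src_{i:03d}", seq))
    for j in range(n_copies):
        i = int(rng.integers(0, n_sources))
        seq = sources[i]
        # truncate from one end, keep >= 130 bp
        keep = int(rng.integers(130, len(seq) + 1))
        seq = seq[:keep] if rng.random() < 0.5 else seq[-keep:]
        # sprinkle substitutions below the 3% divergence budget
        n_mut = min(int(rng.binomial(len(seq), snp_rate)), len(seq) // 40)
        chars = list(seq)
        for p in rng.choice(len(seq), size=n_mut, replace=False):
            alt = BASES[int(rng.integers(0, 4))]
            while alt == chars[p]:
                alt = BASES[int(rng.integers(0, 4))]
            chars[int(p)] = alt
        out.append(SequenceRecord(f"cpy_{j:03d}", "".join(chars)))
    for s in range(n_singletons):
        out.append(SequenceRecord(f"sgl_{s:03d}", _rand_seq(rng, int(rng.integers(150, 320)))))
    return out


def sample_cds_variants(ref: Reference, n: int, seed: int) -> list[Variant]:
    """Random CDS SNPs and small indels across both strands, plus targeted
    start/stop-codon hits, for effect-annotation checks.

    Deletions lie wholly inside one CDS interval; insertion anchors are
    interior to one. Effects are NOT attached: label via the oracle.
    """
    rng = np.random.default_rng(seed)
    genome = {r.id: r.seq for r in ref.genome}
    variants: list[Variant] = []

    def snp_at(gene: GeneModel, pos: int) -> Variant:
        ref_b = genome[gene.chrom][pos]
        alt_b = BASES[int(rng.integers(0, 4))]
        while alt_b == ref_b:
            alt_b = BASES[int(rng.integers(0, 4))]
        return Variant(gene.chrom, pos, ref_b, alt_b, "snp", 10, 10)

    genes = list(ref.genes)
    # targeted: every gene's start codon and stop codon gets one hit each
    for g in genes:
        cds_pos: list[int] = []
        for s, e in g.cds:
            cds_pos.extend(range(s, e))
        if g.strand == "-":
            cds_pos.reverse()
        variants.append(snp_at(g, cds_pos[int(rng.integers(0, 3))]))
        variants.append(snp_at(g, cds_pos[-3 + int(rng.integers(0, 3))]))
    while len(variants) < n:
        g = genes[int(rng.integers(0, len(genes)))]
        iv = g.cds[int(rng.integers(0, len(g.cds)))]
        kind = rng.random()
        if kind < 0.6:
            variants.append(snp_at(g, int(rng.integers(iv[0], iv[1]))))
        elif kind < 0.8:
            dlen = int(rng.integers(1, 4))
            if iv[1] - iv[0] < dlen + 4:
                continue
            pos = int(rng.integers(iv[0], iv[1] - dlen - 1))
            ref_a = genome[g.chrom][pos:pos + 1 + dlen]
            variants.append(Variant(g.chrom, pos, ref_a, ref_a[0], "del", 10, 10))
        else:
            ilen = int(rng.integers(1, 4))
            if iv[1] - iv[0] < 6:
                continue
            pos = int(rng.integers(iv[0] + 1, iv[1] - 3))
            ref_b = genome[g.chrom][pos]
            variants.append(Variant(g.chrom, pos, ref_b, ref_b + _rand_seq(rng, ilen),
                                    "ins", 10, 10))
    return variants[:max(n, len(variants))]


# ---------------------------------------------------------------------------
# planted enrichment case (for the over-representation test)
# ---------------------------------------------------------------------------

def generate_enrichment_case(
    seed: int,
    n_study: int = 50,
    n_background: int = 1000,
    study_freq: float = 0.40,
    background_freq: float = 0.05,
    term: str = "GO:0000001",
) -> tuple[set[str], set[str], dict[str, set[str]]]:
    """Study/background/term-map with one term planted at ``study_freq`` in
    the study set and ``background_freq`` elsewhere."""
    rng = np.random.default_rng(seed)
    background = {f"e{i:04d}" for i in range(n_background)}
    study = set(sorted(background)[:n_study])
    term_map: dict[str, set[str]] = {}
    for eid in sorted(background):
        p = study_freq if eid in study else background_freq
        if rng.random() < p:
            term_map.setdefault(eid, set()).add(term)
        for t in range(2, 8):
            if rng.random() < 0.10:
                term_map.setdefault(eid, set()).add(f"GO:{t:07d}")
    return study, background, term_map


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_outputs(ref: Reference, acc: Accession, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "transcripts": outdir / "transcripts.fasta",
        "strand_counts": outdir / "strand_counts.tsv",
        "pileup": outdir / "pileup.tsv",
        "go_map": outdir / "go_map.tsv",
        "go_background": outdir / "go_background.txt",
    }
    write_fasta(ref.genome, paths["genome"])
    write_gff3(ref.genes, paths["annotation"])
    write_fasta(acc.transcripts, paths["transcripts"])
    write_strand_counts(acc.strand_counts, paths["strand_counts"])
    write_pileup_tsv(acc.pileup, paths["pileup"])
    write_go_map(acc.go_map, paths["go_map"])
    paths["go_background"].write_text("".join(f"{e}\n" for e in acc.go_background))

    t = acc.truth
    p = outdir / "truth_variants.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvtype\tregion\teffect\tgene_id\n")
        for v in sorted(t.planted_variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.vtype}\t"
                     f"{v.region}\t{v.effect}\t{v.gene_id or '.'}\n")
    paths["truth_variants"] = p
    p = outdir / "truth_decoys.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tviolated_rule\n")
        for d in sorted(t.decoys, key=lambda d: (d.chrom, d.pos)):
            fh.write(f"{d.chrom}\t{d.pos + 1}\t{d.ref}\t{d.alt}\t{d.violated_rule}\n")
    paths["truth_decoys"] = p
    p = outdir / "truth_distinct.tsv"
    with open(p, "w") as fh:
        fh.write("contig_id\tcoding_label\n")
        for cid in sorted(t.distinct_truth):
            fh.write(f"{cid}\t{t.distinct_truth[cid]}\n")
    paths["truth_distinct"] = p
    p = outdir / "truth_antisense.tsv"
    with open(p, "w") as fh:
        fh.write("contig_a\tcontig_b\tgeometry\tpairing\n")
        for a, b, geom, pairing in sorted(t.antisense_truth):
            fh.write(f"{a}\t{b}\t{geom}\t{pairing}\n")
    paths["truth_antisense"] = p
    p = outdir / "truth_artifacts.tsv"
    p.write_text("".join(f"{c}\n" for c in sorted(t.artifact_truth)))
    paths["truth_artifacts"] = p
    p = outdir / "truth_clusters.tsv"
    with open(p, "w") as fh:
        fh.write("cluster_index\tmember_id\n")
        for i, cluster in enumerate(sorted(t.cluster_truth, key=lambda c: sorted(c)[0])):
            for m in sorted(cluster):
                fh.write(f"{i}\t{m}\n")
    paths["truth_clusters"] = p
    p = outdir / "truth_mapping.tsv"
    with open(p, "w") as fh:
        fh.write("contig_id\tcategory\n")
        for cid in sorted(t.mapping_truth):
            fh.write(f"{cid}\t{t.mapping_truth[cid]}\n")
    paths["truth_mapping"] = p
    (outdir / "truth_meta.tsv").write_text(f"enriched_term\t{t.enriched_term}\n")
    paths["truth_meta"] = outdir / "truth_meta.tsv"
    return paths


def generate(config: SynthConfig) -> tuple[Reference, Accession]:
    ref = generate_reference(config)
    return ref, generate_accession(config, ref)
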