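"""Brute-force effect oracle: apply the variant to the genome, re-extract the
whole CDS through coordinate-shifted gene intervals, translate both alleles
and classify from the protein diff.

This path shares no codon arithmetic with the per-codon annotator in
variant_annot; the synthetic-data generator uses it to label planted CDS
variants, and the test suite uses it for oracle-equivalence checks.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .io_formats import GeneModel
from .variant_annot import Variant

STOPS = {"TAA", "TAG", "TGA"}


def _apply_variant(chrom_seq: str, v: Variant) -> tuple[str, int, int]:
    """Mutated chromosome plus (shift_from, delta) for coordinate mapping."""
    if v.vtype == "snp":
        assert chrom_seq[v.pos] == v.ref
        return chrom_seq[: v.pos] + v.alt + chrom_seq[v.pos + 1:], v.pos + 1, 0
    if v.vtype == "ins":
        ins = v.alt[1:]
        return chrom_seq[: v.pos + 1] + ins + chrom_seq[v.pos + 1:], v.pos + 1, len(ins)
    dlen = len(v.ref) - 1
    return (
        chrom_seq[: v.pos + 1] + chrom_seq[v.pos + 1 + dlen:],
        v.pos + 1 + dlen,
        -dlen,
    )


def _shift(x: int, shift_from: int, delta: int) -> int:
    if delta < 0 and shift_from + delta < x < shift_from:
        return shift_from + delta  # coordinate inside the deleted span
    if x < shift_from:
        return x
    return x + delta


def _extract_cds(chrom_seq: str, gene: GeneModel,
                 shift_from: int = 0, delta: int = 0) -> str:
    parts = []
    for s, e in gene.cds:
        s2, e2 = _shift(s, shift_from, delta), _shift(e, shift_from, delta)
        parts.append(chrom_seq[s2:e2])
    cds = "".join(parts)
    return cds if gene.strand == "+" else str(Seq(cds).reverse_complement())


def classify_cds_variant(chrom_seq: str, gene: GeneModel, v: Variant) -> str:
    """Effect class of a variant lying wholly inside the CDS of ``gene``.

    SNP classes: start_lost, stop_lost, stop_gained, nonsynonymous,
    synonymous. Indels: frameshift when the length is not a multiple of 3,
    inframe_indel otherwise.
    """
    ref_cds = _extract_cds(chrom_seq, gene)
    mut_chrom, shift_from, delta = _apply_variant(chrom_seq, v)
    mut_cds = _extract_cds(mut_chrom, gene, shift_from, delta)

    if v.vtype != "snp":
        assert len(mut_cds) == len(ref_cds) + delta
        return "frameshift" if len(mut_cds) % 3 else "inframe_indel"
    assert len(ref_cds) == len(mut_cds)

    if mut_cds[:3] != "ATG":
        return "start_lost"
    ref_last, mut_last = ref_cds[-3:], mut_cds[-3:]
    if ref_last in STOPS and mut_last not in STOPS:
        return "stop_lost"
    ref_prot = str(Seq(ref_cds).translate())
    mut_prot = str(Seq(mut_cds).translate())
    # a premature stop appearing where the reference had none
    ref_internal_stop = "*" in ref_prot[:-1]
    mut_internal_stop = "*" in mut_prot[:-1]
    if mut_internal_stop and not ref_internal_stop:
        return "stop_gained"
    return "nonsynonymous" if ref_prot != mut_prot else "synonymous"
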