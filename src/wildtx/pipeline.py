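"""End-to-end orchestration: qc -> map -> distinct -> variants -> cisnat -> enrich.

Every stage reads and writes plain files, so any stage can be re-run alone
from the previous stage's outputs. In synth-mode the generator's truth
tables are compared against every stage's calls and the report carries a
truth-comparison section with a discrepancy list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assembly_qc, cisnat, distinct_genes, enrichment, genome_map, synthdata, variant_annot
from .io_formats import (
    read_fasta, read_go_map, read_gff3, read_pileup_tsv, read_strand_counts,
    write_alignment_tsv, write_fasta, write_vcf,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, at their standard defaults."""

    min_identity: float = 0.97
    overlap_threshold: float = 0.90
    min_coverage: float = 0.90
    cluster_min_overlap: int = 100
    strand_ratio: float = 0.1
    min_support: int = 4
    min_af: float = 0.70
    cisnat_min_overlap: int = 50
    orf_ref_len: int = 300
    alpha: float = 0.05
    polya_min_run: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_identity", 0.5, 1.0), ("overlap_threshold", 0.0, 1.0),
            ("min_coverage", 0.0, 1.0), ("strand_ratio", 0.0, 1.0),
            ("min_af", 0.0, 1.0), ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_support < 1 or self.cluster_min_overlap < 1 or self.cisnat_min_overlap < 0:
            raise ValueError("count thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        synth = data.pop("synth", None)
        cfg = cls(**data)
        cfg._synth = synth  # type: ignore[attr-defined]
        return cfg


@dataclass
class Report:
    assembly_stats: dict
    stage_counts: dict
    mapping_counts: dict
    effect_counts: dict
    cisnat_counts: dict
    ns_ratio: float | None
    enriched_terms: list[str]
    truth_comparison: dict | None = None
    discrepancies: list[str] = field(default_factory=list)

    @property
    def zero_discrepancies(self) -> bool:
        return self.truth_comparison is not None and not self.discrepancies

    def render(self) -> str:
        lines = ["# wildtx pipeline report", "", "## Assembly"]
        for k, v in self.assembly_stats.items():
            lines.append(f"{k}\t{v}")
        lines += ["", "## Stage counts"]
        for k, v in self.stage_counts.items():
            lines.append(f"{k}\t{v}")
        lines += ["", "## Mapping categories"]
        for k in genome_map.CATEGORIES:
            lines.append(f"{k}\t{self.mapping_counts.get(k, 0)}")
        lines += ["", "## Variant effects"]
        for k, v in sorted(self.effect_counts.get("region", {}).items()):
            lines.append(f"region:{k}\t{v}")
        for k, v in sorted(self.effect_counts.get("effect", {}).items()):
            lines.append(f"effect:{k}\t{v}")
        lines.append(f"ns_ratio\t{'undefined' if self.ns_ratio is None else f'{self.ns_ratio:.3f}'}")
        lines += ["", "## cis-NAT pairs"]
        for k, v in sorted(self.cisnat_counts.items()):
            lines.append(f"{k}\t{v}")
        lines += ["", "## Enriched terms (corrected P <= alpha)"]
        for t in self.enriched_terms:
            lines.append(t)
        if self.truth_comparison is not None:
            lines += ["", "## Truth comparison"]
            for k, v in self.truth_comparison.items():
                lines.append(f"{k}\t{v}")
            lines.append(f"discrepancies\t{len(self.discrepancies)}")
            for d in self.discrepancies:
                lines.append(f"DISCREPANCY\t{d}")
        return "\n".join(lines) + "\n"


def run_pipeline(
    config: PipelineConfig,
    inputs: dict[str, Path] | None,
    outdir: str | Path,
    synth: synthdata.SynthConfig | None = None,
) -> Report:
    """Run every stage; either on real input files or in synth-mode.

    ``inputs`` maps names (transcripts, genome, annotation, strand_counts,
    pileup, go_map, optionally go_background) to paths. In synth-mode the
    generator's outputs are written under ``outdir``/synth and used as the
    inputs, and the report gains a truth-comparison section.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    go_background = None
    if synth is not None:
        ref, acc = synthdata.generate(synth)
        inputs = synthdata.write_outputs(ref, acc, outdir / "synth")
        truth = acc.truth
        go_background = acc.go_background
    if inputs is None:
        raise PipelineError("qc", "no inputs and no synth config given")

    def need(stage: str, key: str) -> Path:
        p = inputs.get(key)
        if p is None or not Path(p).exists():
            raise PipelineError(stage, f"missing input {key!r}")
        return Path(p)

    # ---- qc ---------------------------------------------------------------
    contigs = read_fasta(need("qc", "transcripts"))
    stats = assembly_qc.compute_assembly_stats(contigs)
    counts = read_strand_counts(need("qc", "strand_counts"))
    kept_ids, discarded_ids = assembly_qc.filter_strand_artifacts(
        counts, contig_ids=[c.id for c in contigs], ratio=config.strand_ratio
    )
    kept_set = set(kept_ids)
    clean = []
    for c in contigs:
        if c.id not in kept_set:
            continue
        t = assembly_qc.trim_polya(c, min_run=config.polya_min_run)
        if t is not None:
            clean.append(t)
    write_fasta(clean, outdir / "contigs_clean.fasta")
    stage_counts = {
        "contigs_in": len(contigs),
        "strand_artifacts_discarded": len(discarded_ids),
        "contigs_clean": len(clean),
    }

    # ---- map ---------------------------------------------------------------
    genome = read_fasta(need("map", "genome"))
    annotation = read_gff3(need("map", "annotation"), genome)
    alignments = genome_map.align_transcripts(
        clean, genome, min_identity=config.min_identity, min_coverage=config.min_coverage
    )
    classes = genome_map.classify_transcripts(
        alignments, annotation,
        overlap_threshold=config.overlap_threshold,
        contig_ids=[c.id for c in clean],
        chrom_names={r.id for r in genome},
    )
    write_alignment_tsv(alignments, outdir / "alignments.tsv")
    genome_map.write_classification_tsv(classes, outdir / "mapping_classes.tsv")
    class_of = {m.contig_id: m.category for m in classes}
    mapping_counts: dict[str, int] = {}
    for m in classes:
        mapping_counts[m.category] = mapping_counts.get(m.category, 0) + 1
    stage_counts["alignments"] = len(alignments)

    # ---- distinct ----------------------------------------------------------
    clusters = distinct_genes.cluster_transcripts(
        clean, min_identity=config.min_identity, min_overlap=config.cluster_min_overlap
    )
    by_id = {c.id: c for c in clean}
    coding_sets = distinct_genes.identify_distinct(
        clusters, class_of, by_id, orf_ref_len=config.orf_ref_len
    )
    distinct_coding, distinct_noncoding = coding_sets
    labels = {
        c.id: distinct_genes.score_coding_potential(c, orf_ref_len=config.orf_ref_len).label
        for c in clean
    }
    distinct_genes.write_cluster_tsv(clusters, outdir / "clusters.tsv")
    write_fasta([by_id[i] for i in sorted(distinct_coding)], outdir / "distinct_coding.fasta") \
        if distinct_coding else None
    if distinct_noncoding:
        write_fasta([by_id[i] for i in sorted(distinct_noncoding)],
                    outdir / "distinct_noncoding.fasta")
    stage_counts["clusters"] = len(clusters)
    stage_counts["distinct_coding"] = len(distinct_coding)
    stage_counts["distinct_noncoding"] = len(distinct_noncoding)

    # ---- variants ----------------------------------------------------------
    pileup = read_pileup_tsv(need("variants", "pileup"))
    variants = variant_annot.call_variants(
        pileup, min_support=config.min_support, min_af=config.min_af
    )
    effects = variant_annot.annotate_effects(variants, annotation, genome)
    write_vcf(effects, outdir / "variants.vcf")
    eff_counts = variant_annot.effect_counts(effects)
    nsr = variant_annot.ns_ratio(effects)
    stage_counts["variants_called"] = len(variants)

    # ---- cisnat ------------------------------------------------------------
    candidates = cisnat.find_antisense_overlaps(
        clean, min_overlap=config.cisnat_min_overlap, min_identity=config.min_identity
    )
    pairs = cisnat.confirm_and_classify(candidates, alignments, labels)
    cisnat.write_cisnat_tsv(pairs, outdir / "cisnat_pairs.tsv")
    cisnat_counts: dict[str, int] = {g: 0 for g in cisnat.GEOMETRIES}
    for p in pairs:
        cisnat_counts[p.geometry] += 1
    cisnat_counts["total"] = len(pairs)
    stage_counts["cisnat_pairs"] = len(pairs)

    # ---- enrich ------------------------------------------------------------
    term_map = read_go_map(need("enrich", "go_map"))
    if go_background is None:
        bg_path = inputs.get("go_background")
        if bg_path and Path(bg_path).exists():
            go_background = [l.strip() for l in open(bg_path) if l.strip()]
        else:
            go_background = sorted(c.representative for c in clusters)
    enriched_terms: list[str] = []
    results = []
    if distinct_coding:
        background = set(go_background) | set(distinct_coding)
        term_map = {k: v for k, v in term_map.items() if k in background}
        results = enrichment.test_enrichment(
            distinct_coding, background, term_map, alpha=config.alpha
        )
        enrichment.write_enrichment_tsv(results, outdir / "enrichment.tsv")
        enriched_terms = [r.term_id for r in results if r.enriched]
    stage_counts["enriched_terms"] = len(enriched_terms)

    report = Report(
        assembly_stats={
            "n_contigs": stats.n_contigs,
            "total_bases": stats.total_bases,
            "n50": stats.n50,
            "mean_length": round(stats.mean_length),
            "gc_percent": round(stats.gc_percent, 2),
        },
        stage_counts=stage_counts,
        mapping_counts=mapping_counts,
        effect_counts=eff_counts,
        cisnat_counts=cisnat_counts,
        ns_ratio=nsr,
        enriched_terms=enriched_terms,
    )

    if truth is not None:
        _compare_truth(
            report, truth,
            discarded_ids=discarded_ids, classes=classes, clusters=clusters,
            distinct_coding=distinct_coding, distinct_noncoding=distinct_noncoding,
            variants=variants, effects=effects, pairs=pairs,
            enriched_terms=enriched_terms,
        )

    (outdir / "report.txt").write_text(report.render())
    return report


def _compare_truth(report, truth, *, discarded_ids, classes, clusters,
                   distinct_coding, distinct_noncoding, variants, effects,
                   pairs, enriched_terms) -> None:
    cmp: dict[str, str] = {}
    disc = report.discrepancies

    if set(discarded_ids) == truth.artifact_truth:
        cmp["strand_filter"] = "exact"
    else:
        cmp["strand_filter"] = "MISMATCH"
        disc.append(
            f"strand filter discarded {sorted(set(discarded_ids))} "
            f"vs truth {sorted(truth.artifact_truth)}"
        )

    class_of = {m.contig_id: m.category for m in classes}
    wrong = {
        cid: (class_of.get(cid), cat)
        for cid, cat in truth.mapping_truth.items()
        if class_of.get(cid) != cat
    }
    cmp["mapping"] = "exact" if not wrong else "MISMATCH"
    for cid, (got, want) in sorted(wrong.items()):
        disc.append(f"mapping {cid}: got {got}, expected {want}")

    got_clusters = {frozenset(c.member_ids) for c in clusters}
    want_clusters = set(truth.cluster_truth)
    cmp["clustering"] = "exact" if got_clusters == want_clusters else "MISMATCH"
    if got_clusters != want_clusters:
        disc.append(
            f"clustering differs: {len(got_clusters - want_clusters)} unexpected, "
            f"{len(want_clusters - got_clusters)} missing clusters"
        )

    want_coding = {c for c, l in truth.distinct_truth.items() if l == "coding"}
    want_nc = {c for c, l in truth.distinct_truth.items() if l == "noncoding"}
    cmp["distinct"] = (
        "exact" if (distinct_coding == want_coding and distinct_noncoding == want_nc)
        else "MISMATCH"
    )
    if cmp["distinct"] == "MISMATCH":
        disc.append(
            f"distinct sets differ: coding {sorted(distinct_coding ^ want_coding)}, "
            f"noncoding {sorted(distinct_noncoding ^ want_nc)}"
        )

    called = {v.key(): v for v in variants}
    planted = {(p.chrom, p.pos, p.ref, p.alt): p for p in truth.planted_variants}
    tp = set(called) & set(planted)
    precision = len(tp) / len(called) if called else 0.0
    recall = len(tp) / len(planted) if planted else 0.0
    cmp["variant_precision"] = f"{precision:.4f}"
    cmp["variant_recall"] = f"{recall:.4f}"
    if precision != 1.0 or recall != 1.0:
        disc.append(
            f"variant calls: {len(called) - len(tp)} false positives, "
            f"{len(planted) - len(tp)} missed"
        )
    decoy_keys = {(d.chrom, d.pos) for d in truth.decoys}
    leaked = [k for k in called if (k[0], k[1]) in decoy_keys]
    if leaked:
        disc.append(f"{len(leaked)} decoy sites called")
    eff_of = {(e.variant.chrom, e.variant.pos, e.variant.ref, e.variant.alt): e
              for e in effects}
    eff_wrong = [
        key for key in tp
        if (eff_of[key].region, eff_of[key].effect)
        != (planted[key].region, planted[key].effect)
    ]
    cmp["effect_agreement"] = f"{1 - len(eff_wrong) / len(tp):.4f}" if tp else "n/a"
    for key in sorted(eff_wrong):
        p = planted[key]
        e = eff_of[key]
        disc.append(
            f"effect at {key[0]}:{key[1] + 1}: got {e.region}|{e.effect}, "
            f"expected {p.region}|{p.effect}"
        )

    got_pairs = {(p.contig_a, p.contig_b, p.geometry, p.pairing) for p in pairs}
    want_pairs = {(min(a, b), max(a, b), g, pr) for a, b, g, pr in truth.antisense_truth}
    cmp["cisnat"] = "exact" if got_pairs == want_pairs else "MISMATCH"
    if got_pairs != want_pairs:
        disc.append(
            f"cis-NAT pairs differ: unexpected {sorted(got_pairs - want_pairs)}, "
            f"missing {sorted(want_pairs - got_pairs)}"
        )

    if truth.enriched_term in enriched_terms:
        cmp["enrichment"] = "planted term flagged"
    else:
        cmp["enrichment"] = "MISMATCH"
        disc.append(f"planted term {truth.enriched_term} not flagged as enriched")

    report.truth_comparison = cmp
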