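"""Term over-representation testing for a study set against a background.

The test is the upper-tail hypergeometric probability P(X >= k) of drawing k
term-annotated elements in a study of size n from a background of size N
containing K annotated elements, with Bonferroni correction over the number
of tested terms (terms with at least one study hit). Annotation maps are
expected pre-propagated to ancestor terms by the caller; the module is
ontology-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hits: int        # k
    study_size: int        # n
    background_hits: int   # K
    background_size: int   # N
    p_value: float
    corrected_p: float
    enriched: bool


def test_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term with k >= 1.

    ``correction`` is ``bonferroni`` (default) or ``fdr_bh``
    (Benjamini-Hochberg). Results are sorted by (corrected_p, term_id);
    those with corrected_p <= alpha are flagged enriched.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set is not a subset of the background")
    unknown = set(term_map) - background
    if unknown:
        raise ValueError(
            f"term map annotates ids outside the background, e.g. {sorted(unknown)[0]!r}"
        )

    term_background: dict[str, set[str]] = {}
    for eid, terms in term_map.items():
        for t in terms:
            term_background.setdefault(t, set()).add(eid)

    N, n = len(background), len(study)
    tested: list[tuple[str, int, int, float]] = []
    for term in sorted(term_background):
        members = term_background[term]
        k = len(members & study)
        if k < 1:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, K, min(p, 1.0)))

    m = len(tested)
    results: list[EnrichmentResult] = []
    if correction == "bonferroni":
        corrected = [min(1.0, p * m) for *_, p in tested]
    elif correction == "fdr_bh":
        order = sorted(range(m), key=lambda i: tested[i][3])
        corrected = [1.0] * m
        prev = 1.0
        for rank_from_end, i in enumerate(reversed(order)):
            rank = m - rank_from_end
            q = min(prev, tested[i][3] * m / rank)
            corrected[i] = min(1.0, q)
            prev = q
    else:
        raise ValueError(f"unknown correction {correction!r}")

    for (term, k, K, p), cp in zip(tested, corrected):
        results.append(
            EnrichmentResult(
                term_id=term, study_hits=k, study_size=n,
                background_hits=K, background_size=N,
                p_value=p, corrected_p=cp, enriched=cp <= alpha,
            )
        )
    results.sort(key=lambda r: (r.corrected_p, r.term_id))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    """Report with study (C) and background (B) frequencies per term."""
    with open(path, "w") as fh:
        fh.write("term_id\tstudy_hits\tstudy_pct\tbackground_hits\tbackground_pct\t"
                 "p_value\tcorrected_p\tenriched\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.study_hits}\t{100 * r.study_hits / r.study_size:.1f}\t"
                f"{r.background_hits}\t{100 * r.background_hits / r.background_size:.1f}\t"
                f"{r.p_value:.3e}\t{r.corrected_p:.3e}\t{int(r.enriched)}\n"
            )
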