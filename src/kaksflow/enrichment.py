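"""One-sided Fisher exact GO-category enrichment of positively selected genes.

For each GO category C and the positively selected set S, a 2x2 contingency
table is built over the background (in/out of C x in/out of S) and a
one-sided (over-representation) hypergeometric p-value is computed.  Raw
p-values are reported by default; an optional Benjamini-Hochberg adjustment
is available.  No ontology-graph propagation is performed: a gene counts for
exactly the categories it is annotated to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import fisher_exact

from .errors import ValidationError
from .io_formats import AnnotationTable


@dataclass
class EnrichmentResult:
    category_id: str
    description: str
    taxonomy: str  # P (process), F (function), C (component)
    a: int  # in category, PSG
    b: int  # in category, non-PSG
    c: int  # out of category, PSG
    d: int  # out of category, non-PSG
    p_value: float
    significant: bool = False
    p_adjusted: float | None = None


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH step-up adjusted p-values, order preserved."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def go_enrichment(
    annotations: AnnotationTable,
    psg_ids: Iterable[str],
    background_ids: Iterable[str],
    alpha: float = 0.05,
    go_meta: Mapping[str, tuple[str, str]] | None = None,
    report_all: bool = False,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Per-category over-representation of PSGs against the background.

    psg_ids must be a subset of background_ids; genes missing from the
    annotation table count as out-of-category background members.  By default
    only categories with at least one PSG member are reported; results are
    sorted by p-value then category id, and categories with p <= alpha are
    flagged significant.  go_meta optionally maps a category to its
    (description, taxonomy) for reporting.
    """
    psg = set(psg_ids)
    background = set(background_ids)
    if not psg <= background:
        raise ValidationError("psg_ids must be a subset of background_ids")

    members: dict[str, set[str]] = {}
    for gene in background:
        for cat in annotations.categories_of(gene):
            members.setdefault(cat, set()).add(gene)

    n_bg = len(background)
    n_psg = len(psg)
    results: list[EnrichmentResult] = []
    for cat in sorted(members):
        in_cat = members[cat]
        a = len(in_cat & psg)
        if a == 0 and not report_all:
            continue
        b = len(in_cat) - a
        c = n_psg - a
        d = n_bg - len(in_cat) - c
        p = float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        desc, tax = (go_meta or {}).get(cat, ("", "P"))
        results.append(EnrichmentResult(cat, desc, tax, a, b, c, d, p))

    results.sort(key=lambda r: (r.p_value, r.category_id))
    if adjust and results:
        for r, padj in zip(results, benjamini_hochberg([r.p_value for r in results])):
            r.p_adjusted = padj
    for r in results:
        crit = r.p_adjusted if adjust else r.p_value
        r.significant = crit <= alpha
    return results
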