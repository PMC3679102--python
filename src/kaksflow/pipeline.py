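"""Pipeline orchestration: qc -> orthologs -> kaks -> enrich -> express.

One configured, seeded run writes every stage's TSV plus a machine-readable
summary.json into a run directory.  The summary mirrors the bookkeeping of a
comparative Ka/Ks survey: per-filter exclusion counts (the i-iv audit), the
selection-category counts with percentages of the retained total, the GO
enrichment table and the expression-concordance calls.  A rerun with the same
configuration and seed is byte-identical: no timestamps enter any output and
all collections are sorted before writing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import enrichment as enrich_mod
from . import expression as expr_mod
from . import kaks_evolution as kaks_mod
from . import orthology as orth_mod
from . import read_qc
from .errors import ConfigurationError, KaksflowError
from .io_formats import (
    AnnotationTable,
    read_annotation_table,
    read_fasta,
    read_fastq,
    write_results_table,
)

logger = logging.getLogger("kaksflow")

CATEGORY_ORDER = ("positive", "weak_purifying", "purifying",
                  "ka_only", "ks_only", "incalculable")


def category_percentages(counts: dict[str, int]) -> dict[str, dict[str, float]]:
    """Counts -> {category: {count, percent}} with percent = count/total*100
    rounded to one decimal place."""
    total = sum(counts.values())
    out = {}
    for cat in CATEGORY_ORDER:
        n = counts.get(cat, 0)
        out[cat] = {"count": n,
                    "percent": round(100.0 * n / total, 1) if total else 0.0}
    out["total"] = {"count": total, "percent": 100.0 if total else 0.0}
    return out


def high_quality_count(n_assembled: int, n_excluded: int) -> int:
    """Assembly accounting: unigenes surviving contaminant exclusion."""
    if n_excluded > n_assembled:
        raise ConfigurationError("cannot exclude more unigenes than assembled")
    return n_assembled - n_excluded


@dataclass
class PipelineConfig:
    """All paths and thresholds of one run; seed governs any stochastic step."""

    fasta_a: str
    fasta_b: str
    out_dir: str
    annotations: str | None = None
    # expression inputs: {"A": {"control": path, "stress": path}, "B": {...}}
    reads: dict[str, dict[str, str]] = field(default_factory=dict)
    assume_cds: bool = False
    min_orf_nt: int = 150
    min_score: float = orth_mod.DEFAULT_MIN_SCORE
    min_overlap_nt: int = 150
    min_coverage: float = 0.9
    max_gap_col_frac: float = 0.2
    ks_max: float = 0.1
    method: str = "yn"  # yn | ng
    alpha: float = 0.05
    log2_threshold: float = 1.0
    pseudo: float = 0.1
    max_mismatch: int = 3
    qc_max_n: int = 8
    qc_qual_floor: int = 5
    qc_max_lowq_frac: float = 0.5
    qc_adapter: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("yn", "ng"):
            raise ConfigurationError(f"method must be yn or ng, got {self.method!r}")
        if not (0 <= self.min_coverage <= 1 and 0 <= self.max_gap_col_frac <= 1):
            raise ConfigurationError("coverage/gap fractions must lie in [0, 1]")
        if self.ks_max < 0 or self.min_overlap_nt < 0 or self.alpha <= 0:
            raise ConfigurationError("thresholds out of documented range")


def _load_cds(path: str, species: str, assume_cds: bool, min_orf_nt: int):
    records = read_fasta(path, alphabet="nucleotide")
    if assume_cds:
        return [orth_mod.as_cds(r, species) for r in records], records
    cds = []
    for r in records:
        c = orth_mod.extract_cds(r, min_orf_nt=min_orf_nt, species=species)
        if c is not None:
            cds.append(c)
    return cds, records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    Any stage error aborts the run with the failing stage's name and cause.
    """
    holder = {"stage": "setup"}
    try:
        return _run_pipeline(config, holder)
    except KaksflowError as exc:
        raise KaksflowError(f"stage {holder['stage']!r} failed: {exc}") from exc


def _run_pipeline(config: PipelineConfig, _stage: dict) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: v for k, v in asdict(config).items()},
                     "stages": {}}

    # --- orthology -------------------------------------------------------
    _stage["stage"] = "orthology"
    cds_a, records_a = _load_cds(config.fasta_a, "A", config.assume_cds,
                                 config.min_orf_nt)
    cds_b, records_b = _load_cds(config.fasta_b, "B", config.assume_cds,
                                 config.min_orf_nt)
    logger.info("loaded %d/%d CDS for species A/B", len(cds_a), len(cds_b))
    summary["stages"]["cds"] = {"n_cds_a": len(cds_a), "n_cds_b": len(cds_b),
                                "n_unigenes_a": len(records_a),
                                "n_unigenes_b": len(records_b)}

    cds_by_id = {c.id: c for c in cds_a + cds_b}
    pairs = orth_mod.find_bbh(cds_a, cds_b, min_score=config.min_score)
    for pair in pairs:
        pair.codon_alignment = kaks_mod.codon_align(
            cds_by_id[pair.id_a], cds_by_id[pair.id_b],
            pair_id=pair.pair_id, allow_internal_stop=True)
    retained, excluded = orth_mod.filter_ortholog_pairs(
        pairs, config.min_overlap_nt, config.min_coverage,
        config.max_gap_col_frac)
    logger.info("BBH pairs %d; retained after filters i-iii: %d",
                len(pairs), len(retained))

    # --- Ka/Ks -----------------------------------------------------------
    _stage["stage"] = "kaks"
    estimator = kaks_mod.yn00 if config.method == "yn" else kaks_mod.ng86
    results = [estimator(p.codon_alignment) for p in retained]
    kept_results, ks_excluded = kaks_mod.apply_ks_filter(results, config.ks_max)
    ks_excluded_ids = {r.pair_id for r in ks_excluded}
    for pair in retained:
        if pair.pair_id in ks_excluded_ids:
            pair.filter_flags.add("ks_excess")
    final_pairs = [p for p in retained if p.pair_id not in ks_excluded_ids]

    exclusion_reasons = {p.pair_id: reason for p, reason in excluded}
    exclusion_reasons.update({pid: "ks_excess" for pid in ks_excluded_ids})
    filter_counts = {"overlap": 0, "coverage": 0, "stop_or_ambiguous": 0,
                     "ks_excess": 0}
    for reason in exclusion_reasons.values():
        filter_counts[reason] += 1
    summary["stages"]["orthology"] = {
        "n_bbh_pairs": len(pairs),
        "n_retained": len(final_pairs),
        "filter_exclusions": filter_counts,
    }

    cat_counts: dict[str, int] = {}
    for r in kept_results:
        cat_counts[r.category] = cat_counts.get(r.category, 0) + 1
    summary["categories"] = category_percentages(cat_counts)

    write_results_table(sorted(kept_results, key=lambda r: r.pair_id),
                        out / "kaks.tsv", "kaks")
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("pair_id\tid_a\tid_b\tscore\toverlap_nt\tcoverage_a\tcoverage_b\n")
        for p in sorted(final_pairs, key=lambda p: p.pair_id):
            fh.write(f"{p.pair_id}\t{p.id_a}\t{p.id_b}\t{p.hit.score:.1f}\t"
                     f"{p.hit.overlap_nt}\t{p.hit.coverage_q:.6f}\t"
                     f"{p.hit.coverage_s:.6f}\n")
    with open(out / "exclusions.tsv", "w") as fh:
        fh.write("pair_id\treason\n")
        for pid in sorted(exclusion_reasons):
            fh.write(f"{pid}\t{exclusion_reasons[pid]}\n")

    # --- GO enrichment ---------------------------------------------------
    _stage["stage"] = "enrichment"
    if config.annotations:
        annotations = read_annotation_table(config.annotations)
        result_by_pair = {r.pair_id: r for r in kept_results}
        background = [p.id_a for p in final_pairs]
        psg = [p.id_a for p in final_pairs
               if result_by_pair[p.pair_id].category == "positive"]
        enr = enrich_mod.go_enrichment(annotations, psg, background,
                                       alpha=config.alpha)
        write_results_table(enr, out / "enrichment.tsv", "enrichment")
        summary["stages"]["enrichment"] = {
            "n_psg": len(psg), "n_background": len(background),
            "n_categories_tested": len(enr),
            "top_categories": [
                {"category_id": r.category_id, "p_value": r.p_value}
                for r in enr[:5]
            ],
        }

    # --- expression ------------------------------------------------------
    _stage["stage"] = "expression"
    if config.reads:
        gene_len = {r.id: len(r.seq) for r in records_a + records_b}
        rpkm_by: dict[tuple[str, str], dict[str, float]] = {}
        qc_summary = {}
        for species, genes in (("A", records_a), ("B", records_b)):
            for condition in ("control", "stress"):
                path = config.reads.get(species, {}).get(condition)
                if path is None:
                    raise ConfigurationError(
                        f"missing {condition} reads for species {species}")
                reads = read_fastq(path)
                clean, report = read_qc.clean_reads(
                    reads, adapter=config.qc_adapter, max_n=config.qc_max_n,
                    qual_floor=config.qc_qual_floor,
                    max_lowq_frac=config.qc_max_lowq_frac)
                qc_summary[f"{species}_{condition}"] = report.as_dict()
                mapping = expr_mod.map_reads(clean, genes, config.max_mismatch)
                rpkm_by[(species, condition)] = {
                    gid: expr_mod.rpkm(n, gene_len[gid], mapping.total_mapped)
                    for gid, n in mapping.counts.items()
                } if mapping.total_mapped else {gid: 0.0 for gid in mapping.counts}
                logger.info("%s/%s: %d reads, %d mapped", species, condition,
                            mapping.n_input, mapping.total_mapped)
        summary["stages"]["qc"] = qc_summary

        expr_records: list[expr_mod.ExpressionRecord] = []
        for p in final_pairs:
            for species, gid in (("A", p.id_a), ("B", p.id_b)):
                ctrl = rpkm_by[(species, "control")].get(gid, 0.0)
                strs = rpkm_by[(species, "stress")].get(gid, 0.0)
                cls, ratio = expr_mod.classify_regulation(
                    ctrl, strs, config.log2_threshold, config.pseudo)
                expr_records.append(expr_mod.ExpressionRecord(
                    p.pair_id, species, ctrl, strs, ratio, cls))
        write_results_table(sorted(expr_records, key=lambda r: (r.pair_id, r.species)),
                            out / "expression.tsv", "expression")
        calls = expr_mod.concordance(expr_records)
        with open(out / "concordance.tsv", "w") as fh:
            fh.write("pair_id\tcall\n")
            for c in calls:
                fh.write(f"{c.pair_id}\t{c.call}\n")

        result_by_pair = {r.pair_id: r for r in kept_results}
        pos_ids = {pid for pid, r in result_by_pair.items()
                   if r.category == "positive"}
        call_counts = {c: 0 for c in expr_mod.CONCORDANCE_CALLS}
        pos_call_counts = {c: 0 for c in expr_mod.CONCORDANCE_CALLS}
        for c in calls:
            call_counts[c.call] += 1
            if c.pair_id in pos_ids:
                pos_call_counts[c.call] += 1
        summary["stages"]["expression"] = {
            "concordance": call_counts,
            "concordance_positive_pairs": pos_call_counts,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
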