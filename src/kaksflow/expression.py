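"""Mismatch-limited read assignment, RPKM, and salt-stress concordance calls.

Reads are assigned to the gene/position (either strand) with the fewest
mismatches, up to a maximum of three by default; reads tied between genes are
discarded as ambiguous so that assignment is deterministic.  The mapper is an
exact Hamming-distance search accelerated with pigeonhole seeding: a read is
split into max_mismatch+1 chunks, so any placement within the mismatch budget
matches at least one chunk exactly; no indels are modelled.

Expression is quantified as RPKM (reads per kilobase of transcript per million
mapped reads).  Per-species regulation under stress is called from the log2
RPKM ratio with a pseudo-count, and pairs are classified into the concordance
scheme: up in both species, up in exactly one, or other.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Mapping, Sequence

import numpy as np

from .errors import EstimationError, ParameterError, ValidationError
from .io_formats import SequenceRecord
from .read_qc import reverse_complement

REG_CLASSES = ("up", "down", "unchanged")
CONCORDANCE_CALLS = ("up_both", "up_species_a_only", "up_species_b_only", "other")


@dataclass
class MappingResult:
    counts: dict[str, int]          # gene id -> assigned reads
    total_mapped: int
    n_ambiguous: int
    n_unassigned: int
    n_input: int


@dataclass
class ExpressionRecord:
    pair_id: str
    species: str
    rpkm_control: float
    rpkm_stress: float
    log2_ratio: float
    reg_class: str


@dataclass
class ConcordanceCall:
    pair_id: str
    call: str


def map_reads(reads: Sequence[SequenceRecord], genes: Sequence[SequenceRecord],
              max_mismatch: int = 3) -> MappingResult:
    """Assign each read to its minimum-mismatch gene (both strands).

    Reads whose best placement exceeds max_mismatch are unassigned; reads
    whose minimum mismatch count is achieved in more than one gene are
    discarded as ambiguous.  All reads must share one length.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    counts = {g.id: 0 for g in genes}
    if not reads:
        return MappingResult(counts, 0, 0, 0, 0)
    read_len = len(reads[0].seq)
    if any(len(r.seq) != read_len for r in reads):
        raise ValidationError("all reads must have the same length")

    chunk = max(1, read_len // (max_mismatch + 1))
    offsets = [i * chunk for i in range(max_mismatch + 1)]
    # seed index over both strands of every gene
    arrays: list[tuple[str, np.ndarray]] = []   # (gene_id, encoded sequence)
    index: dict[str, list[tuple[int, int]]] = {}  # chunk seq -> [(array_idx, pos)]
    for g in genes:
        for strand_seq in (g.seq, reverse_complement(g.seq)):
            ai = len(arrays)
            arrays.append((g.id, np.frombuffer(strand_seq.encode(), dtype=np.uint8)))
            for pos in range(0, len(strand_seq) - chunk + 1):
                index.setdefault(strand_seq[pos:pos + chunk], []).append((ai, pos))

    n_ambiguous = n_unassigned = 0
    for read in reads:
        arr = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        candidates: set[tuple[int, int]] = set()
        for off in offsets:
            for ai, pos in index.get(read.seq[off:off + chunk], ()):
                start = pos - off
                if 0 <= start and start + read_len <= arrays[ai][1].size:
                    candidates.add((ai, start))
        best = max_mismatch + 1
        best_genes: set[str] = set()
        for ai, start in candidates:
            gid, garr = arrays[ai]
            mm = int(np.count_nonzero(garr[start:start + read_len] != arr))
            if mm < best:
                best, best_genes = mm, {gid}
            elif mm == best:
                best_genes.add(gid)
        if best > max_mismatch:
            n_unassigned += 1
        elif len(best_genes) > 1:
            n_ambiguous += 1
        else:
            counts[next(iter(best_genes))] += 1
    total = sum(counts.values())
    assert total + n_ambiguous + n_unassigned == len(reads)
    return MappingResult(counts, total, n_ambiguous, n_unassigned, len(reads))


def rpkm(count: int, gene_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if total_mapped <= 0:
        raise EstimationError("total_mapped must be > 0")
    if gene_length_nt <= 0:
        raise ParameterError("gene_length_nt must be > 0")
    return 1e9 * count / (gene_length_nt * total_mapped)


def classify_regulation(rpkm_control: float, rpkm_stress: float,
                        log2_threshold: float = 1.0,
                        pseudo: float = 0.1) -> tuple[str, float]:
    """(reg_class, log2_ratio) from the two RPKM values.

    log2_ratio = log2((stress + pseudo) / (control + pseudo)); up when the
    ratio is >= log2_threshold, down when <= -log2_threshold.
    """
    if log2_threshold <= 0 or pseudo <= 0:
        raise ParameterError("log2_threshold and pseudo must be > 0")
    ratio = log2((rpkm_stress + pseudo) / (rpkm_control + pseudo))
    if ratio >= log2_threshold:
        cls = "up"
    elif ratio <= -log2_threshold:
        cls = "down"
    else:
        cls = "unchanged"
    return cls, ratio


def concordance(records: Mapping[str, Sequence[ExpressionRecord]] | Sequence[ExpressionRecord]
                ) -> list[ConcordanceCall]:
    """Per-pair concordance from both species' regulation calls.

    up_both when both species are up; a single-species call when exactly one
    is; other otherwise.  Every pair must have a record for both species.
    """
    if not isinstance(records, Mapping):
        grouped: dict[str, list[ExpressionRecord]] = {}
        for rec in records:
            grouped.setdefault(rec.pair_id, []).append(rec)
    else:
        grouped = {k: list(v) for k, v in records.items()}

    calls: list[ConcordanceCall] = []
    for pair_id in sorted(grouped):
        recs = {r.species: r for r in grouped[pair_id]}
        if set(recs) != {"A", "B"}:
            raise ValidationError(
                f"pair {pair_id!r}: need exactly one record per species, got {sorted(recs)}")
        up_a = recs["A"].reg_class == "up"
        up_b = recs["B"].reg_class == "up"
        if up_a and up_b:
            call = "up_both"
        elif up_a:
            call = "up_species_a_only"
        elif up_b:
            call = "up_species_b_only"
        else:
            call = "other"
        calls.append(ConcordanceCall(pair_id, call))
    return calls
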