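"""Deterministic FASTQ cleaning filters.

Whole-read filters applied in a fixed order: exact-duplicate removal (both
orientations), adapter trimming, too-many-N removal, low-quality removal and
low-complexity removal.  Defaults follow the upstream read-cleaning protocol:
a read is dropped when it has more than 8 unknown base calls (N) or when more
than 50% of its bases have a quality score of 5 or lower.  "Low complexity"
is operationalised as a single nucleotide making up more than 80% of the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Sequence

from .errors import ParameterError
from .io_formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QCReport:
    """Bookkeeping for one clean_reads run; counts reconcile exactly."""

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_adapter_trimmed: int = 0  # reads trimmed, not removed
    n_removed_n: int = 0
    n_removed_quality: int = 0
    n_removed_complexity: int = 0
    n_output: int = 0

    def check(self) -> None:
        removed = (self.n_duplicates_removed + self.n_removed_n
                   + self.n_removed_quality + self.n_removed_complexity)
        assert self.n_output == self.n_input - removed, "QC counts do not reconcile"

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _trim_adapter(seq: str, quals: list[int] | None, adapter: str,
                  min_match: int) -> tuple[str, list[int] | None, bool]:
    """Exact-match adapter trimming at either read end (>= min_match bases).

    A full internal adapter occurrence trims from its start to the 3' end
    (sequencing-through); prefix/suffix partial matches of at least min_match
    bases are clipped.  Repeats until no match remains.
    """
    trimmed = False
    changed = True
    while changed and seq:
        changed = False
        idx = seq.find(adapter)
        if idx != -1:
            seq, quals = seq[:idx], quals[:idx] if quals is not None else None
            trimmed = changed = True
            continue
        # partial adapter prefix at the 3' end of the read
        for k in range(min(len(adapter), len(seq)) , min_match - 1, -1):
            if seq.endswith(adapter[:k]):
                seq = seq[:-k]
                quals = quals[:-k] if quals is not None else None
                trimmed = changed = True
                break
        if changed:
            continue
        # partial adapter suffix at the 5' end of the read
        for k in range(min(len(adapter), len(seq)), min_match - 1, -1):
            if seq.startswith(adapter[-k:]):
                seq = seq[k:]
                quals = quals[k:] if quals is not None else None
                trimmed = changed = True
                break
    return seq, quals, trimmed


def clean_reads(
    reads: Sequence[SequenceRecord],
    adapter: str = "",
    max_n: int = 8,
    qual_floor: int = 5,
    max_lowq_frac: float = 0.5,
    complexity_max_frac: float = 0.8,
    adapter_min_match: int = 8,
) -> tuple[list[SequenceRecord], QCReport]:
    """Apply the cleaning filters in fixed order and return survivors + report.

    Removal rules (strict inequalities): N count > max_n; fraction of bases
    with quality <= qual_floor above max_lowq_frac; most frequent single
    nucleotide above complexity_max_frac of the read (empty reads count as
    low complexity).  A duplicate is a read whose sequence, or its reverse
    complement, equals a previously retained read; the first-seen read wins.
    """
    if max_n < 0 or qual_floor < 0 or max_lowq_frac < 0 or complexity_max_frac < 0:
        raise ParameterError("QC thresholds must be non-negative")
    adapter = adapter.upper()

    report = QCReport(n_input=len(reads))
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for read in reads:
        seq, quals = read.seq, read.qualities
        if seq in seen or reverse_complement(seq) in seen:
            report.n_duplicates_removed += 1
            continue
        seen.add(seq)

        if adapter and len(adapter) >= adapter_min_match:
            seq, quals, trimmed = _trim_adapter(seq, quals, adapter, adapter_min_match)
            if trimmed:
                report.n_adapter_trimmed += 1

        if seq.count("N") > max_n:
            report.n_removed_n += 1
            continue
        if quals is not None and seq:
            lowq = sum(1 for q in quals if q <= qual_floor)
            if lowq / len(seq) > max_lowq_frac:
                report.n_removed_quality += 1
                continue
        if not seq or max(Counter(seq).values()) / len(seq) > complexity_max_frac:
            report.n_removed_complexity += 1
            continue
        out.append(SequenceRecord(read.id, seq, quals))

    report.n_output = len(out)
    report.check()
    return out, report
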