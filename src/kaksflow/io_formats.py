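"""Readers and writers for the external formats the pipeline touches.

FASTA and FASTQ (Phred+33) parsing is delegated to Bio.SeqIO; this module adds
the strict validation the pipeline relies on (unique ids, quality/sequence
length agreement, restricted nucleotide alphabet) and the fixed-schema TSV
result tables.  Reads are tolerant (lowercase is uppercased), writes are strict.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError, ValidationError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

FASTA_LINE_WIDTH = 60


@dataclass
class SequenceRecord:
    """A named sequence, optionally with per-base Phred qualities."""

    id: str
    seq: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValidationError(f"record id empty or contains whitespace: {self.id!r}")
        self.seq = self.seq.upper()
        if self.qualities is not None:
            if len(self.qualities) != len(self.seq):
                raise ValidationError(
                    f"record {self.id!r}: {len(self.qualities)} qualities for "
                    f"{len(self.seq)} bases"
                )
            if any(q < 0 for q in self.qualities):
                raise ValidationError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)

    def check_nucleotide(self) -> "SequenceRecord":
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        return self


class AnnotationTable:
    """gene_id -> set of GO category ids ("GO:NNNNNNN")."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._map: dict[str, set[str]] = {}
        if mapping:
            for gene, gos in mapping.items():
                for go in gos:
                    self.add(gene, go)

    def add(self, gene_id: str, go_id: str) -> None:
        if not GO_ID_PATTERN.match(go_id):
            raise ValidationError(f"malformed GO id {go_id!r} for gene {gene_id!r}")
        self._map.setdefault(gene_id, set()).add(go_id)

    def categories_of(self, gene_id: str) -> frozenset[str]:
        return frozenset(self._map.get(gene_id, ()))

    def genes(self) -> list[str]:
        return sorted(self._map)

    def categories(self) -> list[str]:
        return sorted({go for gos in self._map.values() for go in gos})

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords, preserving order.

    Duplicate ids raise ValidationError naming the offender; an empty file is a
    FormatError.  With alphabet="nucleotide", characters outside {A,C,G,T,N}
    (after uppercasing) are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            out = SequenceRecord(rec.id, str(rec.seq))
            if alphabet == "nucleotide":
                out.check_nucleotide()
            records.append(out)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 characters per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), FASTA_LINE_WIDTH):
                fh.write(rec.seq[i:i + FASTA_LINE_WIDTH] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse Phred+33 FASTQ into SequenceRecords with integer qualities."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                if rec.id in seen:
                    raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
                seen.add(rec.id)
                records.append(
                    SequenceRecord(rec.id, str(rec.seq),
                                   list(rec.letter_annotations["phred_quality"]))
                )
    except ValueError as exc:  # SeqIO signals structural problems as ValueError
        raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTQ records found in {path}")
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records (which must carry qualities) as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValidationError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# Fixed column orders for the three result-table schemas.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "kaks": ["pair_id", "method", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio",
             "kappa", "gc", "gapless_len_nt", "p_fisher", "category"],
    "enrichment": ["category_id", "description", "taxonomy",
                   "a", "b", "c", "d", "p_value"],
    "expression": ["pair_id", "species", "rpkm_control", "rpkm_stress",
                   "log2_ratio", "reg_class"],
}

_FLOAT_COLUMNS = {
    "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "kappa", "gc", "p_fisher",
    "p_value", "rpkm_control", "rpkm_stress", "log2_ratio",
}


def _format_cell(col: str, value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if col in _FLOAT_COLUMNS:
        return f"{float(value):.6f}"
    return str(value)


def write_results_table(records: Sequence[Mapping], path: str | Path, schema: str) -> None:
    """Write result records as a TSV with a fixed header and 6-decimal floats.

    `records` are mappings (or dataclass-like objects exposing the schema's
    fields through attributes); unknown schema names raise ConfigurationError.
    """
    if schema not in TABLE_SCHEMAS:
        raise ConfigurationError(
            f"unknown results schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}"
        )
    cols = TABLE_SCHEMAS[schema]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            get = rec.get if isinstance(rec, Mapping) else lambda c: getattr(rec, c)
            fh.write("\t".join(_format_cell(c, get(c)) for c in cols) + "\n")


def read_results_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read back a results TSV written by write_results_table."""
    if schema not in TABLE_SCHEMAS:
        raise ConfigurationError(f"unknown results schema {schema!r}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    expected = TABLE_SCHEMAS[schema]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: columns {list(df.columns)} != {expected}")
    return df


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a two-column `gene_id<TAB>GO:NNNNNNN` file (one pair per line)."""
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            table.add(parts[0], parts[1])
    return table


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in table.genes():
            for go in sorted(table.categories_of(gene)):
                fh.write(f"{gene}\t{go}\n")
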