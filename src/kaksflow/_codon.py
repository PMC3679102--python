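"""Universal-genetic-code tables and codon-path machinery.

Shared by the codon-pair simulator and the NG86/YN00 estimators: sense-codon
indexing, transition/transversion and synonymy classification, single-nucleotide
neighbourhoods, and enumeration of minimal substitution paths between two codons
(used to decompose multi-position codon differences into synonymous and
nonsynonymous steps).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the universal code

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True for A<->G and C<->T changes."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def is_synonymous(c1: str, c2: str) -> bool:
    """Both codons sense and encoding the same amino acid."""
    return c1 in AMINO_ACID and c2 in AMINO_ACID and AMINO_ACID[c1] == AMINO_ACID[c2]


def codon_neighbors(codon: str) -> list[tuple[int, str]]:
    """All nine single-nucleotide mutants of a codon, stops included.

    Returns (position, target_codon) tuples in deterministic order.
    """
    out = []
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                out.append((pos, codon[:pos] + base + codon[pos + 1:]))
    return out


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon, NG86 counting.

    Each of the three positions contributes one site, split by the fraction of
    its single-nucleotide changes that are synonymous; changes to stop codons
    are excluded from the denominator. s + n == 3 exactly.
    """
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            target = codon[:pos] + base + codon[pos + 1:]
            if target in STOP_CODONS:
                continue
            denom += 1
            if AMINO_ACID[target] == AMINO_ACID[codon]:
                syn += 1
        if denom:
            s += syn / denom
    return s, 3.0 - s


# A path step: (target_codon, is_synonymous, is_transition)
Step = tuple[str, bool, bool]


@lru_cache(maxsize=None)
def substitution_paths(c1: str, c2: str) -> tuple[tuple[Step, ...], ...]:
    """Minimal single-nucleotide substitution paths from c1 to c2.

    Enumerates every ordering of the differing positions.  Orderings passing
    through a stop codon are discarded; in the (rare) case where every ordering
    does, all orderings are kept and steps touching a stop count as
    nonsynonymous.  Endpoints are assumed to be sense codons.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid: list[tuple[Step, ...]] = []
    fallback: list[tuple[Step, ...]] = []
    for order in permutations(diff):
        cur = c1
        steps: list[Step] = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((nxt, is_synonymous(cur, nxt), is_transition(cur[pos], nxt[pos])))
            if nxt in STOP_CODONS:
                through_stop = True
            cur = nxt
        (fallback if through_stop else valid).append(tuple(steps))
    return tuple(valid) if valid else tuple(fallback)


@lru_cache(maxsize=None)
def ng86_difference_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Multi-position differences are resolved by averaging, with equal weight,
    over all minimal substitution paths through sense codons.
    """
    if c1 == c2:
        return 0.0, 0.0
    paths = substitution_paths(c1, c2)
    sd = nd = 0.0
    for path in paths:
        for _, syn, _ in path:
            if syn:
                sd += 1.0
            else:
                nd += 1.0
    k = len(paths)
    return sd / k, nd / k


def translate_cds(nt: str, allow_internal_stop: bool = False) -> str:
    """Translate an in-frame CDS; ambiguous codons become 'X', stops '*'.

    The terminal stop, if present, is dropped.  Raises ValueError on an
    internal stop unless allowed (used by the trust-frame pipeline mode).
    """
    if len(nt) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if not allow_internal_stop:
                raise ValueError(f"internal stop codon at codon {i}")
            aas.append("*")
        elif codon in AMINO_ACID:
            aas.append(AMINO_ACID[codon])
        else:
            aas.append("X")
    return "".join(aas)
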