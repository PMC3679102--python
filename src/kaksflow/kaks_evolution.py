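"""Codon-aware alignment and Ka/Ks estimation.

Two estimators are provided.  ``ng86`` is Nei-Gojobori counting: synonymous
and nonsynonymous sites from exhaustive enumeration of each codon's nine
single-nucleotide changes, differences resolved by equal-weight averaging over
minimal substitution paths, and a Jukes-Cantor correction for multiple hits.
``yn00`` is the Yang-Nielsen approximate method: the transition/transversion
ratio kappa is estimated from fourfold-degenerate and nondegenerate sites,
sites and substitution pathways are weighted by F3x4 codon frequencies and
kappa, distances are corrected with the Kimura two-parameter formula applied
separately to synonymous and nonsynonymous differences, and the pathway
weighting is iterated with the current omega to a fixed point.

A two-sided Fisher exact test on the (rounded) site/substitution 2x2 table
flags pairs whose Ka and Ks rest on too little signal, and ``apply_ks_filter``
implements the paralog guard: pairs with synonymous divergence Ks > 0.1 are
excluded as likely duplicates rather than orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact

from ._codon import (
    BASES,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    is_synonymous,
    is_transition,
    ng86_difference_counts,
    ng86_site_counts,
    substitution_paths,
)
from .errors import EstimationError, ValidationError
from .orthology import CodingSequence, OrthologPair, align_proteins

CATEGORIES = ("positive", "weak_purifying", "purifying",
              "ka_only", "ks_only", "incalculable")

_KAPPA_MIN, _KAPPA_MAX = 0.2, 20.0


@dataclass
class CodonAlignment:
    """Paired gapped codon lists; gaps are whole codons ("---")."""

    pair_id: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValidationError(f"{self.pair_id}: unequal codon list lengths")
        for c in self.codons_a + self.codons_b:
            if len(c) != 3 or ("-" in c and c != "---"):
                raise ValidationError(f"{self.pair_id}: partial-codon gap {c!r}")

    def paired_columns(self) -> list[tuple[str, str]]:
        """Columns ungapped in both sequences, stop/ambiguous codons removed."""
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca in CODON_INDEX and cb in CODON_INDEX
        ]

    @property
    def gapless_len_nt(self) -> int:
        return 3 * len(self.paired_columns())


@dataclass
class KaKsResult:
    pair_id: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    kappa: float | None
    gc: float
    gapless_len_nt: int
    p_fisher: float | None
    category: str
    converged: bool = True


def _backtranslate(pair_id: str, cds_a: CodingSequence, cds_b: CodingSequence,
                   aligned_a: str, aligned_b: str) -> CodonAlignment:
    codons_a, codons_b = [], []
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        if ra == "-":
            codons_a.append("---")
        else:
            codons_a.append(cds_a.nt[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            codons_b.append("---")
        else:
            codons_b.append(cds_b.nt[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(pair_id, codons_a, codons_b)


def codon_align(cds_a: CodingSequence, cds_b: CodingSequence,
                gap_open: float = 11, gap_extend: float = 1,
                pair_id: str | None = None,
                allow_internal_stop: bool = False) -> CodonAlignment:
    """Protein-guided codon alignment (global), back-translated to codons.

    The two translations are globally aligned under BLOSUM62/affine gaps and
    every protein gap becomes a whole-codon gap, so codon structure is exact.
    Internal stops raise ValidationError unless explicitly allowed (trust-frame
    fixture mode, where filtering has not yet removed contaminants).
    """
    if not allow_internal_stop:
        for cds in (cds_a, cds_b):
            if "*" in cds.protein:
                raise ValidationError(f"{cds.id}: internal stop codon in CDS")
    hit = align_proteins(cds_a, cds_b, gap_open=gap_open,
                         gap_extend=gap_extend, mode="global")
    return _backtranslate(pair_id or f"{cds_a.id}|{cds_b.id}",
                          cds_a, cds_b, hit.aligned_q, hit.aligned_s)


def pair_stats(alignment: CodonAlignment) -> tuple[float, int, float, float]:
    """(gc, gapless_len_nt, Sd, Nd) summary of an alignment.

    GC content is computed jointly over both sequences' bases in columns that
    are ungapped (and stop-free) in both; Sd/Nd are the NG86 path-averaged
    difference counts.
    """
    cols = alignment.paired_columns()
    if not cols:
        return 0.0, 0, 0.0, 0.0
    bases = "".join(ca + cb for ca, cb in cols)
    gc = sum(1 for b in bases if b in "GC") / len(bases)
    sd = nd = 0.0
    for ca, cb in cols:
        d_s, d_n = ng86_difference_counts(ca, cb)
        sd += d_s
        nd += d_n
    return gc, 3 * len(cols), sd, nd


def _jukes_cantor(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def _k2p_distance(P: float, Q: float) -> float | None:
    """Kimura two-parameter distance from transition/transversion proportions."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return None
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def _k2p_kappa(P: float, Q: float) -> float | None:
    """kappa (ts/tv rate ratio) from K2P transition/transversion distances."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return None
    alpha_t = -0.5 * math.log(a) + 0.25 * math.log(b)
    beta_t = -0.25 * math.log(b)
    if beta_t <= 0:
        return None if alpha_t <= 0 else _KAPPA_MAX
    return alpha_t / beta_t


def _finish(pair_id: str, method: str, S: float, N: float, Sd: float, Nd: float,
            ka: float | None, ks: float | None, kappa: float | None,
            gc: float, gapless: int, converged: bool = True) -> KaKsResult:
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    # path-averaged Sd can exceed fractional S at extreme divergence skew;
    # the validity table is clipped there (the rates are undefined anyway)
    p = fisher_validity(S, N, min(Sd, S), min(Nd, N))
    return KaKsResult(pair_id, method, S, N, Sd, Nd, ka, ks, ratio, kappa,
                      gc, gapless, p, classify_rates(ka, ks), converged)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori counting with Jukes-Cantor correction."""
    cols = alignment.paired_columns()
    if not cols:
        raise EstimationError(f"{alignment.pair_id}: no ungapped codon columns")
    S = N = 0.0
    for ca, cb in cols:
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
    gc, gapless, Sd, Nd = pair_stats(alignment)
    ks = _jukes_cantor(Sd / S) if S > 0 else None
    ka = _jukes_cantor(Nd / N) if N > 0 else None
    return _finish(alignment.pair_id, "ng86", S, N, Sd, Nd, ka, ks, None,
                   gc, gapless)


def _f3x4(cols: Sequence[tuple[str, str]]) -> np.ndarray:
    """F3x4 sense-codon frequencies from both sequences' aligned codons."""
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for ca, cb in cols:
        for codon in (ca, cb):
            for pos in range(3):
                counts[pos, base_idx[codon[pos]]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    probs = np.maximum(probs, 1e-6)
    probs /= probs.sum(axis=1, keepdims=True)
    pi = np.array([
        probs[0, base_idx[c[0]]] * probs[1, base_idx[c[1]]] * probs[2, base_idx[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def _degeneracy_class(codon: str, pos: int) -> str | None:
    """"4" if every change at pos is synonymous, "0" if every sense change is
    nonsynonymous, else None (intermediate degeneracy is not used)."""
    syn = nonsyn = 0
    for base in BASES:
        if base == codon[pos]:
            continue
        target = codon[:pos] + base + codon[pos + 1:]
        if target in STOP_CODONS:
            nonsyn += 1  # a change to a stop is certainly not synonymous
            continue
        if is_synonymous(codon, target):
            syn += 1
        else:
            nonsyn += 1
    if syn == 3:
        return "4"
    if nonsyn == 3:
        return "0"
    return None


def estimate_kappa(cols: Sequence[tuple[str, str]]) -> float:
    """kappa from fourfold-degenerate and nondegenerate positions.

    Only positions whose degeneracy class (fourfold or nondegenerate) agrees
    between the two sequences are used; at such positions every change is
    either wholly synonymous or wholly nonsynonymous, so the omega parameter
    scales transitions and transversions alike and the ts/tv contrast
    identifies kappa.  Counts are pooled across the two classes and stabilised
    with add-half smoothing (0.5 transitions : 1 transversion, which preserves
    the kappa = 1 null ratio and tames the small-count skew of the ratio
    estimator) before a single K2P inversion.  Falls back to 1.0 when no
    classified site exists; clamped to a broad range for numerical stability.
    """
    sites = ts = tv = 0
    for ca, cb in cols:
        for pos in range(3):
            cls_a = _degeneracy_class(ca, pos)
            if cls_a is None or cls_a != _degeneracy_class(cb, pos):
                continue
            sites += 1
            if ca[pos] != cb[pos]:
                if is_transition(ca[pos], cb[pos]):
                    ts += 1
                else:
                    tv += 1
    if sites == 0:
        return 1.0
    denom = sites + 1.5
    kappa = _k2p_kappa((ts + 0.5) / denom, (tv + 1.0) / denom)
    if kappa is None:
        return 1.0
    return min(max(kappa, _KAPPA_MIN), _KAPPA_MAX)


def _yn_site_counts(cols, pi: np.ndarray, kappa: float) -> tuple[float, float]:
    """S, N with mutations weighted by target-codon frequency and kappa."""
    per_codon: dict[str, float] = {}

    def s_of(codon: str) -> float:
        if codon not in per_codon:
            syn_w = tot_w = 0.0
            for pos in range(3):
                for base in BASES:
                    if base == codon[pos]:
                        continue
                    target = codon[:pos] + base + codon[pos + 1:]
                    if target in STOP_CODONS:
                        continue
                    w = pi[CODON_INDEX[target]] * (kappa if is_transition(codon[pos], base) else 1.0)
                    tot_w += w
                    if is_synonymous(codon, target):
                        syn_w += w
            per_codon[codon] = 3.0 * syn_w / tot_w if tot_w > 0 else 0.0
        return per_codon[codon]

    S = sum((s_of(ca) + s_of(cb)) / 2.0 for ca, cb in cols)
    return S, 3.0 * len(cols) - S


def _yn_count_differences(cols, pi: np.ndarray, kappa: float, omega: float):
    """Expected (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) difference counts.

    Multi-position codon differences are decomposed over minimal substitution
    paths weighted by the product of per-step rates pi_target * kappa^[ts] *
    omega^[nonsynonymous].
    """
    syn_ts = syn_tv = non_ts = non_tv = 0.0
    for ca, cb in cols:
        if ca == cb:
            continue
        paths = substitution_paths(ca, cb)
        weights = []
        for path in paths:
            w = 1.0
            for target, syn, ts in path:
                w *= pi[CODON_INDEX[target]] if target in CODON_INDEX else 1e-12
                if ts:
                    w *= kappa
                if not syn:
                    w *= omega
            weights.append(w)
        total = sum(weights)
        if total <= 0:
            weights = [1.0] * len(paths)
            total = float(len(paths))
        for w, path in zip(weights, paths):
            frac = w / total
            for _, syn, ts in path:
                if syn and ts:
                    syn_ts += frac
                elif syn:
                    syn_tv += frac
                elif ts:
                    non_ts += frac
                else:
                    non_tv += frac
    return syn_ts, syn_tv, non_ts, non_tv


def yn00(alignment: CodonAlignment, tol: float = 1e-6,
         max_iter: int = 100) -> KaKsResult:
    """Yang-Nielsen approximate Ka/Ks with F3x4 frequencies.

    Non-convergence within max_iter is flagged on the result rather than
    raised; undefined rates (K2P correction out of domain) are None.
    """
    cols = alignment.paired_columns()
    if not cols:
        raise EstimationError(f"{alignment.pair_id}: no ungapped codon columns")
    pi = _f3x4(cols)
    kappa = estimate_kappa(cols)
    S, N = _yn_site_counts(cols, pi, kappa)
    gc, gapless, _, _ = pair_stats(alignment)

    omega = 1.0
    converged = False
    ka = ks = None
    counts = (0.0, 0.0, 0.0, 0.0)
    for _ in range(max_iter):
        counts = _yn_count_differences(cols, pi, kappa, omega)
        syn_ts, syn_tv, non_ts, non_tv = counts
        ks = _k2p_distance(syn_ts / S, syn_tv / S) if S > 0 else None
        ka = _k2p_distance(non_ts / N, non_tv / N) if N > 0 else None
        if ka is None or ks is None or ks == 0:
            converged = True  # a fixed point in the defined sense is unreachable
            break
        new_omega = ka / ks
        if abs(new_omega - omega) < tol:
            omega = new_omega
            converged = True
            break
        omega = new_omega
    syn_ts, syn_tv, non_ts, non_tv = counts
    return _finish(alignment.pair_id, "yn00", S, N, syn_ts + syn_tv,
                   non_ts + non_tv, ka, ks, kappa, gc, gapless, converged)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_validity(S: float, N: float, Sd: float, Nd: float) -> float:
    """Two-sided Fisher exact p for the site/substitution 2x2 table.

    Tests whether the synonymous and nonsynonymous substitution proportions
    differ, i.e. whether the Ka/Ks contrast carries signal.  Fractional site
    and substitution counts are rounded half away from zero.
    """
    if min(S, N, Sd, Nd) < 0:
        raise ValidationError("S, N, Sd, Nd must be non-negative")
    if Sd > S or Nd > N:
        raise ValidationError("substitutions cannot exceed sites")
    s, n = _round_half_away(S), _round_half_away(N)
    sd, nd = min(_round_half_away(Sd), s), min(_round_half_away(Nd), n)
    table = [[sd, s - sd], [nd, n - nd]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def apply_ks_filter(results: Sequence[KaKsResult], ks_max: float = 0.1
                    ) -> tuple[list[KaKsResult], list[KaKsResult]]:
    """Paralog guard (filter iv): exclude pairs with defined Ks > ks_max.

    The boundary is strict (Ks == ks_max is retained); pairs with undefined
    Ks are retained and routed to ka_only/incalculable by classification.
    """
    retained, excluded = [], []
    for r in results:
        if r.Ks is not None and r.Ks > ks_max:
            excluded.append(r)
        else:
            retained.append(r)
    return retained, excluded


def classify_rates(ka: float | None, ks: float | None) -> str:
    """Selection category from the two rates.

    positive: ratio > 1; weak_purifying: 0.5 < ratio <= 1; purifying:
    0 < ratio <= 0.5; ka_only / ks_only when only one rate is usable
    (defined and > 0); incalculable otherwise.
    """
    ka_usable = ka is not None and ka > 0
    ks_usable = ks is not None and ks > 0
    if ka is not None and ks_usable:
        ratio = ka / ks
        if ratio > 1:
            return "positive"
        if ratio > 0.5:
            return "weak_purifying"
        if ratio > 0:
            return "purifying"
        return "ks_only"  # Ka == 0 with usable Ks
    if ka_usable:
        return "ka_only"
    if ks_usable:
        return "ks_only"
    return "incalculable"


def classify_pair(result: KaKsResult) -> str:
    return classify_rates(result.Ka, result.Ks)
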