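"""kaks_evolution: codon alignment, NG86/YN00 estimation, classification.

The NG86 site-count oracle is re-derived here by independent brute-force
enumeration of every sense codon's nine single-nucleotide changes.
"""

import math
from fractions import Fraction

import pytest
from scipy.stats import hypergeom

from kaksflow import (
    CodingSequence,
    CodonAlignment,
    CodonModelParams,
    ValidationError,
    apply_ks_filter,
    classify_pair,
    codon_align,
    fisher_validity,
    ng86,
    pair_stats,
    simulate_codon_pair,
    yn00,
)
from kaksflow.kaks_evolution import KaKsResult, classify_rates
from kaksflow._codon import translate_cds

GENETIC_CODE = {}  # independent oracle table, built from first principles below
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate((a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    GENETIC_CODE[_a + _b + _c] = _AAS[_i]


def oracle_site_counts(codon):
    """Brute-force NG86 sites: per position, synonymous fraction of the
    non-stop single-nucleotide changes."""
    s = Fraction(0)
    for pos in range(3):
        syn, denom = 0, 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            target = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[target] == "*":
                continue
            denom += 1
            syn += GENETIC_CODE[target] == GENETIC_CODE[codon]
        s += Fraction(syn, denom)
    return s


def _aln(nt_a, nt_b):
    ca = CodingSequence("a", "A", nt_a, translate_cds(nt_a))
    cb = CodingSequence("b", "B", nt_b, translate_cds(nt_b))
    return codon_align(ca, cb)


class TestCodonAlign:
    def test_identical_cds_gapless(self):
        aln = _aln("ATGGCTAAG", "ATGGCTAAG")
        assert aln.codons_a == aln.codons_b == ["ATG", "GCT", "AAG"]
        assert aln.gapless_len_nt == 9

    def test_gap_is_whole_codon(self):
        aln = _aln("ATGGCT", "ATGAAAGCT")
        assert aln.codons_a == ["ATG", "---", "GCT"]
        assert aln.codons_b == ["ATG", "AAA", "GCT"]

    def test_column_count_covers_longer_sequence(self):
        aln = _aln("ATGGCT", "ATGAAAGCTTGGCAT")
        assert 3 * len(aln.codons_a) >= 15

    def test_internal_stop_rejected(self):
        ca = CodingSequence("a", "A", "ATGTAAGCT", "M*A")
        cb = CodingSequence("b", "B", "ATGAAAGCT", "MKA")
        with pytest.raises(ValidationError):
            codon_align(ca, cb)

    def test_gapless_length_counts_doubly_ungapped_columns(self):
        aln = _aln("ATGGCT", "ATGAAAGCT")
        gc, gapless, _, _ = pair_stats(aln)
        assert gapless == 6


class TestNg86:
    def test_site_counts_match_enumeration_for_all_sense_codons(self):
        from kaksflow._codon import SENSE_CODONS, ng86_site_counts
        for codon in SENSE_CODONS:
            s, n = ng86_site_counts(codon)
            assert s == pytest.approx(float(oracle_site_counts(codon)), abs=1e-12)
            assert s + n == pytest.approx(3.0, abs=1e-12)
        assert oracle_site_counts("TTT") == Fraction(1, 3)

    def test_identical_sequences_incalculable(self):
        r = ng86(_aln("ATGGCTAAGTGC", "ATGGCTAAGTGC"))
        assert (r.Sd, r.Nd, r.Ka, r.Ks) == (0, 0, 0, 0)
        assert r.ratio is None and r.category == "incalculable"

    def test_omega_zero_simulation_gives_zero_ka(self):
        params = CodonModelParams(kappa=1.0, omega=0.0, t=0.5)
        a, b, counts = simulate_codon_pair(100, params, seed=3)
        assert counts.nonsynonymous == 0
        r = ng86(_aln(a.nt, b.nt))
        assert r.Nd == 0 and r.Ka == 0

    def test_single_synonymous_difference(self):
        # K -> K third-position transition among fourfold-degenerate context
        r = ng86(_aln("ATGAAACCCGGG", "ATGAAGCCCGGG"))
        assert r.Sd == 1 and r.Nd == 0 and r.Ka == 0 and r.Ks > 0


class TestYn00:
    def test_identical_sequences_zero_rates(self):
        r = yn00(_aln("ATGGCTAAGTGCCATGAA", "ATGGCTAAGTGCCATGAA"))
        assert r.Ka == 0 and r.Ks == 0 and r.category == "incalculable"
        assert r.converged

    def test_site_conservation_both_estimators(self, sim_results):
        for r in sim_results(0.5, "yn", n_reps=20)[:20]:
            assert r.S + r.N == pytest.approx(r.gapless_len_nt, abs=1e-6)
        for r in sim_results(0.5, "ng", n_reps=20)[:20]:
            assert r.S + r.N == pytest.approx(r.gapless_len_nt, abs=1e-6)

    def test_yn_sites_approach_ng_in_neutral_uniform_limit(self, sim_results):
        yn = sim_results(1.0, "yn", n_reps=100, n_codons=500, kappa=1.0)
        ng = sim_results(1.0, "ng", n_reps=100, n_codons=500, kappa=1.0)
        mean_yn = sum(r.S for r in yn) / len(yn)
        mean_ng = sum(r.S for r in ng) / len(ng)
        assert abs(mean_yn - mean_ng) / mean_ng < 0.02

    def test_sign_agreement_away_from_neutrality(self, sim_results):
        agree = total = 0
        for omega in (0.2, 0.5, 2.0):
            yn = sim_results(omega, "yn")
            ng = sim_results(omega, "ng")
            for ry, rn in zip(yn, ng):
                if ry.ratio is None or rn.ratio is None:
                    continue
                total += 1
                agree += (ry.ratio > 1) == (rn.ratio > 1)
        assert total > 300 and agree / total >= 0.95

    def test_mean_ratio_monotone_in_planted_omega(self, sim_results):
        for est in ("yn", "ng"):
            means = []
            for omega in (0.2, 0.5, 1.0, 2.0):
                rs = [r.ratio for r in sim_results(omega, est) if r.ratio is not None]
                means.append(sum(rs) / len(rs))
            assert means == sorted(means) and len(set(means)) == 4


class TestFisherValidity:
    def test_one_sided_example_by_enumeration(self):
        # table [[3,1],[1,3]]: P(a >= 3) under the hypergeometric with
        # margins (4,4)/(4,4) equals (C(4,3)C(4,1)+C(4,4)C(4,0))/C(8,4) = 17/70
        p_one = hypergeom.sf(2, 8, 4, 4)
        assert p_one == pytest.approx(17 / 70, abs=1e-12)
        # the two-sided validity p sums both tails of the same distribution
        p_two = fisher_validity(4, 4, 3, 1)
        enum = sum(hypergeom.pmf(k, 8, 4, 4) for k in range(5)
                   if hypergeom.pmf(k, 8, 4, 4) <= hypergeom.pmf(3, 8, 4, 4) * (1 + 1e-9))
        assert p_two == pytest.approx(enum, abs=1e-9)

    def test_no_signal_gives_p_one(self):
        assert fisher_validity(100, 200, 0, 0) == 1.0

    def test_row_swap_symmetry(self):
        assert fisher_validity(30, 60, 5, 20) == pytest.approx(
            fisher_validity(60, 30, 20, 5), abs=1e-12)

    def test_substitutions_cannot_exceed_sites(self):
        with pytest.raises(ValidationError):
            fisher_validity(3, 10, 4, 1)


def _result(ka, ks):
    return KaKsResult("p", "yn00", 100, 200, 1, 1, ka, ks,
                      None if ks in (None, 0) or ka is None else ka / ks,
                      2.0, 0.4, 300, 1.0, classify_rates(ka, ks))


class TestKsFilterAndClassification:
    @pytest.mark.parametrize("ks,kept", [(0.12, False), (0.10, True), (None, True)])
    def test_ks_filter_strict_boundary(self, ks, kept):
        retained, excluded = apply_ks_filter([_result(0.01, ks)])
        assert (len(retained) == 1) == kept

    @pytest.mark.parametrize("ka,ks,category", [
        (0.02, 0.01, "positive"),
        (0.007, 0.01, "weak_purifying"),
        (0.005, 0.01, "purifying"),
        (0.01, None, "ka_only"),
        (0.01, 0.0, "ka_only"),
        (0.0, 0.01, "ks_only"),
        (None, 0.01, "ks_only"),
        (0.0, 0.0, "incalculable"),
        (None, None, "incalculable"),
        (0.01, 0.01, "weak_purifying"),  # ratio exactly 1 is not positive
    ])
    def test_category_rules(self, ka, ks, category):
        assert classify_pair(_result(ka, ks)) == category

    def test_planted_decoys_all_removed_by_ks_filter(self, analyzed_fixture):
        fx = analyzed_fixture["fixture"]
        decoys = {t.id_a for t in fx.truth if t.role == "paralog_decoy"}
        dropped = {r.pair_id.split("|")[0] for r in analyzed_fixture["ks_dropped"]}
        assert decoys <= dropped
        kept = {r.pair_id.split("|")[0] for r in analyzed_fixture["kept_results"]}
        assert not decoys & kept


class TestPairStats:
    def test_all_gc_alignment(self):
        gc, _, _, _ = pair_stats(_aln("GGGCCC", "GGGCCC"))
        assert gc == 1.0

    def test_atg_pair_gc_third(self):
        gc, gapless, _, _ = pair_stats(_aln("ATG", "ATG"))
        assert gc == pytest.approx(1 / 3) and gapless == 3
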