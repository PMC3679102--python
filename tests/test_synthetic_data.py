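"""synthetic_data: the codon-pair simulator and the planted-truth fixtures."""

import numpy as np
import pytest

from kaksflow import (
    CodonModelParams,
    ParameterError,
    generate_reads,
    generate_transcriptome_fixture,
    simulate_codon_pair,
)
from kaksflow._codon import SENSE_CODONS, is_synonymous, ng86_site_counts
from kaksflow.synthetic_data import _CodonProcess


class TestSimulateCodonPair:
    def test_zero_branch_length_identical(self):
        params = CodonModelParams(t=0.0)
        a, b, counts = simulate_codon_pair(50, params, seed=4)
        assert a.nt == b.nt and counts.total == 0

    def test_omega_zero_forbids_nonsynonymous(self):
        params = CodonModelParams(omega=0.0, t=0.5)
        a, b, counts = simulate_codon_pair(500, params, seed=5)
        assert counts.nonsynonymous == 0 and counts.synonymous > 0
        assert a.protein == b.protein

    def test_outputs_stop_free_and_full_length(self):
        a, b, _ = simulate_codon_pair(120, CodonModelParams(t=1.0), seed=6)
        assert len(a.nt) == len(b.nt) == 360
        assert "*" not in a.protein and "*" not in b.protein

    @pytest.mark.parametrize("kwargs", [
        dict(n_codons=0), dict(t=-0.1), dict(omega=-1.0), dict(kappa=0.0)])
    def test_parameter_validation(self, kwargs):
        n = kwargs.pop("n_codons", 10)
        with pytest.raises(ParameterError):
            simulate_codon_pair(n, CodonModelParams(**{"t": 0.1, **kwargs}), seed=1)

    def test_codon_freqs_must_sum_to_one(self):
        bad = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        bad[0] += 1e-6
        with pytest.raises(ParameterError):
            CodonModelParams(codon_freqs=bad)

    def test_determinism(self):
        params = CodonModelParams(t=0.3)
        out1 = simulate_codon_pair(80, params, seed=42)
        out2 = simulate_codon_pair(80, params, seed=42)
        assert out1[0].nt == out2[0].nt and out1[1].nt == out2[1].nt

    def test_event_counts_match_hamming_decomposition_at_low_t(self):
        # with at most one event per codon, realised counts must equal the
        # direct syn/nonsyn classification of the observed codon differences
        params = CodonModelParams(kappa=2.0, omega=1.0, t=0.02)
        a, b, counts = simulate_codon_pair(200, params, seed=11)
        assert max(counts.per_codon) <= 1, "seed chosen for <=1 event per codon"
        syn = nonsyn = 0
        for i in range(200):
            ca, cb = a.nt[3 * i:3 * i + 3], b.nt[3 * i:3 * i + 3]
            if ca != cb:
                assert sum(x != y for x, y in zip(ca, cb)) == 1
                syn += is_synonymous(ca, cb)
                nonsyn += not is_synonymous(ca, cb)
        assert (syn, nonsyn) == (counts.synonymous, counts.nonsynonymous)

    def test_neutral_symmetric_event_fractions_match_site_proportions(self):
        # kappa=1, omega=1, uniform frequencies: the realised synonymous event
        # fraction equals the NG86 mean synonymous site proportion (exact flux
        # fraction 0.2548 vs site fraction 0.2550) within Monte-Carlo error
        params = CodonModelParams(kappa=1.0, omega=1.0, t=2.0)
        tot = syn = 0
        for i in range(20):
            _, _, c = simulate_codon_pair(400, params, seed=800 + i)
            tot += c.total
            syn += c.synonymous
        assert tot >= 10_000
        expected = np.mean([ng86_site_counts(c)[0] for c in SENSE_CODONS]) / 3.0
        sigma = np.sqrt(expected * (1 - expected) / tot)
        assert abs(syn / tot - expected) < 4 * sigma + 0.005

    def test_rates_are_reversible_with_stationary_codon_freqs(self):
        # detailed balance of the jump process: pi_i q_ij == pi_j q_ji
        params = CodonModelParams(kappa=3.0, omega=0.4, t=0.1)
        proc = _CodonProcess(params)
        pi = params.codon_freqs
        for i in range(0, len(SENSE_CODONS), 7):
            for k, j in enumerate(proc.targets[i]):
                back = list(proc.targets[j]).index(i)
                assert pi[i] * proc.rates[i][k] == pytest.approx(
                    pi[j] * proc.rates[j][back], rel=1e-9)


class TestTranscriptomeFixture:
    def test_empty_fixture(self):
        fx = generate_transcriptome_fixture(0, 0, 0, [0.2], seed=1)
        assert fx.records_a == [] and fx.records_b == [] and fx.truth == []

    def test_truth_bookkeeping(self):
        fx = generate_transcriptome_fixture(10, 0, 0, [0.2], seed=2)
        assert len(fx.truth) == 10
        assert all(t.true_omega == 0.2 and t.role == "ortholog" for t in fx.truth)

    def test_roles_counts(self):
        fx = generate_transcriptome_fixture(4, 3, 2, [0.2, 2.0], seed=3,
                                            n_short_overlap=1)
        roles = [t.role for t in fx.truth]
        assert roles.count("ortholog") == 4 and roles.count("paralog_decoy") == 3
        assert roles.count("stop_contaminant") == 2 and roles.count("short_overlap") == 1

    def test_contaminants_carry_internal_stop_in_planted_frame(self):
        from kaksflow import as_cds
        fx = generate_transcriptome_fixture(0, 0, 3, [0.2], seed=4)
        by_id = {r.id: r for r in fx.records_b}
        for t in fx.truth:
            assert "*" in as_cds(by_id[t.id_b], "B").protein

    def test_write_round_trip(self, tmp_path):
        from kaksflow import read_annotation_table, read_fasta
        fx = generate_transcriptome_fixture(5, 1, 1, [0.2, 2.0], seed=5)
        paths = fx.write(tmp_path)
        assert len(read_fasta(paths["fasta_a"])) == 7
        back = read_annotation_table(paths["annotations"])
        for t in fx.truth:
            assert back.categories_of(t.id_a) == t.go_ids


@pytest.fixture(scope="module")
def read_fixture():
    return generate_transcriptome_fixture(6, 0, 0, [0.2], seed=6)


class TestGenerateReads:

    def test_error_free_reads_are_exact_substrings(self, read_fixture):
        reads = generate_reads(read_fixture, "A", "control", 200, read_len=50,
                               error_rate=0.0, seed=7)
        genes = {r.id: r.seq for r in read_fixture.records_a}
        for read in reads:
            source = read.id.split("|")[1]
            assert read.seq in genes[source]

    def test_abundance_proportional_sampling(self):
        # two equal-length genes at relative abundance 1:3
        fx = generate_transcriptome_fixture(2, 0, 0, [0.2], seed=8,
                                            codon_len_range=(200, 200))
        fx.truth[0].expression_control["A"] = 1.0
        fx.truth[1].expression_control["A"] = 3.0
        n = 40_000
        reads = generate_reads(fx, "A", "control", n, seed=9)
        n_second = sum(1 for r in reads if r.id.split("|")[1] == fx.truth[1].id_a)
        p = 0.75
        assert abs(n_second - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_seeded_fastq_bytes_identical(self, read_fixture, tmp_path):
        from kaksflow import write_fastq
        for tag in ("x", "y"):
            reads = generate_reads(read_fixture, "B", "stress", 100, seed=10)
            write_fastq(reads, tmp_path / f"{tag}.fastq")
        assert (tmp_path / "x.fastq").read_bytes() == (tmp_path / "y.fastq").read_bytes()

    def test_read_len_longer_than_every_gene_rejected(self, read_fixture):
        with pytest.raises(ParameterError):
            generate_reads(read_fixture, "A", "control", 10, read_len=10_000, seed=1)

    def test_error_positions_get_low_quality(self, read_fixture):
        reads = generate_reads(read_fixture, "A", "stress", 300, error_rate=0.05,
                               seed=12)
        genes = {r.id: r.seq for r in read_fixture.records_a}
        mismatched = 0
        for read in reads:
            _, gid, start = read.id.split("|")
            ref = genes[gid][int(start):int(start) + len(read.seq)]
            for q, rb, gb in zip(read.qualities, read.seq, ref):
                if rb != gb:
                    mismatched += 1
                    assert q == 10
                else:
                    assert q == 40
        assert mismatched > 0
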