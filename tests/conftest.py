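"""Shared fixtures: cached simulation batches and a pipeline-scale fixture.

The Monte-Carlo batches (replicated codon-pair simulations plus estimator
results) and the end-to-end transcriptome fixture are expensive, so they are
built once per session and shared across tests.
"""

from __future__ import annotations

import pytest

import kaksflow as kf
from kaksflow.synthetic_data import DEFAULT_OMEGA_GRID

_ALN_CACHE: dict = {}
_RESULT_CACHE: dict = {}


def _alignments(omega, n_reps, n_codons, t, kappa, base_seed):
    key = (omega, n_reps, n_codons, t, kappa, base_seed)
    if key not in _ALN_CACHE:
        alns = []
        for i in range(n_reps):
            params = kf.CodonModelParams(kappa=kappa, omega=omega, t=t)
            a, b, _ = kf.simulate_codon_pair(
                n_codons, params, seed=base_seed + 1000 * int(omega * 100) + i)
            alns.append(kf.codon_align(a, b))
        _ALN_CACHE[key] = alns
    return _ALN_CACHE[key]


@pytest.fixture(scope="session")
def sim_results():
    """Factory: estimator results on replicated simulations, cached.

    sim_results(omega, estimator="yn", n_reps=200, n_codons=300, t=0.1,
    kappa=2.0) -> list[KaKsResult]
    """

    def get(omega, estimator="yn", n_reps=200, n_codons=300, t=0.1,
            kappa=2.0, base_seed=20_000_000):
        key = (omega, estimator, n_reps, n_codons, t, kappa, base_seed)
        if key not in _RESULT_CACHE:
            fn = kf.yn00 if estimator == "yn" else kf.ng86
            alns = _alignments(omega, n_reps, n_codons, t, kappa, base_seed)
            _RESULT_CACHE[key] = [fn(a) for a in alns]
        return _RESULT_CACHE[key]

    return get


def pooled_ratio(results) -> float:
    """Replicate-level omega: mean Ka over mean Ks (both defined)."""
    kas = [r.Ka for r in results if r.Ka is not None and r.Ks is not None]
    kss = [r.Ks for r in results if r.Ka is not None and r.Ks is not None]
    return sum(kas) / len(kas) / (sum(kss) / len(kss))


@pytest.fixture(scope="session")
def transcriptome_fixture():
    """60 orthologs (6 planted positive), 5 decoys, 3 contaminants, 5 short."""
    return kf.generate_transcriptome_fixture(
        60, 5, 3, list(DEFAULT_OMEGA_GRID), seed=1, n_short_overlap=5)


@pytest.fixture(scope="session")
def analyzed_fixture(transcriptome_fixture):
    """The fixture pushed through BBH, filters, yn00 and the Ks filter."""
    fx = transcriptome_fixture
    cds_a = [kf.as_cds(r, "A") for r in fx.records_a]
    cds_b = [kf.as_cds(r, "B") for r in fx.records_b]
    by_id = {c.id: c for c in cds_a + cds_b}
    pairs = kf.find_bbh(cds_a, cds_b)
    for p in pairs:
        p.codon_alignment = kf.codon_align(
            by_id[p.id_a], by_id[p.id_b], pair_id=p.pair_id,
            allow_internal_stop=True)
    retained, excluded = kf.filter_ortholog_pairs(pairs)
    results = [kf.yn00(p.codon_alignment) for p in retained]
    kept, ks_dropped = kf.apply_ks_filter(results)
    return {
        "fixture": fx,
        "pairs": pairs,
        "retained": retained,
        "excluded": excluded,
        "kept_results": kept,
        "ks_dropped": ks_dropped,
    }
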