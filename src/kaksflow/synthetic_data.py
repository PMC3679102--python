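"""Synthetic codon-evolution fixtures with planted ground truth.

``simulate_codon_pair`` evolves an ancestral codon sequence along two
symmetric lineages (t/2 each) under a GY94-style continuous-time model: only
single-nucleotide codon changes have positive rate, the rate into codon j is
proportional to pi_j * kappa^[transition] * omega^[nonsynonymous], and changes
into stop codons are forbidden.  Rates are normalised so that ``t`` is the
expected number of substitutions per codon along the whole pair-path.  The
model matches the assumptions of the YN00 estimator by design, which makes
parameter recovery a fair end-to-end check.

``generate_transcriptome_fixture`` builds two species' "unigene" sets with
planted ortholog pairs (omega cycled from a grid), deep-diverged paralog
decoy pairs (expected Ks > 0.1), stop-codon contaminants, short-overlap
truncations, GO labels with one category enriched among omega > 1 pairs, and
per-species control/stress expression abundances.  ``generate_reads`` samples
error-bearing Phred+33 reads from those genes, gene-proportionally to
abundance x length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codon import CODON_INDEX, SENSE_CODONS, is_synonymous, is_transition, translate_cds
from .errors import ParameterError
from .io_formats import AnnotationTable, SequenceRecord, write_annotation_table, write_fasta, write_fastq
from .orthology import CodingSequence

ROLES = ("ortholog", "paralog_decoy", "stop_contaminant", "short_overlap")

# Stylized genome-wide omega mixture: mostly purifying selection with a ~10%
# positively selected tail, cycled over the fixture's ortholog pairs.
DEFAULT_OMEGA_GRID = (0.1, 0.2, 0.2, 0.3, 0.3, 0.4, 0.5, 0.5, 0.5, 2.0)

_N_SENSE = len(SENSE_CODONS)


@dataclass
class CodonModelParams:
    """GY94-style codon substitution parameters.

    kappa: transition/transversion rate ratio (> 0); omega: nonsynonymous/
    synonymous rate ratio (>= 0); t: expected substitutions per codon along
    the whole pair-path (>= 0); codon_freqs: probability vector over the 61
    sense codons (uniform by default; stop codons implicitly zero).
    """

    kappa: float = 2.0
    omega: float = 0.3
    t: float = 0.04
    codon_freqs: np.ndarray = field(
        default_factory=lambda: np.full(_N_SENSE, 1.0 / _N_SENSE))

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega < 0 or self.t < 0:
            raise ParameterError("require kappa > 0, omega >= 0, t >= 0")
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (_N_SENSE,) or (self.codon_freqs < 0).any():
            raise ParameterError(f"codon_freqs must be a non-negative vector of length {_N_SENSE}")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ParameterError("codon_freqs must sum to 1 within 1e-9")


@dataclass
class SubstitutionCounts:
    """Realised event counts over both lineages of a simulated pair."""

    synonymous: int = 0
    nonsynonymous: int = 0
    transitions: int = 0
    transversions: int = 0
    per_codon: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.synonymous + self.nonsynonymous


class _CodonProcess:
    """Precomputed jump rates for one parameter set."""

    def __init__(self, params: CodonModelParams):
        pi = params.codon_freqs
        self.targets: list[np.ndarray] = []
        self.rates: list[np.ndarray] = []
        self.meta: list[list[tuple[bool, bool]]] = []  # (synonymous, transition)
        out_rate = np.zeros(_N_SENSE)
        for i, codon in enumerate(SENSE_CODONS):
            tgt, rate, meta = [], [], []
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    target = codon[:pos] + base + codon[pos + 1:]
                    j = CODON_INDEX.get(target)
                    if j is None:  # stop codon: forbidden
                        continue
                    ts = is_transition(codon[pos], base)
                    syn = is_synonymous(codon, target)
                    r = pi[j] * (params.kappa if ts else 1.0) * (1.0 if syn else params.omega)
                    tgt.append(j)
                    rate.append(r)
                    meta.append((syn, ts))
            self.targets.append(np.array(tgt))
            self.rates.append(np.array(rate))
            self.meta.append(meta)
            out_rate[i] = float(np.sum(rate))
        mean_rate = float(pi @ out_rate)
        if mean_rate > 0:
            self.rates = [r / mean_rate for r in self.rates]
        self.out_rate = out_rate / mean_rate if mean_rate > 0 else out_rate
        # per-codon cumulative jump distribution for inverse-cdf sampling
        self.cum = [np.cumsum(r) / r.sum() if r.sum() > 0 else np.cumsum(r)
                    for r in self.rates]


def _evolve_codon(i: int, duration: float, proc: _CodonProcess,
                  rng: np.random.Generator, counts: SubstitutionCounts,
                  codon_idx: int) -> int:
    remaining = duration
    while True:
        total = proc.out_rate[i]
        if total <= 0:
            return i
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return i
        remaining -= wait
        k = int(np.searchsorted(proc.cum[i], rng.random()))
        syn, ts = proc.meta[i][k]
        counts.synonymous += syn
        counts.nonsynonymous += not syn
        counts.transitions += ts
        counts.transversions += not ts
        counts.per_codon[codon_idx] += 1
        i = int(proc.targets[i][k])


def simulate_codon_pair(
    n_codons: int,
    params: CodonModelParams,
    seed: int,
    id_prefix: str = "sim",
) -> tuple[CodingSequence, CodingSequence, SubstitutionCounts]:
    """Evolve one ortholog pair from a common ancestor (t/2 per lineage).

    The ancestor is drawn from codon_freqs; both outputs are stop-free with
    length 3 * n_codons.  The seed is mandatory: all randomness flows through
    one numpy Generator.
    """
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    proc = _CodonProcess(params)
    counts = SubstitutionCounts(per_codon=[0] * n_codons)
    ancestor = rng.choice(_N_SENSE, size=n_codons, p=params.codon_freqs)
    half = params.t / 2.0
    seq_a, seq_b = [], []
    for idx, anc in enumerate(ancestor):
        seq_a.append(_evolve_codon(int(anc), half, proc, rng, counts, idx))
        seq_b.append(_evolve_codon(int(anc), half, proc, rng, counts, idx))
    nt_a = "".join(SENSE_CODONS[i] for i in seq_a)
    nt_b = "".join(SENSE_CODONS[i] for i in seq_b)
    cds_a = CodingSequence(f"{id_prefix}_a", "A", nt_a, translate_cds(nt_a))
    cds_b = CodingSequence(f"{id_prefix}_b", "B", nt_b, translate_cds(nt_b))
    return cds_a, cds_b, counts


@dataclass
class FixtureTruth:
    """Planted ground truth for one pair in the fixture."""

    pair_id: str
    id_a: str
    id_b: str
    role: str
    true_omega: float
    true_t: float
    go_ids: frozenset[str]
    expression_control: dict[str, float]  # species -> relative abundance
    expression_stress: dict[str, float]


@dataclass
class TranscriptomeFixture:
    """Two species' gene sets plus annotations and planted truth."""

    records_a: list[SequenceRecord]
    records_b: list[SequenceRecord]
    annotations: AnnotationTable
    truth: list[FixtureTruth]
    enriched_category: str

    def truth_by_role(self, role: str) -> list[FixtureTruth]:
        return [t for t in self.truth if t.role == role]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta_a": out / "species_a.fasta",
            "fasta_b": out / "species_b.fasta",
            "annotations": out / "go_annotations.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.records_a, paths["fasta_a"])
        write_fasta(self.records_b, paths["fasta_b"])
        write_annotation_table(self.annotations, paths["annotations"])
        with open(paths["truth"], "w") as fh:
            fh.write("pair_id\tid_a\tid_b\trole\ttrue_omega\ttrue_t\tgo_ids\t"
                     "control_a\tcontrol_b\tstress_a\tstress_b\n")
            for t in self.truth:
                fh.write(
                    f"{t.pair_id}\t{t.id_a}\t{t.id_b}\t{t.role}\t"
                    f"{t.true_omega:.6f}\t{t.true_t:.6f}\t"
                    f"{','.join(sorted(t.go_ids)) or '-'}\t"
                    f"{t.expression_control['A']:.6f}\t{t.expression_control['B']:.6f}\t"
                    f"{t.expression_stress['A']:.6f}\t{t.expression_stress['B']:.6f}\n"
                )
        return paths


def generate_transcriptome_fixture(
    n_orthologs: int,
    n_decoys: int,
    n_contaminants: int,
    omega_grid: list[float],
    seed: int,
    n_short_overlap: int = 0,
    kappa: float = 2.0,
    t_ortholog: float = 0.04,
    t_decoy: float = 0.8,
    codon_len_range: tuple[int, int] = (150, 300),
    short_overlap_codons: int = 45,
    n_categories: int = 12,
    enriched_category: str = "GO:0000999",
    n_up_both: int | None = None,
    n_up_a_only: int | None = None,
    n_up_b_only: int | None = None,
    stress_fold: float = 4.0,
) -> TranscriptomeFixture:
    """Build a two-species transcriptome fixture with planted truth.

    Ortholog pairs take omega values cycled from omega_grid at divergence
    t_ortholog (chosen so that expected Ks stays well under the 0.1 paralog
    cut).  Decoys are independent pairs diverged at t_decoy (expected Ks >
    0.1, the old-duplication analog).  Contaminants carry one internal stop
    codon planted mid-sequence in species B.  Short-overlap pairs have the
    species-B copy truncated to short_overlap_codons codons (alignable span
    <= 135 nt < 150).  The enriched GO category is attached to most omega > 1
    ortholog pairs and rarely elsewhere; stress/control abundances plant the
    up-both / up-A-only / up-B-only expression pattern at stress_fold.
    """
    if min(n_orthologs, n_decoys, n_contaminants, n_short_overlap) < 0:
        raise ParameterError("counts must be >= 0")
    if not omega_grid:
        raise ParameterError("omega_grid must be non-empty")
    rng = np.random.default_rng(seed)

    records_a: list[SequenceRecord] = []
    records_b: list[SequenceRecord] = []
    annotations = AnnotationTable()
    truth: list[FixtureTruth] = []
    categories = [f"GO:{i:07d}" for i in range(1, n_categories + 1)]

    def new_pair(omega: float, t: float):
        n_cod = int(rng.integers(codon_len_range[0], codon_len_range[1] + 1))
        params = CodonModelParams(kappa=kappa, omega=omega, t=t)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cds_a, cds_b, _ = simulate_codon_pair(n_cod, params, sub_seed)
        return cds_a.nt, cds_b.nt

    def assign_go(omega: float) -> frozenset[str]:
        gos = set(rng.choice(categories, size=int(rng.integers(1, 4)),
                             replace=False).tolist())
        p_enriched = 0.8 if omega > 1 else 0.05
        if rng.random() < p_enriched:
            gos.add(enriched_category)
        return frozenset(gos)

    specs: list[tuple[str, float, float]] = []
    for k in range(n_orthologs):
        specs.append(("ortholog", float(omega_grid[k % len(omega_grid)]), t_ortholog))
    specs += [("paralog_decoy", 0.3, t_decoy)] * n_decoys
    specs += [("stop_contaminant", 0.3, t_ortholog)] * n_contaminants
    specs += [("short_overlap", 0.3, t_ortholog)] * n_short_overlap

    # expression planting: designated up-regulated pairs among the orthologs.
    # Defaults mirror a small salt-stress concordance pattern (1 shared, 4
    # species-A-only, 3 species-B-only), clamped to the orthologs available;
    # explicitly requested counts beyond the ortholog total are an error.
    explicit = n_up_both is not None or n_up_a_only is not None or n_up_b_only is not None
    if n_up_both is None:
        n_up_both = 1
    if n_up_a_only is None:
        n_up_a_only = 4
    if n_up_b_only is None:
        n_up_b_only = 3
    ortho_ids = list(range(n_orthologs))
    need = n_up_both + n_up_a_only + n_up_b_only
    if need > n_orthologs:
        if explicit:
            raise ParameterError("more planted up-regulated pairs than orthologs")
        n_up_both = min(n_up_both, n_orthologs)
        n_up_a_only = min(n_up_a_only, n_orthologs - n_up_both)
        n_up_b_only = min(n_up_b_only, n_orthologs - n_up_both - n_up_a_only)
        need = n_up_both + n_up_a_only + n_up_b_only
    # prefer positively selected pairs for the planted regulation, as in a
    # PSG-focused expression survey; pad with the remaining orthologs
    pos_first = sorted(ortho_ids, key=lambda k: -float(omega_grid[k % len(omega_grid)]))
    chosen = pos_first[:need]
    up_both = set(chosen[:n_up_both])
    up_a = set(chosen[n_up_both:n_up_both + n_up_a_only])
    up_b = set(chosen[n_up_both + n_up_a_only:need])

    for k, (role, omega, t) in enumerate(specs):
        nt_a, nt_b = new_pair(omega, t)
        if role == "stop_contaminant":
            # plant one internal stop mid-sequence in the B copy
            mid = (len(nt_b) // 6) * 3
            nt_b = nt_b[:mid] + "TAA" + nt_b[mid + 3:]
        elif role == "short_overlap":
            nt_b = nt_b[: 3 * short_overlap_codons]
        id_a, id_b = f"A{k:05d}", f"B{k:05d}"
        pair_id = f"P{k:05d}"
        records_a.append(SequenceRecord(id_a, nt_a))
        records_b.append(SequenceRecord(id_b, nt_b))

        gos = assign_go(omega) if role == "ortholog" else assign_go(0.0)
        for go in gos:
            annotations.add(id_a, go)

        base_a = float(rng.lognormal(0.0, 0.5))
        base_b = float(rng.lognormal(0.0, 0.5))
        fold_a = fold_b = 1.0
        if role == "ortholog":
            if k in up_both:
                fold_a = fold_b = stress_fold
            elif k in up_a:
                fold_a = stress_fold
            elif k in up_b:
                fold_b = stress_fold
        truth.append(FixtureTruth(
            pair_id, id_a, id_b, role, omega, t, gos,
            {"A": base_a, "B": base_b},
            {"A": base_a * fold_a, "B": base_b * fold_b},
        ))

    return TranscriptomeFixture(records_a, records_b, annotations, truth,
                                enriched_category)


def generate_reads(
    fixture: TranscriptomeFixture,
    species: str,
    condition: str,
    n_reads: int,
    read_len: int = 75,
    error_rate: float = 0.005,
    seed: int = 0,
    base_quality: int = 40,
    error_quality: int = 10,
) -> list[SequenceRecord]:
    """Sample forward-strand reads from one species' genes.

    Genes are drawn proportionally to abundance x gene length, start positions
    uniformly; substitution errors occur at error_rate per base and carry
    error_quality instead of base_quality.  Genes shorter than read_len get
    zero weight; if every gene is shorter, a ParameterError is raised.
    """
    if condition not in ("control", "stress"):
        raise ParameterError(f"condition must be control or stress, got {condition!r}")
    if species not in ("A", "B"):
        raise ParameterError(f"species must be A or B, got {species!r}")
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = fixture.records_a if species == "A" else fixture.records_b
    abundances = {
        (t.id_a if species == "A" else t.id_b):
            (t.expression_control if condition == "control" else t.expression_stress)[species]
        for t in fixture.truth
    }
    genes = [r for r in records if len(r.seq) >= read_len]
    if not genes:
        raise ParameterError("read_len is longer than every gene")
    weights = np.array([abundances.get(g.id, 0.0) * len(g.seq) for g in genes])
    if weights.sum() <= 0:
        raise ParameterError("all gene sampling weights are zero")
    weights = weights / weights.sum()

    alt = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    reads: list[SequenceRecord] = []
    gene_idx = rng.choice(len(genes), size=n_reads, p=weights)
    for i, gi in enumerate(gene_idx):
        gene = genes[int(gi)]
        start = int(rng.integers(0, len(gene.seq) - read_len + 1))
        seq = list(gene.seq[start:start + read_len])
        quals = [base_quality] * read_len
        if error_rate > 0:
            err_pos = np.nonzero(rng.random(read_len) < error_rate)[0]
            for p in err_pos:
                seq[p] = alt[seq[p]][int(rng.integers(0, 3))] if seq[p] in alt else "N"
                quals[int(p)] = error_quality
        reads.append(SequenceRecord(
            f"{condition}_{i:06d}|{gene.id}|{start}", "".join(seq), quals))
    return reads
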