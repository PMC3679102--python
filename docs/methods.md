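# Methods

This note documents the models, estimators, numerical choices and known
limitations of `kaksflow`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Codon substitution model (simulator)

`synthetic_data.simulate_codon_pair` evolves each codon independently under a
GY94-style continuous-time Markov process on the 61 sense codons of the
universal code. Only single-nucleotide changes have positive rate; the rate
from codon *i* to codon *j* is

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],

with changes into stop codons forbidden. The chain is reversible with
stationary distribution π (the `codon_freqs` parameter, uniform over the 61
sense codons by default). Rates are normalised so that the divergence
parameter *t* is the expected number of substitutions per codon along the
whole pair-path; the ancestor is drawn from π and each lineage evolves for
*t*/2, making the two species exchangeable. The model deliberately matches
the assumptions of the YN00 estimator, so parameter recovery is a fair
end-to-end check of the estimation code rather than of model mismatch.

Defaults: κ = 2 (a typical plant nuclear transcriptome value), ω = 0.3,
*t* = 0.04 for fixture orthologs. The ortholog divergence is set well below
the Ks ≤ 0.1 paralog cut (expected Ks ≈ 0.02) so that genuine orthologs are
never lost to filter iv; paralog decoys use *t* = 0.8 (expected Ks ≫ 0.1).
The fixture's ω grid default is a stylized genome-wide mixture,
(0.1, 0.2, 0.2, 0.3, 0.3, 0.4, 0.5, 0.5, 0.5, 2.0): mostly purifying with a
10% positively selected tail.

What the generator does **not** emulate: indels, assembly and clustering
errors, sequencing-quality gradients along reads, paired-end structure,
codon-usage heterogeneity across genes, and selection variation among sites
within a gene. Passing tests therefore demonstrate correctness of the
estimators and filters under their own model assumptions, not robustness to
every artefact of real transcriptome assemblies.

## NG86 counting

Synonymous sites per codon are obtained by enumerating all nine
single-nucleotide changes; each position contributes the fraction of its
non-stop changes that are synonymous (changes to stops are excluded from the
denominator), so S + N = 3 per codon exactly and, summed over ungapped
columns (averaged across the two sequences), S + N equals the gapless
alignment length. Codon pairs differing at more than one position are
decomposed by averaging, with equal weight, over all minimal substitution
paths that avoid stop codons (if every ordering passes through a stop, all
orderings are kept and stop-touching steps count as nonsynonymous — a rare
degenerate case). Distances use the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)·p), undefined when the argument is non-positive.

## YN00 approximate estimator

1. **Codon frequencies.** F3×4: position-specific nucleotide frequencies
   estimated from both sequences' aligned codons, floored at 1e−6 and
   renormalised to avoid zero-rate pathways.
2. **κ.** Estimated from positions whose degeneracy class — fourfold
   degenerate or nondegenerate — agrees between the two sequences. At such
   positions every change is wholly synonymous or wholly nonsynonymous, so ω
   cancels from the transition/transversion contrast. Counts are pooled
   across the two classes and stabilised with add-half smoothing (+0.5
   transitions, +1 transversions, preserving the κ = 1 null ratio) before a
   single K2P inversion; the estimate is clamped to [0.2, 20]. Pooling and
   smoothing are variance/bias controls for the low-divergence regime, where
   per-class transversion counts are single digits and the raw ratio
   estimator is strongly Jensen-skewed.
3. **Sites.** Per codon, the synonymous site count is 3 × (synonymous
   mutation flux)/(total flux) with flux weights π_target · κ^[transition],
   stops excluded; averaged over the two sequences per column. S + N equals
   the gapless length by construction.
4. **Differences.** Codon-pair differences are decomposed over minimal
   substitution paths weighted by the product of per-step rates
   π_target · κ^[ts] · ω^[nonsyn], tracking synonymous/nonsynonymous ×
   transition/transversion counts.
5. **Distances and iteration.** Ks and Ka use the K2P correction
   d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q) applied separately to the
   synonymous and nonsynonymous proportions. ω = Ka/Ks feeds back into the
   pathway weighting (initial ω = 1) and the loop runs to a 1e−6 fixed
   point, capped at 100 iterations; non-convergence is flagged on the
   result, never raised. Out-of-domain logarithms yield undefined (None)
   rates.

**Aggregation over replicates.** When an ω is reported for a *set* of
simulated pairs (tests, acceptance script), the pooled estimator
mean(Ka)/mean(Ks) is used. The per-pair ratio has only a handful of
synonymous events in its denominator at low divergence, so the plain mean of
ratios is Jensen-biased upward; pooling removes that bias while remaining a
pure function of the estimator outputs.

## Per-pair Fisher validity test

A two-sided Fisher exact test on the 2×2 table
[[Sd, S − Sd], [Nd, N − Nd]] flags pairs whose Ka/Ks contrast rests on too
little signal. Fractional sites and substitutions are rounded half away from
zero; in the degenerate case where path-averaged substitutions exceed the
fractional site count the table is clipped (the corresponding rate is
undefined there regardless).

## Orthology and filters

- **ORF extraction** (default mode): the longest ATG-initiated stop-free ORF
  across all six frames, minimum 150 nt, ties preferring the forward strand
  then the smaller start. A *trust-frame* mode (`assume_cds`) instead takes
  each sequence as an in-frame CDS and preserves internal stops as `*` so
  that downstream filtering can catch planted contaminants; fixture runs use
  this mode, since a longest-ORF scan would silently route around a
  mid-sequence stop.
- **BBH**: exact pairwise local alignment (BLOSUM62; BLAST-style affine gap
  cost 11 + k) via Biopython's PairwiseAligner; a pair is reported when each
  member is the other's best hit (score ties broken by larger aligned
  overlap, then lexicographic id) and the raw score exceeds 50 — a floor
  calibrated so unrelated fixture proteins never reach it. Raw scores stand
  in for bit scores because Karlin–Altschul statistics are not reproduced.
- **Filters**, applied in order with the first failing rule reported as the
  exclusion reason: (i) overlap — strictly more than 150 bp of aligned
  sequence required; (ii) coverage — both sequences ≥ 90% covered (boundary
  inclusive); (iii) stop/ambiguous — any stop codon in the codon alignment,
  or more than 20% gap columns (the automated stand-in for a manual
  alignment check); (iv) Ks — after estimation, pairs with defined Ks
  strictly greater than 0.1 are excluded as likely paralogs; undefined-Ks
  pairs are retained and classified Ka-only/incalculable.
- **Classification**: positive (ratio > 1), weak purifying (0.5 < ratio ≤ 1,
  half-open — a ratio of exactly 1 is not positive), purifying
  (0 < ratio ≤ 0.5), Ka-only (usable Ka, Ks zero or undefined), Ks-only
  (symmetric), incalculable. Ks = 0 with Ka > 0 maps to Ka-only rather than
  an infinite ratio.

At fixture divergence (*t* = 0.04, roughly 8–12 substitutions per gene) the
positive call is intrinsically noisy: a genuinely positive pair has ~1–2
expected synonymous events and lands in Ka-only whenever none occurs, while
mid-ω pairs occasionally cross ratio > 1. This mirrors the Ka-only class of
real low-divergence ortholog surveys and is why pipeline-level tests assert
audit and bookkeeping properties rather than exact equality of the called
and planted positive sets.

## GO enrichment

One-sided (over-representation) Fisher exact test per category on the 2×2
table of in/out-category × in/out-PSG over the retained ortholog background,
categories without a PSG member omitted by default, results sorted by
p-value then category id. Raw p-values are reported by default (matching the
reporting convention of small PSG surveys); Benjamini–Hochberg adjustment is
optional. No GO-graph propagation: genes count only for the categories they
are annotated to. The default background is the retained ortholog set, which
is configurable.

## Expression

Reads are cleaned with the fixed-order whole-read filters (exact duplicates
in either orientation, adapter trimming with ≥ 8 bp exact match, > 8 Ns,
> 50% of bases at quality ≤ 5, single-nucleotide fraction > 80% as the
low-complexity proxy) and mapped by exact Hamming-distance search with
pigeonhole seeding: max_mismatch + 1 read chunks guarantee that any
placement within the mismatch budget (default 3) has an exact seed, so the
mapper is exhaustive without indel support. Reads tied between genes are
discarded as ambiguous; RPKM = 10⁹ · count / (length · total mapped) over
the full unigene length. Regulation is called from
log2((RPKM_stress + 0.1)/(RPKM_control + 0.1)) at threshold ±1 (both
configurable — the underlying survey states no cutoff), and concordance per
pair is up-both / up-A-only / up-B-only / other.

## Problem sizes and determinism

Monte-Carlo suites use 200 replicates of 300-codon pairs at *t* = 0.1
(estimator recovery, monotonicity, false-positive control), 100 replicates
of 500 codons for the κ = 1 site-count cross-check, and 50,000 reads per
condition for expression calls — sizes at which the targeted effects are
well resolved while the whole suite stays interactive. Every stochastic step
consumes an explicit seed through a single numpy Generator; pipeline reruns
with identical configuration and seed are byte-identical (no timestamps in
outputs, all collections sorted before writing).

## Known limitations

- The YN00 κ estimator retains a small upward bias at very low divergence
  (ratio estimators with few transversions); its effect on ω recovery is
  within a few percent at the tested conditions.
- No full-likelihood codon models (GY94 ML, branch/site models), no
  confidence intervals on ω.
- The read mapper models substitutions only; indel-bearing reads go
  unassigned.
- Coverage is measured on the local alignment span of the protein hit, not
  on a nucleotide-level alignment.
- GO enrichment treats annotations as flat labels; ontology ancestors are
  not propagated.
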