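# Methods

## Enrichment model

Selection readout is the per-variant log2 enrichment
`Enr = log2(f_post / f_pre)`. Frequencies are computed as count / pool total
over the **full** count table, before read filtering, so the filter never
changes the denominators; an invariant test asserts that filtering-then-
scoring equals scoring-then-dropping. The default filter keeps variants with
≥ 5 pre-selection and ≥ 1 post-selection reads, with no pseudocounts, so
every retained variant has strictly positive frequencies and a finite score.
Group uncertainty is the s.e.m. σ/√N with the sample (N−1) standard
deviation; group contrasts use Welch's two-sided *t*-test
(scipy's unequal-variance test, checked in the suite against a hand-rolled
permutation test on small fixtures). For cross-assay comparisons, scores are
min-shifted (`Enr_norm = Enr − Enr_min`, always ≥ 0) and expressed relative
to the mean, `(Enr_norm − ⟨Enr_norm⟩)/⟨Enr_norm⟩`, which has mean zero by
construction; half-lives are treated identically, `(λ − ⟨λ⟩)/⟨λ⟩`. Raw
pairwise Welch p-values are reported for motif triads; Bonferroni correction
is applied only in the per-position base analysis, where the family
(positions × 4 bases) is well defined.

## Simulator (the ground-truth generator)

The simulator defines the study conditions under which every estimator is
validated:

* **Library**: `n_variants` i.i.d. random RNA 50-mers with equal base
  probabilities (defaults: 590,000 variants of length 50 — the scale of an
  analyzed selection library). Duplicate sequences are kept as distinct
  variants; the estimators must tolerate them.
* **True enrichment**: `enr_true = β0 + β_AU·AU + Σ_m Δ_m·(1 − d_m·(p−1)/(L−|m|)) + ε`,
  where AU is the A+U fraction, the motif term applies when the (IUPAC)
  motif occurs at least once, `p` is the 1-based 5′-most occurrence, `d_m ∈
  [0,1]` is the positional decay (full effect at the 5′ end, reduced by
  `d_m` at the last admissible start), and ε ~ N(0, noise_sd) on the log2
  scale, once per variant. Linear decay in the 5′-most start is the simplest
  monotone shape for the positional decline being emulated; it is ground
  truth we control, not an estimate.
* **Selection**: a single multiplicative tilt, `f_post ∝ f_pre·2^enr_true`.
  Since Enr is defined as a frequency ratio, any monotone growth model
  collapses to this tilt; explicit growth curves would add parameters
  without changing anything measurable here.
* **Sequencing**: pre-selection abundances LogNormal(0, skew_sd = 0.5 by
  default), multinomial sampling of both pools at 2×10⁷ reads each
  (per-pool depths are not publicly stated for the assay being emulated;
  these defaults give ~34 reads/variant and are configurable).
* **Default effect model** (`demo_effect_model`): UAUAUA at Δ = 1.74
  (anchored to the printed carrier-vs-library gap 2.60 − 0.86) with decay
  0.45; AAWAAA at Δ = 0.34 (1.20 − 0.86), no decay; a Puf3-like UGUANAUA at
  Δ = 1.0 with decay 0.5; β_AU = 2.0 and noise_sd = 0.5, which together give
  an AU/enrichment Pearson r ≈ 0.23–0.27.

Consequence used throughout testing: `E[Enr_i] = enr_true_i − log2(Σ_j
f_pre_j·2^enr_true_j)` — a common shift, so all pairwise and group
differences of true enrichments are preserved in expectation, and in the
exact-frequency (infinite-depth) limit the differences are exact.

What the simulator does **not** emulate: PCR jackpotting, sequencing errors,
barcode collisions/consensus clustering, epistasis between motifs beyond
additivity, selection saturation at high expression, and the composition
bias that selection induces in a real post-filter library. Passing recovery
tests therefore demonstrates correctness of the estimators under a faithful
additive generative model, not robustness to those artifacts.

One RNG stream is derived per operation from (seed, operation name) (CRC32
tag into a SeedSequence), so results are independent of call order; all
derived seeds are kept below 2³¹.

## k-mer machinery

Sequences are encoded as a uint8 matrix; all length-k window codes are built
by Horner accumulation, row-sorted, and first-occurrence masks give each
sequence's distinct k-mer set without per-sequence Python loops. "Containing"
means ≥ 1 occurrence, counted with overlaps, one vote per sequence.
Group means/s.e.m.s come from bincount accumulations of Σw and Σw²; the
lacking-group statistics are derived from library totals. Ranks order by
descending containing-group mean with lexicographic tie-breaks (stable
sort), so the ranking is always a permutation of all 4^k k-mers; k ≤ 12 is
materialized, larger k is counted only. The exact identity
`Σ_kmer n_with = Σ_seq #distinct-k-mers` doubles as an internal cross-check
and makes the mean containment count per k-mer insensitive to composition
bias.

## Motif analyses

* **Matching** is exact IUPAC matching via compiled regex (ambiguity codes
  expand to character classes); overlapping occurrences are enumerated with
  a manual scan-from-next-position loop, and the test suite checks
  equivalence with brute-force expansion + substring search. This replaces
  a FIMO perfect-match scan; for perfect matches at a permissive threshold
  the two are the same operation.
* **Shuffles**: distinct permutations of the motif's letters (hand-rolled
  multiset-permutation enumeration), Hamming ≥ ⌈|m|/2⌉ from the original,
  never the original; degenerate motifs are expanded first, shuffles pooled
  across expansions, anything still matching the pattern dropped, and the
  50-shuffle cap applied to the pooled set (a per-motif budget). Sampling
  under the cap is seeded. Homopolymers admit no shuffle and return an
  empty set with a warning — their AU-matched control must be supplied
  explicitly (e.g. shuffles of A₄U₄ for U₈, or AAAUUU for AAWAAA, whose
  only expansions AAAAAA/AAUAAA admit no Hamming-≥3 permutation).
* **Triads**: with = contains motif; without = does not; control = contains
  ≥ 1 shuffle (or the explicit control) and not the motif. Exclusion motifs
  remove their carriers from all groups. With/without partition the
  (post-exclusion) library exactly.
* **Positional profiles** use occurrence semantics — a sequence contributes
  at every position where an occurrence starts — while triad means use set
  semantics (one vote per sequence). The n-weighted positional mean
  therefore equals the mean over occurrence–position pairs, an identity in
  the suite.
* **Mutational scans** build every single-base substitution of a concrete
  consensus under two schemes: AU-preserving swaps (A↔U) and transitions
  (U→C, A→G); G/C positions undefined under a scheme are skipped with a log
  entry. Mutant groups exclude consensus carriers and any extra exclusions;
  mutants that re-create the efficiency element UAUAUA are flagged.
* **Arrangement**: sequences carrying both motifs with at least one
  disjoint placement (configurable) are binned into equal-width enrichment
  bins (default 5); within each bin the fraction with motif A's 5′-most
  occurrence upstream of motif B's is reported. In the simulation this
  fraction rises with enrichment purely because of the planted positional
  decay — upstream efficiency elements confer larger effects.
* **Per-position base statistics**: for each position and base, carriers
  vs. rest are compared on their enrichment scores by a two-sided Welch
  test (the enrichment-weighted comparison reduces to exactly this when
  each sequence's weight is its score), Bonferroni factor = positions × 4,
  flagged at corrected p < 0.05. The test's sidedness is exposed in the run
  configuration because the emulated procedure describes its test
  ambiguously ("one-sided two-tailed"); two-sided is the default. Libraries
  larger than the configured subsample (default 50,000) are subsampled
  reproducibly.

## Half-life comparison

Isoform-level records (gene, UTR sequence, half-life, reported gene-mean
half-life) are collapsed to one representative isoform per gene — the
isoform nearest the reported gene mean, ties to the shorter half-life and
then lexicographic sequence, so selection is deterministic and idempotent.
Relative half-lives are scale-invariant by construction. The protein side
applies the identical motif/control/exclusion machinery to relative
normalized enrichment. The synthetic generator draws isoform half-lives
log-normally (median 20 min, log-sd 0.6 — a realistic right-skewed
transcriptome-wide spread) with multiplicative planted motif effects and
emits each gene's isoform mean as the reported gene mean. Note an inherent
attenuation: when a gene mixes carrier and non-carrier isoforms, the
representative is pulled toward the gene mean, so planted folds are
recovered exactly only for single-isoform genes; the tests exploit this
distinction deliberately.

## Problem sizes and numerical choices

The bundled drivers and acceptance checks use 590,000-variant libraries at
2×10⁷ reads/pool (the emulated study scale); unit-test fixtures use
8,000–100,000 variants, chosen so that group s.e.m.s are small enough for
3-s.e.m. recovery bounds to be informative. Tolerances: frequency sums and
relative-mean-zero identities at 1e−9; parameter recovery at 3 combined
s.e.m. of the realized ground truth; null calibration bounds set at the
99.9% Poisson quantile of the expected false-positive count (3 of 4096
hexamer tests at 4 s.e.m.; 1 flag for the Bonferroni-corrected base scan).
Degenerate inputs (empty groups, all-zero pools, zero-variance pairs,
homopolymer shuffles, singleton groups) raise typed errors or return
flagged NaNs rather than silently propagating.

## Known limitations

The pipeline starts from count tables; read clustering/alignment is out of
scope. No de-novo motif discovery or motif-database comparison. No RNA
secondary-structure modeling. Motif effects are assumed additive in the
generator; the estimators make no additivity assumption but are only
validated under it. Real selection data exhibit composition bias in the
filtered library that the uniform simulator intentionally lacks.
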