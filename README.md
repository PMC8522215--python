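# utrselect

Analysis of how 3′ UTR sequence motifs affect protein expression, measured by
massively parallel growth selections of random 50-mer (N50) 3′ UTR inserts in
yeast, together with a ground-truth simulator of the library, selection and
sequencing so that every estimator in the pipeline can be validated by
parameter recovery.

## The problem and the statistic

A reporter gene carries a random 50-mer in its 3′ UTR; hundreds of thousands
of variants compete in a growth selection whose outcome reflects each
variant's protein expression. Each variant's effect is summarized as a log2
enrichment,

    Enr = log2(f_post / f_pre),

where *f*_pre and *f*_post are the variant's population frequencies in the
pre- and post-selection sequencing pools. Variants with ≥ 5 input reads and
≥ 1 output read (no pseudocounts) are retained. Motif effects are then group
comparisons: mean *Enr* (± s.e.m. = σ/√N) of sequences containing a motif vs.
those lacking it, and vs. a composition-matched null — sequences containing
**shuffles** of the motif (same letters, Hamming distance ≥ half the motif
length) but not the motif itself — with Welch's two-sided *t*-tests. Further
analyses: exhaustive *k*-mer effect tables with ranking, AU-content
correlation, positional profiles by the motif's 5′-end location, single-base
mutational scans that exclude consensus carriers, double-motif arrangement by
enrichment bin, kpLogo-style per-position base statistics, and comparison of
relative enrichment, (Enr_norm − ⟨Enr_norm⟩)/⟨Enr_norm⟩, with relative native
mRNA half-life, (λ − ⟨λ⟩)/⟨λ⟩.

The simulator draws uniform random 50-mers, assigns each variant a true
enrichment (baseline + AU-content slope + planted motif effects with
5′-biased linear positional decay + Gaussian log2 noise), tilts pre-selection
frequencies by 2^enr_true, and samples both pools multinomially under
log-normal library skew. Pairwise differences of true enrichments are
preserved in expectation by the estimated scores.

## Worked example

```
python analysis/01_simulate_library.py --seed 1 --out results/simulation
python analysis/02_score_enrichment.py
python analysis/03_kmer_effects.py
python analysis/04_motif_effects.py
```

which prints (among other lines):

```
590000 variants in, 588849 pass the read filter
library mean Enr -0.115 (sd 0.704, min -4.907)
AU content vs Enr: Pearson r = 0.232

k=6: mean carriers per k-mer 6435 (sd 97, min 4815)
top ranks:
  kmer  rank  n_with  mean_with  sem_with
UAUAUA     1    6044   1.409894  0.009024
AUAUAU     2    5928   0.542335  0.012705

UAUAUA: with 1.41 (n=6044) vs without -0.13; positional mean 1.77 at 5' end -> 0.98 at 3' end
```

Reading this: nearly all variants survive the read filter at 2×10⁷ reads per
pool; the AU-content slope in the generative model produces the expected
positive AU/enrichment correlation; the planted efficiency element UAUAUA is
recovered as the top-ranked hexamer (its runners-up are overlap-shifted
variants that co-occur with it, not independently active motifs); and the
positional profile recovers the planted 5′-biased decay. The remaining
drivers (`05`–`07`) run the mutational scans, the efficiency/positioning
element arrangement analysis with per-position base statistics, and the
half-life comparison on a synthetic native-gene table.

Library-level API: `utrselect.score_library`, `kmer_summary`, `motif_effect`,
`positional_profile`, `mutational_scan`, `arrangement_fraction`,
`position_base_enrichment`, `paired_motif_comparison`, and the simulator
(`generate_random_library`, `assign_true_enrichment`, `simulate_counts`).
`run_pipeline(RunConfig(...), out_dir)` executes every stage into one run
directory.

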