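"""Native mRNA half-life side: representative isoforms, relative scales,
and the paired protein/RNA motif comparison."""

import numpy as np
import pandas as pd
import pytest

import utrselect as u
from utrselect.halflife import representative_table
from utrselect.motifs import InsufficientDataError


class TestRepresentativeIsoform:
    def test_nearest_to_gene_mean(self):
        assert u.select_representative_isoform([("A", 10.0), ("C", 30.0)], 18.0) == ("A", 10.0)

    def test_single_isoform(self):
        assert u.select_representative_isoform([("G", 12.0)], 99.0) == ("G", 12.0)

    def test_tie_breaks_toward_shorter_halflife(self):
        assert u.select_representative_isoform([("A", 26.0), ("C", 10.0)], 18.0) == ("C", 10.0)

    def test_equal_halflife_tie_breaks_lexicographically(self):
        assert u.select_representative_isoform([("C", 10.0), ("A", 10.0)], 18.0) == ("A", 10.0)

    def test_deterministic_and_idempotent(self):
        isoforms = [("AU", 14.0), ("GC", 22.0), ("UU", 18.5)]
        first = u.select_representative_isoform(isoforms, 18.0)
        assert u.select_representative_isoform(isoforms, 18.0) == first
        assert u.select_representative_isoform([first], 18.0) == first

    def test_empty_rejected(self):
        with pytest.raises(u.DegenerateInputError):
            u.select_representative_isoform([], 10.0)


class TestRelativeHalflife:
    def _records(self, lams):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(lams))],
                "isoform_utr_seq": ["AUGC"] * len(lams),
                "halflife_min": lams,
                "gene_mean_halflife_min": lams,
            }
        )

    def test_direct_arithmetic(self):
        out = u.relative_halflife(self._records([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out["relative_halflife"], [-0.5, 0.0, 0.5])

    def test_all_equal_gives_zero(self):
        out = u.relative_halflife(self._records([7.0, 7.0]))
        assert (out["relative_halflife"] == 0).all()

    def test_mean_is_zero_and_scale_invariant(self):
        lams = [3.0, 9.5, 14.0, 40.0]
        a = u.relative_halflife(self._records(lams))["relative_halflife"]
        b = u.relative_halflife(self._records([x * 7.3 for x in lams]))["relative_halflife"]
        assert abs(a.mean()) < 1e-12
        np.testing.assert_allclose(a, b)

    def test_nonpositive_rejected(self):
        with pytest.raises(u.InvalidParameterError):
            u.relative_halflife(self._records([5.0, -1.0]))


class TestSyntheticGenerator:
    def test_gene_mean_is_isoform_mean(self):
        tab = u.generate_halflife_table(n_genes=50, seed=1)
        for _, grp in tab.groupby("gene"):
            assert grp["gene_mean_halflife_min"].iloc[0] == pytest.approx(
                grp["halflife_min"].mean()
            )

    def test_planted_fold_effect_recovered(self):
        # single-isoform genes: representative selection is the identity, so
        # the planted fold is recovered exactly (multi-isoform genes attenuate
        # it, since the representative is pulled toward the gene mean)
        tab = u.generate_halflife_table(
            n_genes=3000, motif_effects=[("UAUAUA", 1.5)], max_isoforms=1, seed=2
        )
        reps = representative_table(tab)
        has = reps["isoform_utr_seq"].str.contains("UAUAUA")
        logfold = np.log(reps.loc[has, "halflife_min"]).mean() - np.log(
            reps.loc[~has, "halflife_min"]
        ).mean()
        n1, n0 = has.sum(), (~has).sum()
        sem = 0.6 * np.sqrt(1 / n1 + 1 / n0)  # log-normal sd is the generator's
        assert logfold == pytest.approx(np.log(1.5), abs=3 * sem)


class TestPairedComparison:
    @pytest.fixture(scope="class")
    def scored(self):
        model = u.EffectModel(beta0=0.2, noise_sd=0.3)
        _, _, counts = u.simulate_library(
            model, n_variants=8000, depth_pre=800_000, depth_post=800_000, seed=31
        )
        return u.score_library(counts)

    def test_rna_side_groups_match_brute_force_search(self, scored):
        tab = u.generate_halflife_table(n_genes=800, motif_effects=[("UAUAUA", 1.5)], seed=3)
        cmp_ = u.paired_motif_comparison(scored, tab, "UAUAUA", seed=3)
        reps = representative_table(tab)
        n_with = sum("UAUAUA" in s for s in reps["isoform_utr_seq"])
        assert cmp_.rna_side.with_group.n == n_with
        assert cmp_.rna_side.without_group.n == len(reps) - n_with

    def test_stabilizing_motif_raises_rna_side(self, scored):
        # single-isoform genes so the planted fold reaches the representative
        # table undiluted; 4000 genes give ~100 carriers for adequate power
        tab = u.generate_halflife_table(
            n_genes=4000, motif_effects=[("UAUAUA", 1.5)], max_isoforms=1, seed=4
        )
        cmp_ = u.paired_motif_comparison(scored, tab, "UAUAUA", seed=4)
        rna = cmp_.rna_side
        gap = rna.with_group.mean - rna.without_group.mean
        assert gap > 3 * np.hypot(rna.with_group.sem, rna.without_group.sem)
        assert rna.p_with_vs_without.p_value < 0.01

    def test_discordant_motif_signs_disagree(self, scored):
        """A motif stabilizing mRNA but neutral for expression produces
        opposite-sign group gaps on the two sides (no planted enrichment
        effect here, so the protein side is flat)."""
        tab = u.generate_halflife_table(n_genes=2000, motif_effects=[("GCGCGC", 2.0)], seed=5)
        cmp_ = u.paired_motif_comparison(scored, tab, "GCGCGC", seed=5)
        rna_gap = cmp_.rna_side.with_group.mean - cmp_.rna_side.without_group.mean
        prot_gap = cmp_.protein_side.with_group.mean - cmp_.protein_side.without_group.mean
        assert rna_gap > 0.2
        assert abs(prot_gap) < 0.2

    def test_group_sizes_mirror_motif_machinery(self, scored):
        tab = u.generate_halflife_table(n_genes=500, seed=6)
        cmp_ = u.paired_motif_comparison(scored, tab, "UAUAUA", seed=6)
        eff = u.motif_effect(
            scored, "UAUAUA",
            control=list(cmp_.control_set) if cmp_.control_set else "shuffles",
            seed=6,
        )
        assert cmp_.protein_side.with_group.n == eff.with_group.n
        assert cmp_.protein_side.without_group.n == eff.without_group.n

    def test_empty_dataset_rejected(self, scored):
        with pytest.raises(u.DegenerateInputError):
            u.paired_motif_comparison(scored.iloc[:0], pd.DataFrame(), "UAUAUA")

    def test_missing_motif_on_rna_side_is_an_error(self, scored):
        tab = u.generate_halflife_table(n_genes=20, utr_length=8, seed=7)
        with pytest.raises(InsufficientDataError):
            u.paired_motif_comparison(scored, tab, "GCGCGCGC", seed=7)
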