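"""Directed motif machinery: IUPAC scanning, shuffle nulls, profiles, scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import utrselect as u
from utrselect.motifs import InsufficientDataError, hamming

RNA = "ACGU"


def random_rna(rng, n, L):
    return ["".join(rng.choice(list(RNA), size=L)) for _ in range(n)]


class TestFindOccurrences:
    def test_degenerate_motif_by_hand(self):
        # windows of AAUAAAUAAA: AAUAAA(1) ok, AUAAAU no, UAAAUA no,
        # AAAUAA no (pos 4 must be A under AAWAAA: AAAUAA -> W=A ok? A A A U A A:
        # pattern A A W A A A requires pos4=A, here U) , AAUAAA(5) ok
        assert u.find_occurrences("AAUAAAUAAA", "AAWAAA") == [1, 5]

    def test_poly_a_matches_consensus(self):
        assert u.find_occurrences("AAAAAA", "AAWAAA") == [1]

    def test_wildcard_matches_everywhere(self):
        assert u.find_occurrences("ACGU", "N") == [1, 2, 3, 4]

    def test_overlapping_occurrences_reported(self):
        assert u.find_occurrences("UAUAUAUA", "UAUA") == [1, 3, 5]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(u.InvalidParameterError):
            u.find_occurrences("AAAA", "AXA")

    def test_iupac_equals_brute_force_expansion(self, rng):
        """Degenerate scanning must equal expanding the pattern into its
        concrete set followed by exact substring search."""
        motifs = ["AAWAAA", "UGUANAUA", "YAUN", "WWWW", "UGUANANUA",
                  "AUGY", "NAN", "UAAUNNNUAAU", "YYRR", "UAUAUA"]
        seqs = random_rna(rng, 100, 30)
        for m in motifs:
            expansions = u.expand_iupac(m)
            for s in seqs:
                oracle = sorted(
                    {i + 1 for e in expansions for i in range(len(s) - len(e) + 1)
                     if s[i:i + len(e)] == e}
                )
                assert u.find_occurrences(s, m) == oracle


class TestShuffles:
    def test_hamming_examples(self):
        assert hamming("UAUAUA", "AAAUUU") == 4
        assert hamming("UAUAUA", "AUUAUA") == 2
        shuffles = u.generate_shuffles("UAUAUA", seed=1)
        assert "AAAUUU" in shuffles or len(shuffles) > 0
        assert all(hamming(s, "UAUAUA") >= 3 for s in shuffles)
        assert "AUUAUA" not in shuffles

    def test_homopolymer_has_no_shuffles(self):
        assert u.generate_shuffles("AAAA") == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet=RNA, min_size=2, max_size=8))
    def test_composition_preserved_and_original_excluded(self, motif):
        shuffles = u.generate_shuffles(motif, seed=3)
        for s in shuffles:
            assert sorted(s) == sorted(motif)
            assert s != motif
            assert hamming(s, motif) >= (len(motif) + 1) // 2

    def test_cap_and_determinism(self):
        a = u.shuffle_set_for("UAAUNNNUAAU", max_n=50, seed=9)
        b = u.shuffle_set_for("UAAUNNNUAAU", max_n=50, seed=9)
        assert a == b and 0 < len(a) <= 50  # cap is per motif, after pooling
        assert all(len(s) == 11 for s in a)

    def test_degenerate_motif_shuffles_never_match_pattern(self):
        pat = u.iupac_regex("AAWAAA")
        for s in u.shuffle_set_for("AAWAAA", seed=2):
            assert pat.fullmatch(s) is None


class TestMotifEffect:
    def test_groups_partition_library(self, planted_library):
        variants, _, _ = planted_library
        eff = u.motif_effect(variants, "UAUAUA", seed=1)
        assert eff.with_group.n + eff.without_group.n == len(variants)

    def test_null_library_exchangeable(self, null_library):
        eff = u.motif_effect(null_library, "UAUAUA", seed=1)
        for g in (eff.with_group, eff.shuffle_group):
            gap = abs(g.mean - eff.without_group.mean)
            assert gap < 3 * np.hypot(g.sem, eff.without_group.sem)

    def test_planted_effect_recovered(self, planted_library):
        variants, _, _ = planted_library
        eff = u.motif_effect(variants, "UAUAUA", seed=1)
        est = eff.with_group.mean - eff.without_group.mean
        truth_with = variants.loc[variants.n50.str.contains("UAUAUA"), "enr_true"].mean()
        truth_without = variants.loc[~variants.n50.str.contains("UAUAUA"), "enr_true"].mean()
        tol = 3 * np.hypot(eff.with_group.sem, eff.without_group.sem)
        assert est == pytest.approx(truth_with - truth_without, abs=tol)
        # shuffle control sees only the AU-content component, far below the
        # planted identity effect
        shuffle_gap = eff.shuffle_group.mean - eff.without_group.mean
        assert shuffle_gap < 0.5 * est

    def test_explicit_control_sequence(self, planted_library):
        variants, _, _ = planted_library
        eff = u.motif_effect(variants, "AAWAAA", control="AAAUUU", seed=1)
        assert eff.shuffle_set == ("AAAUUU",)
        assert eff.shuffle_group is not None

    def test_exclusions_remove_from_all_groups(self, planted_library):
        variants, _, _ = planted_library
        eff = u.motif_effect(variants, "AUAUAU", exclusions=["UAUAUA"], seed=1)
        n_excluded = variants["n50"].str.contains("UAUAUA").sum()
        assert eff.with_group.n + eff.without_group.n == len(variants) - n_excluded

    def test_empty_with_group_is_an_error(self, planted_library):
        variants, _, _ = planted_library
        with pytest.raises(InsufficientDataError):
            u.motif_effect(variants, "GCGCGCGCGCGCGCGCGCGC", seed=1)


class TestPositionalProfile:
    def test_constructed_single_position(self):
        seqs = ["CC" + "UAUAUA" + "C" * 42, "CC" + "UAUAUA" + "G" * 42, "G" * 50]
        v = pd.DataFrame({"n50": seqs, "enr": [1.0, 3.0, 0.0]})
        prof = u.positional_profile(v, "UAUAUA", seed=1)
        assert prof.motif_profile["position"].tolist() == [3]
        assert prof.motif_profile["n"].iloc[0] == 2
        assert prof.motif_profile["mean"].iloc[0] == pytest.approx(2.0)

    def test_occurrence_count_identity(self, planted_library):
        variants, _, _ = planted_library
        sub = variants.head(4000)
        prof = u.positional_profile(sub, "UAUAUA", seed=1)
        total = sum(
            len(u.find_occurrences(s, "UAUAUA")) for s in sub["n50"]
        )
        assert prof.motif_profile["n"].sum() == total

    def test_profile_weighted_mean_matches_occurrence_pairs(self, planted_library):
        variants, _, _ = planted_library
        sub = variants.head(4000)
        prof = u.positional_profile(sub, "UAUAUA", seed=1).motif_profile
        pooled = []
        for s, e in zip(sub["n50"], sub["enr"]):
            pooled.extend([e] * len(u.find_occurrences(s, "UAUAUA")))
        expected = np.mean(pooled)
        weighted = (prof["n"] * prof["mean"]).sum() / prof["n"].sum()
        assert weighted == pytest.approx(expected)

    def test_positional_decay_recovered(self):
        """With decay=1 the profile declines monotonically (checked by a
        least-squares slope well below zero); with decay=0 it is flat."""
        model = u.EffectModel(planted_motifs=(u.PlantedMotif("UAUAUA", 2.0, 1.0),),
                              noise_sd=0.05)
        lib = u.generate_random_library(60_000, 50, seed=11)
        truth = u.assign_true_enrichment(lib, model, seed=11)
        v = lib.assign(enr=truth["enr_true"])
        prof = u.positional_profile(v, "UAUAUA", seed=1).motif_profile
        slope = np.polyfit(prof["position"], prof["mean"], 1)[0]
        # true slope of the 5'-most-occurrence effect is -2/44 per position
        assert slope < -0.02
        flat_model = u.EffectModel(planted_motifs=(u.PlantedMotif("UAUAUA", 2.0, 0.0),),
                                   noise_sd=0.05)
        truth0 = u.assign_true_enrichment(lib, flat_model, seed=11)
        prof0 = u.positional_profile(lib.assign(enr=truth0["enr_true"]), "UAUAUA", seed=1).motif_profile
        slope0 = np.polyfit(prof0["position"], prof0["mean"], 1)[0]
        assert abs(slope0) < 0.01


class TestMutationalScan:
    def test_mutant_groups_exclude_consensus(self):
        seqs = [
            "AAUAUA" + "C" * 44,            # mutant at position 1
            "AAUAUA" + "C" * 38 + "UAUAUA",  # mutant AND consensus -> excluded
            "G" * 50,
            "UAUAUA" + "G" * 44,            # consensus only
        ]
        v = pd.DataFrame({"n50": seqs, "enr": [1.0, 5.0, 0.0, 2.0]})
        scan = u.mutational_scan(v, "UAUAUA", "au_swap")
        row = scan.mutants.set_index("mutant").loc["AAUAUA"]
        assert row["n"] == 1 and row["mean"] == pytest.approx(1.0)
        assert scan.consensus_group.n == 2

    def test_transition_scheme_and_skipped_positions(self, planted_library):
        variants, _, _ = planted_library
        scan = u.mutational_scan(variants, "UAUAUA", "transition")
        assert scan.mutants["mutant"].tolist() == [
            "CAUAUA", "UGUAUA", "UACAUA", "UAUGUA", "UAUACA", "UAUAUG"
        ]
        # G/C positions are undefined under the AU swap and skipped
        scan2 = u.mutational_scan(variants, "UAGAUA", "au_swap")
        assert 3 not in scan2.mutants["position"].tolist()

    def test_u5aua_regenerates_efficiency_element(self, planted_library):
        variants, _, _ = planted_library
        scan = u.mutational_scan(variants, "UUUUUAUA", "au_swap")
        flagged = scan.mutants.set_index("position")["contains_efficiency_element"]
        assert flagged.loc[4]  # UUUAUAUA contains UAUAUA
        assert not flagged.loc[1]

    def test_only_exact_consensus_carries_effect(self, planted_library):
        """All mutant groups sit near the library mean while the consensus
        group is elevated, since only UAUAUA was planted."""
        variants, _, _ = planted_library
        scan = u.mutational_scan(variants, "UAUAUA", "au_swap")
        assert scan.consensus_group.mean - scan.library_mean > 1.0
        gaps = (scan.mutants["mean"] - scan.library_mean).abs()
        assert (gaps < 0.25).all()


class TestCountNonoverlapping:
    @pytest.mark.parametrize(
        "seq,motif,n",
        [
            ("UAUAUAUAUA", "UAUAUA", 1),
            ("UAUAUA" + "CCCC" + "UAUAUA", "UAUAUA", 2),
            ("GGGG", "UAUAUA", 0),
        ],
    )
    def test_greedy_disjoint_count(self, seq, motif, n):
        assert u.count_nonoverlapping(seq, motif) == n


class TestArrangement:
    def test_direct_count_single_bin(self):
        ee, pe = "UAUAUA", "AAUAAA"
        seqs = [
            ee + "GG" + pe + "G" * 36,
            ee + "CC" + pe + "G" * 36,
            pe + "GG" + ee + "G" * 36,
            pe + "CC" + ee + "G" * 36,
        ]
        v = pd.DataFrame({"n50": seqs, "enr": [1.0, 1.1, 0.9, 1.05]})
        out = u.arrangement_fraction(v, ee, "AAWAAA", n_bins=1)
        assert out["n"].iloc[0] == 4
        assert out["fraction_a_before_b"].iloc[0] == pytest.approx(0.5)

    def test_bins_partition_qualifying_sequences(self, planted_library):
        variants, _, _ = planted_library
        out = u.arrangement_fraction(variants, "UAUAUA", "AAWAAA", n_bins=3)

        def qualifies(s):  # independent pairwise disjointness check
            pa = u.find_occurrences(s, "UAUAUA")
            pb = u.find_occurrences(s, "AAWAAA")
            return any(
                b >= a + 6 or a >= b + 6 for a in pa for b in pb
            )

        expected = sum(qualifies(s) for s in variants["n50"])
        assert out["n"].sum() == expected
        assert expected > 0

    def test_arrangement_effect_increases_with_bin(self):
        """When EE-before-PE sequences get an extra boost, the 5'-EE fraction
        rises across enrichment bins."""
        rng = np.random.default_rng(5)
        seqs, enr = [], []
        for _ in range(400):
            a_first = rng.random() < 0.5
            gap = "".join(rng.choice(list("GC"), size=10))
            tail = "".join(rng.choice(list("GC"), size=28))
            s = ("UAUAUA" + gap + "AAUAAA" if a_first else "AAUAAA" + gap + "UAUAUA") + tail
            seqs.append(s)
            enr.append(rng.normal(1.0 if a_first else 0.0, 0.3))
        v = pd.DataFrame({"n50": seqs, "enr": enr})
        out = u.arrangement_fraction(v, "UAUAUA", "AAWAAA", n_bins=4)
        assert out["fraction_a_before_b"].iloc[-1] > out["fraction_a_before_b"].iloc[0]

    def test_no_qualifying_sequences_is_an_error(self):
        v = pd.DataFrame({"n50": ["G" * 50], "enr": [0.0]})
        with pytest.raises(InsufficientDataError):
            u.arrangement_fraction(v, "UAUAUA", "AAWAAA")


class TestPositionBaseEnrichment:
    def test_au_slope_pattern(self):
        """A pure AU-content effect flags A/U as enriched and G/C as depleted
        across positions, mirroring a base-level logo of the selection."""
        model = u.EffectModel(beta_au=5.0, noise_sd=0.05)
        lib = u.generate_random_library(20_000, 50, seed=13)
        truth = u.assign_true_enrichment(lib, model, seed=13)
        v = lib.assign(enr=truth["enr_true"])
        tab = u.position_base_enrichment(v, subsample=50_000, seed=1)
        sig = tab[tab["significant"]]
        assert len(sig) > 100
        assert (sig.loc[sig.base.isin(["A", "U"]), "t"] > 0).all()
        assert (sig.loc[sig.base.isin(["G", "C"]), "t"] < 0).all()

    def test_null_yields_no_flags(self, null_library):
        tab = u.position_base_enrichment(null_library, subsample=50_000, seed=1)
        assert tab["significant"].sum() <= 1

    def test_subsampling_is_reproducible(self, planted_library):
        variants, _, _ = planted_library
        a = u.position_base_enrichment(variants, subsample=5_000, seed=7)
        b = u.position_base_enrichment(variants, subsample=5_000, seed=7)
        pd.testing.assert_frame_equal(a, b)
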