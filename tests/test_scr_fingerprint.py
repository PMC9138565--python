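import math

import numpy as np
import pytest

from scrsasa.sasa_core import ResidueSASA, SASAProfile
from scrsasa.scr_fingerprint import (
    correlation_matrix,
    fingerprint,
    identify_scrs,
    residue_preferences,
    scrs_from_intervals,
)
from scrsasa.structure_io import ONE_TO_THREE


def profile_from_values(pid, seq, totals, sidechains=None):
    sidechains = sidechains or [t / 2 for t in totals]
    rows = tuple(
        ResidueSASA(res_index=i, res_name=ONE_TO_THREE[aa], total=t,
                    backbone=t - s, sidechain=s, polar=t / 2, apolar=t / 2)
        for i, (aa, t, s) in enumerate(zip(seq, totals, sidechains))
    )
    return SASAProfile(protein_id=pid, residues=rows)


class TestIdentifyScrs:
    def test_identical_sequences_single_full_region(self):
        aln = [("a", "GAVLM"), ("b", "GAVLM")]
        scrs = identify_scrs(aln, min_len=1, min_conservation=1.0)
        assert scrs.regions == ((0, 5),)
        assert scrs.maps["a"] == (0, 1, 2, 3, 4)

    def test_gap_column_vetoes_every_window(self):
        aln = [("a", "GA-VL-MW"), ("b", "GAGVLGMW")]
        scrs = identify_scrs(aln, min_len=3, min_conservation=0.5)
        assert scrs.regions == ()

    def test_three_sequence_block_with_manual_cursor_trace(self):
        """One 6-column identical block; maps traced by hand.

        Alignment columns:       0123456789...
          a: AA GAVLMW CC  ->  "AAGAVLMWCC"
          b: CA GAVLMW AA  ->  "CAGAVLMWAA"
          c: AD GAVLMW CD  ->  "ADGAVLMWCD"
        Columns 2-7 are identical (GAVLMW); flanks disagree pairwise so
        majority frequency stays below 2/3 there.  With min_len=5 the
        only region is [2, 8).  No gaps, so residue indices equal column
        indices for every sequence.
        """
        aln = [("a", "AAGAVLMWCC"), ("b", "CAGAVLMWAA"), ("c", "ADGAVLMWCD")]
        scrs = identify_scrs(aln, min_len=5, min_conservation=0.7)
        assert scrs.regions == ((2, 8),)
        for pid in "abc":
            assert scrs.maps[pid] == (2, 3, 4, 5, 6, 7)

    def test_gapped_cursor_mapping(self):
        """Gap-skipping cursors: a gap before the block shifts indices."""
        aln = [("a", "G-AVLMW"), ("b", "GCAVLMW")]
        scrs = identify_scrs(aln, min_len=5, min_conservation=1.0)
        assert scrs.regions == ((2, 7),)
        assert scrs.maps["a"] == (1, 2, 3, 4, 5)  # gap at column 1
        assert scrs.maps["b"] == (2, 3, 4, 5, 6)

    def test_permutation_equivariance(self):
        aln = [("a", "GAVLMW"), ("b", "GAVLMW"), ("c", "GAVLYW")]
        fwd = identify_scrs(aln, min_len=2, min_conservation=0.6)
        rev = identify_scrs(aln[::-1], min_len=2, min_conservation=0.6)
        assert fwd.regions == rev.regions
        assert fwd.maps == rev.maps

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            identify_scrs([("a", "GAV"), ("b", "GAVL")])

    def test_min_len_validated(self):
        with pytest.raises(ValueError):
            identify_scrs([("a", "GAV"), ("b", "GAV")], min_len=0)


class TestFingerprint:
    def test_single_column_scr(self):
        aln = [("a", "GAV"), ("b", "GAV")]
        scrs = scrs_from_intervals(aln, [(1, 2)])
        profiles = {
            "a": profile_from_values("a", "GAV", [10.0, 20.0, 30.0]),
            "b": profile_from_values("b", "GAV", [1.0, 2.0, 3.0]),
        }
        fps = {f.protein_id: f.values for f in fingerprint(profiles, scrs)}
        assert fps == {"a": (20.0,), "b": (2.0,)}

    def test_hand_constructed_vectors(self):
        aln = [("a", "GAVL"), ("b", "GAVL")]
        scrs = scrs_from_intervals(aln, [(0, 2), (3, 4)])
        profiles = {
            "a": profile_from_values("a", "GAVL", [5.0, 6.0, 7.0, 8.0]),
            "b": profile_from_values("b", "GAVL", [50.0, 60.0, 70.0, 80.0]),
        }
        fps = {f.protein_id: f.values for f in fingerprint(profiles, scrs)}
        assert fps["a"] == (5.0, 6.0, 8.0)
        assert fps["b"] == (50.0, 60.0, 80.0)

    def test_sidechain_component_option(self):
        aln = [("a", "AV"), ("b", "AV")]
        scrs = scrs_from_intervals(aln, [(0, 2)])
        profiles = {
            "a": profile_from_values("a", "AV", [10.0, 20.0], [4.0, 8.0]),
            "b": profile_from_values("b", "AV", [10.0, 20.0], [5.0, 9.0]),
        }
        fps = {f.protein_id: f.values
               for f in fingerprint(profiles, scrs, component="sidechain")}
        assert fps["a"] == (4.0, 8.0)

    def test_missing_profile_reported(self):
        aln = [("a", "GAV"), ("b", "GAV")]
        scrs = scrs_from_intervals(aln, [(0, 3)])
        profiles = {"a": profile_from_values("a", "GAV", [1.0, 2.0, 3.0])}
        with pytest.raises(KeyError, match="b"):
            fingerprint(profiles, scrs)

    def test_equal_lengths_across_proteins(self):
        aln = [("a", "GAVLM"), ("b", "GAVLM"), ("c", "GAVLM")]
        scrs = identify_scrs(aln, min_len=2, min_conservation=1.0)
        profiles = {
            pid: profile_from_values(pid, "GAVLM", list(range(1, 6)))
            for pid in "abc"
        }
        lengths = {len(f.values) for f in fingerprint(profiles, scrs)}
        assert lengths == {sum(e - s for s, e in scrs.regions)}


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        from scrsasa.scr_fingerprint import Fingerprint

        fps = [Fingerprint("a", (1.0, 2.0, 3.0, 4.0)),
               Fingerprint("b", (2.0, 1.0, 5.0, 3.0))]
        labels, mat = correlation_matrix(fps)
        assert labels == ["a", "b"]
        assert mat[0, 0] == 1.0 and mat[1, 1] == 1.0
        assert mat[0, 1] == pytest.approx(mat[1, 0])

    def test_negation_about_mean_gives_minus_one(self):
        from scrsasa.scr_fingerprint import Fingerprint

        x = np.array([3.0, 7.0, 1.0, 9.0])
        neg = 2 * x.mean() - x
        fps = [Fingerprint("a", tuple(x)), Fingerprint("b", tuple(neg))]
        _, mat = correlation_matrix(fps)
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_textbook_pearson_formula_long_hand(self):
        """r computed long-hand for x=(1,2,4,5), y=(2,1,5,8).

        mean_x=3, mean_y=4; dx=(-2,-1,1,2), dy=(-2,-3,1,4);
        sum dx*dy = 4+3+1+8 = 16; sum dx^2 = 10; sum dy^2 = 30;
        r = 16/sqrt(300) = 0.9237604...
        """
        from scrsasa.scr_fingerprint import Fingerprint

        fps = [Fingerprint("x", (1.0, 2.0, 4.0, 5.0)),
               Fingerprint("y", (2.0, 1.0, 5.0, 8.0))]
        _, mat = correlation_matrix(fps)
        assert mat[0, 1] == pytest.approx(16 / math.sqrt(300), abs=1e-12)

    def test_zero_variance_names_protein(self):
        from scrsasa.scr_fingerprint import Fingerprint

        fps = [Fingerprint("flat", (2.0, 2.0, 2.0)),
               Fingerprint("b", (1.0, 2.0, 3.0))]
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(fps)

    def test_affine_rescaling_invariance(self):
        from scrsasa.scr_fingerprint import Fingerprint

        rng = np.random.default_rng(0)
        x = rng.uniform(1, 50, size=6)
        y = rng.uniform(1, 50, size=6)
        base = correlation_matrix(
            [Fingerprint("a", tuple(x)), Fingerprint("b", tuple(y))]
        )[1]
        scaled = correlation_matrix(
            [Fingerprint("a", tuple(2.5 * x + 7)), Fingerprint("b", tuple(y))]
        )[1]
        np.testing.assert_allclose(base, scaled, atol=1e-12)


class TestResiduePreferences:
    def test_ggg_block(self):
        aln = [("a", "GGG"), ("b", "GGG")]
        scrs = scrs_from_intervals([("a", "GGG")], [(0, 3)])
        counts = residue_preferences(scrs, {"a": "GGG"})
        assert counts["G"] == 3
        assert sum(counts.values()) == 3

    def test_empty_scrset_all_zero(self):
        aln = [("a", "GAV"), ("b", "GCV")]
        scrs = identify_scrs(aln, min_len=3, min_conservation=1.0)
        counts = residue_preferences(scrs, dict(aln))
        assert set(counts.values()) == {0}

    def test_counts_match_brute_tally(self):
        aln = [("a", "GAVLMW"), ("b", "GAVLMW")]
        scrs = scrs_from_intervals(aln, [(1, 3), (4, 6)])
        counts = residue_preferences(scrs, dict(aln))
        tally = {}
        for pid, seq in aln:
            for i in [1, 2, 4, 5]:
                tally[seq[i]] = tally.get(seq[i], 0) + 1
        for aa, n in tally.items():
            assert counts[aa] == n
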