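import itertools

import numpy as np
import pytest

from lncscreen.coding import (coding_potential_score, filter_lncrna_candidates,
                              find_longest_orf)
from lncscreen.io_formats import Transcript
from oracles import brute_longest_orf


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindLongestOrf:
    def test_counting_convention(self):
        # ATG AAA TAA -> Met, Lys: 2 AA, stop excluded
        orf = find_longest_orf("ATGAAATAA")
        assert (orf.aa_length, orf.start_nt, orf.frame) == (2, 0, 0)

    def test_no_atg_gives_none(self):
        assert find_longest_orf("CCCCCC") is None

    def test_atg_without_stop_needs_flag(self):
        assert find_longest_orf("ATGAAAAAA") is None
        orf = find_longest_orf("ATGAAAAAA", require_stop=False)
        assert orf.aa_length == 3 and not orf.has_stop

    def test_n_codons_never_start_or_stop(self):
        # ATN is not a start; TAN is not a stop
        assert find_longest_orf("ATNAAATAA") is None
        orf = find_longest_orf("ATGAAATANAAATAA")
        assert orf.aa_length == 4  # runs through the TAN codon

    def test_frame_invariant(self):
        orf = find_longest_orf("CCATGAAATAA")
        assert orf.start_nt % 3 == orf.frame == 2

    def test_matches_bruteforce_on_random_500nt(self):
        rng = np.random.default_rng(11)
        for _ in range(120):
            seq = _random_seq(rng, 500)
            got = find_longest_orf(seq)
            expected = brute_longest_orf(seq)
            if expected is None:
                assert got is None
            else:
                assert (got.aa_length, got.start_nt, got.frame) == expected

    def test_matches_bruteforce_exhaustive_short(self):
        # full enumeration over a stop/start-rich alphabet subset
        for n in range(1, 11):
            for letters in itertools.product("ATG", repeat=n):
                seq = "".join(letters)
                got = find_longest_orf(seq)
                expected = brute_longest_orf(seq)
                assert (got is None) == (expected is None)
                if got is not None:
                    assert (got.aa_length, got.start_nt, got.frame) == expected

    def test_prefix_truncation_monotonicity(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = _random_seq(rng, 400)
            full = find_longest_orf(seq)
            shorter = find_longest_orf(seq[: 400 - 3 * int(rng.integers(1, 30))])
            full_aa = full.aa_length if full else 0
            short_aa = shorter.aa_length if shorter else 0
            assert short_aa <= full_aa


class TestCodingPotential:
    def test_long_orf_fraction_is_coding(self):
        seq = "TT" + "ATG" + "GCT" * 87 + "TAA" + "TT"  # 267/271 nt in ORF
        label, score = coding_potential_score(seq)
        assert label == "coding" and score > 0.9

    def test_orf_free_is_noncoding(self):
        label, _ = coding_potential_score("CG" * 150)
        assert label == "noncoding"

    def test_external_labels_pass_through(self):
        seq = "ATG" + "GCT" * 150 + "TAA"  # blatantly coding
        label, _ = coding_potential_score(seq, labels={"t": "noncoding"}, transcript_id="t")
        assert label == "noncoding"


class TestFilterCandidates:
    def _noncoding(self, rng, n, max_aa):
        while True:
            seq = _random_seq(rng, n)
            orf = find_longest_orf(seq)
            aa = orf.aa_length if orf else 0
            if aa <= max_aa and (3 * aa + 3) / n <= 0.4:
                return seq

    def test_boundaries_strict(self):
        rng = np.random.default_rng(3)
        keep = Transcript("keep", self._noncoding(rng, 201, 60))
        drop = Transcript("drop", self._noncoding(rng, 200, 60))
        kept = filter_lncrna_candidates([keep, drop])
        assert [t.id for t in kept] == ["keep"]

    def test_orf_boundary_79_kept_80_removed(self):
        pad = "CG" * 200
        t79 = Transcript("t79", pad + "ATG" + "GCT" * 78 + "TAA" + pad)
        t80 = Transcript("t80", pad + "ATG" + "GCT" * 79 + "TAA" + pad)
        kept = filter_lncrna_candidates([t79, t80])
        assert [t.id for t in kept] == ["t79"]

    def test_planted_passers_and_failers(self):
        rng = np.random.default_rng(5)
        passers = [Transcript(f"p{i}", self._noncoding(rng, 300, 50)) for i in range(10)]
        failers = [Transcript(f"f{i}", self._noncoding(rng, 150, 40)) for i in range(5)]
        failers += [Transcript(f"f{5 + i}", "ATG" + "GCT" * 120 + "TAA" + "CG" * 50)
                    for i in range(5)]
        kept = filter_lncrna_candidates(passers + failers)
        assert sorted(t.id for t in kept) == sorted(t.id for t in passers)

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(9)
        pool = [Transcript(f"t{i}", self._noncoding(rng, int(rng.integers(150, 500)), 70))
                for i in range(20)]
        forward = filter_lncrna_candidates(pool)
        backward = filter_lncrna_candidates(pool[::-1])
        assert sorted(t.id for t in forward) == sorted(t.id for t in backward)
        assert filter_lncrna_candidates(forward) == forward
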