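import numpy as np
import pytest

from lncscreen.errors import ValidationError
from lncscreen.io_formats import SmallRNARead, Transcript
from lncscreen.precursor import (align_local, classify_mirna_precursor,
                                 coverage_stats, hierarchical_classify,
                                 match_reads_exact)
from oracles import naive_local_score, revcomp, scan_occurrences


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAlignLocal:
    def test_self_alignment(self):
        hit = align_local("ACGTACGT", "ACGTACGT")
        assert hit.identity_pct == 100.0
        assert hit.query_cov_pct == 100.0 and hit.subject_cov_pct == 100.0

    def test_plus_minus_is_reverse_complement(self):
        hit = align_local("AAAA", "TTTT", orientation="plus/minus")
        assert hit.identity_pct == 100.0 and hit.hit_len == 4

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_local("", "ACGT")

    def test_no_positive_alignment_returns_none(self):
        assert align_local("AAAA", "TTTT") is None

    def test_score_matches_naive_dp_on_random_pairs(self):
        rng = np.random.default_rng(31)
        for k in range(110):
            a, b = _random_seq(rng, 60), _random_seq(rng, 60)
            if k % 3 == 0:   # make some pairs share a planted segment
                seg = _random_seq(rng, 25)
                a = a[:15] + seg + a[40:]
                b = b[:30] + seg + b[55:]
            hit = align_local(a, b)
            got = hit.score if hit else 0.0
            assert got == naive_local_score(a, b)

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(32)
        for _ in range(30):
            a, b = _random_seq(rng, 50), _random_seq(rng, 50)
            h1 = align_local(a, b)
            h2 = align_local(revcomp(a), revcomp(b))
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert h1.score == h2.score

    def test_gap_columns_count_in_hit_len(self):
        core = "ACGTACGTACGTACGTACGT"
        hit = align_local("GG" + core + "GG", "CC" + core[:10] + core[11:] + "CC")
        assert hit.hit_len == len(core)
        assert hit.matches == len(core) - 1


class TestCoverageStats:
    @pytest.mark.parametrize("qlen,slen,hlen,expected", [
        (1258, 246, 254, (20.19, 103.25)),   # coverage above 100 via gap columns
        (357, 2013, 336, (94.12, 16.69)),
        (100, 100, 100, (100.0, 100.0)),
    ])
    def test_values(self, qlen, slen, hlen, expected):
        assert coverage_stats(qlen, slen, hlen) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            coverage_stats(0, 10, 5)


class TestMirnaClassification:
    def test_exact_embedded_precursor_called(self):
        rng = np.random.default_rng(41)
        prec = _random_seq(rng, 120)
        host = Transcript("host", _random_seq(rng, 150) + prec + _random_seq(rng, 150))
        calls = classify_mirna_precursor([host], [("mir1", prec)])
        assert "host" in calls
        hit = calls["host"][0]
        assert hit.identity_pct == 100.0 and hit.subject_cov_pct == 100.0

    def test_low_identity_not_called(self):
        rng = np.random.default_rng(42)
        prec = _random_seq(rng, 120)
        # mutate every 12th base: ~92% identity spread along the hairpin
        degraded = "".join(
            ("A" if c != "A" else "C") if i % 12 == 0 else c
            for i, c in enumerate(prec))
        host = Transcript("host", _random_seq(rng, 100) + degraded + _random_seq(rng, 100))
        assert classify_mirna_precursor([host], [("mir1", prec)]) == {}

    def test_identity_gate_is_strict_just_below_threshold(self):
        rng = np.random.default_rng(43)
        prec = _random_seq(rng, 120)
        # 2 central mismatches: full-length alignment ~98.3% identity, or a
        # trimmed one below 90% precursor coverage; either way the call flips
        degraded = list(prec)
        for pos in (40, 80):
            degraded[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[degraded[pos]]
        host = Transcript("host", _random_seq(rng, 80) + "".join(degraded)
                          + _random_seq(rng, 80))
        assert classify_mirna_precursor([host], [("mir1", prec)]) == {}

    def test_shared_precursor_two_hosts(self):
        rng = np.random.default_rng(44)
        prec = _random_seq(rng, 110)
        hosts = [Transcript(f"h{i}", _random_seq(rng, 90) + prec + _random_seq(rng, 90))
                 for i in range(2)]
        calls = classify_mirna_precursor(hosts, [("mir1", prec)])
        assert set(calls) == {"h0", "h1"}

    def test_minus_strand_embedding_found(self):
        rng = np.random.default_rng(45)
        prec = _random_seq(rng, 120)
        host = Transcript("host", _random_seq(rng, 100) + revcomp(prec)
                          + _random_seq(rng, 100))
        calls = classify_mirna_precursor([host], [("mir1", prec)])
        assert calls["host"][0].orientation == "plus/minus"


class TestReadMatching:
    def test_planted_slice_offset_reported(self):
        rng = np.random.default_rng(51)
        seq = _random_seq(rng, 200)
        read = SmallRNARead("r1", seq[40:61], "siRNA")
        support = match_reads_exact([Transcript("t", seq)], [read])
        assert support[("t", "siRNA")].positions == ((40, "+"),)
        assert support[("t", "siRNA")].distinct_reads == 1

    def test_single_mismatch_kills_support(self):
        rng = np.random.default_rng(52)
        seq = _random_seq(rng, 200)
        piece = list(seq[40:61])
        piece[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[piece[10]]
        read = SmallRNARead("r1", "".join(piece), "siRNA")
        assert match_reads_exact([Transcript("t", seq)], [read]) == {}

    def test_antisense_occurrence_strand(self):
        rng = np.random.default_rng(53)
        seq = _random_seq(rng, 200)
        read = SmallRNARead("r1", revcomp(seq[100:124]), "siRNA")
        support = match_reads_exact([Transcript("t", seq)], [read])
        assert support[("t", "siRNA")].positions == ((100, "-"),)
        assert match_reads_exact([Transcript("t", seq)], [read],
                                 both_strands=False) == {}

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(54)
        for _ in range(110):
            lnc = Transcript("t", _random_seq(rng, 120))
            # low-complexity reads make repeated occurrences likely
            read_seq = "".join("AC"[i] for i in rng.integers(0, 2, 21))
            lnc2 = Transcript("t2", lnc.sequence[:50] + read_seq + lnc.sequence[50:])
            reads = [SmallRNARead("r", read_seq, "siRNA")]
            support = match_reads_exact([lnc2], reads, both_strands=False)
            expected = scan_occurrences(lnc2.sequence, read_seq)
            got = [off for off, strand in support.get(("t2", "siRNA"),
                                                      type("S", (), {"positions": ()})
                                                      ).positions]
            assert got == expected


class TestHierarchy:
    def _support(self, tid, libs, n=3):
        from lncscreen.precursor import ReadSupport
        return {(tid, lib): ReadSupport(tid, lib, n, tuple((i, "+") for i in range(n)))
                for lib in libs}

    def test_mirna_wins_over_read_support(self):
        from lncscreen.precursor import AlignmentHit
        hit = AlignmentHit("t", "mir1", 240.0, 120, 120, 400, 120, "plus/plus")
        cls = hierarchical_classify("t", {"t": [hit]}, self._support("t", ["siRNA"]))
        assert cls.label == "miRNA_precursor"

    def test_both_libraries_gives_shsi(self):
        cls = hierarchical_classify("t", {}, self._support("t", ["shRNA", "siRNA"]))
        assert cls.label == "shRNA_siRNA_precursor"

    def test_sirna_only(self):
        cls = hierarchical_classify("t", {}, self._support("t", ["siRNA"]))
        assert cls.label == "siRNA_precursor"

    def test_shrna_only_falls_to_other_with_flag(self):
        cls = hierarchical_classify("t", {}, self._support("t", ["shRNA"]))
        assert cls.label == "other" and cls.shrna_only

    def test_min_reads_gate(self):
        support = self._support("t", ["siRNA"], n=2)
        assert hierarchical_classify("t", {}, support, min_reads=3).label == "other"
        assert hierarchical_classify("t", {}, support, min_reads=2).label == "siRNA_precursor"

    def test_no_evidence_is_other(self):
        cls = hierarchical_classify("t", {}, {})
        assert cls.label == "other" and not cls.shrna_only
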