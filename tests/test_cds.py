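import numpy as np
import pytest

from lncscreen.cds import pair_with_cds, table4_report
from lncscreen.errors import ValidationError
from lncscreen.io_formats import Transcript
from oracles import revcomp


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPairing:
    def test_planted_antisense_partner_passes(self):
        rng = np.random.default_rng(61)
        lnc = Transcript("lnc", _random_seq(rng, 500))
        cds = ("cds", revcomp(lnc.sequence[100:400]))
        pairs = pair_with_cds([lnc], [cds])
        passing = [p for p in pairs if p.passes_threshold]
        assert len(passing) == 1
        hit = passing[0].hit
        assert hit.identity_pct == 100.0
        assert hit.subject_cov_pct == 100.0
        assert hit.orientation == "plus/minus"

    def test_sense_copy_fails_plus_minus_search(self):
        # a sense-strand (plus/plus) copy must not pass an antisense screen
        rng = np.random.default_rng(62)
        lnc = Transcript("lnc", _random_seq(rng, 500))
        cds = ("cds", lnc.sequence[100:400])
        pairs = pair_with_cds([lnc], [cds])
        assert not any(p.passes_threshold for p in pairs)

    def test_random_sequences_never_pass(self):
        rng = np.random.default_rng(63)
        lncs = [Transcript(f"l{i}", _random_seq(rng, 400)) for i in range(5)]
        cds_set = [(f"c{j}", _random_seq(rng, 300)) for j in range(5)]
        pairs = pair_with_cds(lncs, cds_set)
        assert not any(p.passes_threshold for p in pairs)

    def test_planted_cohort_exact_recovery(self):
        rng = np.random.default_rng(64)
        lncs = [Transcript(f"l{i}", _random_seq(rng, 450)) for i in range(20)]
        cds_set = [(f"decoy{j}", _random_seq(rng, 300)) for j in range(15)]
        planted = set()
        for k in range(4):
            lnc = lncs[3 * k]
            cds_set.append((f"partner{k}", revcomp(lnc.sequence[50:350])))
            planted.add((lnc.id, f"partner{k}"))
        pairs = pair_with_cds(lncs, cds_set)
        got = {(p.lncrna_id, p.cds_id) for p in pairs if p.passes_threshold}
        assert got == planted

    def test_one_lncrna_many_cds(self):
        rng = np.random.default_rng(65)
        lnc = Transcript("lnc", _random_seq(rng, 700))
        cds_set = [("c1", revcomp(lnc.sequence[0:300])),
                   ("c2", revcomp(lnc.sequence[350:650]))]
        pairs = pair_with_cds([lnc], cds_set)
        assert sum(p.passes_threshold for p in pairs) == 2

    def test_coverage_modes(self):
        rng = np.random.default_rng(66)
        lnc = Transcript("lnc", _random_seq(rng, 600))
        cds = ("c", revcomp(lnc.sequence[100:400]))  # query coverage only 50%
        assert pair_with_cds([lnc], [cds], coverage_mode="max")[0].passes_threshold
        assert not pair_with_cds([lnc], [cds], coverage_mode="both")[0].passes_threshold
        assert not pair_with_cds([lnc], [cds], coverage_mode="query")[0].passes_threshold

    def test_empty_cds_set_rejected(self):
        with pytest.raises(ValidationError):
            pair_with_cds([Transcript("l", "ACGT" * 60)], [])


class TestReport:
    def test_columns_and_rounding(self):
        rng = np.random.default_rng(67)
        lnc = Transcript("lnc", _random_seq(rng, 591))
        cds = ("c", revcomp(lnc.sequence))
        df = table4_report(pair_with_cds([lnc], [cds]))
        assert list(df.columns) == [
            "Query_name", "Hit_name", "Query_len", "Sbject_len", "Hit_len",
            "Percent_identity", "Percent_query_aligned", "Percent_Sbject_aligned"]
        row = df.iloc[0]
        assert row["Percent_query_aligned"] == 100.0
        assert row["Percent_Sbject_aligned"] == 100.0

    def test_empty_pairs_header_only(self, tmp_path):
        out = tmp_path / "t4.tsv"
        df = table4_report([], out)
        assert df.empty
        assert out.read_text().startswith("Query_name\t")

    def test_per_side_coverages_consistent(self):
        # qcov * qlen == scov * slen == 100 * hit_len, up to rounding
        rng = np.random.default_rng(68)
        lncs = [Transcript(f"l{i}", _random_seq(rng, int(rng.integers(300, 800))))
                for i in range(6)]
        cds_set = [(f"p{i}", revcomp(l.sequence[20:20 + 240])) for i, l in enumerate(lncs)]
        df = table4_report(pair_with_cds(lncs, cds_set))
        for _, r in df.iterrows():
            lhs = r["Percent_query_aligned"] * r["Query_len"]
            rhs = r["Percent_Sbject_aligned"] * r["Sbject_len"]
            assert lhs == pytest.approx(100 * r["Hit_len"], rel=1e-3)
            assert rhs == pytest.approx(100 * r["Hit_len"], rel=1e-3)

    def test_score_symmetric_in_roles(self):
        rng = np.random.default_rng(69)
        a, b = _random_seq(rng, 300), _random_seq(rng, 250)
        from lncscreen.precursor import align_local
        h1 = align_local(a, b, orientation="plus/minus")
        h2 = align_local(b, a, orientation="plus/minus")
        if h1 is not None and h2 is not None:
            assert h1.score == h2.score
            assert h1.hit_len == h2.hit_len
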