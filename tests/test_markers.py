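import itertools

import pandas as pd
import pytest

from lporlab import simulate as sim
from lporlab.errors import TbloutParseError, ValidationError
from lporlab.markers import (
    MARKERS,
    HmmHit,
    MarkerMatrix,
    call_aapb,
    classify_genomes,
    parse_hmm_tblout,
    presence_matrix,
    read_cutoff_table,
)

TBLOUT = """\
#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----
# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target
#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ ----- --- --- --- --- --- --- --- --- ---------------------
G0001|p7             -          LPOR                 TIGR01289    1.2e-50  120.0   0.1   1.5e-49  119.0   0.1   1.0   1   0   0   1   1   1   1 putative oxidoreductase
G0002|p3             -          LPOR                 TIGR01289    2.0e-06   80.0   0.0   3.0e-06   79.0   0.0   1.0   1   0   0   1   1   1   1 -
G0001|p9             -          BchL                 TIGR02016    5.0e-40  101.5   0.0   6.0e-40  100.9   0.0   1.0   1   0   0   1   1   1   1 -
G0001|p2             -          BchL                 TIGR02016    9.0e-09   40.0   0.0   1.0e-08   39.5   0.0   1.0   1   0   0   1   1   1   1 -
"""

COMMENTS_ONLY = """\
# target name        accession  query name           accession    E-value  score
#
# Program:         hmmsearch
"""


@pytest.fixture
def tblout_path(tmp_path):
    p = tmp_path / "search.tbl"
    p.write_text(TBLOUT)
    return p


CUTOFFS = {"LPOR": 100.0, "BchL": 50.0}


class TestParseTblout:
    def test_comments_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tbl"
        p.write_text(COMMENTS_ONLY)
        assert parse_hmm_tblout(p) == []

    def test_hit_above_cutoff_retained_as_meeting(self, tblout_path):
        hits = parse_hmm_tblout(tblout_path, cutoffs=CUTOFFS)
        above = [h for h in hits if h.genome_id == "G0001" and h.marker == "LPOR"]
        assert above[0].score == 120.0 and above[0].meets_cutoff

    def test_hit_below_cutoff_parsed_but_flagged(self, tblout_path):
        hits = parse_hmm_tblout(tblout_path, cutoffs=CUTOFFS)
        below = [h for h in hits if h.genome_id == "G0002"]
        assert below[0].score == 80.0 and not below[0].meets_cutoff

    def test_unknown_marker_rejected(self, tmp_path):
        p = tmp_path / "bad.tbl"
        p.write_text(TBLOUT.replace("LPOR ", "Xyz  "))
        with pytest.raises(TbloutParseError, match="no known marker"):
            parse_hmm_tblout(p)

    def test_cutoff_table_round_trip(self, tmp_path):
        p = tmp_path / "cutoffs.tsv"
        p.write_text("model_name\ttrusted_cutoff_bits\nLPOR\t100.0\nBchL\t50.0\n")
        assert read_cutoff_table(p) == CUTOFFS


class TestPresenceMatrix:
    def test_no_hits_all_absent(self):
        m = presence_matrix([], genomes=["G1"])
        assert not m.presence.loc["G1"].any()

    def test_single_qualifying_hit(self):
        hit = HmmHit("G1", "LPOR", 120.0, 1e-50, trusted_cutoff=100.0)
        m = presence_matrix([hit], genomes=["G1"])
        assert m.presence.loc["G1", "LPOR"]
        assert m.presence.loc["G1"].sum() == 1

    def test_best_qualifying_hit_kept_as_provenance(self):
        hits = [HmmHit("G1", "BchL", 101.5, 1e-40, trusted_cutoff=50.0),
                HmmHit("G1", "BchL", 40.0, 1e-8, trusted_cutoff=50.0)]
        m = presence_matrix(hits, genomes=["G1"])
        assert m.presence.loc["G1", "BchL"]
        assert m.provenance[("G1", "BchL")].score == 101.5

    def test_order_independent_and_idempotent(self, tblout_path):
        hits = parse_hmm_tblout(tblout_path, cutoffs=CUTOFFS)
        a = presence_matrix(hits)
        b = presence_matrix(list(reversed(hits)))
        pd.testing.assert_frame_equal(a.presence, b.presence)

    def test_evalue_fallback_without_cutoff(self):
        good = HmmHit("G1", "PufL", 30.0, 1e-10)
        weak = HmmHit("G1", "PufM", 5.0, 0.5)
        m = presence_matrix([good, weak], genomes=["G1"])
        assert m.presence.loc["G1", "PufL"]
        assert not m.presence.loc["G1", "PufM"]


RULE_MARKERS = ("BchB", "BchL", "BchN", "PufL", "PufM", "AcsF", "BchE",
                "RuBisCO_large", "PRK")


def oracle_rule(row):
    """Independent truth-table evaluation of the AAPB definition."""
    return (row["BchB"] and row["BchL"] and row["BchN"]
            and row["PufL"] and row["PufM"]
            and (row["AcsF"] or row["BchE"])
            and not (row["RuBisCO_large"] and row["PRK"]))


class TestCallAapb:
    def base_row(self, **overrides):
        row = {m: False for m in MARKERS}
        row.update({m: True for m in ("BchB", "BchL", "BchN", "PufL",
                                      "PufM", "AcsF")})
        row.update(overrides)
        return row

    def test_canonical_aapb_pattern(self):
        assert call_aapb(self.base_row()).is_aapb

    def test_both_calvin_markers_disqualify(self):
        assert not call_aapb(self.base_row(RuBisCO_large=True, PRK=True)).is_aapb

    def test_one_calvin_marker_tolerated(self):
        assert call_aapb(self.base_row(RuBisCO_large=True)).is_aapb

    def test_missing_dpor_subunit_disqualifies(self):
        assert not call_aapb(self.base_row(BchL=False)).is_aapb

    def test_strict_calvin_option(self):
        row = self.base_row(RuBisCO_large=True)
        assert not call_aapb(row, strict_calvin=True).is_aapb

    def test_reasons_reconstruct_decision(self):
        call = call_aapb(self.base_row(BchL=False, PRK=True))
        assert len(call.reasons) == 4
        assert any("violated" in r and "DPOR" in r for r in call.reasons)
        assert any("satisfied" in r and "RuBisCO" in r for r in call.reasons)

    def test_exhaustive_truth_table_agreement(self):
        # all 2^9 combinations of the rule-relevant markers (RuBisCO and
        # PRK vary independently of the seven presence-side markers)
        for bits in itertools.product([False, True], repeat=len(RULE_MARKERS)):
            row = {m: False for m in MARKERS}
            row.update(dict(zip(RULE_MARKERS, bits)))
            assert call_aapb(row).is_aapb == oracle_rule(row)

    def test_incomplete_row_rejected(self):
        with pytest.raises(ValidationError):
            call_aapb({"BchB": True})


def test_generator_labels_recovered_on_thousand_genomes():
    mat, labels = sim.gen_marker_table(
        1000, sim.SimConfig(seed=42),
        class_mix={"aapb": 0.4, "oxygenic": 0.3, "non_phototroph": 0.3})
    calls = classify_genomes(mat)
    assert [c.is_aapb for c in calls] == [lab == "aapb" for lab in labels]


def test_matrix_tsv_round_trip(tmp_path):
    mat, _ = sim.gen_marker_table(20, sim.SimConfig(seed=8))
    p = tmp_path / "markers.tsv"
    mat.to_tsv(p)
    back = MarkerMatrix.from_tsv(p)
    pd.testing.assert_frame_equal(back.presence, mat.presence)
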