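import pytest

from isoscan.report import (check_additive_identities, derive_report,
                            percent, round_half_up)


def test_percent_rounding_half_up():
    assert percent(134204, 197709, 2) == 67.88
    assert percent(21326, 28599, 1) == 74.6
    assert percent(1211, 1577, 1) == 76.8
    assert percent(2433, 3026, 1) == 80.4
    assert percent(0, 100) == 0.0
    assert percent(1, 0) is None


def test_round_half_up_behaviour():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(74.55, 1) == 74.6


def test_additive_identities_pass_on_consistent_counts():
    counts = dict(flnc_type1=175375, flnc_type2=22334, flnc_total=197709,
                  undetermined=10944, g1=134204, g2=15352, g3=27014,
                  g4=8669, g5=1526, hq_reads=91881, excluded_reads=42323,
                  loci_total=16188, loci_extant=13162, loci_novel=3026,
                  transcripts_total=22768, transcripts_known_loci=19023,
                  transcripts_novel_loci=3745, transcripts_confirmed=13177,
                  transcripts_new_at_known=5846, novel_transcripts=9591,
                  hq_reads_extant=83736, hq_reads_novel=8145)
    check_additive_identities(counts)


def test_additive_identities_detect_violation():
    with pytest.raises(AssertionError):
        check_additive_identities(dict(flnc_type1=10, flnc_type2=5,
                                       flnc_total=14))


def test_derive_report_core_figures():
    counts = dict(flnc_type1=175375, flnc_type2=22334,
                  undetermined=10944, g1=134204,
                  orf_reads_complete=21326, orf_reads_total=28599,
                  loci_extant=13162, loci_novel=3026,
                  transcripts_known_loci=19023, transcripts_novel_loci=3745,
                  transcripts_new_at_known=5846,
                  novel_mean_length=2433, known_mean_length=2388,
                  family_reads_complete=1211, family_reads_positive=1577,
                  novel_loci_annotated=2433)
    d = derive_report(counts)
    assert d["flnc_total"] == 197709
    assert d["strand_resolved"] == 186765
    assert d["g1_percent_of_flnc"] == 67.88
    assert d["orf_complete_percent"] == 74.6
    assert d["loci_total"] == 16188
    assert d["transcripts_total"] == 22768
    assert d["novel_transcripts"] == 9591
    assert d["novel_minus_known_mean_length"] == 45
    assert d["family_complete_percent"] == 76.8
    assert d["novel_loci_annotated_percent"] == 80.4
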