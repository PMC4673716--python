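"""Summary-report arithmetic: derived counts and percentages.

Every percentage the pipeline prints is recomputed here from its component
counts (half-up rounding at reporting time only), and the additive
identities that must hold between stage counts are enforced as hard checks.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Headline counts of the hexaploid wheat caryopsis single-molecule
#: transcriptome dataset whose analysis this package re-implements at toy
#: scale.  They are inputs to the reporting layer: every derived figure
#: (sums, differences, percentages) is recomputed from these components.
REFERENCE_WHEAT_COUNTS = {
    "clr_total": 526915,
    "subreads_type1": 1618400,
    "subreads_type2": 570293,
    "ccs": 240312,
    "flnc_type1": 175375,
    "flnc_type2": 22334,
    "flnc_total": 197709,
    "undetermined": 10944,
    "g1": 134204,
    "g2": 15352,
    "g3": 27014,
    "g4": 8669,
    "g5": 1526,
    "g2_refined": 15049,
    "g2_one_best": 554,
    "g2_multi_within": 6348,
    "g2_multi_across": 8147,
    "excluded_reads": 42323,
    "hq_reads": 91881,
    "hq_reads_extant": 83736,
    "hq_reads_novel": 8145,
    "loci_extant": 13162,
    "loci_novel": 3026,
    "loci_total": 16188,
    "novel_loci_annotated": 2433,
    "novel_loci_on_annotated_contigs": 666,
    "novel_loci_on_model_free_contigs": 2360,
    "transcripts_confirmed": 13177,
    "transcripts_new_at_known": 5846,
    "transcripts_known_loci": 19023,
    "transcripts_novel_loci": 3745,
    "transcripts_total": 22768,
    "novel_transcripts": 9591,
    "orf_reads_total": 28599,
    "orf_reads_complete": 21326,
    "orf_loci_shared": 1347,
    "novel_mean_length": 2433,
    "known_mean_length": 2388,
    "family_reads_positive": 1577,
    "family_reads_complete": 1211,
    "family_unique_transcripts": 72,
    "spanning_transcripts": 180,
}


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float,
            decimals: int = 1) -> float | None:
    """Half-up rounded percentage; None when the denominator is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, decimals)


def check_additive_identities(c: dict) -> None:
    """Hard assertions over the count table; raises on any violation."""
    def has(*keys):
        return all(k in c for k in keys)

    if has("flnc_type1", "flnc_type2", "flnc_total"):
        assert c["flnc_total"] == c["flnc_type1"] + c["flnc_type2"], \
            "FLNC total != type I + type II"
    if has("flnc_total", "undetermined", "g1", "g2", "g3", "g4", "g5"):
        assert (c["g1"] + c["g2"] + c["g3"] + c["g4"] + c["g5"] +
                c["undetermined"]) == c["flnc_total"], \
            "group sizes do not sum to the FLNC total"
    if has("g1", "hq_reads", "excluded_reads"):
        assert c["hq_reads"] == c["g1"] - c["excluded_reads"], \
            "high-quality reads != G1 - excluded"
    if has("loci_total", "loci_extant", "loci_novel"):
        assert c["loci_total"] == c["loci_extant"] + c["loci_novel"], \
            "locus total != extant + novel"
    if has("transcripts_total", "transcripts_known_loci",
           "transcripts_novel_loci"):
        assert c["transcripts_total"] == (c["transcripts_known_loci"] +
                                          c["transcripts_novel_loci"]), \
            "transcript total != at-known + at-novel"
    if has("transcripts_known_loci", "transcripts_confirmed",
           "transcripts_new_at_known"):
        assert c["transcripts_known_loci"] == (
            c["transcripts_confirmed"] + c["transcripts_new_at_known"]), \
            "known-locus transcripts != confirmed + new"
    if has("novel_transcripts", "transcripts_new_at_known",
           "transcripts_novel_loci"):
        assert c["novel_transcripts"] == (
            c["transcripts_new_at_known"] + c["transcripts_novel_loci"]), \
            "novel transcripts != new-at-known + at-novel-loci"
    if has("hq_reads", "hq_reads_extant", "hq_reads_novel"):
        assert c["hq_reads"] == c["hq_reads_extant"] + c["hq_reads_novel"], \
            "high-quality reads != extant-assigned + novel-assigned"


def derive_report(counts: dict) -> dict:
    """All derived figures the summary prints, from component counts.

    Only the figures whose components are present are produced; every
    percentage is rounded half-up to the number of decimals used in
    reporting (2 for read-share figures, 1 otherwise).
    """
    c = dict(counts)
    d: dict = {}
    if "flnc_type1" in c and "flnc_type2" in c:
        c.setdefault("flnc_total", c["flnc_type1"] + c["flnc_type2"])
        d["flnc_total"] = c["flnc_total"]
    if "flnc_total" in c and "undetermined" in c:
        d["strand_resolved"] = c["flnc_total"] - c["undetermined"]
    if "g1" in c and "flnc_total" in c:
        d["g1_percent_of_flnc"] = percent(c["g1"], c["flnc_total"], 2)
    if "orf_reads_complete" in c and "orf_reads_total" in c:
        d["orf_complete_percent"] = percent(c["orf_reads_complete"],
                                            c["orf_reads_total"], 1)
    if "loci_extant" in c and "loci_novel" in c:
        d["loci_total"] = c["loci_extant"] + c["loci_novel"]
    if "transcripts_known_loci" in c and "transcripts_novel_loci" in c:
        d["transcripts_total"] = (c["transcripts_known_loci"] +
                                  c["transcripts_novel_loci"])
    if "transcripts_new_at_known" in c and "transcripts_novel_loci" in c:
        d["novel_transcripts"] = (c["transcripts_new_at_known"] +
                                  c["transcripts_novel_loci"])
    if "novel_mean_length" in c and "known_mean_length" in c:
        d["novel_minus_known_mean_length"] = (c["novel_mean_length"] -
                                              c["known_mean_length"])
    if "family_reads_complete" in c and "family_reads_positive" in c:
        d["family_complete_percent"] = percent(c["family_reads_complete"],
                                               c["family_reads_positive"], 1)
    if "novel_loci_annotated" in c and "loci_novel" in c:
        d["novel_loci_annotated_percent"] = percent(
            c["novel_loci_annotated"], c["loci_novel"], 1)
    if "g2_refined" in c and "g2_one_best" in c and \
            "g2_multi_within" in c and "g2_multi_across" in c:
        d["g2_pattern_sum"] = (c["g2_one_best"] + c["g2_multi_within"] +
                               c["g2_multi_across"])
    if "junctions_supported" in c and "junctions_total" in c:
        d["junction_supported_percent"] = percent(
            c["junctions_supported"], c["junctions_total"], 0)
    return d
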