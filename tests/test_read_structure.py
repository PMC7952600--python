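"""Barcode parsing, whitelist correction and antibody-tag extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genotag.read_structure import (
    AntibodyPanel,
    BarcodeSchema,
    Whitelist,
    correct_sequence,
    hamming,
    parse_antibody_tag,
    parse_cell_barcode,
    parse_tag_read_pair,
)
from genotag.synthetic_data import (
    default_panel,
    default_schema,
    default_whitelist,
    emit_antibody_reads,
    simulate_truth,
)
from genotag.scenarios import get_scenario
from genotag.read_structure import read_fastq_pairs
from genotag.umi_counting import group_umis


Q30 = "?" * 10  # Phred+33: '?' = Q30
HIGH = "I" * 18


class TestCorrectSequence:
    @pytest.mark.parametrize(
        "observed,entries,expect_seq,expect_reason",
        [
            ("ACGT", {"ACGT", "TTTT"}, "ACGT", "ok"),  # identity
            ("ACGTACGT", {"ACGTACGA"}, "ACGTACGA", "ok"),  # one substitution
            ("AAAA", {"AAAT", "AAAC"}, None, "ambiguous"),  # two at distance 1
            ("GGGG", {"AAAA", "TTTT"}, None, "no_match"),  # too far
            ("AC", {"ACGT"}, None, "length"),
        ],
    )
    def test_matching_outcomes(self, observed, entries, expect_seq, expect_reason):
        res = correct_sequence(observed, frozenset(entries))
        assert res.sequence == expect_seq
        assert res.reason == expect_reason

    def test_exact_match_wins_at_distance_zero(self):
        # entry at distance 0 beats competitors at distance 1
        res = correct_sequence("AAAA", frozenset({"AAAA", "AAAT"}))
        assert res.sequence == "AAAA" and res.distance == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(observed=st.text(alphabet="ACGT", min_size=9, max_size=9))
    def test_correction_is_idempotent_and_within_distance(self, observed, whitelist):
        entries = whitelist.segments[0]
        res = correct_sequence(observed, entries)
        if res.ok:
            assert hamming(observed, res.sequence) <= 1
            again = correct_sequence(res.sequence, entries)
            assert again.sequence == res.sequence and again.distance == 0


class TestParseCellBarcode:
    def _read(self, schema, s1, s2, link_override=None):
        linker = link_override if link_override is not None else schema.linker_sequences[0]
        return schema.adapter_5p + s1 + linker + s2

    def test_exact_segments(self, schema, whitelist):
        s1 = sorted(whitelist.segments[0])[0]
        s2 = sorted(whitelist.segments[1])[0]
        seq = self._read(schema, s1, s2)
        bc, reason = parse_cell_barcode(seq, "I" * len(seq), schema, whitelist)
        assert bc == s1 + s2 and reason == "ok"

    def test_one_substitution_corrected(self, schema, whitelist):
        s1 = sorted(whitelist.segments[0])[0]
        s2 = sorted(whitelist.segments[1])[0]
        mutated = ("A" if s2[0] != "A" else "C") + s2[1:]
        seq = self._read(schema, s1, mutated)
        bc, reason = parse_cell_barcode(seq, "I" * len(seq), schema, whitelist)
        assert bc == s1 + s2 and reason == "ok"

    def test_broken_linker_is_structure_failure(self, schema, whitelist):
        s1 = sorted(whitelist.segments[0])[0]
        s2 = sorted(whitelist.segments[1])[0]
        bad_linker = "A" * len(schema.linker_sequences[0])
        seq = self._read(schema, s1, s2, link_override=bad_linker)
        bc, reason = parse_cell_barcode(seq, "I" * len(seq), schema, whitelist)
        assert bc is None and reason == "structure"

    def test_truncated_read_is_structure_failure(self, schema, whitelist):
        bc, reason = parse_cell_barcode("ACGT", "IIII", schema, whitelist)
        assert bc is None and reason == "structure"


class TestParseAntibodyTag:
    def test_exact_tag_good_umi(self, panel):
        seq = panel.tags[0] + "ACGTACGTAC"
        ab, umi, reason = parse_antibody_tag(seq, HIGH, panel)
        assert ab == panel.names[0] and umi == "ACGTACGTAC" and reason == "ok"

    def test_low_quality_umi_base_rejected(self, panel):
        # one UMI base at Q10 ('+') fails the Q20 minimum
        quals = "I" * 8 + "+" + "I" * 9
        seq = panel.tags[0] + "ACGTACGTAC"
        ab, umi, reason = parse_antibody_tag(seq, quals, panel)
        assert ab is None and reason == "umi_quality"

    def test_q20_boundary_accepted(self, panel):
        # '5' encodes exactly Q20, which satisfies "minimum quality of 20"
        quals = "I" * 8 + "5" * 10
        ab, umi, reason = parse_antibody_tag(panel.tags[0] + "ACGTACGTAC", quals, panel)
        assert reason == "ok"

    def test_tag_with_one_substitution_corrected(self, panel):
        tag = panel.tags[1]
        mutated = ("A" if tag[0] != "A" else "C") + tag[1:]
        ab, umi, reason = parse_antibody_tag(mutated + "ACGTACGTAC", HIGH, panel)
        assert ab == panel.names[1] and reason == "ok"

    def test_unknown_tag_rejected(self, panel):
        ab, umi, reason = parse_antibody_tag("ATATATAT" + "ACGTACGTAC", HIGH, panel)
        assert ab is None and reason == "tag"


class TestPanelValidation:
    def test_close_tags_rejected(self):
        with pytest.raises(ValueError, match="too close"):
            AntibodyPanel([("a", "AAAAAAAA", False), ("b", "AAAAAAAT", False)])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AntibodyPanel([("a", "AAAACCCC", False), ("a", "GGGGTTTT", False)])


class TestWhitelistValidation:
    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            Whitelist([["ACGT", "ACGTA"]])

    def test_min_pairwise_distance_recorded(self, whitelist):
        assert all(d >= 3 for d in whitelist.min_pairwise_distance)


def test_error_free_reads_all_parse_to_origin(tmp_path, panel, whitelist, schema):
    """With substitution rates 0, every emitted read resolves to its true cell."""
    sc = get_scenario("three_populations", scale=0.01)
    truth = simulate_truth(sc.populations, sc.tech, seed=7)
    r1, r2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
    emit_antibody_reads(truth, r1, r2, schema, sc.tech, seed=7)
    true_cells = set(truth.cells.index)
    n = 0
    for s1, q1, s2, q2 in read_fastq_pairs(r1, r2):
        r = parse_tag_read_pair(s1, q1, s2, q2, schema, whitelist, panel)
        assert r.valid and r.cell_barcode in true_cells
        n += 1
    assert n > 0
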