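"""Record-level quality control."""

import pytest
from hypothesis import given, settings, strategies as st

from pinot.mitab import RawRecord
from pinot.qc import DiscardEntry, EvidenceUnit, filter_batch, filter_record

HUMAN = 9606


def rec(codes=("MI:0018",), pmids=("11111111",), taxa=(HUMAN, HUMAN),
        a="P99999", b="P37840", line_no=1):
    return RawRecord(
        source_db="intact",
        id_a=f"uniprotkb:{a}",
        id_b=f"uniprotkb:{b}",
        taxid_a=taxa[0],
        taxid_b=taxa[1],
        detection_codes=tuple(codes),
        pmids=tuple(pmids),
        line_no=line_no,
    )


class TestFilterRecord:
    def test_complete_record_yields_one_unit(self, method_table, tiny_mapping):
        out = filter_record(rec(), HUMAN, method_table, tiny_mapping)
        assert isinstance(out, list) and len(out) == 1
        unit = out[0]
        assert isinstance(unit, EvidenceUnit)
        assert unit.category == "Two Hybrid (2Hyb)"
        assert unit.pmid == "11111111"

    @pytest.mark.parametrize(
        "kwargs,stage,reason",
        [
            (dict(pmids=()), "pmid", "no_pmid"),
            (dict(pmids=("111", "222")), "pmid", "multiple_pmids"),
            (dict(codes=()), "method", "no_method"),
            (dict(taxa=(HUMAN, 10090)), "taxonomy", "wrong_taxid"),
            (dict(b="P88888"), "mapping", "ambiguous"),
            (dict(b="Q99999"), "mapping", "unmapped"),
        ],
    )
    def test_discard_reasons(self, method_table, tiny_mapping, kwargs, stage, reason):
        out = filter_record(rec(**kwargs), HUMAN, method_table, tiny_mapping)
        assert out == DiscardEntry(stage, reason, out.payload)
        assert out.stage == stage and out.reason == reason

    def test_repeated_identical_pmid_tokens_are_single_publication(
        self, method_table, tiny_mapping
    ):
        out = filter_record(
            rec(pmids=("111", "111")), HUMAN, method_table, tiny_mapping
        )
        assert isinstance(out, list) and out[0].pmid == "111"

    def test_multi_code_record_yields_unit_per_code(self, method_table, tiny_mapping):
        out = filter_record(
            rec(codes=("MI:0018", "MI:0019")), HUMAN, method_table, tiny_mapping
        )
        assert [u.category for u in out] == [
            "Two Hybrid (2Hyb)", "Affinity Purification (AP)"
        ]

    def test_self_interaction_retained(self, method_table, tiny_mapping):
        out = filter_record(rec(b="P99999"), HUMAN, method_table, tiny_mapping)
        assert isinstance(out, list)
        assert out[0].triple_a == out[0].triple_b

    def test_missing_taxid_tolerated_lenient_only(self, method_table, tiny_mapping):
        record = rec(taxa=(None, HUMAN))
        lenient = filter_record(record, HUMAN, method_table, tiny_mapping, "lenient")
        stringent = filter_record(
            record, HUMAN, method_table, tiny_mapping, "stringent"
        )
        assert isinstance(lenient, list)
        assert stringent == DiscardEntry("taxonomy", "missing_taxid", stringent.payload)

    def test_unmapped_code_split_by_mode(self, method_table, tiny_mapping):
        record = rec(codes=("MI:9999",))
        lenient = filter_record(record, HUMAN, method_table, tiny_mapping, "lenient")
        stringent = filter_record(
            record, HUMAN, method_table, tiny_mapping, "stringent"
        )
        assert isinstance(lenient, list) and lenient[0].category == "MI:9999"
        assert stringent.reason == "unmapped_method"


class TestFilterBatch:
    def test_conservation_on_mixed_batch(self, method_table, tiny_mapping):
        records = (
            [rec(line_no=i + 1) for i in range(6)]
            + [rec(pmids=(), line_no=7), rec(pmids=(), line_no=8)]
            + [rec(pmids=("1", "2"), line_no=9)]
            + [rec(taxa=(HUMAN, 10090), line_no=10)]
        )
        units, discards = filter_batch(records, HUMAN, method_table, tiny_mapping)
        assert len(discards) == 4
        assert len(units) == 6
        assert {d.reason for d in discards} == {
            "no_pmid", "multiple_pmids", "wrong_taxid"
        }

    def test_empty_batch(self, method_table, tiny_mapping):
        assert filter_batch([], HUMAN, method_table, tiny_mapping) == ([], [])

    def test_purity_same_batch_twice(self, method_table, tiny_mapping):
        records = [rec(), rec(pmids=())]
        first = filter_batch(records, HUMAN, method_table, tiny_mapping)
        second = filter_batch(records, HUMAN, method_table, tiny_mapping)
        assert first == second


@st.composite
def raw_records(draw):
    codes = draw(st.lists(
        st.sampled_from(["MI:0018", "MI:0397", "MI:0019", "MI:9999"]),
        max_size=3, unique=True))
    pmids = draw(st.lists(st.sampled_from(["111", "222"]), max_size=2,
                          unique=True))
    taxa = draw(st.tuples(st.sampled_from([HUMAN, 10090, None]),
                          st.sampled_from([HUMAN, None])))
    b = draw(st.sampled_from(["P37840", "O60260", "P88888", "Q99999"]))
    return rec(codes=codes, pmids=pmids, taxa=taxa, b=b)


class TestModeOrdering:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(raw_records(), max_size=12))
    def test_stringent_units_subset_of_lenient(
        self, method_table, tiny_mapping, records
    ):
        """The stringent regime can only remove evidence, never add it."""
        lenient, _ = filter_batch(
            records, HUMAN, method_table, tiny_mapping, "lenient"
        )
        stringent, _ = filter_batch(
            records, HUMAN, method_table, tiny_mapping, "stringent"
        )
        assert set(stringent) <= set(lenient)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(raw_records(), max_size=12))
    def test_record_conservation(self, method_table, tiny_mapping, records):
        """Every record yields units or exactly one discard entry."""
        for mode in ("lenient", "stringent"):
            units, discards = filter_batch(
                records, HUMAN, method_table, tiny_mapping, mode
            )
            sourced = len(records) - len(discards)
            assert sourced >= 0
            assert len(units) >= sourced  # >=1 unit per surviving record

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(raw_records())
    def test_species_purity(self, method_table, tiny_mapping, record):
        """A record with any off-species taxid is discarded at taxonomy."""
        out = filter_record(record, HUMAN, method_table, tiny_mapping)
        off_species = any(
            t is not None and t != HUMAN for t in (record.taxid_a, record.taxid_b)
        )
        if off_species:
            assert isinstance(out, DiscardEntry) and out.stage == "taxonomy"
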