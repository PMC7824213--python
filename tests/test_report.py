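import pandas as pd
import pytest

from trlocus.report import (
    CellEntry,
    GeneRecord,
    build_repertoire_table,
    cdr_length_table,
    compare_repertoires,
    fixture_path,
    load_cdr_fixture,
    load_table_fixture,
    locus_statistics,
    parse_cell,
    parse_count_cell,
    render_cell,
)
from oracles import table_totals_loop


class TestCellGrammar:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("1 F", [CellEntry(1, "F", 1)]),
            ("1 O (2)", [CellEntry(1, "ORF", 2)]),
            ("2 F (3), 1 P", [CellEntry(2, "F", 3), CellEntry(1, "P", 1)]),
            ("1 FP (2)", [CellEntry(1, "FP", 2)]),
            ("1 FOP (3)", [CellEntry(1, "FOP", 3)]),
            ("-", []),
            ("", []),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_cell(text) == expected

    def test_render_roundtrip(self):
        for text in ("1 F", "2 F (3), 1 P", "1 FP (2)", "-"):
            assert render_cell(parse_cell(text)) == text

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_cell("two F")

    def test_count_cell_with_non_localized(self):
        assert parse_count_cell("277 (+16 non localized)") == (277, 16)
        assert parse_count_cell("56") == (56, 0)


FIXTURE_TOTALS = {
    # (fixture, prefix) -> species -> printed totals row (genes, alleles)
    ("traj_sets.tsv", "TRAJ"): {"human": (61, 71), "bovine": (60, 72), "sheep": (80, 87)},
    ("trdd_sets.tsv", "TRDD"): {"human": (3, 3), "bovine": (9, 9), "sheep": (9, 10)},
    ("trdj_sets.tsv", "TRDJ"): {"human": (4, 4), "bovine": (4, 4), "sheep": (4, 4)},
    ("trav_subgroups.tsv", "TRAV"): {"human": (61, 134), "bovine": (183, 263), "sheep": (293, 344)},
    ("trdv_subgroups.tsv", "TRDV"): {"human": (3, 6), "bovine": (55, 72), "sheep": (88, 117)},
}


class TestFixtureTables:
    @pytest.mark.parametrize("key", list(FIXTURE_TOTALS))
    def test_grand_totals_reproduce_printed_rows(self, key):
        name, prefix = key
        for species, want in FIXTURE_TOTALS[key].items():
            table = load_table_fixture(fixture_path(name), species, prefix)
            assert table.grand_total() == want

    @pytest.mark.parametrize("key", list(FIXTURE_TOTALS))
    def test_totals_agree_with_naive_counting_oracle(self, key):
        name, _ = key
        df = pd.read_csv(fixture_path(name), sep="\t", dtype=str).fillna("-")
        for species in ("human", "bovine", "sheep"):
            table = load_table_fixture(fixture_path(name), species, key[1])
            rows = dict(zip(df.iloc[:, 0], df[species]))
            assert table.grand_total() == table_totals_loop(rows)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            load_table_fixture(fixture_path("traj_sets.tsv"), "mouse", "TRAJ")


class TestBuildTable:
    RECORDS = [
        GeneRecord("TRAJ8-1", "TRAJ", "TRAJ8", "F", alleles=2),
        GeneRecord("TRAJ8-2", "TRAJ", "TRAJ8", "F", alleles=1),
        GeneRecord("TRAJ9", "TRAJ", "TRAJ9", "FP", alleles=2),
        GeneRecord("TRAJ10", "TRAJ", "TRAJ10", "P", alleles=1, localized=False),
    ]

    def test_rows_and_totals(self):
        table = build_repertoire_table(self.RECORDS)
        assert table.rows["TRAJ8"] == [CellEntry(2, "F", 3)]
        assert table.grand_total() == (4, 6)
        assert table.non_localized == 1

    def test_empty_input_gives_zero_totals(self):
        table = build_repertoire_table([])
        assert table.grand_total() == (0, 0) and table.rows == {}

    def test_record_without_combined_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            build_repertoire_table([GeneRecord("x", "TRAJ", "TRAJ1", "Q")])

    def test_mixed_prefixes_rejected(self):
        bad = self.RECORDS + [GeneRecord("TRDJ1", "TRDJ", "TRDJ1", "F")]
        with pytest.raises(ValueError, match="prefix"):
            build_repertoire_table(bad)


@pytest.fixture(scope="module")
def traj():
    return {
        sp: load_table_fixture(fixture_path("traj_sets.tsv"), sp, "TRAJ")
        for sp in ("human", "bovine", "sheep")
    }


class TestComparison:

    def test_missing_sets_human_vs_ruminants(self, traj):
        for other in ("bovine", "sheep"):
            rep = compare_repertoires(traj["human"], traj[other])
            assert rep.missing_sets == ["TRAJ51", "TRAJ55"]

    def test_sheep_duplication_block(self, traj):
        rep = compare_repertoires(traj["human"], traj["sheep"])
        block = {f"TRAJ{i}" for i in range(29, 40)}
        assert block <= set(rep.duplications)

    def test_swap_exchanges_missing_and_new(self, traj):
        ab = compare_repertoires(traj["human"], traj["bovine"])
        ba = compare_repertoires(traj["bovine"], traj["human"])
        assert ab.missing_sets == ba.new_sets and ab.new_sets == ba.missing_sets

    def test_table_against_itself_is_empty(self, traj):
        rep = compare_repertoires(traj["human"], traj["human"])
        assert rep.missing_sets == [] and rep.new_sets == [] and rep.duplications == []

    def test_prefix_mismatch_rejected(self, traj):
        other = load_table_fixture(fixture_path("trdd_sets.tsv"), "human", "TRDD")
        with pytest.raises(ValueError, match="prefix"):
            compare_repertoires(traj["human"], other)


class TestLocusStatistics:
    def test_non_localized_dialect(self):
        genes = [GeneRecord(f"TRDV1-{i}", "TRDV", "TRDV1", "F") for i in range(1, 40)]
        genes += [GeneRecord(f"TRDV1N{i}", "TRDV", "TRDV1", "F", localized=False) for i in range(16)]
        stats = locus_statistics(genes)
        assert stats["TRDV"] == "39 (+16 non localized)"

    def test_counts_match_truth_tallies(self, small_sim):
        prefix_of = {"V": "TRV", "D": "TRDD", "J": "TRJ", "C": "TRC"}
        genes = [
            GeneRecord(t.gene_id, prefix_of[t.gene_type], t.gene_id, "F", localized=t.localized)
            for t in small_sim.truth
            if t.gene_type == "V"
        ]
        stats = locus_statistics(genes, small_sim.locus)
        want = sum(1 for t in small_sim.truth if t.gene_type == "V" and t.localized)
        nl = sum(1 for t in small_sim.truth if t.gene_type == "V" and not t.localized)
        assert stats["TRV"] == f"{want} (+{nl} non localized)"
        assert stats["size_kb"] == str(small_sim.locus.span_kb)


@pytest.fixture(scope="module")
def trav():
    return load_cdr_fixture(fixture_path("trav_cdr_lengths.tsv"))


class TestCdrLengthTable:

    def test_human_specific_lengths_flagged(self, trav):
        table = cdr_length_table(trav)
        for sg in ("TRAV11", "TRAV35", "TRAV39"):
            assert table[sg]["flagged"], sg
        assert not table["TRAV1"]["flagged"]
        assert not table["TRAV6"]["flagged"]  # present only in one species

    def test_multilength_bovine_subgroups_flagged(self, trav):
        table = cdr_length_table(trav)
        for sg in ("TRAV10", "TRAV17", "TRAV18", "TRAV20", "TRAV22", "TRAV38"):
            assert table[sg]["flagged"], sg

    def test_trdv_fixture_shapes(self):
        trdv = load_cdr_fixture(fixture_path("trdv_cdr_lengths.tsv"))
        assert len(trdv["bovine"]["TRDV1"]) == 9
        assert len(trdv["sheep"]["TRDV1"]) == 5
        table = cdr_length_table(trdv)
        assert table["TRDV2"]["flagged"]  # human [8.3.4] vs ruminant [9.3.4]

    def test_single_species_never_flags(self, trav):
        table = cdr_length_table({"human": trav["human"]})
        assert not any(row["flagged"] for row in table.values())

    def test_engineered_single_difference(self):
        data = {
            "a": {"SG1": frozenset({"[6.6.3]"}), "SG2": frozenset({"[7.5.4]"})},
            "b": {"SG1": frozenset({"[6.6.3]"}), "SG2": frozenset({"[7.5.3]"})},
        }
        table = cdr_length_table(data)
        assert [sg for sg, row in table.items() if row["flagged"]] == ["SG2"]
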