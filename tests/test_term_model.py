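"""Term graph loading, validation, traversal and label round-trips."""

import pytest

import variodna as v
from variodna.errors import (
    ConflictError,
    CycleError,
    LabelConsistencyError,
    LabelSyntaxError,
    NotFoundError,
    StructuralError,
)
from variodna.term_model import ISOLATED_ACCESSIONS, load_term_table


HEADER = "accession\tname\tparent_accessions\tdefinition\n"


def write_table(tmp_path, rows):
    p = tmp_path / "table.tsv"
    p.write_text(HEADER + "".join(r + "\n" for r in rows))
    return p


class TestLoading:
    def test_packaged_table_is_clean(self, graph):
        report = graph.validate()
        assert report.defects == []

    def test_packaged_contains_every_checklist_accession(self, graph):
        missing = [a for a in v.load_accession_checklist() if a not in graph]
        assert missing == []

    def test_sentinels_match_conflict_ledger(self, graph):
        ledger = v.load_conflict_ledger()
        report = graph.validate()
        # one sentinel per ledgered collision, and the kept name still owns
        # the official accession
        assert len(report.sentinels) == len(ledger)
        for row in ledger:
            official = int(row["accession"])
            kept, displaced = row["claimed_names"].split(";")
            assert graph.get_term(official).name == kept
            assert graph.get_term(displaced).accession >= 9000

    def test_empty_table_is_structural_error(self, tmp_path):
        with pytest.raises(StructuralError, match="no branch roots"):
            load_term_table(write_table(tmp_path, []))

    def test_two_term_cycle_rejected(self, tmp_path):
        p = write_table(tmp_path, ["1\ta\t2\t", "2\tb\t1\t"])
        with pytest.raises(CycleError):
            load_term_table(p)

    def test_missing_parent_rejected(self, tmp_path):
        p = write_table(tmp_path, ["1\ta\t99\t"])
        with pytest.raises(StructuralError, match="missing parent 99"):
            load_term_table(p)

    def test_duplicate_accession_names_both_lines(self, tmp_path):
        p = write_table(tmp_path, ["1\ta\t.\t", "1\tb\t.\t"])
        with pytest.raises(ConflictError) as exc:
            load_term_table(p)
        assert "'a'" in str(exc.value) and "'b'" in str(exc.value)

    def test_duplicate_name_rejected(self, tmp_path):
        p = write_table(tmp_path, ["1\tsame\t.\t", "2\tSame\t.\t"])
        with pytest.raises(StructuralError, match="name"):
            load_term_table(p)

    def test_missing_edge_makes_term_unreachable(self, tmp_path):
        # transition-like term whose only parent edge was dropped
        p = write_table(tmp_path, ["129\troot\t.\t", "313\torphanish\t\t"])
        g = load_term_table(p)
        assert 313 in g.validate().unreachable

    def test_cross_branch_term_reported(self, tmp_path):
        p = write_table(
            tmp_path,
            ["129\ttype root\t.\t", "148\tfunction root\t.\t", "5\tboth\t129,148\t"],
        )
        assert load_term_table(p).validate().cross_branch == [5]


class TestLookup:
    def test_lookup_by_name_and_accession(self, graph):
        assert graph.get_term("chromosomal variation").accession == 132
        assert graph.get_term(136).name == "DNA substitution"
        assert graph.get_term("dna SUBSTITUTION").accession == 136

    def test_unknown_keys_raise_not_found(self, graph):
        with pytest.raises(NotFoundError):
            graph.get_term(9999)
        with pytest.raises(NotFoundError):
            graph.get_term("no such term")


class TestTraversal:
    def test_ancestor_order_nearest_first(self, graph):
        assert graph.ancestors(314) == [313, 136, 135, 322, 129]
        assert graph.ancestors(450) == [448, 72, 159, 155]

    def test_branch_roots_have_no_ancestors(self, graph):
        for root in graph.roots.values():
            assert graph.ancestors(root) == []

    @pytest.mark.parametrize(
        "accession, expected",
        [(135, [136, 141, 142, 143, 144]), (127, [130, 146]), (316, [])],
    )
    def test_children(self, graph, accession, expected):
        assert graph.children(accession) == expected

    def test_is_a_including_reflexive(self, graph):
        assert graph.is_a(316, 136)
        assert graph.is_a(136, 136)
        assert not graph.is_a(136, 148)

    def test_ancestors_descendants_mutually_consistent(self, graph):
        """b in ancestors(a) <=> a in descendants(b), via a brute-force closure."""
        parents = {t.accession: set(t.parents) for t in graph}

        def closure(a):
            out, stack = set(), [a]
            while stack:
                for p in parents[stack.pop()]:
                    if p not in out:
                        out.add(p)
                        stack.append(p)
            return out

        for t in graph:
            anc = closure(t.accession)
            assert set(graph.ancestors(t.accession)) == anc
            for b in anc:
                assert t.accession in graph.descendants(b)

    def test_multi_parent_term_stays_in_one_branch(self, graph):
        # nucleosome positioning sits under both chromatin structure variation
        # and epigenetic DNA modification, both inside the structure branch
        assert graph.parents(158) == [156, 226]
        assert graph.branch(158) == "structure"

    def test_isolated_process_term_documented_not_unreachable(self, graph):
        assert 139 in ISOLATED_ACCESSIONS
        assert graph.get_term(139).parents == ()
        assert 139 not in graph.validate().unreachable


class TestLabels:
    def test_rendering_zero_pads_to_four_digits(self, graph):
        assert v.format_label(graph.get_term(132)) == "VariO:0132 chromosomal variation"
        assert (
            v.format_label(graph.get_term(72))
            == "VariO:0072 extrachromosomal DNA affected"
        )

    def test_round_trip_over_all_packaged_terms(self, graph):
        for term in graph:
            label = v.parse_label(v.format_label(term), graph)
            assert (label.accession, label.name) == (term.accession, term.name)

    def test_unpadded_accessions_parse(self, graph):
        assert v.parse_label("VariO:136 DNA substitution", graph).accession == 136

    def test_mismatched_name_is_consistency_error(self, graph):
        with pytest.raises(LabelConsistencyError) as exc:
            v.parse_label("VariO:0136 chromosomal variation", graph)
        assert "DNA substitution" in str(exc.value)

    def test_malformed_prefix_is_syntax_error(self, graph):
        with pytest.raises(LabelSyntaxError):
            v.parse_label("Vario 136 DNA substitution", graph)


class TestObo:
    def test_obo_export_reimports_identically(self, graph, tmp_path):
        obo = tmp_path / "vario_dna.obo"
        graph.write_obo(obo)
        diff = graph.diff_against_obo(obo)
        assert all(entries == [] for entries in diff.values()), diff

    def test_obo_diff_detects_drift(self, graph, tmp_path):
        obo = tmp_path / "drift.obo"
        text = graph.to_obo().replace("name: DNA substitution", "name: something else")
        obo.write_text(text)
        assert 136 in graph.diff_against_obo(obo)["name_mismatch"]
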