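"""Variation-type and affected-level classification rules."""

from itertools import permutations

import pytest

import variodna as v
from variodna.classify import EditClass, NormalizedEdit
from variodna.errors import (
    AmbiguityError,
    DomainError,
    NonVariationError,
    NotFoundError,
    RegionLookupError,
)


# independent chemical oracle: purines are the double-ring bases
def _oracle_subtype(ref, alt):
    ring = {"A": 2, "G": 2, "C": 1, "T": 1}
    if ring[ref] == ring[alt]:
        return "purine transition" if ring[ref] == 2 else "pyrimidine transition"
    return "transversion"


class TestSubstitutionSubtype:
    def test_all_twelve_ordered_pairs_against_oracle(self, graph):
        leaf_names = {}
        for ref, alt in permutations("ACGT", 2):
            path = v.classify_substitution_subtype(ref, alt)
            leaf_names[(ref, alt)] = graph.get_term(path.deepest).name
        assert leaf_names == {
            pair: _oracle_subtype(*pair) for pair in permutations("ACGT", 2)
        }
        # the partition is exactly 4 transitions + 8 transversions
        transitions = [p for p, n in leaf_names.items() if "transition" in n]
        assert sorted(transitions) == [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
        assert sum("transversion" == n for n in leaf_names.values()) == 8

    def test_transition_paths_pass_through_the_transition_term(self):
        assert tuple(v.classify_substitution_subtype("C", "T")) == (313, 314)
        assert tuple(v.classify_substitution_subtype("A", "G")) == (313, 315)
        assert tuple(v.classify_substitution_subtype("C", "G")) == (316,)

    def test_complement_invariance_of_subtype(self):
        for ref, alt in permutations("ACGT", 2):
            direct = v.classify_substitution_subtype(ref, alt)
            comp = v.classify_substitution_subtype(
                v.complement(ref), v.complement(alt)
            )
            # transition status is invariant; purine<->pyrimidine leaves swap
            assert (313 in tuple(direct)) == (313 in tuple(comp))
            swap = {314: 315, 315: 314, 316: 316}
            assert swap[direct.deepest] == comp.deepest

    def test_rejections(self):
        with pytest.raises(NonVariationError):
            v.classify_substitution_subtype("A", "A")
        with pytest.raises(DomainError):
            v.classify_substitution_subtype("N", "A")


class TestVariationType:
    @pytest.mark.parametrize(
        "hgvs, deepest",
        [
            ("g.101374535del", 141),
            ("c.1684_1685delinsT", 143),
            ("g.101374623insT", 142),
            ("g.101362620C>G", 316),
            ("c.82C>T", 314),
            ("g.3_8inv", 145),
            ("g.7_9dup", 142),
        ],
    )
    def test_deepest_term_from_hgvs(self, hgvs, deepest):
        assert v.classify_variation_type(v.parse_hgvs(hgvs)).deepest == deepest

    def test_inversion_path_nests_under_translocation(self):
        assert tuple(v.classify_variation_type(v.parse_hgvs("g.3_8inv"))) == (
            129, 322, 135, 144, 145,
        )

    def test_paths_are_graph_chains_within_the_type_branch(self, graph):
        inputs = ["g.5del", "g.5_6insAT", "c.10delinsAG", "g.9A>G", "g.2_5inv", "g.4dup"]
        for text in inputs:
            path = v.classify_variation_type(v.parse_hgvs(text))
            path.verify(graph)
            assert graph.branch(path.deepest) == "variation_type"

    def test_normalized_edits_classify_like_hgvs(self):
        edit = NormalizedEdit(EditClass.INDEL, 1684, ref="CA", alt="T")
        assert v.classify_variation_type(edit).deepest == 143
        bnd = NormalizedEdit(EditClass.TRANSLOCATION, 100)
        assert v.classify_variation_type(bnd).deepest == 144


class TestAffectedLevel:
    def test_mitochondrial_prefix(self):
        paths = v.classify_affected_level(v.parse_hgvs("m.100A>G"))
        assert [tuple(p) for p in paths] == [(155, 159, 72, 448, 450)]

    def test_coding_coordinates_without_offset_are_exonic(self):
        assert v.classify_affected_level(v.parse_hgvs("c.82C>T"))[0].deepest == 162
        assert v.classify_affected_level(v.parse_hgvs("c.*45del"))[0].deepest == 162

    def test_intron_offset_maps_to_intron(self):
        assert v.classify_affected_level(v.parse_hgvs("c.123+5G>A"))[0].deepest == 161

    def test_genomic_position_located_in_region_model(self):
        model = v.RegionModel(
            [
                ("chrX", 101374000, 101375000, "intron"),
                ("chrX", 101300000, 101400000, "gene"),
            ]
        )
        paths = v.classify_affected_level(v.parse_hgvs("g.101374535del"), model)
        assert [tuple(p) for p in paths] == [(155, 159, 160, 161)]

    def test_genomic_fallbacks(self):
        no_model = v.classify_affected_level(v.parse_hgvs("g.500A>T"))
        assert [p.deepest for p in no_model] == [160]
        elsewhere = v.RegionModel([("chr1", 5000, 6000, "gene")])
        assert (
            v.classify_affected_level(v.parse_hgvs("g.500A>T"), elsewhere)[0].deepest
            == 163
        )
        empty = v.RegionModel([])
        assert v.classify_affected_level(v.parse_hgvs("g.500A>T"), empty)[0].deepest == 160

    def test_gene_only_position_stays_at_chain_affected(self):
        model = v.RegionModel([("chr1", 0, 1000, "gene")])
        assert v.classify_affected_level(v.parse_hgvs("g.500A>T"), model)[0].deepest == 160

    def test_conflicting_labels_raise_ambiguity_listing_intervals(self):
        model = v.RegionModel(
            [("chr1", 0, 1000, "exon"), ("chr1", 500, 1500, "intron")]
        )
        with pytest.raises(AmbiguityError) as exc:
            v.classify_affected_level(v.parse_hgvs("g.600A>T"), model)
        assert len(exc.value.intervals) == 2

    def test_sequence_name_mismatch_raises_lookup_error(self):
        model = v.RegionModel([("chr1", 0, 1000, "exon")])
        with pytest.raises(RegionLookupError):
            v.classify_affected_level(
                v.parse_hgvs("g.500A>T"), model, sequence="chr2"
            )

    def test_bed_round_trip_uses_half_open_coordinates(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t99\t100\texon\n")  # covers HGVS position 100 only
        model = v.RegionModel.from_bed(bed)
        assert v.classify_affected_level(v.parse_hgvs("g.100A>T"), model)[0].deepest == 162
        assert v.classify_affected_level(v.parse_hgvs("g.99A>T"), model)[0].deepest == 163


class TestBranchValidation:
    def test_origin_term_valid_in_origin_branch(self, graph):
        report = v.validate_branch_terms([446], "origin", graph)
        assert report.ok and report.valid == [446]

    def test_cross_branch_accession_is_violation(self, graph):
        report = v.validate_branch_terms([136], "origin", graph)
        assert not report.ok
        assert report.violations[0][0] == 136

    def test_ancestor_of_supplied_term_flagged_redundant(self, graph):
        report = v.validate_branch_terms([313, 314], "type", graph)
        assert report.ok and report.redundant == [313]

    def test_branch_root_itself_is_not_a_strict_descendant(self, graph):
        report = v.validate_branch_terms([127], "origin", graph)
        assert not report.ok

    def test_unknown_accession_raises(self, graph):
        with pytest.raises(NotFoundError):
            v.validate_branch_terms([9999], "origin", graph)
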