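"""Alignment handling, column profiles, mutation calling and filtering."""

import pytest

from mutpanel import synth_fixtures as sf
from mutpanel.family_align import (
    AA20,
    SCHEMES,
    Alignment,
    PropertyRecord,
    call_mutations,
    classify_substitution,
    column_profiles,
    load_alignment,
    manual_filter,
    map_alignment_to_structures,
    parse_active_sites,
    parse_mutation_label,
    rarity_class,
)


def _aln(rows):
    return Alignment(rows=rows, mutant_row=0, reference_row=1)


class TestLoadAlignment:
    def _write(self, tmp_path, records):
        path = tmp_path / "aln.fasta"
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path

    def test_basic_load_and_reorder(self, tmp_path):
        path = self._write(
            tmp_path, [("wt", "ACD-E"), ("other", "ACDWE"), ("mut", "acdwe")]
        )
        aln = load_alignment(path, mutant_id="mut", reference_id="wt")
        assert aln.length == 5
        assert aln.rows[0] == ("mut", "ACDWE")  # uppercased, mutant first
        assert aln.rows[1] == ("wt", "ACD-E")

    def test_missing_id(self, tmp_path):
        path = self._write(tmp_path, [("a", "AC"), ("b", "AC")])
        with pytest.raises(ValueError, match="'zz'"):
            load_alignment(path, mutant_id="zz", reference_id="a")

    def test_ragged_rows(self, tmp_path):
        path = self._write(tmp_path, [("a", "ACDE"), ("b", "AC")])
        with pytest.raises(ValueError, match="ragged"):
            load_alignment(path, mutant_id="a", reference_id="b")


class TestMapping:
    def test_gap_columns_unmapped(self):
        st, _ = sf.make_toy_structure("ACD", "extended")
        aln = _aln([("mut", "A-CD"), ("ref", "A-CD")])
        mapping = map_alignment_to_structures(aln, {"ref": st})["ref"]
        assert sorted(mapping) == [1, 3, 4]
        assert mapping[1].aa == "A" and mapping[3].aa == "C" and mapping[4].aa == "D"

    def test_identity_mapping_without_gaps(self):
        st, _ = sf.make_toy_structure("KDE", "helix")
        aln = _aln([("mut", "KDE"), ("ref", "KDE")])
        mapping = map_alignment_to_structures(aln, {"mut": st})["mut"]
        assert [mapping[c].aa for c in (1, 2, 3)] == ["K", "D", "E"]

    def test_mismatch_reports_position(self):
        st, _ = sf.make_toy_structure("ACD", "extended")
        aln = _aln([("mut", "ACE"), ("ref", "ACE")])
        with pytest.raises(ValueError, match="position 3"):
            map_alignment_to_structures(aln, {"ref": st})

    def test_short_structure_reports_position(self):
        st, _ = sf.make_toy_structure("ACD", "extended")
        aln = _aln([("mut", "ACDE"), ("ref", "ACDE")])
        with pytest.raises(ValueError, match="position 4"):
            map_alignment_to_structures(aln, {"ref": st})


class TestCallMutations:
    def test_identical_rows_empty(self):
        assert call_mutations(_aln([("m", "ACDE"), ("r", "ACDE")])) == []

    def test_single_substitution(self):
        muts = call_mutations(_aln([("m", "ACE"), ("r", "ACD")]))
        assert len(muts) == 1
        m = muts[0]
        assert (m.column, m.label) == (3, "D3E")
        assert (m.ref_aa, m.mut_aa) == ("D", "E")

    def test_gap_columns_skipped(self):
        muts = call_mutations(_aln([("m", "A-CE"), ("r", "AGCD"), ("x", "AGCD")]))
        # column 2 (gap in mutant) is skipped; the label carries the
        # reference's own ungapped numbering
        assert [m.label for m in muts] == ["D4E"]
        assert muts[0].mut_seq_pos == 3 and muts[0].ref_seq_pos == 4

    def test_label_round_trip(self):
        for label in ("D3E", "I20A", "K221A"):
            aa_ref, pos, aa_mut = parse_mutation_label(label)
            assert f"{aa_ref}{pos}{aa_mut}" == label
        with pytest.raises(ValueError):
            parse_mutation_label("XYZ")

    def test_mutation_agrees_with_alignment_rows(self, planted_small):
        aln = planted_small.alignment
        for m in planted_small.mutations:
            assert aln.mutant[1][m.column - 1] == m.mut_aa
            assert aln.reference[1][m.column - 1] == m.ref_aa


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "scheme,a,b,expected",
        [
            ("CINEMA", "K", "R", True),   # both polar positive
            ("CINEMA", "A", "G", True),   # both non-polar aliphatic
            ("CINEMA", "A", "R", False),
            ("CINEMA", "F", "Y", True),   # non-polar ring
            ("CLUSTAL", "I", "V", True),
            ("CLUSTAL", "D", "E", False),  # both ungrouped in CLUSTAL
            ("CLUSTAL", "G", "T", True),
            ("LESK", "H", "N", True),
            ("LESK", "K", "D", False),
        ],
    )
    def test_examples(self, scheme, a, b, expected):
        assert classify_substitution(SCHEMES[scheme], a, b) is expected

    def test_symmetric_and_reflexive(self):
        import random

        rnd = random.Random(0)
        pairs = [(rnd.choice(AA20), rnd.choice(AA20)) for _ in range(50)]
        for scheme in SCHEMES.values():
            for a, b in pairs:
                assert classify_substitution(scheme, a, b) == classify_substitution(
                    scheme, b, a
                )
            for aa in AA20:
                assert classify_substitution(scheme, aa, aa)

    def test_cinema_and_lesk_partition_all_residues(self):
        for name in ("CINEMA", "LESK"):
            covered = set()
            for _, members in SCHEMES[name].groups:
                assert not (covered & members), "groups overlap"
                covered |= members
            assert covered == set(AA20)

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            classify_substitution(SCHEMES["CINEMA"], "B", "A")


class TestColumnProfiles:
    def test_frequencies_and_res_freq(self):
        aln = _aln(
            [("m", "E"), ("r", "E"), ("x", "E"), ("y", "S")]
        )
        prof = column_profiles(aln, {})[0]
        assert prof.freq == pytest.approx({"E": 0.75, "S": 0.25})
        assert prof.res_freq_mut == pytest.approx(0.75)
        assert sum(prof.freq.values()) == pytest.approx(1.0)

    def test_property_averages(self):
        aln = _aln([("m", "A"), ("r", "A")])
        props = {
            "m": {1: PropertyRecord(acc=10.0, deg=3, bet=1.0, clo=0.1)},
            "r": {1: PropertyRecord(acc=30.0, deg=5, bet=3.0, clo=0.3)},
        }
        prof = column_profiles(aln, props)[0]
        assert prof.deg_avg == pytest.approx(4.0)
        assert prof.acc_avg == pytest.approx(20.0)

    def test_unmapped_column_has_null_averages(self):
        aln = _aln([("m", "AC"), ("r", "AC")])
        props = {"m": {1: PropertyRecord(acc=1, deg=1, bet=1, clo=1)}}
        profs = column_profiles(aln, props)
        assert profs[1].acc_avg is None

    def test_active_site_flags(self):
        st, _ = sf.make_toy_structure("NKHEG", "helix")
        aln = _aln([("m", "NKHEG"), ("ref", "NKHEG")])
        from mutpanel.contact_graph import centralities, residue_graph, structure_contacts
        from mutpanel.structure_io import annotate_atom_types

        annotate_atom_types(st)
        rg = centralities(residue_graph(structure_contacts(st), nodes=st.residues))
        cmap = map_alignment_to_structures(aln, {"ref": st})["ref"]
        profs = column_profiles(
            aln, {}, active_sites=parse_active_sites(["N1", "H3"]),
            ref_graph=rg, ref_column_map=cmap,
        )
        assert profs[0].is_active_site and profs[2].is_active_site
        assert not profs[1].is_active_site
        # neighbours of the active residues in the contact graph are flagged
        flagged = {p.column for p in profs if p.contacts_active_site}
        expected = set()
        for col, res in cmap.items():
            if any(nb in {cmap[1], cmap[3]} for nb in rg.neighbors(res)):
                expected.add(col)
        assert flagged == expected

    def test_active_site_letter_mismatch(self):
        aln = _aln([("m", "AC"), ("r", "AC")])
        with pytest.raises(ValueError, match="active site"):
            column_profiles(aln, {}, active_sites=[("G", 1)])


class TestRarityAndFilter:
    def _profile(self, freq):
        from mutpanel.family_align import ColumnProfile

        return ColumnProfile(
            column=1, freq=freq, res_freq_mut=0.0,
            acc_avg=None, deg_avg=None, bet_avg=None, clo_avg=None,
        )

    @pytest.mark.parametrize(
        "freq,expected",
        [(0.0, "very_rare"), (0.019, "very_rare"), (0.05, "rare"), (0.5, "frequent")],
    )
    def test_rarity_bands(self, freq, expected):
        assert rarity_class(self._profile({"K": freq}), "K") == expected

    def test_planted_rare_nonconservative_selected(self):
        spec = sf.FamilySpec(
            reference_seq="MKVLITGAHE",
            n_rows=10,
            column_spec={4: {"L": 1.0}, 6: {"T": 0.5, "S": 0.5}},
            mutant_edits=[(4, "K"), (6, "S"), (7, "A")],
            seed=5,
        )
        aln = sf.make_family(spec)[0]
        muts = call_mutations(aln)
        profs = column_profiles(aln, {})
        selected = manual_filter(muts, profs, scheme="CINEMA")
        # L4K: non-conservative, K seen once in 12 rows (rare) -> kept
        # T6S: conservative polar neutral -> dropped
        # G7A: conservative aliphatic -> dropped
        assert [m.label for m in selected] == ["L4K"]
        assert selected[0].rarity == "rare"

    def test_frequent_nonconservative_excluded(self):
        spec = sf.FamilySpec(
            reference_seq="MKVLITGAHE",
            n_rows=10,
            column_spec={2: {"E": 0.8, "K": 0.2}},
            mutant_edits=[(2, "E")],
            seed=2,
        )
        aln = sf.make_family(spec)[0]
        muts = call_mutations(aln)
        profs = column_profiles(aln, {})
        assert muts[0].conservative_by_scheme["CINEMA"] is False
        assert manual_filter(muts, profs) == []
        assert muts[0].rarity == "frequent"

    def test_sort_order_by_structural_importance(self):
        from mutpanel.family_align import ColumnProfile, Mutation

        def prof(col, deg, bet, acc):
            return ColumnProfile(
                column=col, freq={"A": 1.0}, res_freq_mut=0.0,
                acc_avg=acc, deg_avg=deg, bet_avg=bet, clo_avg=1.0,
            )

        def mut(col):
            m = Mutation(column=col, ref_aa="L", mut_aa="K",
                         ref_seq_pos=col, mut_seq_pos=col)
            m.conservative_by_scheme = {"CINEMA": False}
            return m

        profiles = [
            prof(1, deg=3, bet=10, acc=50),
            prof(2, deg=8, bet=1, acc=90),
            prof(3, deg=3, bet=20, acc=10),
        ]
        ordered = manual_filter([mut(1), mut(2), mut(3)], profiles)
        assert [m.column for m in ordered] == [2, 3, 1]


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st_

    aa = st_.sampled_from(AA20)

    @given(ref=aa, mut=aa, pos=st_.integers(min_value=1, max_value=9999))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_label_round_trip_property(self, ref, mut, pos):
        from mutpanel.family_align import Mutation

        label = Mutation(
            column=1, ref_aa=ref, mut_aa=mut, ref_seq_pos=pos, mut_seq_pos=pos
        ).label
        assert parse_mutation_label(label) == (ref, pos, mut)

    @given(a=aa, b=aa, scheme=st_.sampled_from(sorted(SCHEMES)))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_classification_symmetric_reflexive_property(self, a, b, scheme):
        sch = SCHEMES[scheme]
        assert classify_substitution(sch, a, b) == classify_substitution(sch, b, a)
        assert classify_substitution(sch, a, a)


def test_parse_active_sites_file(tmp_path):
    path = tmp_path / "sites.txt"
    path.write_text("# catalytic residues\nN10\nK12\nH95\nE165\nG171\n")
    assert parse_active_sites(path) == [
        ("N", 10), ("K", 12), ("H", 95), ("E", 165), ("G", 171)
    ]
    with pytest.raises(ValueError):
        parse_active_sites(["Z9"])
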