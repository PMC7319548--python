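import json

import numpy as np
import pytest

from shiftcrypt import (
    GeneratorConfig, ProfileRecord, Residue, ShiftFormatError, ShiftTable,
    generate, parse_nef, parse_nmrstar, read_profile_json, write_nef,
    write_nmrstar, write_profile_json,
)

MINIMAL_V3 = """
data_test
loop_
   _Atom_chem_shift.ID
   _Atom_chem_shift.Comp_index_ID
   _Atom_chem_shift.Comp_ID
   _Atom_chem_shift.Atom_ID
   _Atom_chem_shift.Val
   1 1 ALA CA 52.5
   2 2 GLY CA 45.1
stop_
"""

MINIMAL_V2 = """
data_test
loop_
   _Residue_seq_code
   _Residue_label
   _Atom_name
   _Chem_shift_value
   1 ALA CA 52.5
   2 GLY CA 45.1
stop_
"""

MINIMAL_NEF = """
data_test
save_nef_chemical_shift_list_1
   _nef_chemical_shift_list.sf_category  nef_chemical_shift_list
   loop_
      _nef_chemical_shift.chain_code
      _nef_chemical_shift.sequence_code
      _nef_chemical_shift.residue_name
      _nef_chemical_shift.atom_name
      _nef_chemical_shift.value
      A 1 LEU N 121.3
      A 1 LEU H 8.2
   stop_
save_
"""


class TestParseNmrstar:
    @pytest.mark.parametrize("doc", [MINIMAL_V3, MINIMAL_V2],
                             ids=["v3", "v2.1"])
    def test_minimal_document_both_dialects(self, doc):
        table = parse_nmrstar(doc)
        assert table.sequence == "AG"
        assert table.residues[0].shifts == {"CA": 52.5}
        assert table.residues[1].shifts == {"CA": 45.1}
        assert [r.seq_id for r in table] == [1, 2]

    def test_duplicate_atom_keeps_first_and_warns(self, caplog):
        doc = MINIMAL_V3.replace("   2 2 GLY",
                                 "   9 1 ALA CA 53.0\n   2 2 GLY")
        with caplog.at_level("WARNING", logger="shiftcrypt.shift_io"):
            table = parse_nmrstar(doc)
        assert table.residues[0].shifts["CA"] == 52.5
        assert any("duplicate atom" in r.message for r in caplog.records)

    def test_ligand_residue_dropped(self):
        doc = MINIMAL_V3.replace("   2 2 GLY",
                                 "   9 5 MYR C1 14.2\n   2 2 GLY")
        table = parse_nmrstar(doc)
        assert table.sequence == "AG"

    def test_no_shift_loop_is_format_error(self):
        with pytest.raises(ShiftFormatError, match="_Atom_chem_shift"):
            parse_nmrstar("data_x\nloop_\n_Other.Tag\n1\nstop_\n")

    def test_unparsable_value_skips_atom(self, caplog):
        doc = MINIMAL_V3.replace("   2 2 GLY CA 45.1",
                                 "   2 1 ALA CB abc\n   3 2 GLY CA 45.1")
        with caplog.at_level("WARNING", logger="shiftcrypt.shift_io"):
            table = parse_nmrstar(doc)
        assert table.sequence == "AG"
        assert table.residues[0].shifts == {"CA": 52.5}  # CB skipped
        assert any("unparsable" in r.message for r in caplog.records)

    def test_multi_chain_uses_first_with_warning(self, caplog):
        doc = MINIMAL_V3.replace(
            "   _Atom_chem_shift.Comp_index_ID",
            "   _Atom_chem_shift.Entity_assembly_ID\n"
            "   _Atom_chem_shift.Comp_index_ID").replace(
            "   1 1 ALA CA 52.5", "   1 1 1 ALA CA 52.5").replace(
            "   2 2 GLY CA 45.1", "   2 1 2 GLY CA 44.0\n"
                                  "   3 2 2 GLY CA 45.1")
        with caplog.at_level("WARNING", logger="shiftcrypt.shift_io"):
            table = parse_nmrstar(doc)
        assert table.residues[1].shifts["CA"] == 44.0
        assert any("multiple chains" in r.message for r in caplog.records)


class TestParseNef:
    def test_minimal_frame(self):
        table = parse_nef(MINIMAL_NEF)
        assert len(table) == 1
        assert table.residues[0].shifts == {"N": 121.3, "H": 8.2}
        assert table.sequence == "L"

    def test_two_chains_uses_first(self, caplog):
        doc = MINIMAL_NEF.replace("   stop_",
                                  "      B 1 ALA CA 52.0\n   stop_")
        with caplog.at_level("WARNING", logger="shiftcrypt.shift_io"):
            table = parse_nef(doc)
        assert table.sequence == "L"

    def test_empty_shift_list_is_valid(self):
        doc = "\n".join(l for l in MINIMAL_NEF.splitlines()
                        if not l.startswith("      A"))
        assert len(parse_nef(doc)) == 0

    def test_missing_frame_is_format_error(self):
        with pytest.raises(ShiftFormatError, match="nef_chemical_shift_list"):
            parse_nef("data_x\nsave_other\n_other.tag 1\nsave_\n")

    def test_wildcard_atom_names_kept_verbatim(self):
        doc = MINIMAL_NEF.replace("A 1 LEU H 8.2", "A 1 LEU HB% 1.4")
        table = parse_nef(doc)
        assert table.residues[0].shifts["HB%"] == 1.4


class TestForwardCompatibility:
    def test_unknown_loops_and_frames_are_ignored(self):
        extra = ("data_test\nsave_future_frame\n"
                 "   _future.tag   something\n"
                 "   loop_\n      _future_loop.a\n      _future_loop.b\n"
                 "      1 2\n      3 4\n   stop_\nsave_\n")
        table = parse_nmrstar(extra + MINIMAL_V3.replace("data_test", ""))
        assert table.sequence == "AG"

    def test_quoted_and_multiline_values_tokenize(self):
        doc = MINIMAL_V3.replace(
            "data_test",
            "data_test\n_note 'a quoted value'\n;\na multi-line\nvalue\n;\n")
        assert parse_nmrstar(doc).sequence == "AG"


class TestRoundTrips:
    @pytest.mark.parametrize("writer,parser", [
        (write_nmrstar, parse_nmrstar), (write_nef, parse_nef),
    ], ids=["nmrstar", "nef"])
    def test_write_parse_reproduces_all_shifts(self, writer, parser):
        tables, _ = generate(GeneratorConfig(n_proteins=3, seed=8))
        for table in tables:
            back = parser(writer(table), table.entry_id)
            assert back.sequence == table.sequence
            assert [r.seq_id for r in back] == [r.seq_id for r in table]
            for got, want in zip(back, table):
                assert got.shifts == want.shifts

    def test_nef_and_nmrstar_of_same_table_agree(self):
        tables, _ = generate(GeneratorConfig(n_proteins=2, seed=9))
        for table in tables:
            a = parse_nmrstar(write_nmrstar(table))
            b = parse_nef(write_nef(table))
            assert a.sequence == b.sequence
            assert all(x.shifts == y.shifts for x, y in zip(a, b))

    def test_numbering_gaps_preserved(self):
        table = ShiftTable("gappy", [Residue(3, "ALA", {"CA": 52.5}),
                                     Residue(7, "GLY", {"CA": 45.1})])
        back = parse_nmrstar(write_nmrstar(table))
        assert [r.seq_id for r in back] == [3, 7]


class TestProfileJson:
    def test_single_residue_shape(self):
        p = ProfileRecord("e1", [5], "A", [0.5])
        obj = json.loads(write_profile_json(p))
        assert obj == {"entry_id": "e1",
                       "residues": [{"seq_id": 5, "aa": "A", "value": 0.5}]}

    def test_missing_value_serialized_as_null(self):
        p = ProfileRecord("e1", [1], "G", [None])
        assert json.loads(write_profile_json(p))["residues"][0]["value"] is None

    def test_round_trip_random_profile(self):
        rng = np.random.default_rng(4)
        values = [None if rng.random() < 0.1 else float(rng.random())
                  for _ in range(50)]
        aas = "ACDEFGHIKLMNPQRSTVWY"
        p = ProfileRecord("e2", list(range(10, 60)),
                          "".join(aas[k] for k in rng.integers(0, 20, 50)),
                          values)
        assert read_profile_json(write_profile_json(p)) == p

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ProfileRecord("bad", [1], "A", [1.5])
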