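import io

import numpy as np
import pytest

from tyrcav import Structure, Trajectory, parse_pdb, read_table, select_atoms, write_pdb, write_table
from tyrcav.structure_io import ParseError, SelectionError

from conftest import make_atom

ALA_CA = "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"

TWO_CU = (
    "HETATM    1 CU    CU A 500       0.000   0.000   0.000  1.00  0.00          CU\n"
    "HETATM    2 CU    CU A 501       0.000   0.000   2.750  1.00  0.00          CU\n"
)

HIS_RESIDUE = """ATOM      1  N   HIS A  42      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  HIS A  42       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  HIS A  42       1.000   1.000   0.000  1.00  0.00           C
ATOM      4  CG  HIS A  42       2.000   1.500   0.000  1.00  0.00           C
ATOM      5  ND1 HIS A  42       3.000   1.000   0.000  1.00  0.00           N
ATOM      6  CD2 HIS A  42       2.500   2.800   0.000  1.00  0.00           C
ATOM      7  CE1 HIS A  42       4.100   1.800   0.000  1.00  0.00           C
ATOM      8  NE2 HIS A  42       3.800   3.000   0.000  1.00  0.00           N
"""


class TestParsePdb:
    def test_single_atom(self):
        st = parse_pdb(ALA_CA)
        assert len(st) == 1
        a = st.atoms[0]
        assert (a.name, a.element, a.residue_name) == ("CA", "C", "ALA")
        assert a.coordinates == pytest.approx((11.639, 6.071, -5.147))

    def test_hetatm_copper_retained(self):
        st = parse_pdb(TWO_CU)
        assert len(st) == 2
        assert all(a.element.upper() == "CU" for a in st.atoms)
        assert all(a.is_hetero for a in st.atoms)

    def test_alt_loc_highest_occupancy_wins(self):
        text = (
            "ATOM      1  CB AALA A   1      12.000   7.000  -4.000  0.60  0.00           C\n"
            "ATOM      2  CB BALA A   1      12.100   7.100  -4.100  0.40  0.00           C\n"
        )
        st = parse_pdb(text)
        assert len(st) == 1
        assert st.atoms[0].alt_loc == "A"

    def test_alt_loc_tie_keeps_first(self):
        text = (
            "ATOM      1  CB AALA A   1      12.000   7.000  -4.000  0.50  0.00           C\n"
            "ATOM      2  CB BALA A   1      12.100   7.100  -4.100  0.50  0.00           C\n"
        )
        st = parse_pdb(text)
        assert len(st) == 1
        assert st.atoms[0].alt_loc == "A"

    def test_malformed_coordinate_names_line(self):
        bad = ALA_CA + "ATOM      3  CB  ALA A   1      xx.000   7.000  -4.000  1.00  0.00           C\n"
        with pytest.raises(ParseError, match="line 2"):
            parse_pdb(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(ParseError):
            parse_pdb("REMARK nothing here\n")

    def test_round_trip_preserves_atoms(self):
        st = parse_pdb(ALA_CA + TWO_CU + HIS_RESIDUE)
        buf = io.StringIO()
        write_pdb(st, buf)
        again = parse_pdb(buf.getvalue())
        assert len(again) == len(st)
        assert [a.name for a in again.atoms] == [a.name for a in st.atoms]
        np.testing.assert_allclose(
            again.coordinates, st.coordinates, atol=1e-3
        )


class TestSelectAtoms:
    def test_element_selection(self):
        st = parse_pdb(TWO_CU)
        assert len(select_atoms(st, "element = CU").atoms) == 2

    def test_residue_range(self):
        atoms = [make_atom(i, (float(i), 0, 0), resnum=i) for i in range(19, 470, 25)]
        st = Structure(atoms)
        sel = select_atoms(st, "residue_number in 19..118")
        assert all(19 <= a.residue_number <= 118 for a in sel.atoms)
        assert len(sel.atoms) == sum(1 for a in atoms if 19 <= a.residue_number <= 118)

    def test_his_sidechain_nitrogens(self):
        st = parse_pdb(HIS_RESIDUE)
        sel = select_atoms(st, "atom_name in {ND1, NE2} and residue_name = HIS")
        assert sorted(a.name for a in sel.atoms) == ["ND1", "NE2"]

    def test_empty_selection_allowed(self):
        st = parse_pdb(TWO_CU)
        assert len(select_atoms(st, "element = FE").atoms) == 0

    @pytest.mark.parametrize("expr", ["", "bogus ~ 3", "element like CU", "resnum in a..b"])
    def test_unparseable_expressions(self, expr):
        st = parse_pdb(TWO_CU)
        with pytest.raises(SelectionError):
            select_atoms(st, expr)


class TestTables:
    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_table([], path, fieldnames=["mutation", "ddg"])
        assert path.read_text().strip() == "mutation\tddg"

    def test_rows_and_round_trip(self, tmp_path):
        records = [{"mutation": f"M{i}", "ddg": 0.1 * i - 1.23456789} for i in range(8)]
        path = tmp_path / "t.tsv"
        write_table(records, path)
        df = read_table(path)
        assert len(df) == 8
        np.testing.assert_array_equal(
            df["ddg"].to_numpy(), [r["ddg"] for r in records]
        )

    def test_mismatched_schema_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_table([{"a": 1}, {"b": 2}], tmp_path / "x.tsv")


class TestTrajectory:
    def test_rejects_mismatched_identity(self):
        f0 = Structure([make_atom(1, (0, 0, 0)), make_atom(2, (1, 0, 0))])
        f1 = Structure([make_atom(1, (0, 0, 0)), make_atom(3, (1, 0, 0))])
        with pytest.raises(ValueError, match="identity"):
            Trajectory([f0, f1])

    def test_accepts_matching_frames_with_labels(self):
        f0 = Structure([make_atom(1, (0, 0, 0))], frame_label=0.0)
        f1 = Structure([make_atom(1, (0, 0, 1))], frame_label=100.0)
        traj = Trajectory([f0, f1])
        assert traj.time_labels == [0.0, 100.0]
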