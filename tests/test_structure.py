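"""Parsing, symmetry-aware neighbor search and dataset selection."""

from __future__ import annotations

import itertools

import gemmi
import numpy as np
import pytest

from mgrna.fixtures import FixtureSpec, battery_catalogue, build_fixture
from mgrna.structure import (Contact, StructureModel, UnitCell,
                             count_linked_nucleotides, neighbor_search,
                             normalize_atom_name, read_structure,
                             select_structures)

from conftest import make_model

MINIMAL_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1
HETATM    1 MG    MG A   1      10.000  10.000  10.000  1.00 15.00          MG
END
"""

STAR_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1
ATOM      1  O2* A   A   1       1.000   2.000   3.000  1.00 20.00           O
ATOM      2  O1P A   A   1       4.000   2.000   3.000  1.00 20.00           O
END
"""


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model) == 1
        assert model.cell is not None and model.cell.a == 50.0
        mg = model.atoms[0]
        assert mg.element == "Mg" and mg.is_metal and not mg.is_water
        assert mg.b_factor == 15.0

    def test_mmcif_equivalence(self, tmp_path):
        """The same content read from PDB and mmCIF gives identical atoms."""
        text, _ = build_fixture(FixtureSpec(recipe=battery_catalogue()[9],
                                            seed=3))
        pdb = tmp_path / "f.pdb"
        pdb.write_text(text)
        st = gemmi.read_structure(str(pdb))
        cif = tmp_path / "f.cif"
        st.make_mmcif_document().write_file(str(cif))
        a = read_structure(pdb, format="pdb")
        b = read_structure(cif, format="mmcif")
        assert len(a) == len(b)
        for x, y in zip(a.atoms, b.atoms):
            assert (x.atom_name, x.residue_name, x.element) == \
                (y.atom_name, y.residue_name, y.element)
            assert np.allclose(x.xyz, y.xyz, atol=1e-3)
            assert x.occupancy == y.occupancy
        assert a.cell.space_group == b.cell.space_group

    def test_star_names_normalized_and_match_independent_parser(self, tmp_path):
        """O2* becomes O2' (and O1P becomes OP1), consistent with what a
        second, independent parser reads from the raw file."""
        from Bio.PDB import PDBParser
        p = tmp_path / "s.pdb"
        p.write_text(STAR_PDB)
        model = read_structure(p)
        names = {a.atom_name for a in model.atoms}
        assert names == {"O2'", "OP1"}
        bio = PDBParser(QUIET=True).get_structure("s", str(p))
        raw = {a.get_name() for a in bio.get_atoms()}
        assert {normalize_atom_name(n) for n in raw} == names

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_structure("/nonexistent/file.pdb")

    def test_no_cell_warns_and_degrades(self, tmp_path, caplog):
        p = tmp_path / "n.pdb"
        p.write_text("ATOM      1  O   HOH A   1       "
                     "1.000   2.000   3.000  1.00 20.00           O\nEND\n")
        model = read_structure(p)
        assert model.cell is None
        contacts = neighbor_search(model, np.zeros(3), 5.0,
                                   use_symmetry=True)
        assert len(contacts) == 1  # asymmetric-unit fallback

    def test_roundtrip_preserves_atoms(self, tmp_path):
        """parse -> write -> re-parse keeps count, names, B, occupancy."""
        text, _ = build_fixture(FixtureSpec(recipe=battery_catalogue()[10],
                                            seed=5))
        p1 = tmp_path / "a.pdb"
        p1.write_text(text)
        m1 = read_structure(p1)
        st = gemmi.read_structure(str(p1))
        p2 = tmp_path / "b.pdb"
        p2.write_text(st.make_pdb_string())
        m2 = read_structure(p2)
        assert len(m1) == len(m2)
        for x, y in zip(m1.atoms, m2.atoms):
            assert x.atom_name == y.atom_name
            assert x.b_factor == pytest.approx(y.b_factor, abs=0.01)
            assert x.occupancy == y.occupancy


def brute_force_neighbors(model: StructureModel, center: np.ndarray,
                          radius: float) -> set[tuple]:
    """Independent oracle: explicitly generate every symmetry copy in a
    3x3x3 block of cells and measure distances directly."""
    cell = model.cell
    frac = cell.fractionalize(model.coords)
    found = set()
    for op_index, (rot, tran) in enumerate(cell.ops):
        moved = frac @ rot.T + tran
        for shift in itertools.product((-2, -1, 0, 1, 2), repeat=3):
            cart = cell.orthogonalize(moved + np.asarray(shift, dtype=float))
            d = np.linalg.norm(cart - center, axis=1)
            for idx in np.nonzero(d <= radius)[0]:
                if d[idx] < 1e-6:
                    continue
                found.add((int(idx), op_index, shift,
                           round(float(d[idx]), 6)))
    return found


class TestNeighborSearch:
    def test_plain_distance(self):
        model = make_model([("O", "O", "HOH", 1, "W", (0, 0, 0)),
                            ("O", "O", "HOH", 2, "W", (2, 0, 0))])
        contacts = neighbor_search(model, model.atoms[0], 3.0,
                                   use_symmetry=False)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(2.0)

    def test_periodic_image(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90, "P 1")
        model = make_model([("O", "O", "HOH", 1, "W", (0.1, 0, 0)),
                            ("O", "O", "HOH", 2, "W", (9.9, 0, 0))],
                           cell=cell)
        contacts = neighbor_search(model, model.atoms[0], 2.0)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(0.2)
        assert contacts[0].image_shift != (0, 0, 0)

    def test_sorted_and_excludes_self(self):
        model = make_model([("MG", "MG", "MG", 1, "M", (0, 0, 0)),
                            ("O", "O", "HOH", 2, "W", (3, 0, 0)),
                            ("O", "O", "HOH", 3, "W", (2, 0, 0))])
        contacts = neighbor_search(model, model.atoms[0], 5.0,
                                   use_symmetry=False)
        assert [c.target_index for c in contacts] == [2, 1]

    @pytest.mark.parametrize("space_group,cell_lengths", [
        ("P 1", (11.0, 13.0, 12.0)),
        ("P 21 21 21", (14.0, 12.0, 13.0)),
    ])
    def test_matches_brute_force_oracle(self, space_group, cell_lengths):
        """Cell-aware search equals the expanded-copy oracle on >= 100
        randomized fixtures."""
        rng = np.random.default_rng(20240915)
        a, b, c = cell_lengths
        for trial in range(50):
            cell = UnitCell(a, b, c, 90, 90, 90, space_group)
            n = int(rng.integers(5, 35))
            coords = rng.uniform(0, 1, size=(n, 3)) * np.array([a, b, c])
            model = make_model([("O", "O", "HOH", i + 1, "W", xyz)
                                for i, xyz in enumerate(coords)], cell=cell)
            center = rng.uniform(0.2, 0.8, size=3) * np.array([a, b, c])
            radius = float(rng.uniform(2.0, 4.5))
            got = {(ct.target_index, ct.sym_op_index, ct.image_shift,
                    round(ct.distance, 6))
                   for ct in neighbor_search(model, center, radius)}
            want = brute_force_neighbors(model, center, radius)
            assert got == want

    def test_translation_invariance(self):
        """Contact distances are unchanged when the whole model and the
        query point translate together."""
        rng = np.random.default_rng(99)
        coords = rng.uniform(5, 15, size=(20, 3))
        shift = np.array([3.7, -2.2, 8.1])
        m1 = make_model([("O", "O", "HOH", i + 1, "W", xyz)
                         for i, xyz in enumerate(coords)])
        m2 = make_model([("O", "O", "HOH", i + 1, "W", xyz + shift)
                         for i, xyz in enumerate(coords)])
        c1 = neighbor_search(m1, coords[0], 6.0, use_symmetry=False)
        c2 = neighbor_search(m2, coords[0] + shift, 6.0, use_symmetry=False)
        assert [(c.target_index, round(c.distance, 9)) for c in c1] == \
            [(c.target_index, round(c.distance, 9)) for c in c2]

    def test_radius_validation(self):
        model = make_model([("O", "O", "HOH", 1, "W", (0, 0, 0))])
        with pytest.raises(ValueError):
            neighbor_search(model, np.zeros(3), 12.0)


LINKED_TEMPLATE = (
    "ATOM  {serial:5d} {name:^4s} {res:>3s} {chain}{num:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00           {elem:>2s}"
)


def _linked_chain_pdb(n_residues: int, with_mg: bool) -> str:
    """n nucleotides linked via O3'(i)-P(i+1) = 1.6 A."""
    lines = ["CRYST1   90.000   90.000   90.000  90.00  90.00  90.00 P 1"]
    serial = 1
    for i in range(n_residues):
        x = 6.0 * i
        for name, elem, dx in (("P", "P", 0.0), ("O3'", "O", 4.4)):
            lines.append(LINKED_TEMPLATE.format(
                serial=serial, name=name, res="G", chain="A", num=i + 1,
                x=x + dx, y=0.0, z=0.0, elem=elem))
            serial += 1
    if with_mg:
        lines.append("HETATM{serial:5d} MG    MG B   1      50.000  50.000"
                     "  50.000  1.00 20.00          MG".format(serial=serial))
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestSelectStructures:
    def test_criteria(self, tmp_path):
        too_short = tmp_path / "short.pdb"
        too_short.write_text(_linked_chain_pdb(2, with_mg=True))
        no_mg = tmp_path / "nomg.pdb"
        no_mg.write_text(_linked_chain_pdb(5, with_mg=False))
        good = tmp_path / "good.pdb"
        good.write_text(_linked_chain_pdb(5, with_mg=True))
        result = select_structures([too_short, no_mg, good])
        assert [p for p, _, _ in result.accepted] == [str(good)]
        reasons = dict(result.rejected)
        assert "ribonucleotide" in reasons[str(too_short)]
        assert "Mg" in reasons[str(no_mg)]

    def test_linkage_counting(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(_linked_chain_pdb(4, with_mg=True))
        model = read_structure(p)
        assert count_linked_nucleotides(model) == 4
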