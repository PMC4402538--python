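"""Outer coordination sphere: hydrogen bonds from inner-sphere waters to
RNA, aggregated into phosphate / ribose / nucleobase moieties.

Hydrogen bonds are detected by a purely geometric criterion (heavy-atom
distance window plus an angle test keeping acceptors on the far side of
the water from the ion).  Only direct water->RNA bonds define the outer
sphere; second-shell water networks are not traversed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .inner_sphere import InnerSphere, LigandContact, LigandClass
from .structure import (AtomRecord, Contact, StructureModel,
                        bonded_phosphorus, neighbor_search)

_PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3"})
_RIBOSE_ONLY = frozenset({"O2'", "O4'", "C1'", "C2'", "C3'", "C4'", "C5'"})
_BRIDGING = frozenset({"O3'", "O5'"})


@dataclass
class HydrogenBond:
    """A water-mediated hydrogen bond from the inner sphere to RNA."""

    water: LigandContact          # inner-sphere water (ligand of the Mg)
    contact: Contact              # water -> RNA atom contact
    rna_atom: AtomRecord
    distance: float
    mg_water_target_angle: float  # degrees
    via_symmetry: bool

    @property
    def residue_key(self):
        return (self.contact.sym_op_index, self.contact.image_shift,
                self.rna_atom.chain_id, self.rna_atom.residue_number,
                self.rna_atom.insertion_code)


@dataclass
class OuterMoiety:
    """One phosphate/ribose/nucleobase moiety H-bonded to the site's
    inner-sphere waters; counted once per (kind, residue)."""

    kind: str                     # "P_out" | "R_out" | "B_out"
    residue_key: tuple            # (op, shift, chain, number, icode)
    residue_name: str
    bonds: list[HydrogenBond] = field(default_factory=list)

    @property
    def chain_frame(self) -> tuple:
        """(op, shift, chain): residues are sequence-comparable only when
        these match."""
        return self.residue_key[:3]

    @property
    def residue_number(self) -> int:
        return self.residue_key[3]

    def bond_atom_names(self) -> set[str]:
        return {b.rna_atom.atom_name for b in self.bonds}


def find_water_rna_hbonds(model: StructureModel, inner: InnerSphere,
                          hb_min: float = 2.4, hb_max: float = 3.5,
                          min_angle_deg: float = 90.0,
                          use_symmetry: bool = True) -> list[HydrogenBond]:
    """Hydrogen bonds from every inner-sphere water to RNA O/N atoms.

    A bond requires heavy-atom distance in [hb_min, hb_max] and an
    Mg-Ow-acceptor angle >= ``min_angle_deg`` (the acceptor must sit on
    the side of the water facing away from the ion).  Atoms that are
    inner-sphere ligands of the same Mg are excluded.
    """
    mg_xyz = inner.mg.xyz
    inner_ids = {(l.contact.target_index, l.contact.sym_op_index,
                  l.contact.image_shift) for l in inner.ligands}
    bonds: list[HydrogenBond] = []
    for water in inner.waters:
        w_xyz = water.contact.pos
        for c in neighbor_search(model, w_xyz, hb_max,
                                 use_symmetry=use_symmetry):
            atom = model.atoms[c.target_index]
            if not atom.is_rna or atom.element not in ("O", "N"):
                continue
            if c.distance < hb_min:
                continue
            if (c.target_index, c.sym_op_index, c.image_shift) in inner_ids:
                continue
            v_mg = mg_xyz - w_xyz
            v_x = c.pos - w_xyz
            cosang = float(np.dot(v_mg, v_x)
                           / (np.linalg.norm(v_mg) * np.linalg.norm(v_x)))
            angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if angle < min_angle_deg:
                continue
            bonds.append(HydrogenBond(
                water=water, contact=c, rna_atom=atom,
                distance=c.distance, mg_water_target_angle=angle,
                via_symmetry=not c.is_identity))
    bonds.sort(key=lambda b: (b.residue_key, b.rna_atom.atom_name,
                              b.distance))
    return bonds


def _phosphate_residue_key(model: StructureModel, bond_sym: tuple,
                           atom: AtomRecord) -> Optional[tuple]:
    """Residue key of the phosphate group ``atom`` belongs to (via the
    covalently bonded P), in the same symmetry frame as the contact."""
    if atom.atom_name == "P":
        p = atom
    else:
        p = bonded_phosphorus(model, atom)
        if p is None:
            return None
    op, shift = bond_sym
    return (op, shift, p.chain_id, p.residue_number, p.insertion_code)


def _inner_moiety_keys(model: StructureModel,
                       inner: InnerSphere) -> set[tuple[str, tuple]]:
    """(kind, residue_key) pairs of moieties already coordinating the ion
    through the inner sphere; such moieties never appear in the outer
    sphere of the same site."""
    keys: set[tuple[str, tuple]] = set()
    bridging: list[LigandContact] = []
    for lig in inner.ligands:
        sym = (lig.contact.sym_op_index, lig.contact.image_shift)
        if lig.ligand_class is LigandClass.O_PH:
            pk = _phosphate_residue_key(model, sym, lig.atom)
            keys.add(("P_out", pk if pk is not None else lig.residue_key))
        elif lig.ligand_class is LigandClass.O_R:
            if lig.atom.atom_name in _BRIDGING:
                bridging.append(lig)
            else:
                keys.add(("R_out", lig.residue_key))
        elif lig.ligand_class in (LigandClass.O_B, LigandClass.N_B):
            keys.add(("B_out", lig.residue_key))
    inner_phosphates = {k for kind, k in keys if kind == "P_out"}
    for lig in bridging:
        sym = (lig.contact.sym_op_index, lig.contact.image_shift)
        pk = _phosphate_residue_key(model, sym, lig.atom)
        if pk is not None and pk in inner_phosphates:
            keys.add(("P_out", pk))
        else:
            keys.add(("R_out", lig.residue_key))
    return keys


def assign_moieties(model: StructureModel, inner: InnerSphere,
                    bonds: list[HydrogenBond]) -> list[OuterMoiety]:
    """Aggregate hydrogen bonds into outer-sphere moieties.

    OP1/OP2/P map to the phosphate moiety, O2'/O4' to the ribose, base
    atoms to the nucleobase.  Bridging O3'/O5' atoms belong to the ribose
    unless their covalently connected phosphate already contributes to the
    inner or outer sphere of the same ion, in which case they fold into
    that phosphate moiety.  Each (kind, residue) is counted once, and a
    moiety that itself coordinates the ion in the inner sphere is dropped.
    """
    inner_keys = _inner_moiety_keys(model, inner)

    definite: dict[tuple[str, tuple], OuterMoiety] = {}
    bridging_bonds: list[HydrogenBond] = []

    def add(kind: str, key: tuple, name: str, bond: HydrogenBond) -> None:
        moiety = definite.setdefault(
            (kind, key), OuterMoiety(kind=kind, residue_key=key,
                                     residue_name=name))
        moiety.bonds.append(bond)

    for bond in bonds:
        atom = bond.rna_atom
        sym = (bond.contact.sym_op_index, bond.contact.image_shift)
        if atom.atom_name in _PHOSPHATE_ATOMS:
            key = _phosphate_residue_key(model, sym, atom) or bond.residue_key
            add("P_out", key, atom.residue_name, bond)
        elif atom.atom_name in _BRIDGING:
            bridging_bonds.append(bond)
        elif atom.atom_name in _RIBOSE_ONLY:
            add("R_out", bond.residue_key, atom.residue_name, bond)
        else:
            add("B_out", bond.residue_key, atom.residue_name, bond)

    contributing_phosphates = ({k for kind, k in definite if kind == "P_out"}
                               | {k for kind, k in inner_keys
                                  if kind == "P_out"})
    for bond in bridging_bonds:
        sym = (bond.contact.sym_op_index, bond.contact.image_shift)
        pk = _phosphate_residue_key(model, sym, bond.rna_atom)
        if pk is not None and pk in contributing_phosphates:
            add("P_out", pk, bond.rna_atom.residue_name, bond)
        else:
            add("R_out", bond.residue_key, bond.rna_atom.residue_name, bond)

    moieties = [m for (kind, key), m in definite.items()
                if (kind, key) not in inner_keys]
    moieties.sort(key=lambda m: (m.kind, m.residue_key))
    return moieties


def moiety_counts(moieties: list[OuterMoiety]) -> tuple[int, int, int]:
    """(#P_out, #R_out, #B_out)."""
    kinds = [m.kind for m in moieties]
    return (kinds.count("P_out"), kinds.count("R_out"), kinds.count("B_out"))
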