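"""Inner coordination sphere of Mg2+: ligand typing, the two-step
chemically constrained search, coordination number and geometric isomerism.

The search accepts every O/N close to the ideal bond length outright
(step 1) and then, only for under-coordinated ions, scans a wider shell
under three chemical rules that forbid bidentate phosphates, protonated or
exocyclic base nitrogens, and implausibly acute ligand-Mg-ligand angles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure import (AtomRecord, Contact, StructureModel,
                        bonded_phosphorus, neighbor_search)


class LigandClass(str, enum.Enum):
    O_PH = "O_ph"       # phosphate oxygen OP1/OP2
    O_R = "O_r"         # ribose / bridging oxygen O2'/O4'/O3'/O5'
    O_B = "O_b"         # nucleobase oxygen
    N_B = "N_b"         # nucleobase nitrogen
    WATER_O = "water_O"
    OTHER_O = "other_O"
    OTHER_N = "other_N"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


RNA_LIGAND_CLASSES = frozenset({LigandClass.O_PH, LigandClass.O_R,
                                LigandClass.O_B, LigandClass.N_B})

_PHOSPHATE_O = frozenset({"OP1", "OP2", "OP3"})
_RIBOSE_O = frozenset({"O2'", "O4'", "O3'", "O5'"})
_BASE_O = frozenset({"O2", "O4", "O6"})

#: endocyclic nitrogens with an in-plane lone pair (-N=); the only
#: nucleobase nitrogens that can coordinate Mg2+
LONE_PAIR_NITROGENS = frozenset({
    ("A", "N1"), ("A", "N3"), ("A", "N7"),
    ("G", "N3"), ("G", "N7"),
    ("C", "N3"),
})


def classify_atom(atom: AtomRecord) -> LigandClass:
    """Map an atom to its coordinating-atom class (O_ph/O_r/O_b/N_b/...)."""
    if atom.is_water:
        return LigandClass.WATER_O if atom.element == "O" else LigandClass.OTHER
    if atom.is_rna:
        name = atom.atom_name
        if name in _PHOSPHATE_O:
            return LigandClass.O_PH
        if name in _RIBOSE_O:
            return LigandClass.O_R
        if atom.element == "O" and name in _BASE_O:
            return LigandClass.O_B
        if atom.element == "N":
            return LigandClass.N_B
    if atom.element == "O":
        return LigandClass.OTHER_O
    if atom.element == "N":
        return LigandClass.OTHER_N
    return LigandClass.OTHER


def is_lone_pair_nitrogen(atom: AtomRecord) -> bool:
    """True for the six -N= nucleobase nitrogens (A-N1/N3/N7, G-N3/N7, C-N3)."""
    return (atom.residue_name, atom.atom_name) in LONE_PAIR_NITROGENS


@dataclass
class LigandContact:
    """One inner-sphere Mg-ligand interaction."""

    contact: Contact
    atom: AtomRecord
    ligand_class: LigandClass
    distance: float
    unit_vector: np.ndarray
    step: int                      # 1 or 2
    valence: Optional[float] = None  # filled in by the quality module

    @property
    def residue_key(self):
        """Symmetry-aware residue identity: (op, shift, chain, num, icode)."""
        return (self.contact.sym_op_index, self.contact.image_shift,
                self.atom.chain_id, self.atom.residue_number,
                self.atom.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.ligand_class is LigandClass.WATER_O


@dataclass
class InnerSphere:
    """The inner coordination sphere of one Mg2+ ion."""

    mg: AtomRecord
    ligands: list[LigandContact] = field(default_factory=list)
    isomerism: Optional[str] = None   # cis / trans / fac / mer

    @property
    def cn(self) -> int:
        return len(self.ligands)

    @property
    def waters(self) -> list[LigandContact]:
        return [l for l in self.ligands if l.is_water]

    @property
    def cn_flagged(self) -> bool:
        """CN > 6 indicates a modeling problem; sites are kept but flagged."""
        return self.cn > 6

    def ligands_of_class(self, cls: LigandClass) -> list[LigandContact]:
        return [l for l in self.ligands if l.ligand_class is cls]

    def class_counts(self) -> tuple[int, int, int, int]:
        """(#O_ph, #O_r, #O_b, #N_b)."""
        return (len(self.ligands_of_class(LigandClass.O_PH)),
                len(self.ligands_of_class(LigandClass.O_R)),
                len(self.ligands_of_class(LigandClass.O_B)),
                len(self.ligands_of_class(LigandClass.N_B)))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return math.degrees(math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0))))


def phosphate_group_key(model: StructureModel, contact: Contact,
                        atom: AtomRecord) -> Optional[tuple]:
    """Identity of the phosphate group an oxygen belongs to, or None.

    The group is the covalently bonded P atom's residue, carried together
    with the contact's symmetry id so that symmetry copies of one phosphate
    are distinct groups only when they are physically distinct.
    """
    if atom.element != "O":
        return None
    p = bonded_phosphorus(model, atom)
    if p is None:
        return None
    return (contact.sym_op_index, contact.image_shift,
            p.chain_id, p.residue_number, p.insertion_code)


def find_inner_sphere(model: StructureModel, mg: AtomRecord,
                      d_ideal_o: float = 2.08, d_ideal_n: float = 2.20,
                      step1_margin: float = 0.5, step2_margin: float = 1.0,
                      min_angle_deg: float = 50.0,
                      use_symmetry: bool = True) -> InnerSphere:
    """Two-step inner-sphere ligand search around one Mg2+ ion.

    Step 1 accepts every O within ``d_ideal_o + step1_margin`` and N within
    ``d_ideal_n + step1_margin``.  Step 2 runs only when step 1 found fewer
    than six ligands, scanning the next 0.5 A shell in ascending distance
    order under three rules: (i) no second oxygen of an already-contributing
    phosphate group, (ii) nucleobase nitrogens must be -N=, (iii) angle at
    Mg with every previously accepted ligand > ``min_angle_deg``.

    CN is not capped; CN > 6 sites are flagged via ``cn_flagged``.
    """
    if mg.element.upper() != "MG":
        raise ValueError(f"{mg!r} is not a magnesium atom")
    radius = max(d_ideal_o, d_ideal_n) + step2_margin
    contacts = neighbor_search(model, mg, radius, use_symmetry=use_symmetry)

    candidates = []
    for c in contacts:
        atom = model.atoms[c.target_index]
        if atom.element not in ("O", "N"):
            continue
        candidates.append((c, atom))
    # deterministic order regardless of atom input order
    candidates.sort(key=lambda ca: (ca[0].distance, ca[1].chain_id,
                                    ca[1].residue_number, ca[1].atom_name,
                                    ca[0].sym_op_index, ca[0].image_shift))

    def make_ligand(c: Contact, atom: AtomRecord, step: int) -> LigandContact:
        u = (c.pos - mg.xyz) / c.distance
        return LigandContact(contact=c, atom=atom,
                             ligand_class=classify_atom(atom),
                             distance=c.distance, unit_vector=u, step=step)

    def cutoff(atom: AtomRecord) -> float:
        return d_ideal_n if atom.element == "N" else d_ideal_o

    accepted: list[LigandContact] = []
    step2_pool = []
    for c, atom in candidates:
        d0 = cutoff(atom)
        if c.distance <= d0 + step1_margin:
            accepted.append(make_ligand(c, atom, step=1))
        elif c.distance <= d0 + step2_margin:
            step2_pool.append((c, atom))

    if len(accepted) < 6:
        group_keys = {phosphate_group_key(model, l.contact, l.atom)
                      for l in accepted if l.atom.element == "O"}
        group_keys.discard(None)
        for c, atom in step2_pool:
            # rule (i): a phosphate group cannot bind bidentately
            gk = phosphate_group_key(model, c, atom)
            if gk is not None and gk in group_keys:
                continue
            # rule (ii): only -N= nucleobase nitrogens may coordinate
            if (classify_atom(atom) is LigandClass.N_B
                    and not is_lone_pair_nitrogen(atom)):
                continue
            # rule (iii): planar angle > min_angle_deg with every accepted
            lig = make_ligand(c, atom, step=2)
            if any(_angle_deg(lig.unit_vector, a.unit_vector) <= min_angle_deg
                   for a in accepted):
                continue
            accepted.append(lig)
            if gk is not None:
                group_keys.add(gk)

    inner = InnerSphere(mg=mg, ligands=accepted)
    inner.isomerism = geometric_isomerism(inner)
    return inner


def geometric_isomerism(inner: InnerSphere,
                        trans_angle_deg: float = 135.0) -> Optional[str]:
    """cis/trans (2 or 4 O_ph) or fac/mer (3 O_ph) isomer label.

    trans/mer iff some O_ph pair subtends an angle at Mg greater than
    ``trans_angle_deg``; sites with #O_ph outside {2, 3, 4} get no label.
    """
    o_ph = inner.ligands_of_class(LigandClass.O_PH)
    n = len(o_ph)
    if n not in (2, 3, 4):
        return None
    has_trans_pair = any(
        _angle_deg(o_ph[i].unit_vector, o_ph[j].unit_vector) > trans_angle_deg
        for i in range(n) for j in range(i + 1, n))
    if n == 3:
        return "mer" if has_trans_pair else "fac"
    return "trans" if has_trans_pair else "cis"
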