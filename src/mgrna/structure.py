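"""Symmetry-aware coordinate model for RNA crystal structures.

Parses PDB/mmCIF files into a flat list of :class:`AtomRecord` objects,
keeps the crystallographic unit cell and space-group operators, and offers
a radius query (:func:`neighbor_search`) that generates symmetry mates and
periodic images on the fly.  Every downstream stage — inner-sphere search,
quality scoring, hydrogen-bond detection, classification — runs on top of
these primitives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue names treated as water
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

#: the four common ribonucleotides
RNA_RESIDUES = frozenset({"A", "G", "C", "U"})

#: legacy atom-name spellings -> PDB v3 names
_NAME_FIXES = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3"}

IDENTITY_SHIFT = (0, 0, 0)


@dataclass(slots=True)
class AtomRecord:
    """One non-hydrogen atom of the model."""

    index: int
    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    alt_loc: str
    xyz: np.ndarray
    b_factor: float
    occupancy: float
    is_water: bool
    is_metal: bool

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_rna(self) -> bool:
        return self.residue_name in RNA_RESIDUES

    def __repr__(self) -> str:  # compact, used in error messages
        return (f"<{self.chain_id}/{self.residue_name}{self.residue_number}"
                f"/{self.atom_name}>")


@dataclass
class UnitCell:
    """Unit cell plus space-group operators in fractional coordinates.

    ``ops`` holds (rotation, translation) pairs; the identity operator is
    always at index 0 so that ``sym_op_index == 0`` marks an asymmetric-unit
    contact.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for length in (self.a, self.b, self.c):
            if length <= 0:
                raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")
        cell = gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)
        self._orth = np.array(cell.orth.mat.tolist())
        self._frac = np.array(cell.frac.mat.tolist())
        if not self.ops:
            sg = gemmi.SpaceGroup(self.space_group)
            den = float(gemmi.Op.DEN)
            for op in sg.operations():
                rot = np.array(op.rot, dtype=float) / den
                tran = np.array(op.tran, dtype=float) / den
                self.ops.append((rot, tran))
        # identity first
        ident = [i for i, (r, t) in enumerate(self.ops)
                 if np.allclose(r, np.eye(3)) and np.allclose(t, 0)]
        if not ident:
            raise ValueError("identity operator missing from symmetry list")
        if ident[0] != 0:
            self.ops.insert(0, self.ops.pop(ident[0]))

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self._frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self._orth.T


@dataclass(frozen=True, slots=True)
class Contact:
    """A source->target contact, possibly through crystal symmetry.

    ``pos`` is the Cartesian position of the (transformed) target atom, so
    callers never need to re-apply the operator.
    """

    source_index: Optional[int]
    target_index: int
    distance: float
    sym_op_index: int
    image_shift: tuple[int, int, int]
    pos: np.ndarray

    @property
    def is_identity(self) -> bool:
        return self.sym_op_index == 0 and self.image_shift == IDENTITY_SHIFT

    @property
    def sym_id(self) -> tuple[int, tuple[int, int, int]]:
        return (self.sym_op_index, self.image_shift)


class StructureModel:
    """A parsed structure: flat atom list + optional cell + metadata."""

    def __init__(self, atoms: Sequence[AtomRecord], cell: Optional[UnitCell],
                 resolution: Optional[float], identifier: str,
                 meta: Optional[dict] = None) -> None:
        self.atoms = list(atoms)
        self.cell = cell
        self.resolution = resolution
        self.identifier = identifier
        self.meta = dict(meta or {})
        if len({a.index for a in self.atoms}) != len(self.atoms):
            raise ValueError("atom indices must be unique")
        self._coords = (np.vstack([a.xyz for a in self.atoms])
                        if self.atoms else np.empty((0, 3)))

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def magnesium_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.upper() == "MG"]

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"StructureModel({self.identifier!r}, {len(self)} atoms)"


# ---------------------------------------------------------------------------
# parsing

def _prune_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first
    altloc alphabetically."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        else:
            kept.append(sorted(group, key=lambda a: (-a.occ, a.altloc))[0])
    return kept


def normalize_atom_name(name: str) -> str:
    """Unify ribose prime naming (O2* -> O2') and legacy phosphate names."""
    name = name.strip().replace("*", "'").replace("′", "'")
    return _NAME_FIXES.get(name, name)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens are dropped, alternate conformers reduced to the
    highest-occupancy one, and atom names normalized.  A missing CRYST1 /
    ``_cell`` block yields a model without a cell (symmetry queries then
    degrade to the asymmetric unit with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    st.remove_hydrogens()

    atoms: list[AtomRecord] = []
    index = 0
    if len(st) == 0:
        raise ValueError(f"{path.name}: no coordinate model found")
    model = st[0]
    for chain in model:
        for residue in chain:
            res_name = residue.name.strip()
            water = residue.is_water() or res_name in WATER_NAMES
            for atom in _prune_altlocs(residue):
                elem = atom.element.name
                if elem == "H" or elem == "D":
                    continue
                altloc = atom.altloc if atom.altloc != "\0" else ""
                atoms.append(AtomRecord(
                    index=index,
                    element=elem,
                    atom_name=normalize_atom_name(atom.name),
                    residue_name=res_name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    chain_id=chain.name,
                    alt_loc=altloc,
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    b_factor=max(atom.b_iso, 0.0),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    is_water=water,
                    is_metal=atom.element.is_metal,
                ))
                index += 1

    if not atoms:
        raise ValueError(f"{path.name}: no atom records found")

    cell = None
    if st.cell.is_crystal() and st.cell.a > 1.0:
        try:
            cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                            st.cell.alpha, st.cell.beta, st.cell.gamma,
                            space_group=st.spacegroup_hm or "P 1")
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: unusable cell/space group (%s); "
                           "symmetry disabled", path.name, exc)
    else:
        logger.warning("%s: no unit cell; symmetry queries degrade to the "
                       "asymmetric unit", path.name)

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    meta = dict(st.info)
    return StructureModel(atoms, cell, resolution,
                          identifier=st.name or path.stem, meta=meta)


# ---------------------------------------------------------------------------
# neighbor search

_NEIGHBOR_OFFSETS = np.array([(i, j, k)
                              for i in (-1, 0, 1)
                              for j in (-1, 0, 1)
                              for k in (-1, 0, 1)], dtype=float)


def neighbor_search(model: StructureModel,
                    center: AtomRecord | np.ndarray,
                    radius: float,
                    use_symmetry: bool = True) -> list[Contact]:
    """All atoms within ``radius`` of ``center``, symmetry mates included.

    Returns contacts sorted by ascending distance.  The center atom itself
    (and any image coinciding with it at distance ~0) is excluded.  With
    ``use_symmetry`` and no cell, falls back to the asymmetric unit.
    """
    if not 0 < radius <= 10:
        raise ValueError("radius must lie in (0, 10] A")
    if isinstance(center, AtomRecord):
        center_xyz = center.xyz
        source_index: Optional[int] = center.index
    else:
        center_xyz = np.asarray(center, dtype=float)
        source_index = None
    if len(model) == 0:
        return []

    contacts: list[Contact] = []
    cell = model.cell
    if use_symmetry and cell is None:
        logger.warning("%s: symmetry requested but no cell; using "
                       "asymmetric unit only", model.identifier)
    if not use_symmetry or cell is None:
        diff = model.coords - center_xyz
        dists = np.linalg.norm(diff, axis=1)
        for idx in np.nonzero(dists <= radius)[0]:
            d = float(dists[idx])
            if d < 1e-6:
                continue
            contacts.append(Contact(source_index, int(idx), d, 0,
                                    IDENTITY_SHIFT, model.coords[idx].copy()))
        contacts.sort(key=lambda c: c.distance)
        return contacts

    frac_atoms = cell.fractionalize(model.coords)       # (N, 3)
    frac_center = cell.fractionalize(center_xyz)
    for op_index, (rot, tran) in enumerate(cell.ops):
        transformed = frac_atoms @ rot.T + tran
        delta = transformed - frac_center
        base_shift = -np.round(delta)
        # nearest image plus the 26 surrounding cells (covers small or
        # skewed cells where radius exceeds half a cell edge)
        for offset in _NEIGHBOR_OFFSETS:
            shift = base_shift + offset
            cart = cell.orthogonalize(transformed + shift) - \
                cell.orthogonalize(frac_center)
            dists = np.linalg.norm(cart, axis=1)
            for idx in np.nonzero(dists <= radius)[0]:
                d = float(dists[idx])
                if d < 1e-6:
                    continue
                pos = cell.orthogonalize(transformed[idx] + shift[idx]) \
                    - cell.orthogonalize(frac_center) + center_xyz
                contacts.append(Contact(
                    source_index, int(idx), d, op_index,
                    tuple(int(s) for s in shift[idx]), pos))
    # dedupe (op/shift pairs may coincide across offsets)
    seen: set[tuple] = set()
    unique: list[Contact] = []
    for c in sorted(contacts, key=lambda c: (c.distance, c.target_index,
                                             c.sym_op_index, c.image_shift)):
        key = (c.target_index, c.sym_op_index, c.image_shift)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def bonded_phosphorus(model: StructureModel, oxygen: AtomRecord,
                      max_bond: float = 1.9) -> Optional[AtomRecord]:
    """The P atom covalently bonded to ``oxygen`` (P-O bond <= ``max_bond``).

    Identifies the phosphate group an oxygen belongs to: OP1/OP2/O5' bond to
    their own residue's P, O3' to the 3'-neighbor's P.
    """
    best = None
    best_d = max_bond
    for atom in model.atoms:
        if atom.element != "P":
            continue
        d = float(np.linalg.norm(atom.xyz - oxygen.xyz))
        if d <= best_d:
            best, best_d = atom, d
    return best


# ---------------------------------------------------------------------------
# dataset selection

@dataclass
class SelectionResult:
    accepted: list[tuple[str, StructureModel, str]]  # (path, model, subset)
    rejected: list[tuple[str, str]]                  # (path, failed criterion)


def count_linked_nucleotides(model: StructureModel,
                             max_link: float = 2.0) -> int:
    """Size of the largest chain of common ribonucleotides covalently linked
    by phosphodiester bonds (O3'(i)-P(i+1) distance <= ``max_link``)."""
    residues: dict[tuple, dict[str, AtomRecord]] = {}
    for atom in model.atoms:
        if atom.is_rna and atom.atom_name in ("O3'", "P"):
            residues.setdefault(atom.residue_key, {})[atom.atom_name] = atom
    keys = list(residues)
    if not keys:
        return 0
    # union-find over residues
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    o3_list = [(k, r["O3'"]) for k, r in residues.items() if "O3'" in r]
    p_list = [(k, r["P"]) for k, r in residues.items() if "P" in r]
    for k1, o3 in o3_list:
        for k2, p in p_list:
            if k1 == k2:
                continue
            if np.linalg.norm(o3.xyz - p.xyz) <= max_link:
                union(k1, k2)
    sizes: dict = {}
    for k in keys:
        r = find(k)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def is_ribosome(model: StructureModel,
                keywords: Iterable[str] = ("ribosom",),
                id_list: Optional[Iterable[str]] = None) -> bool:
    """Tag a structure as ribosomal by metadata keyword match (overridable
    by an explicit id list)."""
    if id_list is not None:
        return model.identifier.lower() in {i.lower() for i in id_list}
    text = " ".join(str(v) for v in model.meta.values()).lower()
    return any(kw.lower() in text for kw in keywords)


def select_structures(paths: Sequence[str | Path],
                      min_linked: int = 3,
                      max_link: float = 2.0,
                      ribosome_keywords: Iterable[str] = ("ribosom",),
                      ribosome_ids: Optional[Iterable[str]] = None,
                      ) -> SelectionResult:
    """Apply the full-dataset criteria: X-ray (when metadata says so),
    >= ``min_linked`` covalently linked A/G/C/U residues, >= 1 Mg ion.
    Accepted structures are tagged ribosome / non-ribosome."""
    accepted, rejected = [], []
    for p in paths:
        p = str(p)
        try:
            model = read_structure(p)
        except (ValueError, FileNotFoundError) as exc:
            rejected.append((p, f"unreadable: {exc}"))
            continue
        method = str(model.meta.get("_exptl.method", "")).upper()
        if method and "X-RAY" not in method:
            rejected.append((p, "not X-ray"))
            continue
        if count_linked_nucleotides(model, max_link) < min_linked:
            rejected.append((p, f"fewer than {min_linked} linked "
                                "ribonucleotides"))
            continue
        if not model.magnesium_atoms():
            rejected.append((p, "no Mg ion"))
            continue
        subset = ("ribosome" if is_ribosome(model, ribosome_keywords,
                                            ribosome_ids)
                  else "non-ribosome")
        accepted.append((p, model, subset))
    return SelectionResult(accepted, rejected)
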