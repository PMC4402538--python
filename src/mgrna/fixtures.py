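"""Synthetic structure fixtures with planted ground truth.

Builds small, fully specified PDB files around idealized Mg2+ sites:
ligands sit on exact octahedral (or pentagonal-bipyramidal) vertices at
the ideal bond lengths, outer-sphere acceptors extend radially from
inner-sphere waters, and every file carries a short covalently linked
RNA chain so the dataset-selection criteria hold.  Residue fragments use
plausible internal geometry (correct atom names and bond lengths); full
stereochemical realism is out of scope.  The planted class, type, CN,
isomerism, motif and benchmark labels are emitted as ground truth for
end-to-end recovery tests.

Determinism: the same seed yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

D_MG_O = 2.08   # ideal Mg-O bond length (A)
D_MG_N = 2.20   # ideal Mg-N bond length (A)
HB_LEN = 2.8    # default water...acceptor heavy-atom distance (A)

# octahedral vertices
PX, MX, PY, MY, PZ, MZ = ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                          (0, -1, 0), (0, 0, 1), (0, 0, -1))
OCTAHEDRON = (PX, MX, PY, MY, PZ, MZ)

_S = math.sin(math.radians(72))
_C = math.cos(math.radians(72))
#: pentagonal bipyramid (7 vertices) for CN=7 fixtures
BIPYRAMID7 = ((0, 0, 1), (0, 0, -1), (1, 0, 0), (_C, _S, 0),
              (math.cos(math.radians(144)), math.sin(math.radians(144)), 0),
              (math.cos(math.radians(216)), math.sin(math.radians(216)), 0),
              (math.cos(math.radians(288)), math.sin(math.radians(288)), 0))


class FixtureError(ValueError):
    """Raised when a recipe is geometrically unrealizable."""


# ---------------------------------------------------------------------------
# residue fragment templates (local frame: anchor at origin, body in +z)

PHOSPHATE_FRAGMENT = (
    ("OP1", "O", (0.0, 0.0, 0.0)),
    ("P", "P", (0.0, 0.0, 1.50)),
    ("OP2", "O", (1.35, 0.0, 2.19)),
    ("O5'", "O", (-1.30, 0.0, 2.40)),
    ("C5'", "C", (-1.30, 0.0, 3.85)),
)

RIBOSE_FRAGMENT = (
    ("O2'", "O", (0.0, 0.0, 0.0)),
    ("C2'", "C", (0.0, 0.0, 1.43)),
    ("C1'", "C", (1.05, 0.0, 2.33)),
    ("C3'", "C", (-1.20, 0.45, 1.95)),
    ("O3'", "O", (-2.00, 1.00, 2.95)),
    ("C4'", "C", (-0.55, 1.35, 3.05)),
    ("O4'", "O", (0.75, 1.15, 3.45)),
    ("C5'", "C", (-1.15, 2.10, 4.15)),
    ("O5'", "O", (-0.35, 3.05, 4.80)),
)

SULFATE_FRAGMENT = (
    ("O1", "O", (0.0, 0.0, 0.0)),
    ("S", "S", (0.0, 0.0, 1.47)),
    ("O2", "O", (1.25, 0.0, 2.20)),
    ("O3", "O", (-1.20, 0.55, 2.20)),
    ("O4", "O", (0.0, -1.30, 2.10)),
)


def _ring_coords() -> dict[str, dict[str, np.ndarray]]:
    """2D coordinates for planar base templates (approximate but with
    correct atom names, connectivity and ~1.4 A bond lengths)."""
    side = 1.39
    hexagon = {}
    order = ("N1", "C2", "N3", "C4", "C5", "C6")
    for k, name in enumerate(order):
        ang = math.radians(60 * k)
        hexagon[name] = side * np.array([math.cos(ang), math.sin(ang)])

    def exocyclic(host: np.ndarray, length: float = 1.25) -> np.ndarray:
        return host * (1.0 + length / np.linalg.norm(host))

    # fused pentagon on the C4-C5 edge: ring C4-N9-C8-N7-C5
    c4, c5 = hexagon["C4"], hexagon["C5"]
    mid = (c4 + c5) / 2
    w = mid / np.linalg.norm(mid)
    apothem = side / (2 * math.tan(math.radians(36)))
    r5 = side / (2 * math.sin(math.radians(36)))
    center5 = mid + apothem * w
    a4 = math.atan2(*(c4 - center5)[::-1])
    a5 = math.atan2(*(c5 - center5)[::-1])
    step = math.radians(72)
    # choose the rotation direction that reaches C5 after four steps
    sign = 1 if abs(((a4 + 4 * step) - a5) % (2 * math.pi)) < 1e-6 else -1
    pent = {}
    for k, name in enumerate(("N9", "C8", "N7"), start=1):
        ang = a4 + sign * step * k
        pent[name] = center5 + r5 * np.array([math.cos(ang), math.sin(ang)])

    purine = dict(hexagon, **pent)
    bases = {
        "G": dict(purine, O6=exocyclic(hexagon["C6"]),
                  N2=exocyclic(hexagon["C2"])),
        "A": dict(purine, N6=exocyclic(hexagon["C6"])),
        "U": dict(hexagon, O2=exocyclic(hexagon["C2"]),
                  O4=exocyclic(hexagon["C4"])),
        "C": dict(hexagon, O2=exocyclic(hexagon["C2"]),
                  N4=exocyclic(hexagon["C4"])),
    }
    return bases


_BASES_2D = _ring_coords()

_ELEMENT = {"O": "O", "N": "N", "C": "C", "P": "P", "S": "S"}


def base_fragment(base: str, anchor: str) -> tuple[tuple[str, str, tuple], ...]:
    """Planar base template anchored at ``anchor`` with the ring body in
    the +z half-space (plane spanned by local x and z)."""
    coords = _BASES_2D[base]
    if anchor not in coords:
        raise FixtureError(f"no atom {anchor} in base {base}")
    origin = coords[anchor]
    centroid = np.mean(list(coords.values()), axis=0)
    toward = centroid - origin
    norm = np.linalg.norm(toward)
    if norm < 1e-9:
        toward, norm = np.array([0.0, 1.0]), 1.0
    toward = toward / norm
    # rotate 2D so 'toward' becomes +y, then embed (x2d, y2d) -> (x, 0, z)
    rot = np.array([[toward[1], -toward[0]], [toward[0], toward[1]]])
    atoms = []
    for name, xy in coords.items():
        local2 = rot @ (xy - origin)
        atoms.append((name, name[0], (float(local2[0]), 0.0,
                                      float(local2[1]))))
    return tuple(atoms)


def _orthonormal_frame(outward: np.ndarray,
                       azimuth_deg: float = 0.0) -> np.ndarray:
    """Rotation matrix with +z mapped to ``outward``; azimuth spins the
    fragment around its outward axis (deterministic reference axis)."""
    e3 = np.asarray(outward, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(e3 @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, e3)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    rot = np.column_stack([e1, e2, e3])
    if azimuth_deg:
        a = math.radians(azimuth_deg)
        spin = np.array([[math.cos(a), -math.sin(a), 0],
                         [math.sin(a), math.cos(a), 0],
                         [0, 0, 1.0]])
        rot = rot @ spin
    return rot


def place_fragment(template: Sequence[tuple[str, str, tuple]],
                   target: np.ndarray, outward: np.ndarray,
                   azimuth_deg: float = 0.0) -> list[tuple[str, str, np.ndarray]]:
    rot = _orthonormal_frame(outward, azimuth_deg)
    return [(name, elem, target + rot @ np.asarray(local))
            for name, elem, local in template]


# ---------------------------------------------------------------------------
# recipes

@dataclass(frozen=True)
class Ligand:
    """One planted inner-sphere ligand (or bare water)."""

    kind: str                      # water|O_ph|O_r|O_b|N_b|other_O|bidentate
    direction: tuple               # direction from Mg (normalized at build)
    residue: Optional[tuple] = None  # (chain, residue name, number)
    atom: Optional[str] = None       # anchor atom name (default per kind)
    distance: Optional[float] = None
    azimuth_deg: float = 45.0
    image_shift: Optional[tuple] = None  # place via this lattice translation


@dataclass(frozen=True)
class Acceptor:
    """An outer-sphere hydrogen-bond acceptor planted beyond one water."""

    kind: str                      # P_out | R_out | B_out
    residue: tuple                 # (chain, residue name, number)
    atom: Optional[str] = None
    hb_distance: float = HB_LEN
    azimuth_deg: float = 45.0


@dataclass(frozen=True)
class SiteRecipe:
    """Declarative description of one planted site plus its truth labels."""

    name: str
    inner: tuple[Ligand, ...]
    acceptors: tuple[tuple[int, Acceptor], ...] = ()  # (inner water idx, acc)
    extra_metals: tuple[tuple[str, tuple, float], ...] = ()
    mg_b: float = 20.0
    mg_occ: float = 1.0
    env_b: float = 20.0
    cell: tuple = (60.0, 60.0, 60.0, 90.0, 90.0, 90.0, "P 1")
    mg_frac: tuple = (0.5, 0.5, 0.5)
    carrier_origin: Optional[tuple] = None  # absolute; default Mg - 22 each
    truth: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FixtureSpec:
    """A recipe plus noise parameters and a seed."""

    recipe: SiteRecipe
    seed: int = 0
    distance_sigma: float = 0.0     # radial jitter on planted distances (A)
    b_factor_range: Optional[tuple[float, float]] = None


_DEFAULT_ANCHORS = {"O_ph": "OP1", "O_r": "O2'", "O_b": "O6", "N_b": "N7",
                    "other_O": "O1"}


def _default_distance(kind: str, atom: str) -> float:
    if kind == "N_b" or (atom or "").startswith("N"):
        return D_MG_N
    return D_MG_O


def _fragment_for(kind: str, residue_name: str, anchor: str):
    if kind == "O_ph":
        if anchor != "OP1":
            raise FixtureError("phosphate fragments anchor at OP1")
        return PHOSPHATE_FRAGMENT
    if kind == "O_r":
        if anchor != "O2'":
            raise FixtureError("ribose fragments anchor at O2'")
        return RIBOSE_FRAGMENT
    if kind in ("O_b", "N_b"):
        return base_fragment(residue_name, anchor)
    if kind == "other_O":
        return SULFATE_FRAGMENT
    raise FixtureError(f"unknown ligand kind {kind!r}")


_CARRIER_SUGAR = (
    ("P", "P", (0.0, 0.0, 0.0)),
    ("OP1", "O", (0.75, 1.25, 0.35)),
    ("OP2", "O", (-0.95, 1.05, -0.65)),
    ("O5'", "O", (0.55, -1.25, 0.75)),
    ("C5'", "C", (1.85, -1.55, 1.25)),
    ("C4'", "C", (2.85, -0.85, 2.05)),
    ("O4'", "O", (2.65, 0.35, 2.75)),
    ("C3'", "C", (3.45, -0.45, 0.95)),
    ("O3'", "O", (4.40, 0.0, 0.0)),
    ("C2'", "C", (3.15, 1.05, 1.15)),
    ("O2'", "O", (3.85, 1.45, 2.35)),
    ("C1'", "C", (2.15, 1.55, 2.95)),
)

_CARRIER_BASES = ("G", "C", "A")


def _carrier_atoms(origin: np.ndarray):
    """Three covalently linked nucleotides (O3'(i)-P(i+1) = 1.6 A) far from
    the planted site; they satisfy the dataset criteria and populate the
    background atom census."""
    atoms = []  # (chain, resname, resnum, atom name, element, xyz)
    for i, base in enumerate(_CARRIER_BASES):
        shift = origin + np.array([6.0 * i, 0.0, 0.0])
        resnum = 101 + i
        for name, elem, local in _CARRIER_SUGAR:
            atoms.append(("R", base, resnum, name, elem,
                          shift + np.asarray(local)))
        glyco = "N9" if base in ("G", "A") else "N1"
        frag = base_fragment(base, glyco)
        anchor_pos = shift + np.array([1.95, 2.45, 4.15])
        for name, elem, xyz in place_fragment(frag, anchor_pos,
                                              (0.0, 0.55, 0.84)):
            atoms.append(("R", base, resnum, name, elem, xyz))
    return atoms


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def build_fixture(spec: FixtureSpec) -> tuple[str, dict]:
    """Assemble the fixture; returns (PDB text, truth record).

    Raises :class:`FixtureError` before writing when the recipe is not
    realizable (atom clashes, or stray atoms that would corrupt the
    planted inner/outer spheres).
    """
    recipe = spec.recipe
    rng = np.random.default_rng(spec.seed)
    a, b, c, al, be, ga, sg = recipe.cell
    cell = gemmi.UnitCell(a, b, c, al, be, ga)
    mg_xyz = np.array(cell.orthogonalize(gemmi.Fractional(*recipe.mg_frac))
                      .tolist())
    orth = np.array(cell.orth.mat.tolist())

    atoms: list[tuple] = []   # (chain, resname, resnum, name, elem, xyz, frag)
    frag_id = 0

    def jitter(d: float) -> float:
        if spec.distance_sigma:
            return d + float(rng.normal(0.0, spec.distance_sigma))
        return d

    atoms.append(("M", "MG", 1, "MG", "MG", mg_xyz, frag_id))

    water_positions: dict[int, np.ndarray] = {}
    planted_inner: list[np.ndarray] = []
    water_count = 0
    for idx, lig in enumerate(recipe.inner):
        frag_id += 1
        u = _normalize(lig.direction)
        if lig.kind == "water":
            d = jitter(lig.distance or D_MG_O)
            pos = mg_xyz + d * u
            if lig.image_shift is not None:
                stored = pos + orth @ np.asarray(lig.image_shift, dtype=float)
            else:
                stored = pos
            water_count += 1
            atoms.append(("W", "HOH", water_count, "O", "O", stored, frag_id))
            water_positions[idx] = pos
            planted_inner.append(pos)
            continue
        if lig.kind == "bidentate":
            # OP1/OP2 of one phosphate offered to the ion 60 deg apart;
            # only the nearer may be accepted (no bidentate phosphates)
            chain, resname, resnum = lig.residue
            d = lig.distance or 2.90
            rot = _orthonormal_frame(u, lig.azimuth_deg)
            perp = rot[:, 0]
            u2 = math.cos(math.radians(60)) * u + \
                math.sin(math.radians(60)) * perp
            bis = _normalize(u + u2)
            op1 = mg_xyz + jitter(d) * u
            op2 = mg_xyz + jitter(d + 0.02) * u2
            p = mg_xyz + 3.19 * bis
            o5 = p + 1.58 * bis
            for name, elem, pos in (("OP1", "O", op1), ("OP2", "O", op2),
                                    ("P", "P", p), ("O5'", "O", o5)):
                atoms.append((chain, resname, resnum, name, elem, pos,
                              frag_id))
            planted_inner.extend([op1, op2])
            continue
        anchor = lig.atom or _DEFAULT_ANCHORS[lig.kind]
        chain, resname, resnum = lig.residue
        d = jitter(lig.distance or _default_distance(lig.kind, anchor))
        target = mg_xyz + d * u
        frag = _fragment_for(lig.kind, resname, anchor)
        for name, elem, xyz in place_fragment(frag, target, u,
                                              lig.azimuth_deg):
            atoms.append((chain, resname, resnum, name, elem, xyz, frag_id))
        planted_inner.append(target)

    planted_acceptors: list[np.ndarray] = []
    for water_idx, acc in recipe.acceptors:
        frag_id += 1
        if water_idx not in water_positions:
            raise FixtureError(f"acceptor references inner ligand "
                               f"{water_idx} which is not a water")
        w = water_positions[water_idx]
        u = _normalize(w - mg_xyz)
        target = w + jitter(acc.hb_distance) * u
        chain, resname, resnum = acc.residue
        if acc.kind == "P_out":
            frag = PHOSPHATE_FRAGMENT
            anchor = acc.atom or "OP1"
            if anchor != "OP1":
                raise FixtureError("P_out acceptors anchor at OP1")
        elif acc.kind == "R_out":
            frag = RIBOSE_FRAGMENT
            anchor = acc.atom or "O2'"
        else:
            anchor = acc.atom or "O6"
            frag = base_fragment(resname, anchor)
        for name, elem, xyz in place_fragment(frag, target, u,
                                              acc.azimuth_deg):
            atoms.append((chain, resname, resnum, name, elem, xyz, frag_id))
        planted_acceptors.append(target)

    for elem, direction, dist in recipe.extra_metals:
        frag_id += 1
        pos = mg_xyz + dist * _normalize(direction)
        atoms.append(("X", elem.upper(), 50 + frag_id, elem.upper(),
                      elem.upper(), pos, frag_id))

    origin = (np.asarray(recipe.carrier_origin, dtype=float)
              if recipe.carrier_origin is not None
              else mg_xyz - np.array([22.0, 22.0, 22.0]))
    frag_id += 1
    for chain, resname, resnum, name, elem, xyz in _carrier_atoms(origin):
        atoms.append((chain, resname, resnum, name, elem, xyz, frag_id))

    _check_realizable(atoms, mg_xyz, planted_inner, planted_acceptors,
                      water_positions, recipe)

    text = _write_pdb(atoms, recipe, rng, spec)
    truth = dict(recipe.truth)
    truth.setdefault("name", recipe.name)
    return text, truth


def _check_realizable(atoms, mg_xyz, planted_inner, planted_acceptors,
                      water_positions, recipe) -> None:
    planted = planted_inner + planted_acceptors
    positions = {}
    for chain, resname, resnum, name, elem, xyz, frag in atoms:
        positions.setdefault(frag, []).append((elem, np.asarray(xyz), name))
    frags = list(positions)
    # cross-fragment clash check (bonded atoms live inside one fragment)
    for i, fa in enumerate(frags):
        for fb in frags[i + 1:]:
            for ea, xa, _ in positions[fa]:
                for eb, xb, _ in positions[fb]:
                    if np.linalg.norm(xa - xb) < 1.5:
                        raise FixtureError(
                            f"{recipe.name}: clash between fragments "
                            f"{fa} and {fb}")
    # no stray O/N inside the inner-sphere search shell
    for chain, resname, resnum, name, elem, xyz, frag in atoms:
        if elem not in ("O", "N"):
            continue
        d = np.linalg.norm(np.asarray(xyz) - mg_xyz)
        if d < 3.25 and not any(np.linalg.norm(np.asarray(xyz) - p) < 0.3
                                for p in planted):
            # waters placed via an image shift are stored away from the site
            raise FixtureError(
                f"{recipe.name}: stray inner-shell atom {name} of "
                f"{resname}{resnum} at {d:.2f} A")


_HET_RESIDUES = {"HOH", "MG", "NA", "K", "SO4"}


def _write_pdb(atoms, recipe: SiteRecipe, rng, spec: FixtureSpec) -> str:
    st = gemmi.Structure()
    st.name = recipe.name
    a, b, c, al, be, ga, sg = recipe.cell
    st.cell = gemmi.UnitCell(a, b, c, al, be, ga)
    st.spacegroup_hm = sg
    model = gemmi.Model("1")
    # gemmi containers copy on add_*, so residues must be complete before
    # they go into a chain
    chain_order: list[str] = []
    per_chain: dict[str, dict[tuple, gemmi.Residue]] = {}
    for chain_id, resname, resnum, name, elem, xyz, frag in atoms:
        if chain_id not in per_chain:
            per_chain[chain_id] = {}
            chain_order.append(chain_id)
        key = (resname, resnum)
        res = per_chain[chain_id].get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if resname in _HET_RESIDUES else "A"
            per_chain[chain_id][key] = res
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(elem)
        atom.pos = gemmi.Position(*np.asarray(xyz, dtype=float))
        if resname == "MG":
            atom.occ = recipe.mg_occ
            atom.b_iso = recipe.mg_b
        else:
            atom.occ = 1.0
            if spec.b_factor_range:
                lo, hi = spec.b_factor_range
                atom.b_iso = float(np.round(rng.uniform(lo, hi), 2))
            else:
                atom.b_iso = recipe.env_b
        res.add_atom(atom)
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        for res in per_chain[chain_id].values():
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


def make_site_fixture(spec: FixtureSpec, out_dir: str | Path,
                      stem: Optional[str] = None) -> tuple[Path, dict]:
    """Write one fixture (PDB + truth JSON sidecar) into ``out_dir``."""
    import json
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    text, truth = build_fixture(spec)
    stem = stem or spec.recipe.name
    pdb_path = out_dir / f"{stem}.pdb"
    pdb_path.write_text(text)
    (out_dir / f"{stem}.truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return pdb_path, truth


# ---------------------------------------------------------------------------
# the recipe catalogue

def _waters(*dirs, distance=None) -> tuple[Ligand, ...]:
    return tuple(Ligand("water", d, distance=distance) for d in dirs)


def _truth(cls, type_name, cn, isomerism, motifs, benchmark) -> dict:
    return {"class": cls, "type": type_name, "cn": cn,
            "isomerism": isomerism,
            "motifs": ",".join(sorted(motifs)), "benchmark_pass": benchmark}


def battery_catalogue() -> list[SiteRecipe]:
    """The full fixture catalogue: every class, >= 20 site types, all 13
    motifs, CN 0-7, the three second-step chemical rules, a symmetry-mate
    contact and a partial-occupancy site."""
    A = "A"
    oph = lambda n, d, **kw: Ligand("O_ph", d, residue=(A, "G", n), **kw)
    recipes: list[SiteRecipe] = []

    def add(name, inner, acceptors=(), truth=None, **kw):
        recipes.append(SiteRecipe(name=name, inner=tuple(inner),
                                  acceptors=tuple(acceptors),
                                  truth=truth or {}, **kw))

    # --- canonical geometries -------------------------------------------
    add("hexaaqua", _waters(*OCTAHEDRON),
        truth=_truth(None, None, 6, None, [], False))
    add("cn0", [], truth=_truth(None, None, 0, None, [], False))
    add("cn1", _waters(PX), truth=_truth(None, None, 1, None, [], False))
    add("cn2", _waters(PX, MX), truth=_truth(None, None, 2, None, [], False))
    add("cn3", _waters(PX, PY, PZ),
        truth=_truth(None, None, 3, None, [], False))
    add("cn5_waters", _waters(PX, MX, PY, MY, PZ),
        truth=_truth(None, None, 5, None, [], False))
    add("cn7_bipyramid", _waters(*BIPYRAMID7),
        truth=_truth(None, None, 7, None, [], False))
    add("cn4_rna", [oph(5, PX)] + list(_waters(MX, PY, MY)),
        truth=_truth("rna_inner", "O_ph", 4, None, [], True))
    add("cn5_rna", [oph(5, PX)] + list(_waters(MX, PY, MY, PZ)),
        truth=_truth("rna_inner", "O_ph", 5, None, [], True))

    # --- inner-sphere motifs --------------------------------------------
    add("clamp_cis", [oph(5, PX), oph(20, PY)] + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "cis-2O_ph", 6, "cis", ["I:cis"], True))
    add("clamp_trans", [oph(5, PX), oph(30, MX)]
        + list(_waters(PY, MY, PZ, MZ)),
        truth=_truth("rna_inner", "trans-2O_ph", 6, "trans", ["I:trans"],
                     True))
    add("ring10_cis", [oph(8, PX), oph(9, PY)] + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "cis-2O_ph", 6, "cis", ["II:2O_ph"], True))
    add("ring10_fac3", [oph(8, PX), oph(9, PY), oph(10, PZ)]
        + list(_waters(MX, MY, MZ)),
        truth=_truth("rna_inner", "fac-3O_ph", 6, "fac",
                     ["II:3O_ph-consecutive-fac"], True))
    add("ring10_mer3", [oph(8, PX), oph(9, PY), oph(10, MX)]
        + list(_waters(MY, PZ, MZ)),
        truth=_truth("rna_inner", "mer-3O_ph", 6, "mer",
                     ["II:3O_ph-consecutive-mer"], True))
    add("ring10_adjacent_fac", [oph(8, PX), oph(9, PY), oph(11, PZ)]
        + list(_waters(MX, MY, MZ)),
        truth=_truth("rna_inner", "fac-3O_ph", 6, "fac",
                     ["II:3O_ph-adjacent-fac"], True))
    add("ring10_adjacent_mer", [oph(8, PX), oph(9, PY), oph(11, MX)]
        + list(_waters(MY, PZ, MZ)),
        truth=_truth("rna_inner", "mer-3O_ph", 6, "mer",
                     ["II:3O_ph-adjacent-mer"], True))
    add("ring10_double", [oph(8, PX), oph(9, PY), oph(30, MX), oph(31, MY)]
        + list(_waters(PZ, MZ)),
        truth=_truth("rna_inner", "trans-4O_ph", 6, "trans",
                     ["II:4O_ph-double-ring"], True))
    add("y_clamp", [oph(8, PX), oph(9, PY), oph(40, MX)]
        + list(_waters(MY, PZ, MZ)),
        truth=_truth("rna_inner", "mer-3O_ph", 6, "mer", ["A"], True))
    add("g_phosphate",
        [oph(5, PX), Ligand("O_b", PY, residue=(A, "G", 9), atom="O6")]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "O_ph•O_b", 6, None, ["III"], True))
    add("u_phosphate",
        [oph(5, PX), Ligand("O_b", PY, residue=(A, "U", 9), atom="O4")]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "O_ph•O_b", 6, None, ["B"], True))
    add("purine_n7_seat",
        [Ligand("N_b", PX, residue=(A, "G", 20), atom="N7"),
         Ligand("N_b", PY, residue=(A, "G", 21), atom="N7")]
        + list(_waters(MX, MY, PZ, MZ)),
        acceptors=[(2, Acceptor("P_out", (A, "G", 22))),
                   (3, Acceptor("P_out", (A, "G", 23))),
                   (4, Acceptor("P_out", (A, "G", 24)))],
        truth=_truth("rna_inner", "2N_b", 6, None, ["D"], True))
    add("macrochelate_inner",
        [Ligand("N_b", PX, residue=(A, "G", 7), atom="N7")]
        + list(_waters(MX, PY, MY, PZ, MZ)),
        acceptors=[(1, Acceptor("P_out", (A, "G", 7)))],
        truth=_truth("rna_inner", "N_b", 6, None, ["E"], True))
    add("ring10_purine_n7",
        [oph(8, PX), oph(9, PY),
         Ligand("N_b", PZ, residue=(A, "G", 11), atom="N7")]
        + list(_waters(MX, MY, MZ)),
        truth=_truth("rna_inner", "cis-2O_ph•N_b", 6, "cis", ["G"], True))

    # --- other inner types ----------------------------------------------
    add("oph_or", [oph(15, PX), Ligand("O_r", PY, residue=(A, "G", 6))]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "O_ph•O_r", 6, None, [], True))
    add("two_ob",
        [Ligand("O_b", PX, residue=(A, "G", 5), atom="O6"),
         Ligand("O_b", PY, residue=(A, "U", 9), atom="O4")]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "2O_b", 6, None, [], True))
    add("ob_nb",
        [Ligand("O_b", PX, residue=(A, "U", 5), atom="O4"),
         Ligand("N_b", PY, residue=(A, "G", 9), atom="N7")]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "O_b•N_b", 6, None, [], True))
    add("two_nb_no_seat",
        [Ligand("N_b", PX, residue=(A, "G", 10), atom="N7"),
         Ligand("N_b", PY, residue=(A, "A", 30), atom="N7")]
        + list(_waters(MX, MY, PZ, MZ)),
        truth=_truth("rna_inner", "2N_b", 6, None, [], True))
    add("oph_with_pout",
        [oph(5, PX)] + list(_waters(MX, PY, MY, PZ, MZ)),
        acceptors=[(2, Acceptor("P_out", (A, "G", 20)))],
        truth=_truth("rna_inner", "O_ph(+1P_out)", 6, None, [], True))

    # --- outer-sphere motifs and types ----------------------------------
    add("zipper", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("P_out", (A, "G", 5))),
                   (2, Acceptor("P_out", (A, "G", 40)))],
        truth=_truth("rna_outer", "2P_out", 6, None, ["VI"], True))
    add("ring12", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("P_out", (A, "G", 8))),
                   (2, Acceptor("P_out", (A, "G", 9)))],
        truth=_truth("rna_outer", "2P_out", 6, None, ["C"], True))
    add("gg_full", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 10), atom="O6")),
                   (2, Acceptor("B_out", (A, "G", 11), atom="O6")),
                   (4, Acceptor("P_out", (A, "G", 10))),
                   (5, Acceptor("P_out", (A, "G", 9)))],
        truth=_truth("rna_outer", "2P_out•2B_out", 6, None,
                     ["IV:2P_out•2B_out"], True))
    add("gg_bases", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 10), atom="O6")),
                   (2, Acceptor("B_out", (A, "G", 11), atom="O6"))],
        truth=_truth("rna_outer", "2B_out", 6, None, ["IV:2B_out"], True))
    add("gg_distant_p", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 10), atom="O6")),
                   (2, Acceptor("B_out", (A, "G", 11), atom="O6")),
                   (4, Acceptor("P_out", (A, "G", 30)))],
        truth=_truth("rna_outer", "P_out•2B_out", 6, None,
                     ["IV:P_out•2B_out"], True))
    add("triple_g", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 10), atom="O6")),
                   (2, Acceptor("B_out", (A, "G", 11), atom="O6")),
                   (4, Acceptor("B_out", (A, "G", 12), atom="O6"))],
        truth=_truth("rna_outer", "3B_out", 6, None, ["V"], True))
    add("macrochelate_outer", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 7), atom="N7")),
                   (2, Acceptor("P_out", (A, "G", 7)))],
        truth=_truth("rna_outer", "P_out•B_out", 6, None, ["F"], True))
    add("single_pout", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("P_out", (A, "G", 9)))],
        truth=_truth("rna_outer", "P_out", 6, None, [], True))
    add("single_bout", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("B_out", (A, "G", 9), atom="O6"))],
        truth=_truth("rna_outer", "B_out", 6, None, [], True))
    add("single_rout", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("R_out", (A, "G", 9)))],
        truth=_truth("rna_outer", "R_out", 6, None, [], True))
    add("two_pout_bout", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("P_out", (A, "G", 8))),
                   (2, Acceptor("P_out", (A, "G", 9))),
                   (4, Acceptor("B_out", (A, "G", 30), atom="O6"))],
        truth=_truth("rna_outer", "2P_out•B_out", 6, None, [], True))
    add("pout_rout", _waters(*OCTAHEDRON),
        acceptors=[(0, Acceptor("P_out", (A, "G", 8))),
                   (2, Acceptor("R_out", (A, "G", 30)))],
        truth=_truth("rna_outer", "P_out•R_out", 6, None, [], True))

    # --- the other two classes ------------------------------------------
    add("metal_nearby", [oph(5, PX), oph(20, PY)]
        + list(_waters(MX, MY, PZ, MZ)),
        extra_metals=[("NA", (1, 1, 1), 3.5)],
        truth=_truth("metal_within_4A", None, 6, "cis", [], True))
    add("non_rna_inner",
        [Ligand("other_O", PX, residue=("X", "SO4", 60))]
        + list(_waters(MX, PY, MY, PZ)),
        acceptors=[(1, Acceptor("P_out", (A, "G", 9)))],
        truth=_truth("non_rna_inner", None, 5, None, [], True))

    # --- second-step chemical rules -------------------------------------
    add("step2_accept", [oph(5, MZ, distance=2.9)]
        + list(_waters(PX, MX, PY, MY, PZ)),
        truth=_truth("rna_inner", "O_ph", 6, None, [], True))
    add("step2_bidentate",
        [Ligand("bidentate", MZ, residue=(A, "G", 5))]
        + list(_waters(PX, MX, PY, MY, PZ)),
        truth=_truth("rna_inner", "O_ph", 6, None, [], True))
    add("step2_amino_reject",
        [Ligand("N_b", MZ, residue=(A, "C", 5), atom="N4", distance=3.0)]
        + list(_waters(PX, MX, PY, MY, PZ)),
        truth=_truth(None, None, 5, None, [], False))
    add("step2_lone_pair_accept",
        [Ligand("N_b", MZ, residue=(A, "G", 5), atom="N7", distance=3.0)]
        + list(_waters(PX, MX, PY, MY, PZ)),
        truth=_truth("rna_inner", "N_b", 6, None, [], True))
    add("step2_angle_reject",
        [oph(5, (math.sin(math.radians(45)), 0.0, math.cos(math.radians(45))),
             distance=2.9)]
        + list(_waters(PX, MX, PY, MY, PZ)),
        truth=_truth(None, None, 5, None, [], False))

    # --- quality failures ------------------------------------------------
    add("fail_qv", [oph(5, PX, distance=2.5)]
        + list(_waters(MX, PY, MY, PZ, MZ, distance=2.5)),
        truth=_truth("rna_inner", "O_ph", 6, None, [], False))
    add("fail_qs", [oph(5, PX)]
        + list(_waters(PY, PZ, (1, 1, 1))),
        truth=_truth("rna_inner", "O_ph", 4, None, [], False))
    add("fail_qe", [oph(5, PX)] + list(_waters(MX, PY, MY, PZ, MZ)),
        mg_b=60.0,
        truth=_truth("rna_inner", "O_ph", 6, None, [], False))

    # --- crystallographic edge cases -------------------------------------
    add("partial_occupancy", [oph(5, PX)] + list(_waters(MX, PY, MY, PZ, MZ)),
        mg_b=16.0, mg_occ=0.8,
        truth=_truth("rna_inner", "O_ph", 6, None, [], True))
    add("symmetry_water",
        list(_waters(PX, PY, MY, PZ, MZ))
        + [Ligand("water", MX, image_shift=(1, 0, 0))],
        cell=(24.0, 24.0, 24.0, 90.0, 90.0, 90.0, "P 1"),
        mg_frac=(1.0 / 24.0, 0.5, 0.5),
        carrier_origin=(3.0, 1.0, 1.0),
        truth=_truth(None, None, 6, None, [], False))

    return recipes


def make_battery(n: int, seed: int, out_dir: str | Path,
                 distance_sigma: float = 0.0,
                 ) -> tuple[list[Path], pd.DataFrame]:
    """Write ``n`` fixtures (cycling the catalogue) plus a truth table.

    The same seed reproduces the same files byte for byte.  With zero
    ``distance_sigma`` the planted truth labels are exact; with jitter
    they describe the intended (pre-noise) site.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalogue = battery_catalogue()
    paths: list[Path] = []
    rows = []
    for i in range(n):
        recipe = catalogue[i % len(catalogue)]
        spec = FixtureSpec(recipe=recipe, seed=(seed + i) % (2 ** 31),
                           distance_sigma=distance_sigma)
        stem = f"fixture_{i:03d}_{recipe.name}"
        path, truth = make_site_fixture(spec, out_dir, stem=stem)
        paths.append(path)
        rows.append({"fixture": i, "file": path.name, **truth})
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths, truth_df
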