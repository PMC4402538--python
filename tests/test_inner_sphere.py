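"""Ligand typing, the two-step inner-sphere search and isomer labels."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mgrna.inner_sphere import (InnerSphere, LigandClass, LigandContact,
                                classify_atom, find_inner_sphere,
                                geometric_isomerism, is_lone_pair_nitrogen,
                                phosphate_group_key)
from mgrna.structure import Contact

from conftest import make_model


@pytest.mark.parametrize("resname,atom,element,expected", [
    ("G", "OP2", "O", LigandClass.O_PH),
    ("A", "OP1", "O", LigandClass.O_PH),
    ("U", "O4", "O", LigandClass.O_B),
    ("G", "O6", "O", LigandClass.O_B),
    ("C", "O2", "O", LigandClass.O_B),
    ("G", "O2'", "O", LigandClass.O_R),
    ("A", "O4'", "O", LigandClass.O_R),
    ("C", "O3'", "O", LigandClass.O_R),
    ("U", "O5'", "O", LigandClass.O_R),
    ("A", "N6", "N", LigandClass.N_B),
    ("A", "N7", "N", LigandClass.N_B),
    ("C", "N3", "N", LigandClass.N_B),
    ("HOH", "O", "O", LigandClass.WATER_O),
    ("SO4", "O1", "O", LigandClass.OTHER_O),
    ("LYS", "NZ", "N", LigandClass.OTHER_N),
])
def test_classify_atom(resname, atom, element, expected):
    model = make_model([(element, atom, resname, 1, "A", (0, 0, 0))])
    assert classify_atom(model.atoms[0]) is expected


def test_lone_pair_nitrogens():
    """Only the six in-plane endocyclic nitrogens can coordinate; the
    exocyclic amino nitrogens (A-N6, C-N4, G-N2) cannot."""
    lone = {("A", "N1"), ("A", "N3"), ("A", "N7"), ("G", "N3"), ("G", "N7"),
            ("C", "N3")}
    amino = {("A", "N6"), ("C", "N4"), ("G", "N2"), ("G", "N1"), ("U", "N3")}
    for res, name in lone | amino:
        model = make_model([("N", name, res, 1, "A", (0, 0, 0))])
        assert is_lone_pair_nitrogen(model.atoms[0]) == ((res, name) in lone)


class TestTwoStepSearch:
    """Planted fixtures exercising each acceptance rule."""

    def test_hexaaqua_all_step1(self, site_by_recipe):
        site = site_by_recipe("hexaaqua")
        assert site.inner.cn == 6
        assert all(l.step == 1 for l in site.inner.ligands)

    def test_step2_completes_octahedron(self, site_by_recipe):
        site = site_by_recipe("step2_accept")
        assert site.inner.cn == 6
        steps = sorted(l.step for l in site.inner.ligands)
        assert steps == [1] * 5 + [2]
        oph = site.inner.ligands_of_class(LigandClass.O_PH)[0]
        assert oph.step == 2 and oph.distance == pytest.approx(2.9, abs=0.01)

    def test_bidentate_phosphate_rejected(self, site_by_recipe):
        """Only the nearer of OP1/OP2 from one phosphate is accepted."""
        site = site_by_recipe("step2_bidentate")
        oph = site.inner.ligands_of_class(LigandClass.O_PH)
        assert len(oph) == 1 and oph[0].atom.atom_name == "OP1"
        assert site.inner.cn == 6

    def test_amino_nitrogen_rejected(self, site_by_recipe):
        site = site_by_recipe("step2_amino_reject")
        assert site.inner.cn == 5
        assert not site.inner.ligands_of_class(LigandClass.N_B)

    def test_lone_pair_nitrogen_accepted(self, site_by_recipe):
        site = site_by_recipe("step2_lone_pair_accept")
        assert site.inner.cn == 6
        nb = site.inner.ligands_of_class(LigandClass.N_B)[0]
        assert nb.atom.atom_name == "N7" and nb.step == 2

    def test_acute_angle_rejected(self, site_by_recipe):
        site = site_by_recipe("step2_angle_reject")
        assert site.inner.cn == 5
        assert not site.inner.ligands_of_class(LigandClass.O_PH)

    def test_cn_above_six_flagged_not_truncated(self, site_by_recipe):
        site = site_by_recipe("cn7_bipyramid")
        assert site.inner.cn == 7
        assert site.inner.cn_flagged


def _random_site_model(rng):
    """A randomized distorted site: O/N candidates at 1.9-3.3 A in random
    directions, including phosphate pairs sharing one P atom."""
    atoms = [("MG", "MG", "MG", 1, "M", (0.0, 0.0, 0.0))]
    resnum = 2
    n_candidates = int(rng.integers(3, 9))
    for _ in range(n_candidates):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        d = float(rng.uniform(1.9, 3.3))
        kind = rng.integers(0, 4)
        pos = d * u
        if kind == 0:  # water
            atoms.append(("O", "O", "HOH", resnum, "W", pos))
        elif kind == 1:  # phosphate pair sharing a P (rule i applies)
            perp = np.cross(u, [0.12, 0.97, 0.21])
            perp /= np.linalg.norm(perp)
            u2 = math.cos(math.radians(55)) * u + \
                math.sin(math.radians(55)) * perp
            p = 0.75 * (pos + (d + 0.15) * u2)
            atoms.append(("O", "OP1", "G", resnum, "A", pos))
            atoms.append(("O", "OP2", "G", resnum, "A", (d + 0.15) * u2))
            atoms.append(("P", "P", "G", resnum, "A", p))
        elif kind == 2:  # nucleobase nitrogen, sometimes not -N=
            name = rng.choice(["N7", "N6", "N1", "N3"])
            base = rng.choice(["A", "G", "C", "U"])
            atoms.append(("N", str(name), str(base), resnum, "A", pos))
        else:  # base oxygen
            atoms.append(("O", "O6", "G", resnum, "A", pos))
        resnum += 1
    return make_model(atoms)


def exhaustive_oracle(model, mg):
    """Independent oracle: enumerate every subset of second-step candidates
    and keep the unique subset that is consistent with the three chemical
    rules applied in ascending-distance order.  Returns accepted atom
    indices (step 1 and step 2)."""
    cand = []
    for atom in model.atoms:
        if atom.element not in ("O", "N"):
            continue
        d = float(np.linalg.norm(atom.xyz - mg.xyz))
        d0 = 2.20 if atom.element == "N" else 2.08
        if d <= d0 + 1.0 and d > 1e-6:
            cand.append((d, atom))
    cand.sort(key=lambda da: (da[0], da[1].chain_id, da[1].residue_number,
                              da[1].atom_name))
    step1 = [a for d, a in cand
             if d <= (2.20 if a.element == "N" else 2.08) + 0.5]
    step2 = [(d, a) for d, a in cand
             if d > (2.20 if a.element == "N" else 2.08) + 0.5]
    if len(step1) >= 6:
        return {a.index for a in step1}

    def group(atom):
        if atom.element != "O":
            return None
        best, best_d = None, 1.9
        for other in model.atoms:
            if other.element == "P":
                dd = float(np.linalg.norm(other.xyz - atom.xyz))
                if dd <= best_d:
                    best, best_d = other, dd
        if best is None:
            return None
        return (best.chain_id, best.residue_number)

    def angle_ok(a, accepted):
        ua = a.xyz / np.linalg.norm(a.xyz)
        for b in accepted:
            ub = b.xyz / np.linalg.norm(b.xyz)
            ang = math.degrees(math.acos(np.clip(ua @ ub, -1, 1)))
            if ang <= 50.0:
                return False
        return True

    def rules_ok(a, accepted):
        g = group(a)
        if g is not None and any(group(b) == g for b in accepted
                                 if b.element == "O"):
            return False
        if classify_atom(a) is LigandClass.N_B and \
                not is_lone_pair_nitrogen(a):
            return False
        return angle_ok(a, accepted)

    admissible = []
    for bits in itertools.product((0, 1), repeat=len(step2)):
        accepted = list(step1)
        valid = True
        for (d, a), take in zip(step2, bits):
            ok = rules_ok(a, accepted)
            if take and not ok:
                valid = False
                break
            if not take and ok:
                valid = False
                break
            if take:
                accepted.append(a)
        if valid:
            admissible.append({a.index for a in accepted})
    assert len(admissible) == 1, "greedy fixed point must be unique"
    return admissible[0]


def test_two_step_search_matches_exhaustive_oracle():
    """Accepted ligand sets equal the subset-enumeration oracle on
    randomized distorted fixtures (<= 10 candidates each)."""
    rng = np.random.default_rng(777)
    checked = 0
    for _ in range(120):
        model = _random_site_model(rng)
        mg = model.atoms[0]
        inner = find_inner_sphere(model, mg, use_symmetry=False)
        got = {l.atom.index for l in inner.ligands}
        want = exhaustive_oracle(model, mg)
        assert got == want
        checked += 1
    assert checked == 120


def test_input_order_invariance():
    """The accepted ligand list does not depend on atom ordering."""
    rng = np.random.default_rng(4242)
    for _ in range(20):
        model = _random_site_model(rng)
        mg_spec = [(a.element, a.atom_name, a.residue_name, a.residue_number,
                    a.chain_id, tuple(a.xyz)) for a in model.atoms]
        ids1 = [(l.atom.chain_id, l.atom.residue_number, l.atom.atom_name)
                for l in find_inner_sphere(model, model.atoms[0],
                                           use_symmetry=False).ligands]
        perm = [mg_spec[0]] + [mg_spec[i] for i in
                               rng.permutation(range(1, len(mg_spec)))]
        model2 = make_model(perm)
        ids2 = [(l.atom.chain_id, l.atom.residue_number, l.atom.atom_name)
                for l in find_inner_sphere(model2, model2.atoms[0],
                                           use_symmetry=False).ligands]
        assert ids1 == ids2


def _inner_from_unit_vectors(vectors, cls=LigandClass.O_PH):
    model = make_model(
        [("MG", "MG", "MG", 1, "M", (0, 0, 0))]
        + [("O", "OP1", "G", i + 2, "A", 2.08 * np.asarray(v, dtype=float))
           for i, v in enumerate(vectors)])
    inner = find_inner_sphere(model, model.atoms[0], use_symmetry=False)
    assert all(l.ligand_class is cls for l in inner.ligands)
    return inner


S2 = math.sqrt(2) / 2


class TestIsomerism:
    @pytest.mark.parametrize("vectors,label", [
        (((1, 0, 0), (0, 1, 0)), "cis"),
        (((1, 0, 0), (-1, 0, 0)), "trans"),
        (((1, 0, 0), (0, 1, 0), (0, 0, 1)), "fac"),
        (((1, 0, 0), (-1, 0, 0), (0, 1, 0)), "mer"),
        (((1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)), "trans"),
        (((1, 0, 0), (0, 1, 0), (0, 0, 1), (S2, S2, 0)), "cis"),
    ])
    def test_labels(self, vectors, label):
        assert _inner_from_unit_vectors(vectors).isomerism == label

    def test_absent_outside_2_to_4(self):
        assert _inner_from_unit_vectors(((1, 0, 0),)).isomerism is None
        inner = _inner_from_unit_vectors(
            ((1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0), (0, -1, 0)))
        assert inner.isomerism is None

    def test_135_degree_boundary(self):
        """The trans label needs an angle strictly above 135 degrees."""
        a134 = math.radians(134)
        a136 = math.radians(136)
        below = _inner_from_unit_vectors(
            ((1, 0, 0), (math.cos(a134), math.sin(a134), 0)))
        above = _inner_from_unit_vectors(
            ((1, 0, 0), (math.cos(a136), math.sin(a136), 0)))
        assert below.isomerism == "cis"
        assert above.isomerism == "trans"


def test_non_mg_center_rejected():
    model = make_model([("O", "O", "HOH", 1, "W", (0, 0, 0))])
    with pytest.raises(ValueError):
        find_inner_sphere(model, model.atoms[0])
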