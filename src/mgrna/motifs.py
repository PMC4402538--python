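"""Mg2+-binding motif queries over classified sites.

Thirteen motif definitions: six literature-derived (I-VI: magnesium clamp,
10-member ring family, G-phosphate, G•G, triple-G, metal-ion zipper) and
seven discovered through site-type census work (A-G: Y-clamp, U-phosphate,
12-member ring, purine-N7 seat, two G-N7 macrochelates, 10-member ring
with purine-N7).  Each definition is a pure predicate over one site;
overlapping hits are all reported.

Sequence conventions: "distant" means different chains (or symmetry
frames) or separation greater than seven residues; "consecutive" means
residues i and i+1 of the same chain; "downstream" means higher in the
sequence of the same chain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Optional, TYPE_CHECKING

from .classification import SiteClass
from .inner_sphere import LigandClass

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import MgSite

DISTANT_SEPARATION = 7  # residues; beyond this phosphates count as distant

_PURINES = ("A", "G")


def _frame(key: tuple) -> tuple:
    return key[:3]  # (sym op, lattice shift, chain)


def _num(key: tuple) -> int:
    return key[3]


def same_frame(k1: tuple, k2: tuple) -> bool:
    return _frame(k1) == _frame(k2)


def distant(k1: tuple, k2: tuple) -> bool:
    """Different chains/frames, or more than seven residues apart."""
    if not same_frame(k1, k2):
        return True
    return abs(_num(k1) - _num(k2)) > DISTANT_SEPARATION


def consecutive(k1: tuple, k2: tuple) -> bool:
    return same_frame(k1, k2) and abs(_num(k1) - _num(k2)) == 1


def separated_by_one(k1: tuple, k2: tuple) -> bool:
    return same_frame(k1, k2) and abs(_num(k1) - _num(k2)) == 2


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    name: str
    structure_id: str
    mg_id: str
    residues: tuple[tuple, ...]
    variant: Optional[str] = None


@dataclass(frozen=True)
class MotifDefinition:
    id: str
    name: str
    site_class: SiteClass
    predicate: Callable[["MgSite"], list[tuple[tuple, ...] | tuple]]
    # predicate returns a list of (residues, variant) hits


def _hit(residues: Iterable[tuple], variant: Optional[str] = None):
    return (tuple(sorted(residues)), variant)


# --- inner-sphere feature helpers -----------------------------------------

def _oph_residues(site: "MgSite") -> list[tuple]:
    return [l.residue_key for l in
            site.inner.ligands_of_class(LigandClass.O_PH)]


def _nb_ligands(site: "MgSite"):
    return site.inner.ligands_of_class(LigandClass.N_B)


def _ob_ligands(site: "MgSite"):
    return site.inner.ligands_of_class(LigandClass.O_B)


def _inner_counts(site: "MgSite") -> tuple[int, int, int, int]:
    return site.inner.class_counts()


def _pout(site: "MgSite"):
    return [m for m in site.moieties if m.kind == "P_out"]


def _bout(site: "MgSite"):
    return [m for m in site.moieties if m.kind == "B_out"]


def _outer_counts(site: "MgSite") -> tuple[int, int, int]:
    kinds = [m.kind for m in site.moieties]
    return (kinds.count("P_out"), kinds.count("R_out"), kinds.count("B_out"))


def _consecutive_run(keys: list[tuple]) -> bool:
    """True when the residues form a single run i, i+1, ..., i+len-1 in the
    same chain/frame."""
    if len({_frame(k) for k in keys}) != 1:
        return False
    nums = sorted(_num(k) for k in keys)
    return all(b - a == 1 for a, b in zip(nums, nums[1:]))


# --- motif predicates ------------------------------------------------------

def _magnesium_clamp(site: "MgSite"):
    if _inner_counts(site) != (2, 0, 0, 0):
        return []
    r1, r2 = _oph_residues(site)
    if not distant(r1, r2):
        return []
    return [_hit([r1, r2], variant=site.inner.isomerism)]


def _ten_member_ring(site: "MgSite"):
    counts = _inner_counts(site)
    hits = []
    if counts == (2, 0, 0, 0):
        r1, r2 = _oph_residues(site)
        if consecutive(r1, r2):
            hits.append(_hit([r1, r2], variant="2O_ph"))
    elif counts == (3, 0, 0, 0):
        keys = _oph_residues(site)
        iso = site.inner.isomerism
        if _consecutive_run(keys):
            hits.append(_hit(keys, variant=f"3O_ph-consecutive-{iso}"))
        else:
            for pair in combinations(keys, 2):
                if not consecutive(*pair):
                    continue
                (extra,) = [k for k in keys if k not in pair]
                if any(separated_by_one(extra, k) for k in pair):
                    hits.append(_hit(keys, variant=f"3O_ph-adjacent-{iso}"))
                    break
    elif counts == (4, 0, 0, 0):
        keys = _oph_residues(site)
        for (a, b), (c, d) in (((0, 1), (2, 3)), ((0, 2), (1, 3)),
                               ((0, 3), (1, 2))):
            p1 = (keys[a], keys[b])
            p2 = (keys[c], keys[d])
            if consecutive(*p1) and consecutive(*p2):
                hits.append(_hit(keys, variant="4O_ph-double-ring"))
                break
    return hits


def _g_phosphate(site: "MgSite"):
    if _inner_counts(site) != (1, 0, 1, 0):
        return []
    ob = _ob_ligands(site)[0]
    if ob.atom.residue_name != "G":
        return []
    return [_hit([_oph_residues(site)[0], ob.residue_key])]


def _u_phosphate(site: "MgSite"):
    if _inner_counts(site) != (1, 0, 1, 0):
        return []
    ob = _ob_ligands(site)[0]
    if ob.atom.residue_name != "U":
        return []
    return [_hit([_oph_residues(site)[0], ob.residue_key])]


def _gg_site(site: "MgSite"):
    counts = _outer_counts(site)
    gs = [m for m in _bout(site) if m.residue_name == "G"]
    cons_gs = None
    for pair in combinations(gs, 2):
        if consecutive(pair[0].residue_key, pair[1].residue_key):
            cons_gs = pair
            break
    if cons_gs is None:
        return []
    g_keys = [m.residue_key for m in cons_gs]
    hits = []
    if counts == (2, 0, 2):
        # phosphates of residues n and n-1, n = lower guanine in sequence
        n = min(_num(k) for k in g_keys)
        frame = _frame(g_keys[0])
        want = {(n,), (n - 1,)}
        have = {( _num(m.residue_key),) for m in _pout(site)
                if _frame(m.residue_key) == frame}
        if have == want:
            hits.append(_hit(g_keys + [m.residue_key for m in _pout(site)],
                             variant="2P_out•2B_out"))
    elif counts == (0, 0, 2):
        hits.append(_hit(g_keys, variant="2B_out"))
    elif counts == (1, 0, 2):
        p = _pout(site)[0]
        if all(distant(p.residue_key, k) for k in g_keys):
            hits.append(_hit(g_keys + [p.residue_key],
                             variant="P_out•2B_out"))
    return hits


def _triple_g(site: "MgSite"):
    if _outer_counts(site) != (0, 0, 3):
        return []
    gs = [m for m in _bout(site) if m.residue_name == "G"]
    if len(gs) != 3:
        return []
    keys = [m.residue_key for m in gs]
    if not _consecutive_run(keys):
        return []
    return [_hit(keys)]


def _metal_ion_zipper(site: "MgSite"):
    if _outer_counts(site) != (2, 0, 0):
        return []
    k1, k2 = [m.residue_key for m in _pout(site)]
    if not distant(k1, k2):
        return []
    return [_hit([k1, k2])]


def _y_clamp(site: "MgSite"):
    if _inner_counts(site) != (3, 0, 0, 0) or site.inner.isomerism != "mer":
        return []
    keys = _oph_residues(site)
    for pair in combinations(keys, 2):
        if not consecutive(*pair):
            continue
        (extra,) = [k for k in keys if k not in pair]
        if all(distant(extra, k) for k in pair):
            return [_hit(keys)]
    return []


def _twelve_member_ring(site: "MgSite"):
    if _outer_counts(site) != (2, 0, 0):
        return []
    k1, k2 = [m.residue_key for m in _pout(site)]
    if not consecutive(k1, k2):
        return []
    return [_hit([k1, k2])]


def _purine_n7_seat(site: "MgSite"):
    if _inner_counts(site) != (0, 0, 0, 2):
        return []
    nbs = _nb_ligands(site)
    if not all(l.atom.atom_name == "N7" and l.atom.residue_name in _PURINES
               for l in nbs):
        return []
    pouts = _pout(site)
    if len(pouts) not in (3, 4):
        return []
    purine_keys = [l.residue_key for l in nbs]
    for m in pouts:
        if not any(same_frame(m.residue_key, pk)
                   and _num(m.residue_key) > _num(pk)
                   for pk in purine_keys):
            return []
    return [_hit(purine_keys + [m.residue_key for m in pouts])]


def _macrochelate_inner(site: "MgSite"):
    if _inner_counts(site) != (0, 0, 0, 1):
        return []
    nb = _nb_ligands(site)[0]
    if nb.atom.residue_name != "G" or nb.atom.atom_name != "N7":
        return []
    for m in _pout(site):
        if m.residue_key == nb.residue_key:
            return [_hit([nb.residue_key])]
    return []


def _macrochelate_outer(site: "MgSite"):
    if _outer_counts(site) != (1, 0, 1):
        return []
    b = _bout(site)[0]
    if b.residue_name != "G" or "N7" not in b.bond_atom_names():
        return []
    p = _pout(site)[0]
    if p.residue_key != b.residue_key:
        return []
    return [_hit([b.residue_key])]


def _ring_with_purine_n7(site: "MgSite"):
    if _inner_counts(site) != (2, 0, 0, 1):
        return []
    r1, r2 = _oph_residues(site)
    if not consecutive(r1, r2):
        return []
    nb = _nb_ligands(site)[0]
    if nb.atom.atom_name != "N7" or nb.atom.residue_name not in _PURINES:
        return []
    if not (separated_by_one(nb.residue_key, r1)
            or separated_by_one(nb.residue_key, r2)):
        return []
    return [_hit([r1, r2, nb.residue_key])]


DEFAULT_MOTIFS: list[MotifDefinition] = [
    MotifDefinition("I", "magnesium clamp", SiteClass.RNA_INNER,
                    _magnesium_clamp),
    MotifDefinition("II", "10-member ring", SiteClass.RNA_INNER,
                    _ten_member_ring),
    MotifDefinition("III", "G-phosphate", SiteClass.RNA_INNER, _g_phosphate),
    MotifDefinition("IV", "G•G metal-binding site", SiteClass.RNA_OUTER,
                    _gg_site),
    MotifDefinition("V", "triple-G", SiteClass.RNA_OUTER, _triple_g),
    MotifDefinition("VI", "metal-ion zipper", SiteClass.RNA_OUTER,
                    _metal_ion_zipper),
    MotifDefinition("A", "Y-clamp", SiteClass.RNA_INNER, _y_clamp),
    MotifDefinition("B", "U-phosphate", SiteClass.RNA_INNER, _u_phosphate),
    MotifDefinition("C", "12-member ring", SiteClass.RNA_OUTER,
                    _twelve_member_ring),
    MotifDefinition("D", "purine-N7 seat", SiteClass.RNA_INNER,
                    _purine_n7_seat),
    MotifDefinition("E", "G-N7 macrochelate I", SiteClass.RNA_INNER,
                    _macrochelate_inner),
    MotifDefinition("F", "G-N7 macrochelate II", SiteClass.RNA_OUTER,
                    _macrochelate_outer),
    MotifDefinition("G", "10-member ring with purine-N7",
                    SiteClass.RNA_INNER, _ring_with_purine_n7),
]


def detect_motifs(site: "MgSite",
                  definitions: list[MotifDefinition] = DEFAULT_MOTIFS,
                  ) -> list[MotifHit]:
    """Evaluate all motif definitions against one classified site."""
    hits: list[MotifHit] = []
    for d in definitions:
        if site.site_class is not d.site_class:
            continue
        for residues, variant in d.predicate(site):
            hits.append(MotifHit(motif_id=d.id, name=d.name,
                                 structure_id=site.structure_id,
                                 mg_id=site.mg_id,
                                 residues=residues, variant=variant))
    return hits


def motif_census(sites: Iterable["MgSite"]) -> Counter:
    """Per-motif (and per-variant) hit counts over a set of sites."""
    counts: Counter = Counter()
    for site in sites:
        for hit in site.motif_hits:
            counts[(hit.motif_id, hit.variant)] += 1
    return counts
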