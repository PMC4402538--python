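"""Hierarchical classification of Mg2+ sites.

Each validated site falls into one of four mutually exclusive classes
(checked in precedence order): another metal within 4 A, a non-RNA ligand
in the inner sphere, RNA-inner (at least one RNA inner-sphere ligand) or
RNA-outer (water-only inner sphere with RNA in the outer sphere).  Sites
with only water in both spheres are not RNA-bound and stay unclassified.

RNA-inner and RNA-outer sites additionally get a canonical type name, e.g.
``cis-2O_ph``, ``O_ph•O_b``, ``2P_out•2B_out``, which round-trips through
:func:`parse_type_name`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

from .inner_sphere import InnerSphere, LigandClass, RNA_LIGAND_CLASSES
from .outer_sphere import OuterMoiety, moiety_counts
from .structure import AtomRecord, StructureModel, neighbor_search


class SiteClass(str, enum.Enum):
    METAL_WITHIN_4A = "metal_within_4A"
    NON_RNA_INNER = "non_rna_inner"
    RNA_INNER = "rna_inner"
    RNA_OUTER = "rna_outer"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


def assign_class(model: StructureModel, inner: InnerSphere,
                 moieties: list[OuterMoiety],
                 metal_radius: float = 4.0,
                 use_symmetry: bool = True) -> Optional[SiteClass]:
    """First matching rule wins; None means 'not RNA-bound'."""
    for c in neighbor_search(model, inner.mg, metal_radius,
                             use_symmetry=use_symmetry):
        if model.atoms[c.target_index].is_metal:
            return SiteClass.METAL_WITHIN_4A
    non_rna = any(l.ligand_class in (LigandClass.OTHER_O, LigandClass.OTHER_N,
                                     LigandClass.OTHER)
                  for l in inner.ligands)
    if non_rna:
        return SiteClass.NON_RNA_INNER
    if any(l.ligand_class in RNA_LIGAND_CLASSES for l in inner.ligands):
        return SiteClass.RNA_INNER
    if moieties:  # water-only inner sphere, RNA in the outer sphere
        return SiteClass.RNA_OUTER
    return None


_ISOMERS = ("cis", "trans", "fac", "mer")
_INNER_TOKENS = ("O_ph", "O_r", "O_b", "N_b")
_OUTER_TOKENS = ("P_out", "R_out", "B_out")


@dataclass(frozen=True)
class SiteType:
    """Canonical site type: token counts plus an optional isomer prefix.

    ``kind`` is "inner" (counts = #O_ph, #O_r, #O_b, #N_b, with
    ``outer_phosphates`` subdividing the lone-O_ph branch) or "outer"
    (counts = #P_out, #R_out, #B_out).
    """

    kind: str
    counts: tuple[int, ...]
    isomer: Optional[str] = None
    outer_phosphates: Optional[int] = None

    @property
    def name(self) -> str:
        tokens = _INNER_TOKENS if self.kind == "inner" else _OUTER_TOKENS
        parts = [f"{n if n > 1 else ''}{t}"
                 for n, t in zip(self.counts, tokens) if n > 0]
        if not parts:
            raise ValueError("empty site type")
        name = "•".join(parts)
        if self.isomer:
            name = f"{self.isomer}-{name}"
        if self.outer_phosphates:
            name += f"(+{self.outer_phosphates}P_out)"
        return name

    def __str__(self) -> str:  # pragma: no cover
        return self.name


def type_rna_inner(inner: InnerSphere, moieties: list[OuterMoiety],
                   ) -> SiteType:
    """Type an RNA-inner site from its inner-sphere composition.

    The isomer prefix applies when two or more phosphate oxygens
    coordinate; the most populous branch (a single O_ph and nothing else)
    is subdivided by the number of outer-sphere phosphate moieties.
    """
    counts = inner.class_counts()
    if sum(counts) == 0:
        raise ValueError("site has no RNA inner-sphere ligand; not RNA-inner")
    n_oph, others = counts[0], sum(counts[1:])
    isomer = inner.isomerism if n_oph >= 2 else None
    outer_p = None
    if n_oph == 1 and others == 0:
        p_out = moiety_counts(moieties)[0]
        outer_p = p_out if p_out > 0 else None
    return SiteType(kind="inner", counts=counts, isomer=isomer,
                    outer_phosphates=outer_p)


def type_rna_outer(moieties: list[OuterMoiety]) -> SiteType:
    """Type an RNA-outer site from its outer-sphere moiety counts."""
    counts = moiety_counts(moieties)
    if sum(counts) == 0:
        raise ValueError("site has no outer-sphere moiety; not RNA-outer")
    return SiteType(kind="outer", counts=counts)


_TOKEN_RE = re.compile(r"^(\d*)(O_ph|O_r|O_b|N_b|P_out|R_out|B_out)$")
_NAME_RE = re.compile(
    r"^(?:(cis|trans|fac|mer)-)?"
    r"(?P<body>[^()]+?)"
    r"(?:\(\+(?P<pout>\d+)P_out\))?$")


def parse_type_name(name: str) -> SiteType:
    """Inverse of the typing operations; raises ValueError on malformed
    names.  Round-trips: ``parse_type_name(t.name) == t``."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"malformed site type name: {name!r}")
    isomer = m.group(1)
    body = m.group("body")
    seen: dict[str, int] = {}
    for raw in body.split("•"):
        tm = _TOKEN_RE.match(raw)
        if not tm:
            raise ValueError(f"malformed token {raw!r} in {name!r}")
        mult = int(tm.group(1)) if tm.group(1) else 1
        token = tm.group(2)
        if mult < 1 or token in seen:
            raise ValueError(f"invalid multiplicity/duplicate in {name!r}")
        seen[token] = mult
    inner = [t for t in seen if t in _INNER_TOKENS]
    outer = [t for t in seen if t in _OUTER_TOKENS]
    if inner and outer:
        raise ValueError(f"mixed inner/outer tokens in {name!r}")
    if outer:
        if isomer or m.group("pout"):
            raise ValueError(f"outer type cannot carry prefix/suffix: {name!r}")
        counts = tuple(seen.get(t, 0) for t in _OUTER_TOKENS)
        return SiteType(kind="outer", counts=counts)
    counts = tuple(seen.get(t, 0) for t in _INNER_TOKENS)
    if isomer and counts[0] < 2:
        raise ValueError(f"isomer prefix needs >= 2 O_ph: {name!r}")
    pout = m.group("pout")
    if pout is not None and (counts[0] != 1 or sum(counts[1:]) != 0):
        raise ValueError(f"(+nP_out) suffix only valid for lone O_ph: {name!r}")
    return SiteType(kind="inner", counts=counts, isomer=isomer,
                    outer_phosphates=int(pout) if pout else None)
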