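"""Dataset-level statistics: normalized interaction frequencies (F_atom)
and summary distributions (CN by resolution, class/type census, per-site
composition).

F_atom(X) = p(Mg-X) / p(X): the share of Mg-X interactions among all
coordinating interactions in the benchmark set, normalized by the share of
type-X atoms among all ligand-capable atoms in the full dataset.  Values
above 1 mark atoms that coordinate Mg2+ more often than their abundance
alone would predict.  Because both numerator and denominator are shares,
F_atom is unchanged when every structure is duplicated.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, TYPE_CHECKING

import numpy as np
import pandas as pd

from .inner_sphere import LigandClass, classify_atom, RNA_LIGAND_CLASSES
from .structure import StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import MgSite

#: default resolution bin edges (A) for CN histograms
DEFAULT_RESOLUTION_BINS = (1.5, 2.0, 2.4, 2.9, 3.7, 4.5)


def _atom_identity(residue_name: str, atom_name: str) -> str:
    return f"{residue_name}-{atom_name}"


def background_census(models: Iterable[StructureModel],
                      scope: str = "ligand_capable") -> Counter:
    """Count atoms per identity (e.g. ``G-O6``) over the full dataset.

    ``scope`` selects the denominator convention: "ligand_capable"
    restricts to O_ph/O_r/O_b/N_b identities (the default), while
    "all_rna_atoms" counts every atom in common-ribonucleotide residues.
    """
    if scope not in ("ligand_capable", "all_rna_atoms"):
        raise ValueError(f"unknown background scope {scope!r}")
    census: Counter = Counter()
    for model in models:
        for atom in model.atoms:
            if not atom.is_rna:
                continue
            if scope == "ligand_capable":
                if classify_atom(atom) not in RNA_LIGAND_CLASSES:
                    continue
            census[_atom_identity(atom.residue_name, atom.atom_name)] += 1
    return census


def interaction_census(sites: Iterable["MgSite"], sphere: str) -> Counter:
    """Count Mg-RNA interactions per atom identity.

    ``sphere="inner"`` counts coordination bonds (non-water RNA ligands);
    ``sphere="outer"`` counts one interaction per (water, RNA atom)
    hydrogen bond.
    """
    if sphere not in ("inner", "outer"):
        raise ValueError(f"sphere must be 'inner' or 'outer', got {sphere!r}")
    counts: Counter = Counter()
    for site in sites:
        if sphere == "inner":
            for lig in site.inner.ligands:
                if lig.ligand_class in RNA_LIGAND_CLASSES:
                    counts[_atom_identity(lig.atom.residue_name,
                                          lig.atom.atom_name)] += 1
        else:
            for bond in site.hbonds:
                counts[_atom_identity(bond.rna_atom.residue_name,
                                      bond.rna_atom.atom_name)] += 1
    return counts


def f_atom(benchmark_sites: Iterable["MgSite"],
           background: Counter,
           sphere: str = "inner") -> pd.DataFrame:
    """Normalized interaction frequency table.

    Returns a DataFrame indexed by atom identity with columns ``N``
    (interaction count) and ``F_atom``; identities observed with zero
    background abundance are flagged with ``F_atom = inf``.
    """
    interactions = interaction_census(benchmark_sites, sphere)
    total_int = sum(interactions.values())
    total_bg = sum(background.values())
    rows = []
    identities = sorted(set(interactions) | set(background))
    for ident in identities:
        n = interactions.get(ident, 0)
        p_mg = n / total_int if total_int else 0.0
        bg = background.get(ident, 0)
        p_x = bg / total_bg if total_bg else 0.0
        if p_x == 0.0:
            f = math.inf if n > 0 else 0.0
        else:
            f = p_mg / p_x
        rows.append({"identity": ident, "N": n, "F_atom": f})
    return pd.DataFrame(rows).set_index("identity")


@dataclass
class DatasetSummary:
    n_sites: int
    class_census: Counter = field(default_factory=Counter)
    type_census: Counter = field(default_factory=Counter)
    cn_by_resolution: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame())
    inner_rna_ligand_distribution: Counter = field(default_factory=Counter)
    outer_moiety_distribution: Counter = field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "class_census": {str(k): v for k, v in self.class_census.items()},
            "type_census": dict(self.type_census),
            "cn_by_resolution": self.cn_by_resolution.to_dict(),
            "inner_rna_ligand_distribution":
                {str(k): v for k, v in
                 self.inner_rna_ligand_distribution.items()},
            "outer_moiety_distribution":
                {str(k): v for k, v in self.outer_moiety_distribution.items()},
        }


def summarize(sites: list["MgSite"],
              resolutions: Optional[dict[str, float]] = None,
              bins: tuple[float, ...] = DEFAULT_RESOLUTION_BINS,
              ) -> DatasetSummary:
    """Dataset summary: CN histogram per resolution bin, class/type census
    and per-site composition distributions.  Empty input yields an empty
    summary."""
    summary = DatasetSummary(n_sites=len(sites))
    if not sites:
        return summary
    resolutions = resolutions or {}
    records = []
    for site in sites:
        summary.class_census[site.site_class.value
                             if site.site_class else "unclassified"] += 1
        if site.site_type is not None:
            summary.type_census[site.site_type.name] += 1
        n_inner_rna = sum(1 for l in site.inner.ligands
                          if l.ligand_class in RNA_LIGAND_CLASSES)
        summary.inner_rna_ligand_distribution[n_inner_rna] += 1
        summary.outer_moiety_distribution[len(site.moieties)] += 1
        records.append({"cn": site.inner.cn,
                        "resolution": resolutions.get(site.structure_id,
                                                      np.nan)})
    df = pd.DataFrame(records)
    labels = [f"({lo}, {hi}]" for lo, hi in zip(bins, bins[1:])]
    df["bin"] = pd.cut(df["resolution"], bins=list(bins), labels=labels)
    hist = (df.groupby(["bin", "cn"], observed=False).size()
            .unstack(fill_value=0))
    summary.cn_by_resolution = hist
    return summary
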