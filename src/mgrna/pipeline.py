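"""End-to-end pipeline: structure -> per-Mg site reports -> summaries.

Stages per site: inner-sphere search -> quality scores -> outer-sphere
hydrogen bonds and moieties -> class and type -> motif screening ->
benchmark filter.  Per-structure failures are isolated and reported; a
batch never aborts because one file is broken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .classification import (SiteClass, SiteType, assign_class,
                             type_rna_inner, type_rna_outer)
from .config import RunConfig
from .inner_sphere import InnerSphere, find_inner_sphere
from .motifs import DEFAULT_MOTIFS, MotifHit, detect_motifs
from .outer_sphere import (HydrogenBond, OuterMoiety, assign_moieties,
                           find_water_rna_hbonds)
from .quality import QualityScores, benchmark_filter, score_site
from .stats import DatasetSummary, summarize
from .structure import AtomRecord, StructureModel, read_structure

logger = logging.getLogger(__name__)


@dataclass
class MgSite:
    """Everything the pipeline knows about one magnesium site."""

    structure_id: str
    mg: AtomRecord
    inner: InnerSphere
    scores: QualityScores
    hbonds: list[HydrogenBond] = field(default_factory=list)
    moieties: list[OuterMoiety] = field(default_factory=list)
    site_class: Optional[SiteClass] = None
    site_type: Optional[SiteType] = None
    motif_hits: list[MotifHit] = field(default_factory=list)
    benchmark_pass: bool = False
    benchmark_reasons: list[str] = field(default_factory=list)
    config_hash: str = ""

    @property
    def mg_id(self) -> str:
        return f"{self.mg.chain_id}{self.mg.residue_number}"

    def to_dict(self) -> dict:
        return {
            "structure": self.structure_id,
            "mg": self.mg_id,
            "cn": self.inner.cn,
            "cn_flagged": self.inner.cn_flagged,
            "isomerism": self.inner.isomerism,
            "ligands": [
                {"atom": l.atom.atom_name, "residue": l.atom.residue_name,
                 "chain": l.atom.chain_id, "number": l.atom.residue_number,
                 "class": l.ligand_class.value,
                 "distance": round(l.distance, 3), "step": l.step,
                 "valence": (round(l.valence, 4)
                             if l.valence is not None else None),
                 "via_symmetry": not l.contact.is_identity}
                for l in self.inner.ligands],
            "q_v": round(self.scores.q_v, 3),
            "q_s": round(self.scores.q_s, 3),
            "q_e": round(self.scores.q_e, 3),
            "valence_sum": round(self.scores.valence_sum, 4),
            "b_mg": self.scores.b_mg, "b_env": round(self.scores.b_env, 2),
            "occ_mg": self.scores.occ_mg,
            "occ_env": round(self.scores.occ_env, 3),
            "moieties": [
                {"kind": m.kind, "residue": m.residue_name,
                 "chain": m.residue_key[2], "number": m.residue_key[3],
                 "n_bonds": len(m.bonds),
                 "atoms": sorted(m.bond_atom_names())}
                for m in self.moieties],
            "class": self.site_class.value if self.site_class else None,
            "type": self.site_type.name if self.site_type else None,
            "motifs": [
                {"id": h.motif_id, "name": h.name, "variant": h.variant}
                for h in self.motif_hits],
            "benchmark_pass": self.benchmark_pass,
            "benchmark_reasons": self.benchmark_reasons,
            "config": self.config_hash,
        }


def process_site(model: StructureModel, mg: AtomRecord,
                 config: RunConfig = RunConfig()) -> MgSite:
    """Run the full per-site analysis for one magnesium ion."""
    bv = config.bond_valence()
    inner = find_inner_sphere(
        model, mg, d_ideal_o=config.d_ideal_o, d_ideal_n=config.d_ideal_n,
        step1_margin=config.step1_margin, step2_margin=config.step2_margin,
        min_angle_deg=config.min_angle_deg, use_symmetry=config.use_symmetry)
    scores = score_site(model, inner, bv, env_radius=config.env_radius,
                        use_symmetry=config.use_symmetry)
    hbonds = find_water_rna_hbonds(
        model, inner, hb_min=config.hb_min, hb_max=config.hb_max,
        min_angle_deg=config.hb_angle_min_deg,
        use_symmetry=config.use_symmetry)
    moieties = assign_moieties(model, inner, hbonds)
    site = MgSite(structure_id=model.identifier, mg=mg, inner=inner,
                  scores=scores, hbonds=hbonds, moieties=moieties,
                  config_hash=config.hash)
    site.site_class = assign_class(model, inner, moieties,
                                   metal_radius=config.metal_radius,
                                   use_symmetry=config.use_symmetry)
    if site.site_class is SiteClass.RNA_INNER:
        site.site_type = type_rna_inner(inner, moieties)
    elif site.site_class is SiteClass.RNA_OUTER:
        site.site_type = type_rna_outer(moieties)
    if site.site_type is not None:
        site.motif_hits = detect_motifs(site, DEFAULT_MOTIFS)
    site.benchmark_pass, site.benchmark_reasons = benchmark_filter(
        site, config.thresholds())
    return site


def process_model(model: StructureModel,
                  config: RunConfig = RunConfig()) -> list[MgSite]:
    return [process_site(model, mg, config)
            for mg in model.magnesium_atoms()]


@dataclass
class PipelineResult:
    sites: list[MgSite]
    summary: DatasetSummary
    failures: list[tuple[str, str]]   # (path, error)

    @property
    def benchmark_sites(self) -> list[MgSite]:
        return [s for s in self.sites if s.benchmark_pass]

    @property
    def exit_code(self) -> int:
        if self.failures and not self.sites:
            return 2
        return 1 if self.failures else 0

    def to_dict(self) -> dict:
        return {
            "sites": [s.to_dict() for s in self.sites],
            "summary": self.summary.to_dict(),
            "failures": [{"path": p, "error": e} for p, e in self.failures],
        }


def run_pipeline(paths: Sequence[str | Path],
                 config: RunConfig = RunConfig()) -> PipelineResult:
    """Process a batch of structure files; failures never abort the run."""
    sites: list[MgSite] = []
    failures: list[tuple[str, str]] = []
    resolutions: dict[str, float] = {}
    for path in paths:
        try:
            model = read_structure(path)
            model_sites = process_model(model, config)
        except Exception as exc:  # noqa: BLE001 - per-structure isolation
            logger.error("failed on %s: %s", path, exc)
            failures.append((str(path), str(exc)))
            continue
        if model.resolution is not None:
            resolutions[model.identifier] = model.resolution
        sites.extend(model_sites)
        logger.info("%s: %d Mg sites", model.identifier, len(model_sites))
    summary = summarize(sites, resolutions, bins=config.resolution_bins)
    return PipelineResult(sites=sites, summary=summary, failures=failures)
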