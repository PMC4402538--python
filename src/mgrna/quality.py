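"""Site-quality parameters Q_v, Q_s, Q_e and the benchmark filter.

Q_v checks the bond-valence sum against the +2 oxidation state of Mg,
Q_s the symmetry of the ligand arrangement via the vector sum of the
bond-valence vectors, and Q_e the agreement of the ion's B-factor and
occupancy with its 4 A environment.  All three live in [0, 1] with 1 best.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import numpy as np

from .inner_sphere import InnerSphere, LigandClass, is_lone_pair_nitrogen
from .structure import AtomRecord, StructureModel, neighbor_search

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import MgSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BondValenceModel:
    """Exponential bond-valence relation V(d) = exp((r0 - d) / b).

    Default r0 values are the standard Mg-O and Mg-N bond-valence
    parameters (1.693 and 1.85 A) with the universal softness b = 0.37 A.
    V is strictly decreasing in d.
    """

    r0_mg_o: float = 1.693
    r0_mg_n: float = 1.85
    b: float = 0.37

    def valence(self, distance: float, element: str = "O") -> float:
        if distance <= 0:
            raise ValueError("distance must be positive")
        r0 = self.r0_mg_n if element == "N" else self.r0_mg_o
        return math.exp((r0 - distance) / self.b)


@dataclass
class QualityScores:
    q_v: float
    q_s: float
    q_e: float
    valence_sum: float
    b_mg: float
    occ_mg: float
    b_env: float
    occ_env: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q_v, self.q_s, self.q_e)


def _fill_valences(inner: InnerSphere, bv: BondValenceModel) -> np.ndarray:
    vals = np.array([bv.valence(l.distance, l.atom.element)
                     for l in inner.ligands])
    for lig, v in zip(inner.ligands, vals):
        lig.valence = float(v)
    return vals


def q_v(inner: InnerSphere, bv: BondValenceModel = BondValenceModel()) -> float:
    """Valence-agreement score: 1 - |sum(V_i) - 2| / 2, clamped to [0, 1]."""
    if inner.cn == 0:
        return 0.0
    s = float(_fill_valences(inner, bv).sum())
    return float(np.clip(1.0 - abs(s - 2.0) / 2.0, 0.0, 1.0))


def q_s(inner: InnerSphere, bv: BondValenceModel = BondValenceModel()) -> float:
    """Symmetry score: 1 - |sum(V_i * u_i)| / sum(V_i).

    1.0 for a perfectly symmetric ligand arrangement (the valence vectors
    cancel), 0.0 for a single ligand.
    """
    if inner.cn == 0:
        return 0.0
    vals = _fill_valences(inner, bv)
    vecs = np.vstack([l.unit_vector for l in inner.ligands])
    vsum = vals @ vecs
    return float(np.clip(1.0 - np.linalg.norm(vsum) / vals.sum(), 0.0, 1.0))


def q_e(model: StructureModel, mg: AtomRecord,
        bv: BondValenceModel = BondValenceModel(),
        env_radius: float = 4.0, use_symmetry: bool = True,
        ) -> tuple[float, float, float]:
    """Environment score from B-factors and occupancies within 4 A.

    Environmental B_e and O_e are valence-weighted means over all
    non-hydrogen atoms within ``env_radius`` (symmetry mates included),
    with weights from the bond-valence relation at each neighbor's
    distance.  With full occupancies Q_e = min(B_m, B_e) / max(B_m, B_e);
    with partial occupancy Q_e = min(O_m, O_e) * min(r, 1/r) where
    r = (B_m / O_m) / (B_e / O_e).

    Returns (q_e, b_env, occ_env).
    """
    contacts = neighbor_search(model, mg, env_radius, use_symmetry=use_symmetry)
    if not contacts:
        logger.warning("empty %.1f A environment around %r", env_radius, mg)
        return 0.0, 0.0, 0.0
    weights, bs, occs = [], [], []
    for c in contacts:
        atom = model.atoms[c.target_index]
        weights.append(bv.valence(c.distance, atom.element))
        bs.append(atom.b_factor)
        occs.append(atom.occupancy)
    w = np.array(weights)
    b_e = float(w @ np.array(bs) / w.sum())
    o_e = float(w @ np.array(occs) / w.sum())
    b_m, o_m = mg.b_factor, mg.occupancy

    def ratio(x: float, y: float) -> float:
        hi = max(x, y)
        return 1.0 if hi <= 0 else min(x, y) / hi

    if o_m >= 1.0 - 1e-9 and o_e >= 1.0 - 1e-9:
        score = ratio(b_m, b_e)
    else:
        if o_m <= 0 or o_e <= 0:
            score = 0.0
        else:
            score = min(o_m, o_e) * ratio(b_m / o_m, b_e / o_e)
    return float(np.clip(score, 0.0, 1.0)), b_e, o_e


def score_site(model: StructureModel, inner: InnerSphere,
               bv: BondValenceModel = BondValenceModel(),
               env_radius: float = 4.0,
               use_symmetry: bool = True) -> QualityScores:
    """Compute all three validation parameters for one site."""
    vals = _fill_valences(inner, bv) if inner.cn else np.zeros(0)
    qe, b_env, occ_env = q_e(model, inner.mg, bv, env_radius, use_symmetry)
    return QualityScores(
        q_v=q_v(inner, bv),
        q_s=q_s(inner, bv),
        q_e=qe,
        valence_sum=float(vals.sum()),
        b_mg=inner.mg.b_factor,
        occ_mg=inner.mg.occupancy,
        b_env=b_env,
        occ_env=occ_env,
    )


@dataclass(frozen=True)
class BenchmarkThresholds:
    qv_min: float = 0.5
    qs_min: float = 0.6
    qe_min: float = 0.5
    cn_min: int = 4
    cn_max: int = 6


def benchmark_filter(site: "MgSite",
                     thresholds: BenchmarkThresholds = BenchmarkThresholds(),
                     ) -> tuple[bool, list[str]]:
    """Benchmark-dataset filter; returns (accepted, failed criteria).

    Accepts a site iff it is (i) RNA-bound through the inner or outer
    sphere, (ii) CN in [cn_min, cn_max], (iii) all three quality scores at
    or above threshold, and (iv) free of inner-sphere nucleobase nitrogens
    that are not -N=.
    """
    reasons: list[str] = []
    inner = site.inner
    rna_inner = any(l.ligand_class in
                    (LigandClass.O_PH, LigandClass.O_R,
                     LigandClass.O_B, LigandClass.N_B)
                    for l in inner.ligands)
    if not rna_inner and not site.moieties:
        reasons.append("not RNA-bound (no inner RNA ligand, no outer moiety)")
    if not thresholds.cn_min <= inner.cn <= thresholds.cn_max:
        reasons.append(f"CN={inner.cn} outside "
                       f"[{thresholds.cn_min}, {thresholds.cn_max}]")
    scores = site.scores
    if scores.q_v < thresholds.qv_min:
        reasons.append(f"Q_v={scores.q_v:.3f} < {thresholds.qv_min}")
    if scores.q_s < thresholds.qs_min:
        reasons.append(f"Q_s={scores.q_s:.3f} < {thresholds.qs_min}")
    if scores.q_e < thresholds.qe_min:
        reasons.append(f"Q_e={scores.q_e:.3f} < {thresholds.qe_min}")
    for lig in inner.ligands:
        if (lig.ligand_class is LigandClass.N_B
                and not is_lone_pair_nitrogen(lig.atom)):
            reasons.append(f"inner-sphere non -N= base nitrogen {lig.atom!r}")
            break
    return (not reasons, reasons)
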