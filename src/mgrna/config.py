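"""Run configuration: every tunable constant of the pipeline in one place.

Defaults follow the published procedure: ideal Mg-O / Mg-N bond lengths of
2.08 / 2.20 A with +0.5 / +1.0 A search margins, a 50 deg minimum
ligand-Mg-ligand angle for second-step acceptance, a 135 deg threshold for
trans/mer isomer assignment, a [2.4, 3.5] A / 90 deg hydrogen-bond window,
a 4 A environment radius, and benchmark thresholds Q_v >= 0.5, Q_s >= 0.6,
Q_e >= 0.5 with CN 4-6.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .quality import BenchmarkThresholds, BondValenceModel
from .stats import DEFAULT_RESOLUTION_BINS


@dataclass
class RunConfig:
    # inner-sphere search
    d_ideal_o: float = 2.08
    d_ideal_n: float = 2.20
    step1_margin: float = 0.5
    step2_margin: float = 1.0
    min_angle_deg: float = 50.0
    trans_angle_deg: float = 135.0
    # hydrogen bonds / outer sphere
    hb_min: float = 2.4
    hb_max: float = 3.5
    hb_angle_min_deg: float = 90.0
    # environment / classification
    env_radius: float = 4.0
    metal_radius: float = 4.0
    # bond valence
    bv_r0_o: float = 1.693
    bv_r0_n: float = 1.85
    bv_b: float = 0.37
    # benchmark thresholds
    qv_min: float = 0.5
    qs_min: float = 0.6
    qe_min: float = 0.5
    cn_min: int = 4
    cn_max: int = 6
    # dataset selection
    linkage_max: float = 2.0
    min_linked_nucleotides: int = 3
    ribosome_keywords: tuple[str, ...] = ("ribosom",)
    # statistics
    resolution_bins: tuple[float, ...] = DEFAULT_RESOLUTION_BINS
    background_scope: str = "ligand_capable"
    # misc
    use_symmetry: bool = True
    seed: int = 0

    def bond_valence(self) -> BondValenceModel:
        return BondValenceModel(r0_mg_o=self.bv_r0_o, r0_mg_n=self.bv_r0_n,
                                b=self.bv_b)

    def thresholds(self) -> BenchmarkThresholds:
        return BenchmarkThresholds(qv_min=self.qv_min, qs_min=self.qs_min,
                                   qe_min=self.qe_min, cn_min=self.cn_min,
                                   cn_max=self.cn_max)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ribosome_keywords"] = list(self.ribosome_keywords)
        d["resolution_bins"] = list(self.resolution_bins)
        return d

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("ribosome_keywords", "resolution_bins"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @property
    def hash(self) -> str:
        """Short digest embedded in every report for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
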