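"""Shared fixtures: a session-scoped planted battery plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mgrna.config import RunConfig
from mgrna.fixtures import FixtureSpec, battery_catalogue, make_site_fixture
from mgrna.pipeline import run_pipeline
from mgrna.structure import AtomRecord, StructureModel, UnitCell

BATTERY_N = 100
BATTERY_SEED = 1


@pytest.fixture(scope="session")
def catalogue():
    return {r.name: r for r in battery_catalogue()}


@pytest.fixture(scope="session")
def battery(tmp_path_factory):
    """100 zero-noise fixtures + truth table + processed pipeline result."""
    from mgrna.fixtures import make_battery
    out = tmp_path_factory.mktemp("battery")
    paths, truth = make_battery(BATTERY_N, seed=BATTERY_SEED, out_dir=out)
    result = run_pipeline(paths, RunConfig())
    assert not result.failures
    assert len(result.sites) == BATTERY_N
    return paths, truth, result


@pytest.fixture(scope="session")
def site_by_recipe(tmp_path_factory, catalogue):
    """Process one instance of a named recipe on demand (cached)."""
    from mgrna.pipeline import process_model
    from mgrna.structure import read_structure
    out = tmp_path_factory.mktemp("single")
    cache: dict[str, object] = {}

    def get(name: str, seed: int = 7):
        key = f"{name}_{seed}"
        if key not in cache:
            path, _ = make_site_fixture(
                FixtureSpec(recipe=catalogue[name], seed=seed), out, stem=key)
            cache[key] = process_model(read_structure(path))[0]
        return cache[key]

    return get


def make_model(atoms_spec, cell=None, identifier="synthetic"):
    """Build an in-memory StructureModel from terse atom tuples:
    (element, name, resname, resnum, chain, xyz[, b, occ])."""
    atoms = []
    for i, spec in enumerate(atoms_spec):
        element, name, resname, resnum, chain, xyz = spec[:6]
        b = spec[6] if len(spec) > 6 else 20.0
        occ = spec[7] if len(spec) > 7 else 1.0
        atoms.append(AtomRecord(
            index=i, element=element, atom_name=name, residue_name=resname,
            residue_number=resnum, insertion_code="", chain_id=chain,
            alt_loc="", xyz=np.asarray(xyz, dtype=float), b_factor=b,
            occupancy=occ,
            is_water=resname in ("HOH", "WAT"),
            is_metal=element.upper() in ("MG", "NA", "K", "ZN", "MN", "CA"),
        ))
    return StructureModel(atoms, cell, resolution=None, identifier=identifier)


@pytest.fixture()
def simple_model():
    return make_model
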