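"""Shared fixtures: deterministic synthetic structures and ensembles."""

import numpy as np
import pytest

from metalswitch import (ConformationEnsemble, GeneratorConfig, gen_center,
                         gen_ensemble)
from metalswitch.structio import AtomRecord, StructureModel


def make_atom(serial, name, resname, resnum, pos, chain="A", het=False,
              element=None, occupancy=1.0, altloc=""):
    if element is None:
        element = name if name in ("ZN", "CA", "NA", "MG") \
            else name[0]
    return AtomRecord(serial=serial, atom_name=name, element=element,
                      residue_name=resname, residue_number=resnum,
                      insertion_code="", chain_id=chain,
                      position=np.asarray(pos, dtype=float),
                      occupancy=occupancy, b_factor=0.0, is_het=het,
                      altloc=altloc)


@pytest.fixture(scope="session")
def base_cfg():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def clean_center(base_cfg):
    return gen_center(base_cfg, state="Ca2")


@pytest.fixture(scope="session")
def state_centers(base_cfg):
    return {lab: gen_center(base_cfg, state=lab)
            for lab in ("Ca0", "Ca1", "Ca2")}


@pytest.fixture(scope="session")
def state_ensembles():
    """500-frame ensembles for the three calcium regimes."""
    out = {}
    for seed, lab in ((21, "Ca0"), (22, "Ca1"), (23, "Ca2")):
        cfg = GeneratorConfig(seed=seed, state_label=lab)
        out[lab] = gen_ensemble(cfg, n_frames=500)
    return out


@pytest.fixture()
def tiny_static_ensemble(clean_center):
    coords = np.stack([clean_center.coords()] * 4)
    return ConformationEnsemble(clean_center.copy(), coords,
                                state_label="other")


__all__ = ["make_atom", "StructureModel"]
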