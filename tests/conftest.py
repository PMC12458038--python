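"""Shared fixtures: geometries and one moderately long simulated trace.

The session-scoped trace (a single pore-sized species at mean occupancy
N = 2 in the confocal volume) is reused by the correlator and amplitude
tests, since it is the most expensive fixture to build.
"""

import numpy as np
import pytest

import fccs_kin as fk

SEED = 20240901


@pytest.fixture(scope="session")
def geometry():
    """Ideal-overlap geometry (w_xy = 0.25 um, s = 5)."""
    return fk.ConfocalGeometry(w_xy=0.25e-6, w_z=1.25e-6, f_ov=1.0)


@pytest.fixture(scope="session")
def overlap_geometry():
    """Partial-overlap geometry, f_ov = 0.6 (the measured ceiling)."""
    return fk.ConfocalGeometry(w_xy=0.25e-6, w_z=1.25e-6, f_ov=0.6)


def single_species_system(geometry, n_eff, D=1.1e-11, q=3e4):
    """One green-labeled species at mean occupancy ``n_eff`` in V_eff."""
    c = n_eff / (fk.AVOGADRO * fk.effective_volume(geometry))
    sp = fk.FluorSpecies("L", D, c, q_green=q)
    dark = fk.FluorSpecies("NP", D, 0.0)
    dark2 = fk.FluorSpecies("NP.L", D, 0.0)
    return fk.BindingSystem(dark, sp, dark2, geometry)


@pytest.fixture(scope="session")
def n2_trace(geometry):
    """30 s trace of a single diffusing species at N = 2 (green channel)."""
    system = single_species_system(geometry, 2.0)
    return fk.simulate_traces(system, 30.0, 2e-4, seed=SEED)


@pytest.fixture(scope="session")
def n2_system(geometry):
    return single_species_system(geometry, 2.0)
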