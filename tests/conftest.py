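"""Shared fixtures: cached forward models and the desk-scale coupled runs.

The coupled transient runs are expensive (tens of seconds each), so each
study configuration is simulated once per session and shared by every test
that interrogates it.  Desk-scale discretization: refinement level 1 with a
0.5 s time step (the package's documented sweep resolution).
"""

from __future__ import annotations

import numpy as np
import pytest

from rfadope.geometry import phantom_geometry, tissue_geometry
from rfadope.inverse import PhantomForwardModel
from rfadope.mesh import generate_mesh
from rfadope.properties import AUNP_COLLOID, LIVER_TISSUE, doped_tissue_props
from rfadope.thermal import ProtocolSpec, run_protocol

DESK_REFINEMENT = 1
DESK_DT = 0.5


@pytest.fixture(scope="session")
def phantom_model():
    return PhantomForwardModel(refinement=3)


@pytest.fixture(scope="session")
def tissue_meshes():
    """Level-3 meshes of the tissue domain for each doped-zone size."""
    return {
        d: generate_mesh(tissue_geometry(d), 3) for d in (0.0, 0.02, 0.03, 0.04)
    }


def _run(zone_m, doped, volts, max_duration=900.0):
    return run_protocol(
        tissue_geometry(zone_m),
        doped,
        ProtocolSpec(v_applied=volts, time_step=DESK_DT, max_duration=max_duration),
        refinement=DESK_REFINEMENT,
    )


@pytest.fixture(scope="session")
def run_nd_50v():
    return _run(0.0, None, 50.0)


@pytest.fixture(scope="session")
def run_nd_57v_2cm():
    return _run(0.02, None, 57.0)


@pytest.fixture(scope="session")
def run_nd_90v():
    return _run(0.0, None, 90.0)


@pytest.fixture(scope="session")
def aunp10_props():
    return doped_tissue_props(LIVER_TISSUE, AUNP_COLLOID, 0.10)


@pytest.fixture(scope="session")
def run_aunp10_50v(aunp10_props):
    return _run(0.02, aunp10_props, 50.0)


@pytest.fixture(scope="session")
def run_aunp10_90v(aunp10_props):
    return _run(0.02, aunp10_props, 90.0)
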