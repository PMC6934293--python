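"""Shared fixtures.

The heavy protocol fixture runs the full packaging → advancement →
deployment pipeline for the 9-rotation ensemble once per session on the
reduced synthetic sidewall case (5 mm sac, 3 mm vessel, 5 mm × 20 mm coil at
h = 0.5 mm elements); several tests assert different properties of the same
runs.
"""

import warnings

import numpy as np
import pytest

np.seterr(over="ignore", invalid="ignore")
warnings.filterwarnings("ignore", category=RuntimeWarning)

from coildeploy.coil_mechanics import bare_platinum_coil
from coildeploy.deployment import DeploymentSession
from coildeploy.vascular_geometry import make_synthetic_aneurysm


@pytest.fixture(scope="session")
def axium_coil():
    """Bare platinum 5 mm x 2 cm coil (the reduced protocol coil)."""
    return bare_platinum_coil(5.0, 2.0)


@pytest.fixture(scope="session")
def sidewall_case():
    return make_synthetic_aneurysm(5.0, 3.0, vessel_length=21.0)


@pytest.fixture(scope="session")
def terminal_case():
    return make_synthetic_aneurysm(5.0, 3.0, kind="terminal", vessel_length=21.0)


@pytest.fixture(scope="session")
def protocol_ensemble(sidewall_case, axium_coil):
    """Nine full deployments at 40-degree rotation increments.

    Returns a dict with per-rotation deployment results plus detailed
    packaging diagnostics captured for rotation 0.
    """
    results = []
    packaging_audit = None
    for theta in range(0, 360, 40):
        session = DeploymentSession(sidewall_case, axium_coil, element_length=0.5)
        state = session.package(rotation_deg=theta)
        if theta == 0:
            tube = session._tube(funnel=False)
            _, _, dist = tube.project(state.x)
            gap, scale = state.energy_gap(session.ledger_baseline)
            arc = float(np.sum(np.linalg.norm(np.diff(state.x, axis=0), axis=1)))
            packaging_audit = {
                "radial_distances": dist,
                "inner_radius": session.catheter.inner_radius,
                "coil_radius": session.model.coil_radius,
                "energy_gap": gap,
                "energy_scale": scale,
                "ledger": dict(state.ledger),
                "arc_length": arc,
                "rest_length": session.preshape.length,
                "strain": state.ledger["strain"],
            }
        state = session.advance(state)
        session._rotation = theta
        _, cfg = session.deploy(state)
        results.append(cfg)
    return {
        "case": sidewall_case,
        "coil": axium_coil,
        "results": results,
        "packaging": packaging_audit,
    }
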