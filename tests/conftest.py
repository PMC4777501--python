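"""Shared fixtures: the surrogate implant, posed cases, ICP settings.

Everything is generated programmatically; heavyweight objects are
session-scoped so the suite builds each of them once.
"""

import numpy as np
import pytest

from oipf import (
    ICPParams,
    Perturbations,
    SurrogateParams,
    generate_surrogate,
    make_case,
    specimen_pose,
)


@pytest.fixture(scope="session")
def surrogate():
    """Default surrogate implant mesh + its intrinsic frame."""
    return generate_surrogate(SurrogateParams())


@pytest.fixture(scope="session")
def implant_mesh(surrogate):
    return surrogate[0]


@pytest.fixture(scope="session")
def implant_frame(surrogate):
    return surrogate[1]


@pytest.fixture(scope="session")
def tight_icp():
    """ICP settings used throughout the suite: 3000 source points and a
    tight convergence tolerance give sub-0.01 deg / 0.01 mm recovery on
    clean fixtures at a few seconds per registration."""
    return ICPParams(n_samples=3000, max_iterations=500, rms_rel_tolerance=1e-8)


@pytest.fixture(scope="session")
def specimen2_case(surrogate):
    mesh, frame = surrogate
    return make_case(mesh, frame, specimen_pose("specimen2"), seed=11)


@pytest.fixture(scope="session")
def bent_case(surrogate):
    """10-degree hinge bend on the lateral extension, no other perturbation."""
    mesh, frame = surrogate
    return make_case(
        mesh,
        frame,
        specimen_pose("specimen3"),
        Perturbations(bend_angle_deg=10.0),
        seed=21,
    )


def pose_error(pose, truth):
    """(max angle error deg, max translation error mm) between two poses."""
    da = np.abs(
        np.array([pose.roll, pose.pitch, pose.yaw])
        - np.array([truth.roll, truth.pitch, truth.yaw])
    ).max()
    dt = np.abs(pose.translation - truth.translation).max()
    return float(da), float(dt)
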