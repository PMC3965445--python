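"""Shared fixtures: phantoms, forward fields and encoded series.

Everything is generated at test time; session scope avoids repeating the
sparse forward solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from mremouse import (
    AcquisitionProtocol,
    ROIMask,
    ViscoelasticPhantom,
    build_phantom,
    encode_phase,
    polynomial_static_phase,
    solve_forward,
)

# control hippocampal complex modulus (Pa) used as ground truth throughout
G_HIPPO = 4608.0 + 1388.0j
G_PARENCHYMA = 5234.0 + 1447.0j
DENSITY = 1000.0


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def homog_phantom() -> ViscoelasticPhantom:
    return build_phantom(128, 0.025, G_HIPPO, G_HIPPO, DENSITY)


@pytest.fixture(scope="session")
def two_region_phantom() -> ViscoelasticPhantom:
    return build_phantom(128, 0.025, G_PARENCHYMA, G_HIPPO, DENSITY)


@pytest.fixture(scope="session")
def roi_mask(homog_phantom) -> ROIMask:
    return ROIMask.from_phantom(homog_phantom)


@pytest.fixture(scope="session")
def homog_field_left(homog_phantom, protocol):
    return solve_forward(homog_phantom, protocol, "left", 10e-6)


@pytest.fixture(scope="session")
def homog_field_all(homog_phantom, protocol):
    return solve_forward(homog_phantom, protocol, "all", 10e-6)


@pytest.fixture(scope="session")
def encoded_pair(homog_field_left, protocol):
    static = polynomial_static_phase(protocol.matrix)
    pos = encode_phase(homog_field_left, protocol, +1, static, 0.0)
    neg = encode_phase(homog_field_left, protocol, -1, static, 0.0)
    return pos, neg


@pytest.fixture(scope="session")
def full_grid_phantom_factory():
    """Homogeneous phantom filling the whole grid (no background)."""

    def make(matrix: int, fov: float, gstar: complex) -> ViscoelasticPhantom:
        return ViscoelasticPhantom(
            gstar_map=np.full((matrix, matrix), complex(gstar)),
            density=DENSITY,
            region_labels=np.ones((matrix, matrix), dtype=int),
            pixel_spacing=fov / matrix,
        )

    return make
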