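"""Motion encoding: harmonic displacement to wrapped MR phase images.

For dynamic d (of n uniformly spaced offsets over one vibration period) and
MSG polarity s = +/-1, the acquired phase is

    phase_d = wrap( s * xi * Re[u * exp(-2*pi*i*d/n)] + static + noise )

where xi is the protocol's encoding efficiency (rad per meter of
displacement). The static background phase (shim/susceptibility) is modeled
as a caller-supplied field, by default a low-order 2D polynomial, so that
the downstream phase-difference step has something real to cancel.
"""

from __future__ import annotations

import numpy as np

from .fields import ComplexWaveField, PhaseImageSeries, wrap
from .protocol import AcquisitionProtocol

__all__ = ["encode_phase", "polynomial_static_phase"]


def polynomial_static_phase(
    matrix: int, coefficients: np.ndarray | list | None = None
) -> np.ndarray:
    """Low-order 2D polynomial background phase on normalized coordinates.

    ``coefficients[p, q]`` multiplies ``x^q * y^p`` with x, y in [-1, 1].
    Default is a gentle tilted-plus-curved field typical of shim offsets.
    """
    if coefficients is None:
        coefficients = [[0.4, 1.1, -0.6], [0.9, -0.3, 0.0], [0.5, 0.0, 0.0]]
    coefficients = np.asarray(coefficients, dtype=float)
    x = np.linspace(-1.0, 1.0, matrix)
    y = np.linspace(-1.0, 1.0, matrix)
    X, Y = np.meshgrid(x, y)
    out = np.zeros((matrix, matrix))
    for p in range(coefficients.shape[0]):
        for q in range(coefficients.shape[1]):
            c = coefficients[p, q]
            if c != 0.0:
                out += c * X**q * Y**p
    return out


def encode_phase(
    field: ComplexWaveField,
    protocol: AcquisitionProtocol,
    msg_sign: int,
    static_phase: np.ndarray | float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    wrap_output: bool = True,
) -> PhaseImageSeries:
    """Encode a harmonic displacement field into a phase-image series.

    Noise is additive Gaussian (sd in radians) applied before wrapping;
    ``noise_sd = 0`` is exactly deterministic. ``wrap_output=False`` skips
    wrapping (used by identity-chain tests).
    """
    if msg_sign not in (-1, 1):
        raise ValueError(f"msg_sign must be +1 or -1, got {msg_sign}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd > 0 and seed is None:
        raise ValueError("seed is required when noise_sd > 0")

    n = protocol.n_dynamics
    xi = protocol.encoding_efficiency
    u = field.u
    static = np.broadcast_to(np.asarray(static_phase, dtype=float), u.shape)

    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    stack = np.empty((n, *u.shape), dtype=float)
    for d in range(n):
        encoded = msg_sign * xi * (u * np.exp(-2j * np.pi * d / n)).real
        img = encoded + static
        if rng is not None:
            img = img + rng.normal(0.0, noise_sd, size=u.shape)
        stack[d] = wrap(img) if wrap_output else img

    return PhaseImageSeries(
        phase=stack,
        protocol=protocol,
        msg_sign=msg_sign,
        wrapped=wrap_output,
    )
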