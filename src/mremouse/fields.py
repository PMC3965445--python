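"""Field containers shared across the simulation and reconstruction stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = ["ComplexWaveField", "PhaseImageSeries", "wrap"]

TWO_PI = 2.0 * np.pi


def wrap(phase: np.ndarray | float, period: float = TWO_PI) -> np.ndarray:
    """Wrap phase values into ``[-period/2, period/2)``.

    Idempotent: ``wrap(wrap(x)) == wrap(x)``.
    """
    half = period / 2.0
    return (np.asarray(phase) + half) % period - half


@dataclass
class ComplexWaveField:
    """Complex-valued harmonic displacement field at the drive frequency.

    ``u[i, j]`` is the complex through-plane displacement amplitude in meters
    at row ``i``, column ``j`` (0-based, pixel-center convention, x along
    columns).
    """

    u: np.ndarray
    frequency: float
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.ndim != 2:
            raise ValueError(f"u must be a 2D field, got ndim={self.u.ndim}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("wave field contains non-finite values")
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency!r}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass
class PhaseImageSeries:
    """Stack of motion-encoded phase images over one vibration period.

    ``phase`` has shape ``(n_dynamics, H, W)`` in radians for a single MSG
    polarity (``msg_sign``); differenced series carry ``msg_sign = 0``.
    ``period`` is the wrap period: 2*pi for raw acquisitions, pi after the
    half-difference of opposite-polarity series.
    """

    phase: np.ndarray
    protocol: AcquisitionProtocol
    msg_sign: int = 1
    wrapped: bool = True
    period: float = field(default=TWO_PI)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError(f"phase stack must be 3D (dynamic, H, W), got {self.phase.ndim}D")
        if self.phase.shape[0] != self.protocol.n_dynamics:
            raise ValueError(
                f"stack has {self.phase.shape[0]} dynamics, protocol expects "
                f"{self.protocol.n_dynamics}"
            )
        if self.msg_sign not in (-1, 0, 1):
            raise ValueError(f"msg_sign must be +1, -1 or 0 (differenced), got {self.msg_sign}")
        if self.wrapped:
            half = self.period / 2.0
            if np.any(self.phase < -half) or np.any(self.phase >= half):
                raise ValueError("wrapped series has values outside [-period/2, period/2)")

    @property
    def n_dynamics(self) -> int:
        return self.phase.shape[0]
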