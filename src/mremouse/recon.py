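"""Reconstruction of complex shear modulus maps from wrapped phase series.

Pipeline (the study's core computation):

1. half phase-difference of opposite-MSG-polarity series, cancelling the
   static background phase;
2. 2D phase unwrapping of each dynamic;
3. temporal Fourier transformation to the complex harmonic displacement at
   the drive frequency;
4. radial Butterworth band-pass in the spatial-frequency domain, rejecting
   near-DC compression-wave components and high-wavenumber noise;
5. algebraic Helmholtz inversion, G* = -rho * omega^2 * u / laplacian(u),
   with the Laplacian by a central 5-point stencil.

From G* the four tabulated viscoelastic maps are derived per pixel:
storage modulus G' = Re G*, loss modulus G'' = Im G*, magnitude |G*|, and
loss tangent phi = arctan(G''/G').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .fields import TWO_PI, ComplexWaveField, PhaseImageSeries, wrap
from .protocol import AcquisitionProtocol

__all__ = [
    "FilterSpec",
    "Elastogram",
    "phase_difference",
    "unwrap",
    "extract_harmonic",
    "bandpass_filter",
    "helmholtz_invert",
    "reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Radial Butterworth band-pass in wavenumber (rad/m).

    Defaults bracket the physiological shear wavenumber at the drive
    frequency for a reference modulus ``g_ref``: low cutoff 0.3 k_exp
    (kills the near-DC compression-wave regime), high cutoff 3 k_exp,
    order 3.
    """

    low_cut: float
    high_cut: float
    order: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 <= low_cut < high_cut, got {self.low_cut}, {self.high_cut}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    @classmethod
    def default(
        cls, frequency: float = 900.0, density: float = 1000.0, g_ref: float = 5000.0
    ) -> "FilterSpec":
        k_exp = TWO_PI * frequency * np.sqrt(density / g_ref)
        return cls(low_cut=0.3 * k_exp, high_cut=3.0 * k_exp, order=3)

    def gain(self, k: np.ndarray) -> np.ndarray:
        """Amplitude gain at radial wavenumber ``k`` (rad/m); gain(0) = 0."""
        k = np.asarray(k, dtype=float)
        lowpass = 1.0 / np.sqrt(1.0 + (k / self.high_cut) ** (2 * self.order))
        with np.errstate(divide="ignore"):
            ratio = np.where(k > 0, self.low_cut / np.where(k > 0, k, 1.0), np.inf)
        highpass = 1.0 / np.sqrt(1.0 + ratio ** (2 * self.order))
        highpass = np.where(k > 0, highpass, 0.0)
        return lowpass * highpass


@dataclass
class Elastogram:
    """Per-pixel complex shear modulus and its derived parameter maps.

    Invalid pixels (border ring, vanishing Laplacian, negative recovered
    moduli, non-tissue) are NaN in the derived maps and False in
    ``valid_mask``. On valid pixels ``absg**2 == gp**2 + gpp**2`` and
    ``phi == arctan(gpp/gp)`` hold to machine precision by construction.
    """

    gstar: np.ndarray
    gp: np.ndarray
    gpp: np.ndarray
    absg: np.ndarray
    phi: np.ndarray
    valid_mask: np.ndarray
    frequency: float
    density: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.gstar.shape


def phase_difference(
    series_pos: PhaseImageSeries, series_neg: PhaseImageSeries
) -> PhaseImageSeries:
    """Half the wrapped difference of opposite-polarity series.

    Cancels static phase contributions exactly in the noise-free case.
    The output wrap period is pi (the half of a 2*pi-wrapped difference),
    recorded on the returned series.
    """
    if series_pos.protocol != series_neg.protocol:
        raise ValueError("series protocols differ; cannot form phase difference")
    if series_pos.phase.shape != series_neg.phase.shape:
        raise ValueError("series shapes differ; cannot form phase difference")
    if series_pos.msg_sign != 1 or series_neg.msg_sign != -1:
        raise ValueError(
            f"expected msg signs (+1, -1), got ({series_pos.msg_sign}, {series_neg.msg_sign})"
        )
    diff = wrap(series_pos.phase - series_neg.phase) / 2.0
    return PhaseImageSeries(
        phase=diff,
        protocol=series_pos.protocol,
        msg_sign=0,
        wrapped=True,
        period=np.pi,
    )


def unwrap(image: np.ndarray, period: float = TWO_PI, method: str = "quality") -> np.ndarray:
    """Unwrap a 2D wrapped phase field.

    ``method='quality'`` uses quality-guided 2D unwrapping; ``'itoh'`` is a
    row-wise 1D fallback. ``period`` is the wrap period of the input
    (pi for half-differenced series). The output is congruent to the input
    modulo ``period`` at every pixel, up to a global offset for the
    quality-guided method.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D phase image, got ndim={image.ndim}")
    scale = TWO_PI / period
    scaled = image * scale
    if method == "quality":
        out = np.asarray(_skimage_unwrap(scaled))
    elif method == "itoh":
        out = np.unwrap(np.unwrap(scaled, axis=1), axis=0)
    else:
        raise ValueError(f"unknown unwrap method {method!r}")
    return out / scale


def extract_harmonic(
    series: PhaseImageSeries, protocol: AcquisitionProtocol | None = None
) -> ComplexWaveField:
    """Temporal Fourier extraction of the fundamental, in displacement units.

    For a pixel time course xi*A*cos(2*pi*d/n - theta) the fundamental DFT
    bin (normalized by 2/n) has modulus xi*A and phase theta; dividing by
    the encoding efficiency xi yields the complex displacement amplitude u
    in meters.
    """
    protocol = protocol or series.protocol
    n = series.n_dynamics
    if n < 3:
        raise ValueError(f"need at least 3 dynamics to extract the fundamental, got {n}")
    d = np.arange(n)
    basis = np.exp(2j * np.pi * d / n)
    harmonic = (2.0 / n) * np.tensordot(basis, series.phase, axes=(0, 0))
    u = harmonic / protocol.encoding_efficiency
    return ComplexWaveField(
        u=u, frequency=protocol.drive_frequency, pixel_spacing=protocol.pixel_spacing
    )


def bandpass_filter(field: ComplexWaveField, spec: FilterSpec) -> ComplexWaveField:
    """Apply the radial Butterworth band-pass in the spatial-frequency domain."""
    u = field.u
    n_rows, n_cols = u.shape
    ky = TWO_PI * np.fft.fftfreq(n_rows, d=field.pixel_spacing)
    kx = TWO_PI * np.fft.fftfreq(n_cols, d=field.pixel_spacing)
    k = np.hypot(ky[:, None], kx[None, :])
    filtered = np.fft.ifft2(np.fft.fft2(u) * spec.gain(k))
    return ComplexWaveField(
        u=filtered, frequency=field.frequency, pixel_spacing=field.pixel_spacing
    )


def _laplacian_5pt(u: np.ndarray, h: float) -> np.ndarray:
    """Central 5-point Laplacian; the one-pixel border is NaN."""
    lap = np.full(u.shape, np.nan, dtype=complex)
    lap[1:-1, 1:-1] = (
        u[:-2, 1:-1] + u[2:, 1:-1] + u[1:-1, :-2] + u[1:-1, 2:] - 4.0 * u[1:-1, 1:-1]
    ) / h**2
    return lap


def helmholtz_invert(
    field: ComplexWaveField,
    density: float = 1000.0,
    frequency: float | None = None,
    laplacian_floor: float = 0.05,
) -> Elastogram:
    """Algebraic Helmholtz inversion, G* = -rho*omega^2*u / laplacian(u).

    Pixels are marked invalid where the Laplacian magnitude falls below
    ``laplacian_floor`` times its median over the interior (unstable
    division), on the one-pixel border (no stencil support), or where the
    recovered G' <= 0 or G'' < 0 (unphysical; fraction logged). Invalid
    pixels are NaN in every derived map.
    """
    if not density > 0:
        raise ValueError(f"density must be positive, got {density!r}")
    frequency = frequency if frequency is not None else field.frequency
    if not frequency > 0:
        raise ValueError(f"frequency must be positive, got {frequency!r}")

    u = field.u
    omega = 2.0 * np.pi * frequency
    lap = _laplacian_5pt(u, field.pixel_spacing)
    abs_lap = np.abs(lap)

    interior = np.isfinite(abs_lap)
    nonzero = abs_lap[interior]
    nonzero = nonzero[nonzero > 0]
    if nonzero.size == 0:
        raise ValueError(
            "reconstruction failure: Laplacian vanishes everywhere "
            f"({int(interior.sum())} interior pixels, all zero)"
        )
    floor = laplacian_floor * np.median(nonzero)
    stable = interior & (abs_lap >= floor) & (abs_lap > 0)

    gstar = np.full(u.shape, np.nan + 0j)
    gstar[stable] = -density * omega**2 * u[stable] / lap[stable]

    physical = stable & (gstar.real > 0) & (gstar.imag >= 0)
    n_unphysical = int(stable.sum() - physical.sum())
    if stable.sum():
        logger.info(
            "helmholtz_invert: %d/%d stable pixels unphysical (%.1f%%), marked invalid",
            n_unphysical,
            int(stable.sum()),
            100.0 * n_unphysical / stable.sum(),
        )
    if not physical.any():
        raise ValueError(
            "reconstruction failure: no valid pixels "
            f"(interior {int(interior.sum())}, stable {int(stable.sum())}, "
            f"unphysical {n_unphysical})"
        )

    valid = physical
    gp = np.where(valid, gstar.real, np.nan)
    gpp = np.where(valid, gstar.imag, np.nan)
    absg = np.hypot(gp, gpp)
    with np.errstate(invalid="ignore"):
        phi = np.arctan(gpp / gp)
    gstar = np.where(valid, gstar, np.nan + 0j)

    return Elastogram(
        gstar=gstar,
        gp=gp,
        gpp=gpp,
        absg=absg,
        phi=phi,
        valid_mask=valid,
        frequency=frequency,
        density=density,
    )


def reconstruct(
    series_pos: PhaseImageSeries,
    series_neg: PhaseImageSeries,
    protocol: AcquisitionProtocol | None = None,
    spec: FilterSpec | None = None,
    density: float = 1000.0,
    *,
    laplacian_floor: float = 0.05,
    unwrap_method: str = "quality",
    return_intermediates: bool = False,
):
    """Full reconstruction from a pair of opposite-polarity phase series.

    Runs phase_difference -> unwrap (per dynamic) -> extract_harmonic ->
    bandpass_filter -> helmholtz_invert. With ``return_intermediates=True``
    returns ``(elastogram, stages)`` where ``stages`` maps stage names to
    their outputs for inspection or persistence.
    """
    protocol = protocol or series_pos.protocol
    spec = spec or FilterSpec.default(protocol.drive_frequency, density)

    diff = phase_difference(series_pos, series_neg)
    logger.info("reconstruct: phase difference done (%d dynamics)", diff.n_dynamics)

    unwrapped = np.stack(
        [unwrap(diff.phase[d], period=diff.period, method=unwrap_method) for d in range(diff.n_dynamics)]
    )
    unwrapped_series = PhaseImageSeries(
        phase=unwrapped, protocol=protocol, msg_sign=0, wrapped=False
    )
    logger.info("reconstruct: unwrapping done (method=%s)", unwrap_method)

    raw_field = extract_harmonic(unwrapped_series, protocol)
    filtered = bandpass_filter(raw_field, spec)
    logger.info(
        "reconstruct: harmonic extraction + band-pass done (low=%.0f high=%.0f rad/m)",
        spec.low_cut,
        spec.high_cut,
    )

    elastogram = helmholtz_invert(
        filtered, density=density, frequency=protocol.drive_frequency,
        laplacian_floor=laplacian_floor,
    )
    logger.info(
        "reconstruct: inversion done, %d valid pixels", int(elastogram.valid_mask.sum())
    )

    if return_intermediates:
        stages = {
            "difference": diff,
            "unwrapped": unwrapped_series,
            "harmonic": raw_field,
            "filtered": filtered,
        }
        return elastogram, stages
    return elastogram
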