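"""Viscoelastic ground-truth phantoms.

A phantom is a 2D map of the complex shear modulus G* = G' + iG'' together
with a density and integer region labels: 0 background (outside tissue),
1 brain parenchyma, 2 a hippocampus-like interior region of interest. The
geometry is an ellipse ("brain") centered in the grid with a smaller
elliptical sub-region ("hippocampus") placed slightly dorsal of center,
mimicking a transverse mouse-brain slice with a manually segmented
hippocampal ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ViscoelasticPhantom", "build_phantom", "LABEL_BACKGROUND", "LABEL_PARENCHYMA", "LABEL_HIPPOCAMPUS"]

LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_HIPPOCAMPUS = 2


@dataclass
class ViscoelasticPhantom:
    """Ground truth for the forward shear-wave problem.

    Attributes
    ----------
    gstar_map : ndarray of complex
        Complex shear modulus per pixel in Pa; zero outside tissue.
    density : float
        Mass density in kg/m^3, uniform over tissue.
    region_labels : ndarray of int
        0 background, 1 parenchyma, 2 hippocampus-like ROI.
    pixel_spacing : float
        Pixel size in meters.
    """

    gstar_map: np.ndarray
    density: float
    region_labels: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.gstar_map = np.asarray(self.gstar_map, dtype=complex)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.gstar_map.shape != self.region_labels.shape:
            raise ValueError(
                f"gstar_map shape {self.gstar_map.shape} != region_labels shape "
                f"{self.region_labels.shape}"
            )
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density!r}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing!r}")
        tissue = self.region_labels > 0
        if np.any(self.gstar_map[tissue].real <= 0):
            raise ValueError("tissue pixels must have strictly positive storage modulus")
        if np.any(self.gstar_map[tissue].imag < 0):
            raise ValueError("tissue pixels must have non-negative loss modulus")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region_labels > 0


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], semi_axes: tuple[float, float]) -> np.ndarray:
    rows, cols = np.indices(shape)
    cy, cx = center
    ry, rx = semi_axes
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def build_phantom(
    matrix: int,
    fov: float,
    parenchyma_gstar: complex,
    hippocampus_gstar: complex,
    density: float = 1000.0,
) -> ViscoelasticPhantom:
    """Build the two-region elliptical brain phantom.

    The modulus map is piecewise constant per region label. The brain
    ellipse fills ~90% of the grid; the hippocampus-like sub-ellipse sits
    slightly above center, spanning roughly a quarter of the brain width.

    Parameters
    ----------
    matrix : int
        Grid size in pixels per side (>= 32).
    fov : float
        Field of view in meters.
    parenchyma_gstar, hippocampus_gstar : complex
        Complex shear moduli in Pa for labels 1 and 2.
    density : float
        Tissue density in kg/m^3 (default 1000, standard soft-tissue value).
    """
    if matrix < 32:
        raise ValueError(f"matrix must be >= 32, got {matrix}")
    for name, g in (("parenchyma", parenchyma_gstar), ("hippocampus", hippocampus_gstar)):
        g = complex(g)
        if not g.real > 0:
            raise ValueError(
                f"{name} modulus must have strictly positive real part, got {g!r}"
            )
        if g.imag < 0:
            raise ValueError(f"{name} modulus must have non-negative imaginary part, got {g!r}")

    shape = (matrix, matrix)
    c = (matrix - 1) / 2.0
    brain = _ellipse_mask(shape, (c, c), (0.45 * matrix, 0.45 * matrix))
    # hippocampus: small ellipse slightly dorsal (above center), wider than tall
    hippo = _ellipse_mask(
        shape,
        (c - 0.12 * matrix, c),
        (0.08 * matrix, 0.16 * matrix),
    )
    hippo &= brain

    labels = np.zeros(shape, dtype=int)
    labels[brain] = LABEL_PARENCHYMA
    labels[hippo] = LABEL_HIPPOCAMPUS

    gstar = np.zeros(shape, dtype=complex)
    gstar[labels == LABEL_PARENCHYMA] = complex(parenchyma_gstar)
    gstar[labels == LABEL_HIPPOCAMPUS] = complex(hippocampus_gstar)

    return ViscoelasticPhantom(
        gstar_map=gstar,
        density=float(density),
        region_labels=labels,
        pixel_spacing=fov / matrix,
    )
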