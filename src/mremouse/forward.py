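"""Forward shear-wave problem at the drive frequency.

Solves the heterogeneous scalar Helmholtz equation

    div(G* grad u) + rho * omega^2 * u = 0

for the complex through-plane displacement amplitude u on the phantom grid,
with a prescribed harmonic displacement (Dirichlet) on the tissue surface
facing one grid edge and a graded-loss absorbing sponge toward the remaining
edges to emulate outgoing waves. The discretization is a conservative
5-point finite-difference scheme (harmonic-mean interface moduli), solved by
a direct sparse factorization — deterministic and oracle-checkable.

Also provides the closed-form damped plane wave used as the independent
oracle for the inversion: u(x) = A exp(i k* d.x) with complex wavenumber
k* = omega * sqrt(rho / G*), branch chosen so the wave decays along the
propagation direction.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import ComplexWaveField
from .phantom import ViscoelasticPhantom
from .protocol import AcquisitionProtocol

__all__ = ["analytic_plane_wave", "complex_wavenumber", "solve_forward"]

_EDGES = ("left", "right", "top", "bottom")


def complex_wavenumber(gstar: complex, density: float, frequency: float) -> complex:
    """Complex shear wavenumber k* = omega*sqrt(rho/G*), decaying branch.

    The branch is chosen with non-negative imaginary part so that
    exp(i k* s) decays as s increases. For a lossless medium (G'' = 0) the
    wavenumber is real and positive.
    """
    gstar = complex(gstar)
    if not gstar.real > 0:
        raise ValueError(f"G* must have positive real part, got {gstar!r}")
    omega = 2.0 * np.pi * frequency
    k = omega * np.sqrt(density / gstar)
    if k.imag < 0:
        k = -k
    return k


def analytic_plane_wave(
    gstar: complex,
    density: float,
    protocol: AcquisitionProtocol,
    direction: tuple[float, float] = (1.0, 0.0),
    amplitude: float = 10e-6,
) -> ComplexWaveField:
    """Damped plane shear wave on the protocol grid (closed-form oracle).

    ``direction`` is (dx, dy) with x along columns and y along rows;
    it is normalized internally. Returns u(r) = A exp(i k* d.r).
    """
    dx, dy = direction
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    dx, dy = dx / norm, dy / norm

    k = complex_wavenumber(gstar, density, protocol.drive_frequency)
    h = protocol.pixel_spacing
    rows, cols = np.indices((protocol.matrix, protocol.matrix))
    s = (cols * dx + rows * dy) * h
    u = amplitude * np.exp(1j * k * s)
    return ComplexWaveField(u=u, frequency=protocol.drive_frequency, pixel_spacing=h)


def _drive_mask(tissue: np.ndarray, edge: str) -> np.ndarray:
    """First tissue pixel along each scan line starting from ``edge``.

    ``edge='all'`` drives the entire tissue surface (every tissue pixel
    adjacent to background or a grid edge), emulating whole-skull
    vibration where shear waves enter the parenchyma from all sides.
    """
    mask = np.zeros_like(tissue, dtype=bool)
    n_rows, n_cols = tissue.shape
    if edge == "all":
        padded = np.pad(tissue, 1, constant_values=False)
        neighbors_all_tissue = (
            padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
        )
        mask[:] = tissue & ~neighbors_all_tissue
        return mask
    if edge in ("left", "right"):
        cols = range(n_cols) if edge == "left" else range(n_cols - 1, -1, -1)
        for i in range(n_rows):
            for j in cols:
                if tissue[i, j]:
                    mask[i, j] = True
                    break
    else:
        rows = range(n_rows) if edge == "top" else range(n_rows - 1, -1, -1)
        for j in range(n_cols):
            for i in rows:
                if tissue[i, j]:
                    mask[i, j] = True
                    break
    return mask


_OPPOSITE = {"left": "right", "right": "left", "top": "bottom", "bottom": "top"}


def _sponge_profile(
    shape: tuple[int, int], edges: tuple[str, ...], width: int, strength: float
) -> np.ndarray:
    """Quadratic loss ramp rising toward the given grid edges."""
    n_rows, n_cols = shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    ramps = [np.zeros(shape)]
    for e in edges:
        if e == "left":
            d = cols
        elif e == "right":
            d = n_cols - 1 - cols
        elif e == "top":
            d = rows
        else:
            d = n_rows - 1 - rows
        r = np.clip((width - d) / width, 0.0, 1.0)
        ramps.append(np.broadcast_to(r, shape))
    profile = np.max(ramps, axis=0)
    return strength * profile**2


def solve_forward(
    phantom: ViscoelasticPhantom,
    protocol: AcquisitionProtocol,
    drive_boundary: str = "left",
    drive_amplitude: float = 10e-6,
    *,
    sponge_width: int = 12,
    sponge_strength: float = 1.5,
    sponge_edges: str = "opposite",
    min_pixels_per_wavelength: float = 6.0,
) -> ComplexWaveField:
    """Solve the forward problem for the harmonic displacement field.

    The tissue surface facing ``drive_boundary`` is driven at
    ``drive_amplitude`` (plane piston); non-tissue pixels are held at zero;
    tissue within ``sponge_width`` pixels of the edge opposite the drive
    (``sponge_edges='opposite'``, default) or of all three non-drive edges
    (``'all'``) gets a graded extra loss factor (1 + i * strength * ramp^2)
    on G* to absorb outgoing waves. Grid edges themselves are zero-flux
    (Neumann), so a phantom filling the whole grid supports an undisturbed
    laterally-invariant plane wave.

    Raises
    ------
    ValueError
        If any tissue shear wavelength is resolved by fewer than
        ``min_pixels_per_wavelength`` pixels (the computed value is
        reported), or if the linear system is singular.
    """
    if drive_boundary not in _EDGES + ("all",):
        raise ValueError(
            f"drive_boundary must be one of {_EDGES + ('all',)}, got {drive_boundary!r}"
        )

    h = phantom.pixel_spacing
    f = protocol.drive_frequency
    rho = phantom.density
    omega = 2.0 * np.pi * f
    tissue = phantom.tissue_mask
    if not tissue.any():
        raise ValueError("phantom has no tissue pixels")

    # resolution precondition: lambda = sqrt(|G*|/rho)/f over the pixel size
    gmin = np.abs(phantom.gstar_map[tissue]).min()
    lam_min = np.sqrt(gmin / rho) / f
    ppw = lam_min / h
    if ppw < min_pixels_per_wavelength:
        raise ValueError(
            f"shear wavelength under-resolved: {ppw:.2f} pixels/wavelength "
            f"(minimum {min_pixels_per_wavelength})"
        )

    if drive_boundary == "all":
        absorb = ()  # closed drive surface: no outgoing waves to absorb
    elif sponge_edges == "opposite":
        absorb = (_OPPOSITE[drive_boundary],)
    elif sponge_edges == "all":
        absorb = tuple(e for e in _EDGES if e != drive_boundary)
    else:
        raise ValueError(f"sponge_edges must be 'opposite' or 'all', got {sponge_edges!r}")

    G = phantom.gstar_map.astype(complex).copy()
    sponge = _sponge_profile(G.shape, absorb, sponge_width, sponge_strength)
    G[tissue] = G[tissue] * (1.0 + 1j * sponge[tissue])

    drive = _drive_mask(tissue, drive_boundary)
    unknown = tissue & ~drive
    n_unknown = int(unknown.sum())
    if n_unknown == 0:
        raise ValueError("no interior tissue pixels to solve for")

    index = -np.ones(G.shape, dtype=int)
    index[unknown] = np.arange(n_unknown)

    rows_idx, cols_idx = np.nonzero(unknown)
    data, ri, ci = [], [], []
    rhs = np.zeros(n_unknown, dtype=complex)
    inv_h2 = 1.0 / h**2
    n_rows, n_cols = G.shape

    for p, (i, j) in enumerate(zip(rows_idx, cols_idx)):
        diag = rho * omega**2
        gp = G[i, j]
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            qi, qj = i + di, j + dj
            inside = 0 <= qi < n_rows and 0 <= qj < n_cols
            if not inside:
                continue  # grid edge: zero-flux (Neumann)
            if tissue[qi, qj]:
                gq = G[qi, qj]
                ghalf = 2.0 * gp * gq / (gp + gq)
            else:
                ghalf = gp  # flux into the rigid (u=0) background
            diag -= ghalf * inv_h2
            if unknown[qi, qj]:
                data.append(ghalf * inv_h2)
                ri.append(p)
                ci.append(index[qi, qj])
            elif drive[qi, qj]:
                rhs[p] -= ghalf * inv_h2 * drive_amplitude
        data.append(diag)
        ri.append(p)
        ci.append(p)

    A = sp.csr_matrix((data, (ri, ci)), shape=(n_unknown, n_unknown), dtype=complex)
    try:
        x = spla.spsolve(A, rhs)
    except RuntimeError as exc:  # singular factorization
        raise ValueError(
            f"forward system singular on {n_rows}x{n_cols} grid with "
            f"{n_unknown} unknowns: {exc}"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise ValueError(
            f"forward solve produced non-finite values ({n_rows}x{n_cols} grid, "
            f"{n_unknown} unknowns)"
        )

    u = np.zeros(G.shape, dtype=complex)
    u[unknown] = x
    u[drive] = drive_amplitude
    return ComplexWaveField(u=u, frequency=f, pixel_spacing=h)
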