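"""Real-space grids: Fourier synthesis, Patterson maps, peak analysis.

Grids are periodic over the unit cell with 0-based indexing, grid point g
corresponding to fraction g/n.  Synthesis follows

    rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)

with F(000) excluded, so every synthesized grid has zero mean.  The input
structure-factor list holds one representative per unique reflection; the
full sphere is recovered internally through the symmetry operators and
Hermitian (Friedel) completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = [
    "RealSpaceGrid",
    "CoarseGridError",
    "default_grid_dims",
    "expand_to_sphere",
    "synthesize_map",
    "patterson_map_from_coefficients",
    "interpolate",
    "find_peaks",
]


class CoarseGridError(ValueError):
    """Grid sampling too coarse for the resolution content of the data."""


@dataclass
class RealSpaceGrid:
    """Periodic scalar field over the unit cell (density or Patterson)."""

    values: np.ndarray  # (n1,n2,n3) float
    cell: UnitCell
    kind: str = "density"  # "density" | "patterson"

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def standardized(self) -> "RealSpaceGrid":
        """Same grid rescaled to mean 0, standard deviation 1 (sigma units)."""
        v = self.values
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot standardize a constant grid")
        return RealSpaceGrid(values=(v - v.mean()) / sd, cell=self.cell, kind=self.kind)


def _even_fft_friendly(n: int) -> int:
    """Smallest even 5-smooth integer >= n (keeps FFTs fast, halves exact)."""
    m = n + (n % 2)
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 2


def default_grid_dims(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple:
    """Grid dimensions giving ~d_min/factor sampling along each edge."""
    return tuple(_even_fft_friendly(int(np.ceil(e * factor / d_min))) for e in cell.edges)


def expand_to_sphere(hkl: np.ndarray, f: np.ndarray, sg: SpaceGroup):
    """Expand unique reflections to the full sphere of equivalent indices.

    Applies h' = h R with phase shift exp(-2 pi i h.t) and Hermitian
    completion F(-h) = conj(F(h)).  Duplicate images (from centric or
    doubly-listed reflections) are averaged, which is exact for consistent
    input and symmetrizes Bijvoet-inconsistent input into a real map.
    """
    hkl = np.asarray(hkl, dtype=int)
    f = np.asarray(f, dtype=complex)
    rots = sg.rot_array
    trans = sg.trans_array
    h_eq = np.einsum("nj,ojk->onk", hkl, rots)  # (o,n,3)
    ph = np.exp(-2j * np.pi * (hkl @ trans.T)).T  # (o,n)
    f_eq = f[None, :] * ph
    H = h_eq.reshape(-1, 3)
    F = f_eq.reshape(-1)
    H = np.concatenate([H, -H], axis=0)
    F = np.concatenate([F, np.conj(F)], axis=0)
    keep = ~np.all(H == 0, axis=1)
    return H[keep], F[keep]


def _accumulate(H: np.ndarray, F: np.ndarray, dims: tuple) -> np.ndarray:
    n1, n2, n3 = dims
    idx = (np.mod(H[:, 0], n1) * n2 + np.mod(H[:, 1], n2)) * n3 + np.mod(H[:, 2], n3)
    uniq, inv = np.unique(idx, return_inverse=True)
    acc = np.zeros(len(uniq), dtype=complex)
    cnt = np.zeros(len(uniq))
    np.add.at(acc, inv, F)
    np.add.at(cnt, inv, 1.0)
    grid = np.zeros(n1 * n2 * n3, dtype=complex)
    grid[uniq] = acc / cnt
    return grid.reshape(dims)


def synthesize_map(
    hkl,
    f,
    cell: UnitCell,
    sg: SpaceGroup,
    grid_dims: tuple | None = None,
    d_min: float | None = None,
    method: str = "fft",
    kind: str = "density",
) -> RealSpaceGrid:
    """Inverse Fourier synthesis of a (phased) structure-factor set.

    ``d_min`` (when given, or inferred from the indices) is used to check
    grid sampling adequacy: each dimension must be at least 2*edge/d_min.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    f = np.asarray(f, dtype=complex)
    if grid_dims is None:
        if d_min is None:
            if len(hkl):
                d_min = float(np.min(cell.d_spacing(hkl)))
            else:
                d_min = max(cell.edges) / 4.0
        grid_dims = default_grid_dims(cell, d_min)
    if d_min is None and len(hkl):
        d_min = float(np.min(cell.d_spacing(hkl)))
    if d_min is not None:
        need = 2.0 * cell.edges / d_min
        if np.any(np.array(grid_dims) < np.floor(need)):
            raise CoarseGridError(
                f"grid {grid_dims} undersamples d_min={d_min:.3g} (needs >= {need})"
            )
    if len(hkl) == 0:
        return RealSpaceGrid(values=np.zeros(grid_dims), cell=cell, kind=kind)

    H, F = expand_to_sphere(hkl, f, sg)
    if method == "fft":
        A = _accumulate(H, F, grid_dims)
        # rho[g] = (1/V) sum_h A[h] exp(-2 pi i h.g/n): the forward FFT kernel
        rho = np.fft.fftn(A).real / cell.volume
    elif method == "direct":
        n1, n2, n3 = grid_dims
        g1, g2, g3 = np.meshgrid(
            np.arange(n1) / n1, np.arange(n2) / n2, np.arange(n3) / n3, indexing="ij"
        )
        # deduplicate images first so both methods sum the identical set
        A = _accumulate(H, F, grid_dims)
        hh = np.argwhere(A != 0)
        vals = A[hh[:, 0], hh[:, 1], hh[:, 2]]
        # map grid indices back to signed h for the exponent (aliasing-free
        # because sampling adequacy was enforced above)
        dims = np.array(grid_dims)
        hs = np.where(hh > dims // 2, hh - dims, hh)
        rho = np.zeros(grid_dims)
        for hvec, fv in zip(hs, vals):
            arg = hvec[0] * g1 + hvec[1] * g2 + hvec[2] * g3
            rho += (fv * np.exp(-2j * np.pi * arg)).real
        rho /= cell.volume
    else:
        raise ValueError(f"unknown synthesis method {method!r}")
    return RealSpaceGrid(values=rho, cell=cell, kind=kind)


def patterson_map_from_coefficients(
    hkl,
    coefficients,
    cell: UnitCell,
    sg: SpaceGroup,
    grid_dims: tuple | None = None,
    d_min: float | None = None,
    standardize: bool = True,
) -> RealSpaceGrid:
    """Patterson synthesis P(u) = (1/V) sum c_h cos(2 pi h.u).

    Coefficients must be real, finite and not all zero; the origin term is
    excluded.  The returned map is standardized to sigma units by default.
    """
    c = np.asarray(coefficients, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("Patterson coefficients must be finite")
    if np.all(c == 0):
        raise ValueError("all Patterson coefficients are zero")
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    # Patterson symmetry is the Laue group: expand indices through the
    # rotations only — |F|^2-type coefficients carry no translation phase.
    from .symmetry import P1

    h_eq = np.einsum("nj,ojk->onk", hkl, sg.rot_array).reshape(-1, 3)
    c_eq = np.tile(c, len(sg))
    grid = synthesize_map(
        h_eq,
        c_eq.astype(complex),
        cell,
        P1,
        grid_dims=grid_dims,
        d_min=d_min,
        kind="patterson",
    )
    return grid.standardized() if standardize else grid


def interpolate(grid: RealSpaceGrid, frac_points) -> np.ndarray:
    """Trilinear periodic interpolation at fractional positions."""
    pts = np.atleast_2d(np.asarray(frac_points, dtype=float))
    coords = (pts * np.array(grid.dims)).T
    return ndimage.map_coordinates(grid.values, coords, order=1, mode="grid-wrap")


def find_peaks(
    grid: RealSpaceGrid,
    n_peaks: int = 10,
    exclude_origin_radius: float | None = None,
) -> list:
    """Local maxima of the grid as (fractional position, value), descending.

    ``exclude_origin_radius`` (Angstrom) drops peaks within that distance of
    u = 0 — used to suppress the Patterson origin peak.
    """
    v = grid.values
    footprint = ndimage.maximum_filter(v, size=3, mode="wrap")
    mask = v >= footprint
    pos = np.argwhere(mask)
    frac = pos / np.array(grid.dims)
    heights = v[mask]
    if exclude_origin_radius is not None:
        delta = np.minimum(frac, 1.0 - frac) * grid.cell.edges
        dist = np.linalg.norm(delta, axis=1)
        keep = dist > exclude_origin_radius
        frac, heights = frac[keep], heights[keep]
    order = np.argsort(heights)[::-1][:n_peaks]
    return [(frac[i], float(heights[i])) for i in order]
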