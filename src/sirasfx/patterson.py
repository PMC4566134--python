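"""Difference Patterson synthesis, Harker-section analysis and heavy-atom
site search.

A single heavy site x generates, through the screw axes of
P2(1)2(1)2(1), self-vectors confined to the three Harker sections
u = 1/2, v = 1/2 and w = 1/2.  The site search scans candidate positions
and scores each by the *minimum* interpolated Patterson value over all its
Harker vectors (symmetry-minimum function), optionally taking the minimum
across several maps (isomorphous and anomalous) — robust to one
contaminated section or map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import UnitCell
from .maps import (
    CoarseGridError,
    RealSpaceGrid,
    default_grid_dims,
    find_peaks,
    interpolate,
    patterson_map_from_coefficients,
    synthesize_map,
)
from .symmetry import SpaceGroup

__all__ = [
    "HarkerSection",
    "harker_sections",
    "isomorphous_difference_patterson",
    "anomalous_difference_patterson",
    "search_sites",
    "site_distance",
    "anomalous_difference_fourier",
]


@dataclass(frozen=True)
class HarkerSection:
    """One Harker plane: the self-vector map x -> M x + t lies on it."""

    axis: int  # 0,1,2 for u,v,w
    value: float  # constant fractional coordinate of the section
    matrix: tuple  # (R_m - I) as a 3x3 tuple of ints
    shift: tuple  # t_m

    def self_vector(self, site) -> np.ndarray:
        """Harker self-vector of a site (fractional, reduced mod 1)."""
        m = np.array(self.matrix)
        t = np.array(self.shift)
        return np.mod(np.asarray(site, dtype=float) @ m.T + t, 1.0)


def harker_sections(sg: SpaceGroup) -> list:
    """Harker sections from the differences of the symmetry operators.

    For each non-identity operator (R, t), the self-vector x - (Rx + t)
    family lies on a plane when R - I has an all-zero row.  P2(1)2(1)2(1)
    yields exactly the three planes u=1/2, v=1/2, w=1/2; P1 has none.
    """
    if sg.name not in ("P1", "P212121"):
        raise ValueError(f"unsupported space group {sg.name}")
    sections = []
    eye = np.eye(3, dtype=int)
    for rot, trans in zip(sg.rot_array, sg.trans_array):
        if np.array_equal(rot, eye) and np.allclose(trans, 0):
            continue
        m = rot - eye
        zero_rows = np.where(~m.any(axis=1))[0]
        for axis in zero_rows:
            sections.append(
                HarkerSection(
                    axis=int(axis),
                    value=float(np.mod(trans[axis], 1.0)),
                    matrix=tuple(map(tuple, m)),
                    shift=tuple(np.mod(trans, 1.0)),
                )
            )
    return sections


def isomorphous_difference_patterson(
    scaled_pair, cell: UnitCell, sg: SpaceGroup, grid_dims=None, d_min=None
) -> RealSpaceGrid:
    """Patterson with (dF_iso)^2 coefficients, standardized to sigma units."""
    t = scaled_pair.table
    return patterson_map_from_coefficients(
        t[["h", "k", "l"]].to_numpy(),
        t.dF_iso.to_numpy() ** 2,
        cell,
        sg,
        grid_dims=grid_dims,
        d_min=d_min,
    )


def anomalous_difference_patterson(
    scaled_pair,
    cell: UnitCell,
    sg: SpaceGroup,
    grid_dims=None,
    d_min=None,
    normalize: bool = False,
) -> RealSpaceGrid:
    """Patterson of squared anomalous differences.

    Default coefficients are (dF_ano)^2 = (|F+| - |F-|)^2, whose Harker
    peak grows steadily as Bijvoet differences emerge from the noise with
    multiplicity.  ``normalize=True`` uses (dI_ano / <I>)^2 instead, which
    whitens the intensity falloff but also equalizes pure-noise
    reflections and thereby caps the attainable peak height.
    """
    t = scaled_pair.table
    ok = np.isfinite(t.dI_ano.to_numpy())
    tt = t[ok]
    if normalize:
        mean_i = 0.5 * (tt.F_PH_plus.to_numpy() ** 2 + tt.F_PH_minus.to_numpy() ** 2)
        mean_i = np.maximum(mean_i, 1e-9)
        coeff = (tt.dI_ano.to_numpy() / mean_i) ** 2
    else:
        coeff = (tt.F_PH_plus.to_numpy() - tt.F_PH_minus.to_numpy()) ** 2
    return patterson_map_from_coefficients(
        tt[["h", "k", "l"]].to_numpy(), coeff, cell, sg, grid_dims=grid_dims, d_min=d_min
    )


def site_distance(a, b, cell: UnitCell, sg: SpaceGroup) -> float:
    """Distance (Angstrom) between two sites modulo symmetry, allowed
    origin shifts and hand — the metric under which a substructure search
    can be said to have found the true site."""
    a = np.asarray(a, dtype=float)
    best = np.inf
    for hand in (1, -1):
        images = sg.expand_positions(hand * np.asarray(b, dtype=float)).reshape(-1, 3)
        for shift in sg.allowed_origin_shifts:
            delta = np.mod(images + shift - a, 1.0)
            delta = np.minimum(delta, 1.0 - delta) * cell.edges
            best = min(best, float(np.min(np.linalg.norm(delta, axis=1))))
    return best


def search_sites(
    patterson_maps,
    sg: SpaceGroup,
    step: float | None = None,
    n_candidates: int = 5,
    d_min: float | None = None,
    merge_radius: float = 2.0,
) -> list:
    """Symmetry-minimum-function scan for a single heavy site.

    Candidates x are scanned over [0, 1/2)^3 (Harker vectors only determine
    the site modulo the allowed half-cell origin shifts); the score of x is
    the minimum over all Harker self-vectors and all supplied maps of the
    trilinearly interpolated Patterson value.  Nearby candidates are merged
    (greedy clustering within ``merge_radius`` Angstrom) and returned
    descending by score as dicts with the site, its enantiomorph mate and
    the score.
    """
    if isinstance(patterson_maps, RealSpaceGrid):
        patterson_maps = [patterson_maps]
    if not patterson_maps:
        raise ValueError("need at least one Patterson map")
    cell = patterson_maps[0].cell
    sections = harker_sections(sg)
    if not sections:
        raise ValueError(f"{sg.name} has no Harker sections to score against")
    if step is None:
        step = 1.0 / (2 * max(patterson_maps[0].dims))
    if d_min is not None and step > d_min / (2.0 * max(cell.edges)):
        raise CoarseGridError(
            f"scan step {step} too coarse for d_min {d_min} (cell {max(cell.edges)} A)"
        )
    axes = [np.arange(0.0, 0.5, step) for _ in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    score = np.full(len(sites), np.inf)
    for section in sections:
        vec = np.mod(sites @ np.array(section.matrix).T + np.array(section.shift), 1.0)
        for grid in patterson_maps:
            vals = interpolate(grid, vec)
            score = np.minimum(score, vals)

    order = np.argsort(score)[::-1]
    picked = []
    for idx in order:
        cand = sites[idx]
        close = False
        for p in picked:
            delta = np.mod(cand - p["site"], 0.5)
            delta = np.minimum(delta, 0.5 - delta) * cell.edges
            if np.linalg.norm(delta) < merge_radius:
                close = True
                break
        if not close:
            picked.append(
                {
                    "site": cand,
                    "enantiomorph": np.mod(-cand, 0.5),
                    "score": float(score[idx]),
                }
            )
        if len(picked) >= n_candidates:
            break
    return picked


def anomalous_difference_fourier(
    scaled_pair,
    phases,
    cell: UnitCell,
    sg: SpaceGroup,
    grid_dims=None,
    d_min: float | None = None,
    n_peaks: int = 10,
):
    """Anomalous difference Fourier: coefficients m * dF_ano * exp(i(phi-90)).

    ``phases`` is a PhaseSet (protein phases); the synthesis peaks at the
    anomalous scatterer positions.  Returns (standardized grid, peak list of
    (fractional site, height sigma)).
    """
    t = scaled_pair.table
    ok = np.isfinite(t.F_PH_plus.to_numpy()) & np.isfinite(t.F_PH_minus.to_numpy())
    tt = t[ok].set_index(["h", "k", "l"])
    ph = phases.table.set_index(["h", "k", "l"])
    common = tt.index.intersection(ph.index)
    if len(common) == 0:
        raise ValueError("no overlap between phased and measured reflections")
    df_ano = (tt.loc[common, "F_PH_plus"] - tt.loc[common, "F_PH_minus"]).to_numpy()
    phi = np.radians(ph.loc[common, "phi_centroid"].to_numpy() - 90.0)
    fom = ph.loc[common, "fom"].to_numpy()
    coeff = fom * df_ano * np.exp(1j * phi)
    hkl = np.array(list(common))
    grid = synthesize_map(hkl, coeff, cell, sg, grid_dims=grid_dims, d_min=d_min)
    if np.allclose(grid.values, 0):
        peaks = []
        return grid, peaks
    grid = grid.standardized()
    peaks = find_peaks(grid, n_peaks=n_peaks)
    return grid, peaks
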