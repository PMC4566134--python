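"""Generation and asymmetric-unit reduction of Miller index sets.

A :class:`ReflectionSet` lists one representative per symmetry-unique
reflection to a resolution cutoff, with centricity, the multiplicity factor
epsilon, and (optionally) explicit Friedel mates cross-linked so that
anomalous (Bijvoet) pairs can be tracked through merging and phasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = ["ReflectionSet", "generate_reflections", "d_spacing_and_flags", "asu_map"]


def d_spacing_and_flags(cell: UnitCell, sg: SpaceGroup, hkl):
    """d-spacing (Angstrom), centric flag and epsilon for one index."""
    hkl = np.asarray(hkl, dtype=int)
    if np.all(hkl == 0):
        raise ValueError("the (0,0,0) index has no d-spacing")
    return cell.d_spacing(hkl), sg.is_centric(hkl), sg.epsilon(hkl)


@dataclass
class ReflectionSet:
    """Unique reflections (rows of ``hkl``) with per-reflection flags.

    When Friedel mates are kept separate, ``friedel_mate[i]`` is the row
    index of -hkl[i] for acentric reflections and -1 for centrics (whose
    mate is symmetry-equivalent to themselves).
    """

    cell: UnitCell
    sg: SpaceGroup
    hkl: np.ndarray  # (n, 3) int
    d: np.ndarray  # (n,) float
    centric: np.ndarray  # (n,) bool
    epsilon: np.ndarray  # (n,) int
    friedel_separate: bool
    friedel_mate: np.ndarray  # (n,) int, -1 where not applicable
    d_min: float

    def __len__(self) -> int:
        return len(self.hkl)

    def index_lookup(self) -> dict:
        return {tuple(h): i for i, h in enumerate(self.hkl)}


def _canonical_reps(hkl: np.ndarray, sg: SpaceGroup) -> np.ndarray:
    """Friedel-merged canonical representative of each index.

    The representative is the lexicographically largest member of the orbit
    {h R} union {-h R}; this is a pure convention but must be applied
    consistently by generation and by observation mapping.
    """
    rots = sg.rot_array  # (o,3,3)
    eq = np.einsum("nj,ojk->onk", hkl, rots)  # (o,n,3)
    eq = np.concatenate([eq, -eq], axis=0)  # (2o,n,3)
    # lexicographic max via a scalar key (indices are small integers)
    big = 4096
    key = ((eq[..., 0] + 2048) * big + (eq[..., 1] + 2048)) * big + (eq[..., 2] + 2048)
    best = np.argmax(key, axis=0)
    return eq[best, np.arange(hkl.shape[0])]


def asu_map(hkl: np.ndarray, sg: SpaceGroup):
    """Map arbitrary indices to (canonical representative, Friedel branch).

    branch is +1 when the index is symmetry-equivalent to its representative
    without Friedel inversion, -1 when only through inversion.  Centric
    indices always map to branch +1.
    """
    hkl = np.asarray(hkl, dtype=int)
    rots = sg.rot_array
    eq = np.einsum("nj,ojk->onk", hkl, rots)  # (o,n,3)
    big = 4096

    def _key(a):
        return ((a[..., 0] + 2048) * big + (a[..., 1] + 2048)) * big + (a[..., 2] + 2048)

    k_plus = _key(eq)
    k_minus = _key(-eq)
    best_plus = k_plus.max(axis=0)
    best_minus = k_minus.max(axis=0)
    plus_wins = best_plus >= best_minus
    branch = np.where(plus_wins, 1, -1)
    n = hkl.shape[0]
    rep = np.empty((n, 3), dtype=int)
    ip = np.argmax(k_plus, axis=0)
    im = np.argmax(k_minus, axis=0)
    rep[plus_wins] = eq[ip[plus_wins], np.nonzero(plus_wins)[0]]
    neg = ~plus_wins
    rep[neg] = -eq[im[neg], np.nonzero(neg)[0]]
    return rep, branch


def generate_reflections(
    cell: UnitCell,
    sg: SpaceGroup,
    d_min: float,
    keep_friedel_separate: bool = False,
    d_max: float | None = None,
) -> ReflectionSet:
    """Enumerate the symmetry-unique reflections with d >= d_min.

    Systematic absences are excluded.  With ``keep_friedel_separate`` every
    acentric representative is listed together with its Friedel mate
    (-h,-k,-l), cross-linked through ``friedel_mate``.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[~np.all(hkl == 0, axis=1)]
    d = cell.d_spacing(hkl)
    sel = d >= d_min
    if d_max is not None:
        sel &= d <= d_max
    hkl = hkl[sel]

    reps = _canonical_reps(hkl, sg)
    reps = np.unique(reps, axis=0)
    # drop systematic absences
    keep = np.array([not sg.is_absent(hh) for hh in reps])
    reps = reps[keep]

    centric = np.array([sg.is_centric(hh) for hh in reps])
    if keep_friedel_separate:
        acent = reps[~centric]
        hkl_out = np.concatenate([reps, -acent], axis=0)
        mate = np.full(len(hkl_out), -1, dtype=int)
        acent_rows = np.nonzero(~centric)[0]
        mate_rows = len(reps) + np.arange(len(acent))
        mate[acent_rows] = mate_rows
        mate[mate_rows] = acent_rows
        cent_out = np.concatenate([centric, np.zeros(len(acent), dtype=bool)])
    else:
        hkl_out = reps
        mate = np.full(len(reps), -1, dtype=int)
        cent_out = centric

    d_out = cell.d_spacing(hkl_out)
    eps = np.array([sg.epsilon(hh) for hh in hkl_out])
    return ReflectionSet(
        cell=cell,
        sg=sg,
        hkl=hkl_out,
        d=d_out,
        centric=cent_out,
        epsilon=eps,
        friedel_separate=keep_friedel_separate,
        friedel_mate=mate,
        d_min=float(d_min),
    )
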