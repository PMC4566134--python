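"""Space-group symmetry bookkeeping for P1 and P2(1)2(1)2(1).

Operators are stored as integer 3x3 rotation matrices R and fractional
translation vectors t acting on fractional coordinates, x -> R x + t.
Reciprocal-space equivalence follows the row-vector convention
h' = h R, with the phase relation F(h R) = F(h) exp(-2 pi i h.t).

Only the two groups the pipeline needs are provided; both are primitive
orthorhombic (or triclinic) so no centring translations arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "SpaceGroup",
    "P1",
    "P212121",
    "get_space_group",
]


@dataclass(frozen=True)
class SpaceGroup:
    """Symmetry operators plus the bookkeeping phasing needs.

    ``allowed_origin_shifts`` are the translations that leave the symmetry
    (and hence every phase relationship) unchanged; for P2(1)2(1)2(1) these
    are the eight half-cell shifts.  ``enantiomorph_flip`` maps a substructure
    to the inverted hand.
    """

    name: str
    rotations: tuple  # tuple of 3x3 int tuples
    translations: tuple  # tuple of length-3 float tuples

    def __len__(self) -> int:
        return len(self.rotations)

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rotations, dtype=int)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array(self.translations, dtype=float)

    @property
    def enantiomorph_flip(self) -> np.ndarray:
        return -np.eye(3, dtype=int)

    @property
    def allowed_origin_shifts(self) -> np.ndarray:
        if self.name == "P1":
            # Any origin works in P1; expose the half-shifts as the discrete
            # subset used for map comparison.
            vals = (0.0, 0.5)
        else:
            vals = (0.0, 0.5)
        return np.array(list(product(vals, vals, vals)))

    # -- reflection classification ------------------------------------

    def equivalent_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """All h R for one index (may contain duplicates)."""
        hkl = np.asarray(hkl, dtype=int)
        return hkl @ self.rot_array  # (n_ops, 3) via broadcasting on stack

    def is_centric(self, hkl) -> bool:
        hkl = np.asarray(hkl, dtype=int)
        eq = np.einsum("j,ojk->ok", hkl, self.rot_array)
        return bool(np.any(np.all(eq == -hkl, axis=1)))

    def epsilon(self, hkl) -> int:
        """Multiplicity factor: number of operators fixing the index."""
        hkl = np.asarray(hkl, dtype=int)
        eq = np.einsum("j,ojk->ok", hkl, self.rot_array)
        return int(np.sum(np.all(eq == hkl, axis=1)))

    def is_absent(self, hkl) -> bool:
        """Systematic absence from the translational symmetry."""
        hkl = np.asarray(hkl, dtype=int)
        eq = np.einsum("j,ojk->ok", hkl, self.rot_array)
        fixed = np.all(eq == hkl, axis=1)
        phases = self.trans_array @ hkl
        frac = np.mod(phases[fixed], 1.0)
        return bool(np.any((frac > 1e-9) & (frac < 1 - 1e-9)))

    def centric_phase(self, hkl) -> float:
        """One member (degrees, in [0,180)) of the allowed centric phase pair.

        For a centric index some operator sends h to -h; the structure-factor
        phase is then restricted to 180*(h.t) modulo 180.
        """
        hkl = np.asarray(hkl, dtype=int)
        eq = np.einsum("j,ojk->ok", hkl, self.rot_array)
        which = np.where(np.all(eq == -hkl, axis=1))[0]
        if len(which) == 0:
            raise ValueError(f"{tuple(hkl)} is not centric in {self.name}")
        t = self.trans_array[which[0]]
        return float(np.mod(180.0 * (hkl @ t), 180.0))

    def expand_positions(self, frac: np.ndarray) -> np.ndarray:
        """Symmetry images of fractional positions, shape (n_ops, n, 3)."""
        frac = np.atleast_2d(np.asarray(frac, dtype=float))
        return np.einsum("oij,nj->oni", self.rot_array, frac) + self.trans_array[:, None, :]


def _sg(name, ops):
    rots, trans = zip(*ops)
    return SpaceGroup(name=name, rotations=tuple(rots), translations=tuple(trans))


_I = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

P1 = _sg("P1", [(_I, (0.0, 0.0, 0.0))])

# Standard setting of space group #19.
P212121 = _sg(
    "P212121",
    [
        (_I, (0.0, 0.0, 0.0)),
        (((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0.0)),
        (((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.0, 0.5, 0.5)),
        (((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0.0, 0.5)),
    ],
)

_GROUPS = {"P1": P1, "P212121": P212121, "P 21 21 21": P212121}


def get_space_group(name: str) -> SpaceGroup:
    key = name.strip().replace("(", "").replace(")", "")
    if key not in _GROUPS:
        raise KeyError(f"unsupported space group {name!r}; have {sorted(set(_GROUPS))}")
    return _GROUPS[key]
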