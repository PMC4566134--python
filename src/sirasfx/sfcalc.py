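"""Structure-factor computation with anomalous scattering.

The scattering model is intentionally simple: each atom carries a constant
normal scattering factor f0 (no angular falloff beyond the isotropic
B-factor) plus anomalous corrections f' and f''.  For reflection h,

    F(h) = sum_j occ_j (f0_j + f'_j + i f''_j) exp(-B_j s^2 / 4)
           * sum_m exp(2 pi i h . (R_m x_j + t_m)),       s = 1/d.

With f'' = 0 Friedel's law |F(h)| = |F(-h)| holds exactly; a nonzero f''
breaks it, which is the anomalous signal the phasing pipeline exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = ["AtomSite", "StructureFactors", "calc_structure_factors"]


@dataclass(frozen=True)
class AtomSite:
    """One atom in the asymmetric unit, fractional coordinates in [0,1)."""

    label: str
    frac_xyz: tuple  # (x, y, z) fractional
    occupancy: float = 1.0
    b_iso: float = 0.0  # Angstrom^2
    f0: float = 6.0  # electrons
    f_prime: float = 0.0
    f_double_prime: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0,1]")
        if self.b_iso < 0:
            raise ValueError("b_iso must be >= 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    def moved_to(self, frac_xyz) -> "AtomSite":
        return replace(self, frac_xyz=tuple(np.mod(frac_xyz, 1.0)))


@dataclass
class StructureFactors:
    """Complex structure factors on an explicit list of Miller indices."""

    hkl: np.ndarray  # (n,3) int
    f: np.ndarray  # (n,) complex
    anomalous: bool

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.f)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phases in degrees in [0, 360)."""
        return np.mod(np.degrees(np.angle(self.f)), 360.0)

    def lookup(self) -> dict:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def at(self, hkl) -> np.ndarray:
        """Values for the requested indices (must all be present)."""
        lut = self.lookup()
        try:
            idx = [lut[tuple(h)] for h in np.asarray(hkl, dtype=int)]
        except KeyError as exc:
            raise KeyError(f"reflection {exc.args[0]} not in structure-factor set") from None
        return self.f[np.asarray(idx)]


def calc_structure_factors(
    atoms,
    cell: UnitCell,
    sg: SpaceGroup,
    hkl,
    include_anomalous: bool = True,
) -> StructureFactors:
    """Direct-summation structure factors over the symmetry-expanded atoms.

    ``hkl`` may be a ReflectionSet or an (n,3) integer array.
    """
    if hasattr(hkl, "hkl"):
        hkl = hkl.hkl
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    atoms = list(atoms)
    if not atoms:
        raise ValueError("atom list must be nonempty")

    xyz = np.array([a.frac_xyz for a in atoms], dtype=float)  # (na,3)
    occ = np.array([a.occupancy for a in atoms])
    b = np.array([a.b_iso for a in atoms])
    if include_anomalous:
        fj = np.array([a.f0 + a.f_prime + 1j * a.f_double_prime for a in atoms])
    else:
        fj = np.array([complex(a.f0) for a in atoms])

    s2 = 1.0 / cell.d_spacing(hkl) ** 2  # (n,)
    damp = np.exp(-np.outer(s2, b) / 4.0)  # (n, na)
    coef = occ * fj  # (na,)

    pos = sg.expand_positions(xyz)  # (o, na, 3)
    # phase argument h . (R x + t): (n, o, na)
    arg = np.einsum("nj,oaj->noa", hkl.astype(float), pos)
    geom = np.exp(2j * np.pi * arg).sum(axis=1)  # (n, na)
    f = (geom * damp * coef).sum(axis=1)
    return StructureFactors(hkl=hkl, f=f, anomalous=bool(include_anomalous))
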