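"""Unit-cell geometry (orthorhombic restriction).

Cells are described by the six standard parameters; only right-angled
(alpha = beta = gamma = 90 deg) cells are supported in this version, which
covers the orthorhombic space groups the pipeline targets.  The metric is
therefore diagonal and d-spacings reduce to

    1/d^2 = h^2/a^2 + k^2/b^2 + l^2/c^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnitCell"]


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic unit cell with edges in Angstrom."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        if (self.alpha, self.beta, self.gamma) != (90.0, 90.0, 90.0):
            raise NotImplementedError(
                "only right-angled (orthorhombic) cells are supported"
            )

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return self.a * self.b * self.c

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def d_spacing(self, hkl) -> np.ndarray | float:
        """Resolution d (Angstrom) of one or many Miller indices.

        Raises ValueError if any index is (0,0,0).
        """
        hkl = np.asarray(hkl, dtype=float)
        scalar = hkl.ndim == 1
        h2 = np.atleast_2d(hkl)
        if np.any(np.all(h2 == 0, axis=1)):
            raise ValueError("d-spacing undefined for the (0,0,0) index")
        inv_d2 = (h2 / self.edges) ** 2
        d = 1.0 / np.sqrt(inv_d2.sum(axis=1))
        return float(d[0]) if scalar else d

    def orthogonalize(self, frac) -> np.ndarray:
        """Fractional -> orthogonal Angstrom coordinates (diagonal matrix)."""
        return np.asarray(frac, dtype=float) * self.edges

    def fractionalize(self, xyz) -> np.ndarray:
        """Orthogonal Angstrom -> fractional coordinates."""
        return np.asarray(xyz, dtype=float) / self.edges
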