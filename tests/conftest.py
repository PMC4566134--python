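import numpy as np
import pytest

from sirasfx import (
    AtomSite,
    UnitCell,
    P1,
    P212121,
    calc_structure_factors,
    default_ground_truth,
    generate_reflections,
)


@pytest.fixture(scope="session")
def small_cell():
    return UnitCell(10.0, 12.0, 14.0)


@pytest.fixture(scope="session")
def small_atoms():
    rng = np.random.default_rng(7)
    return [
        AtomSite(f"C{i}", tuple(rng.random(3)), f0=6.0 + i, b_iso=5.0) for i in range(5)
    ]


@pytest.fixture(scope="session")
def small_refl(small_cell):
    return generate_reflections(small_cell, P212121, 2.5, keep_friedel_separate=True)


@pytest.fixture(scope="session")
def toy_truth():
    """The default toy crystal pair (session-scoped: structure factors are
    moderately expensive)."""
    return default_ground_truth(seed=11)
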