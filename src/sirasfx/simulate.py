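"""Synthetic serial-snapshot (post-indexing) diffraction data.

The generator emulates what a serial femtosecond crystallography pipeline
hands to Monte-Carlo merging: per-snapshot *partial* Bragg intensities for
native and heavy-atom-derivative crystals of a toy structure, with

* a per-pattern overall scale (beam/crystal-volume fluctuation, log-normal),
* an i.i.d. partiality multiplier per observation (Ewald-offset surrogate),
* Gaussian counting noise sigma(I) = sqrt(max(I,0) + background),
* an optional low-angle absorber that attenuates reflections below a
  resolution threshold by a fixed transmittance,
* an optional fraction of "weak" patterns (to exercise preselection).

Each unique reflection (Friedel mates counted as distinct observables)
appears on a given pattern with fixed probability, so merged multiplicity
grows linearly with pattern count and merged intensities converge to
<g><p> |F|^2 as 1/sqrt(N) — the statistical structure Monte-Carlo
integration relies on.

The default toy crystal is orthorhombic P2(1)2(1)2(1), cell 30 x 40 x 50 A,
40 light pseudo-atoms (f0 = 25 e, residue-scale blobs) plus one Hg-like
heavy site (f0 = 80 e, occupancy 0.7, f'' = 9.75 e), diffracting to 2.5 A.
With these numbers the toy reproduces the signal hierarchy of a small
protein with one Hg: isomorphous differences ~20% of |F|, Bijvoet
differences a few per cent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import UnitCell
from .reflections import ReflectionSet, generate_reflections
from .sfcalc import AtomSite, StructureFactors, calc_structure_factors
from .symmetry import SpaceGroup, get_space_group

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PatternStream",
    "make_toy_structure",
    "default_ground_truth",
    "simulate_patterns",
]

DEFAULT_CELL = UnitCell(30.0, 40.0, 50.0)
DEFAULT_D_MIN = 2.5
HG_F_DOUBLE_PRIME = 9.75  # electrons, Hg near its L-III edge at 12.6 keV


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the snapshot generator; the seed fully determines output."""

    seed: int = 0
    n_patterns: int = 500
    observed_fraction: float = 0.15
    partiality_min: float = 0.1  # partiality ~ Uniform[partiality_min, 1]
    scale_sigma: float = 0.4  # per-pattern scale ~ LogNormal, mean 1
    noise_background: float = 25.0  # sigma(I) = sqrt(max(I,0) + background)
    noise_scale: float = 1.0  # multiplies the counting-noise sigma; 0 = exact
    absorber: tuple | None = None  # (transmittance, d_threshold A) or None
    weak_pattern_fraction: float = 0.0
    weak_scale: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.observed_fraction <= 1):
            raise ValueError("observed_fraction must be in (0,1]")
        if not (0 <= self.partiality_min <= 1):
            raise ValueError("partiality_min must be in [0,1]")
        if self.absorber is not None:
            t, _ = self.absorber
            if not (0 < t <= 1):
                raise ValueError("absorber transmittance must be in (0,1]")
        if not (0 <= self.weak_pattern_fraction <= 1):
            raise ValueError("weak_pattern_fraction must be in [0,1]")


@dataclass
class PatternStream:
    """Snapshot observations as a flat table.

    ``records`` has columns pattern_id, h, k, l, I, sigma; one row per
    observed partial reflection.  Negative I values are legitimate (noise)
    and are retained — their treatment is merging's decision.
    """

    records: pd.DataFrame

    @property
    def n_patterns(self) -> int:
        return self.records.pattern_id.nunique()

    def pattern_ids(self) -> np.ndarray:
        return np.sort(self.records.pattern_id.unique())

    def subset(self, pattern_ids) -> "PatternStream":
        ids = set(int(i) for i in pattern_ids)
        return PatternStream(
            records=self.records[self.records.pattern_id.isin(ids)].reset_index(drop=True)
        )

    def first_n(self, n: int) -> "PatternStream":
        """The first n patterns by id — nested subsampling primitive."""
        ids = self.pattern_ids()
        if n > len(ids):
            raise ValueError(f"requested {n} patterns but stream has {len(ids)}")
        return self.subset(ids[:n])


@dataclass
class GroundTruth:
    """The simulated crystal pair and everything derived from it."""

    cell: UnitCell
    sg: SpaceGroup
    native_atoms: list
    heavy_sites: list
    refl: ReflectionSet  # Friedel-separate listing
    f_native: StructureFactors  # no anomalous terms
    f_derivative: StructureFactors  # includes f'/f''
    d_min: float

    @property
    def derivative_atoms(self) -> list:
        return self.native_atoms + self.heavy_sites

    def true_intensities(self, which: str) -> np.ndarray:
        sf = self.f_native if which == "native" else self.f_derivative
        return np.abs(sf.f) ** 2


def _place_atoms(rng, n_atoms, cell, sg, min_separation, max_tries=20000):
    placed = []
    tries = 0
    while len(placed) < n_atoms:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_atoms} atoms at separation {min_separation} A"
            )
        cand = rng.random(3)
        ok = True
        if placed:
            existing = np.array(placed)
            images = sg.expand_positions(existing).reshape(-1, 3)
            delta = np.abs(images - cand)
            delta = np.minimum(delta, 1.0 - delta) * cell.edges
            if np.min(np.linalg.norm(delta, axis=1)) < min_separation:
                ok = False
        if ok:
            placed.append(cand)
    return placed


def make_toy_structure(
    seed: int = 0,
    n_atoms: int = 40,
    cell: UnitCell = DEFAULT_CELL,
    sg: SpaceGroup | str = "P212121",
    d_min: float = DEFAULT_D_MIN,
    light_f0: float = 25.0,
    light_b: float = 10.0,
    heavy_occupancy: float = 0.7,
    heavy_f0: float = 80.0,
    heavy_f_prime: float = 0.0,
    heavy_f_double_prime: float = HG_F_DOUBLE_PRIME,
    heavy_b: float = 10.0,
    min_separation: float = 2.0,
) -> GroundTruth:
    """Build a toy native/derivative crystal pair with known answers.

    Light atoms are placed uniformly with a minimum-separation rejection
    rule; one heavy site is added to form the derivative.  Structure
    factors (derivative with anomalous terms) are precomputed on the
    Friedel-separate reflection list to ``d_min``.
    """
    if isinstance(sg, str):
        sg = get_space_group(sg)
    if n_atoms < 1:
        raise ValueError("need at least one light atom")
    rng = np.random.default_rng(seed)
    frac = _place_atoms(rng, n_atoms + 1, cell, sg, min_separation)
    native = [
        AtomSite(label=f"C{i+1}", frac_xyz=tuple(x), f0=light_f0, b_iso=light_b)
        for i, x in enumerate(frac[:n_atoms])
    ]
    heavy = [
        AtomSite(
            label="HG",
            frac_xyz=tuple(frac[n_atoms]),
            occupancy=heavy_occupancy,
            b_iso=heavy_b,
            f0=heavy_f0,
            f_prime=heavy_f_prime,
            f_double_prime=heavy_f_double_prime,
        )
    ]
    refl = generate_reflections(cell, sg, d_min, keep_friedel_separate=True)
    f_nat = calc_structure_factors(native, cell, sg, refl, include_anomalous=False)
    f_der = calc_structure_factors(native + heavy, cell, sg, refl, include_anomalous=True)
    return GroundTruth(
        cell=cell,
        sg=sg,
        native_atoms=native,
        heavy_sites=heavy,
        refl=refl,
        f_native=f_nat,
        f_derivative=f_der,
        d_min=d_min,
    )


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The default toy problem used throughout the experiment drivers."""
    return make_toy_structure(seed=seed)


def simulate_patterns(
    truth: GroundTruth, which: str, config: SimulationConfig
) -> PatternStream:
    """Generate a stream of partial-intensity snapshots.

    Per pattern: draw a log-normal scale g (mean 1); include each unique
    Friedel branch independently with probability ``observed_fraction``;
    each included observation gets an i.i.d. partiality p ~ U[p_min, 1];
    I_obs = g p T_eff |F|^2 + eps with T_eff the absorber transmittance for
    reflections at or below the resolution threshold (d >= d_threshold) and
    1 otherwise, and eps Gaussian with sigma = sqrt(max(I_true,0)+background).
    """
    if which not in ("native", "derivative"):
        raise ValueError("which must be 'native' or 'derivative'")
    if len(truth.refl) == 0:
        raise ValueError("ground truth has an empty reflection set")
    rng = np.random.default_rng(config.seed)
    i_true = truth.true_intensities(which)
    d = truth.refl.d
    n_refl = len(i_true)
    n_pat = config.n_patterns

    t_eff = np.ones(n_refl)
    if config.absorber is not None:
        t, d_thr = config.absorber
        t_eff[d >= d_thr] = t

    # per-pattern scale, log-normal with unit mean
    g = rng.lognormal(mean=-0.5 * config.scale_sigma**2, sigma=config.scale_sigma, size=n_pat)
    if config.weak_pattern_fraction > 0:
        weak = rng.random(n_pat) < config.weak_pattern_fraction
        g = np.where(weak, g * config.weak_scale, g)

    obs_mask = rng.random((n_pat, n_refl)) < config.observed_fraction
    pat_idx, refl_idx = np.nonzero(obs_mask)
    n_obs = len(pat_idx)
    p = rng.uniform(config.partiality_min, 1.0, size=n_obs)
    base = g[pat_idx] * p * t_eff[refl_idx] * i_true[refl_idx]
    sigma = config.noise_scale * np.sqrt(np.maximum(base, 0.0) + config.noise_background)
    i_obs = base + rng.normal(0.0, 1.0, size=n_obs) * sigma
    sigma = np.maximum(sigma, 1e-6)  # recorded sigma stays positive

    df = pd.DataFrame(
        {
            "pattern_id": pat_idx,
            "h": truth.refl.hkl[refl_idx, 0],
            "k": truth.refl.hkl[refl_idx, 1],
            "l": truth.refl.hkl[refl_idx, 2],
            "I": i_obs,
            "sigma": sigma,
        }
    )
    return PatternStream(records=df)
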