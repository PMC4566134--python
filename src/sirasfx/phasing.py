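"""Blow-Crick probabilistic phasing in SIR, SAD and SIRAS modes.

For each acentric reflection the native phase phi is scanned on a uniform
grid.  With native amplitude |F_P|, heavy-atom structure factors F_H (at
+h) and F_H-bar = conj(F_H(-h)), the predicted derivative amplitudes are

    F_PH_calc(+/-)(phi) = |F_P| e^{i phi} + F_H (resp. F_H-bar)

and two lack-of-closure residuals are formed:

    eps_iso(phi) = mean(|F_PH+|, |F_PH-|)_obs - mean |F_PH_calc(+/-)(phi)|
    eps_ano(phi) = (|F_PH+| - |F_PH-|)_obs - (|F_PH_calc+| - |F_PH_calc-|)

The phase probability is the product of Gaussian factors
exp(-eps^2 / 2 E^2) — SIR uses the isomorphous factor, SIRAS both, and SAD
only the anomalous factor with the classical sine-rule parameterization
D_calc(phi_T) = 2 |F_H''| sin(phi_T - phi_H) for the derivative total phase
(the sign follows this package's exp(+2 pi i h.x) structure-factor
convention).  Centric reflections are evaluated only at their two
symmetry-allowed phases.

The Gaussian width combines a per-resolution-shell RMS lack of closure E
(model imperfection, estimated iteratively from probability-weighted
residuals) with the propagated per-reflection measurement error, so poorly
measured data — e.g. Bijvoet differences at low multiplicity — yield
correspondingly broad distributions and low figures of merit rather than
confidently wrong phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import UnitCell
from .merge import MergedData, _shell_edges, _shell_mask
from .scaling import ScaledPair, scale_derivative
from .sfcalc import calc_structure_factors
from .symmetry import SpaceGroup

__all__ = [
    "HeavyAtomModel",
    "PhaseSet",
    "LackOfClosure",
    "heavy_atom_sf",
    "phase_probability",
    "estimate_lack_of_closure",
    "phase_dataset",
    "fom_and_phases",
]

MODES = ("SIR", "SAD", "SIRAS")


@dataclass(frozen=True)
class HeavyAtomModel:
    """Heavy-atom substructure used for phasing."""

    sites: tuple  # AtomSite instances
    hand: str = "original"  # "original" | "inverted"

    def __post_init__(self):
        if len(self.sites) < 1:
            raise ValueError("heavy-atom model needs at least one site")

    def inverted(self, sg: SpaceGroup) -> "HeavyAtomModel":
        """The enantiomorph-related model (sites mapped through -x)."""
        flip = sg.enantiomorph_flip
        new_sites = tuple(s.moved_to(flip @ np.asarray(s.frac_xyz)) for s in self.sites)
        hand = "inverted" if self.hand == "original" else "original"
        return HeavyAtomModel(sites=new_sites, hand=hand)


@dataclass
class PhaseSet:
    """Per-reflection phase probability summary.

    ``table`` columns: h, k, l, F (amplitude the phases attach to),
    phi_best, phi_centroid (degrees in [0,360)), fom, centric, d.
    ``prob`` is the retained probability array (n_refl, n_phi) on
    ``phi_grid`` — solvent flattening updates it multiplicatively.
    """

    table: pd.DataFrame
    prob: np.ndarray
    phi_grid: np.ndarray
    mode: str

    @property
    def mean_fom(self) -> float:
        return float(self.table.fom.mean())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LackOfClosure:
    """Per-resolution-shell RMS lack-of-closure estimates."""

    edges: np.ndarray  # shell edges in d, descending, length n_shells+1
    e_iso: np.ndarray
    e_ano: np.ndarray

    def per_reflection(self, d: np.ndarray):
        n_shells = len(self.e_iso)
        ei = np.empty(len(d))
        ea = np.empty(len(d))
        assigned = np.zeros(len(d), dtype=bool)
        for i in range(n_shells):
            m = _shell_mask(d, self.edges, i)
            ei[m], ea[m] = self.e_iso[i], self.e_ano[i]
            assigned |= m
        if not assigned.all():
            out = ~assigned
            near = np.where(d[out] > self.edges[0], 0, n_shells - 1)
            ei[out] = self.e_iso[near]
            ea[out] = self.e_ano[near]
        return ei, ea


def heavy_atom_sf(model: HeavyAtomModel, cell: UnitCell, sg: SpaceGroup, hkl):
    """(F_H at +h, conj(F_H at -h)) with full anomalous terms.

    Without f'' the two coincide; with f'' their difference carries the
    Bijvoet signal of the substructure.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    sf_plus = calc_structure_factors(list(model.sites), cell, sg, hkl, include_anomalous=True)
    sf_minus = calc_structure_factors(list(model.sites), cell, sg, -hkl, include_anomalous=True)
    return sf_plus.f, np.conj(sf_minus.f)


def _epsilons(f_p, fpp, fpm, f_h, f_h_bar, phi_rad, mode):
    """(eps_iso, eps_ano) over the phase grid; entries are None when the
    mode does not use that residual.  Shapes (n, n_phi).

    The isomorphous residual is on the amplitude scale (circle geometry);
    the anomalous residual is on the *intensity* scale, where counting and
    merging noise is Gaussian and the propagated sigma is reliable even
    for weak reflections (the sqrt conversion is ill-behaved there).
    """
    eps_iso = eps_ano = None
    if mode in ("SIR", "SIRAS"):
        fph_calc_plus = np.abs(f_p[:, None] * np.exp(1j * phi_rad) + f_h[:, None])
        fph_calc_minus = np.abs(f_p[:, None] * np.exp(1j * phi_rad) + f_h_bar[:, None])
        obs_mean = 0.5 * (fpp + fpm)
        eps_iso = obs_mean[:, None] - 0.5 * (fph_calc_plus + fph_calc_minus)
        if mode == "SIRAS":
            di_obs = fpp**2 - fpm**2
            eps_ano = di_obs[:, None] - (fph_calc_plus**2 - fph_calc_minus**2)
    else:  # SAD: sine rule on the derivative total phase, intensity scale
        f_dp = 0.5 * np.abs(f_h - f_h_bar)  # |F_H''|
        phi_h = np.angle(0.5 * (f_h + f_h_bar))
        f_t = 0.5 * (fpp + fpm)
        di_calc = 4.0 * (f_t * f_dp)[:, None] * np.sin(phi_rad - phi_h[:, None])
        eps_ano = (fpp**2 - fpm**2)[:, None] - di_calc
    return eps_iso, eps_ano


def _centric_mask_grid(phi_grid, centric, phi0):
    """Probability mask restricting centric reflections to their phase pair."""
    n, nphi = len(centric), len(phi_grid)
    mask = np.ones((n, nphi))
    for i in np.nonzero(centric)[0]:
        allowed = np.mod([phi0[i], phi0[i] + 180.0], 360.0)
        keep = np.zeros(nphi, dtype=bool)
        for a in allowed:
            keep[np.argmin(np.abs(np.mod(phi_grid - a + 180.0, 360.0) - 180.0))] = True
        mask[i] = keep
    return mask


def phase_probability(
    f_p,
    f_ph_plus,
    f_ph_minus,
    f_h,
    f_h_bar,
    e_iso,
    e_ano,
    mode: str = "SIRAS",
    phase_step_deg: float = 5.0,
    centric=None,
    centric_phase=None,
):
    """Normalized phase probabilities on a uniform grid.

    Returns (phi_grid_deg, prob (n, n_phi)).  In SAD mode ``f_p`` may be
    None and the grid parameterizes the derivative total phase.  ``e_iso``
    and ``e_ano`` are the total Gaussian widths per reflection.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    f_ph_plus = np.asarray(f_ph_plus, dtype=float)
    f_ph_minus = np.asarray(f_ph_minus, dtype=float)
    f_h = np.asarray(f_h, dtype=complex)
    f_h_bar = np.asarray(f_h_bar, dtype=complex)
    e_iso = np.asarray(e_iso, dtype=float)
    e_ano = np.asarray(e_ano, dtype=float)
    if mode in ("SIR", "SIRAS"):
        if f_p is None:
            raise ValueError(f"{mode} requires native amplitudes")
        f_p = np.asarray(f_p, dtype=float)
    if np.any(e_iso <= 0) or np.any(e_ano <= 0):
        raise ValueError("lack-of-closure estimates must be positive")

    phi = np.arange(0.0, 360.0, phase_step_deg)
    phi_rad = np.radians(phi)[None, :]
    eps_iso, eps_ano = _epsilons(f_p, f_ph_plus, f_ph_minus, f_h, f_h_bar, phi_rad, mode)

    log_p = np.zeros((len(f_ph_plus), len(phi)))
    if eps_iso is not None:
        log_p += -(eps_iso**2) / (2.0 * e_iso[:, None] ** 2)
    if eps_ano is not None:
        log_p += -(eps_ano**2) / (2.0 * e_ano[:, None] ** 2)

    if centric is not None:
        centric = np.asarray(centric, dtype=bool)
        mask = _centric_mask_grid(phi, centric, np.asarray(centric_phase, dtype=float))
        log_p = np.where(mask > 0, log_p, -np.inf)

    log_p -= log_p.max(axis=1, keepdims=True)
    prob = np.exp(log_p)
    prob /= prob.sum(axis=1, keepdims=True)
    return phi, prob


def fom_and_phases(phi_grid: np.ndarray, prob: np.ndarray):
    """(phi_best, phi_centroid, fom) from a probability distribution."""
    phi_rad = np.radians(phi_grid)
    vec = (prob * np.exp(1j * phi_rad[None, :])).sum(axis=1)
    fom = np.abs(vec)
    centroid = np.mod(np.degrees(np.angle(vec)), 360.0)
    best = phi_grid[np.argmax(prob, axis=1)]
    return best, centroid, np.clip(fom, 0.0, 1.0)


def _prepare_arrays(scaled: ScaledPair, model, cell, sg, mode):
    """Common reflection table with all amplitudes the mode requires.

    The empirical derivative-to-native scaling equalizes shell-mean
    amplitudes, which systematically under-scales the derivative by the
    heavy-atom contribution.  With a substructure model in hand this is
    corrected here: per shell, derivative amplitudes are rescaled so that
    <|F_PH|^2> matches <|F_P|^2 + |F_H|^2> (expectation for independent
    protein and heavy-atom phases).
    """
    t = scaled.table.copy()
    if mode == "SAD":
        # anomalous-only phasing: reflections without a Bijvoet pair carry
        # no information at all
        t = t[np.isfinite(t.dI_ano)]
    t = t.reset_index(drop=True)
    t["has_ano"] = np.isfinite(t.dI_ano.to_numpy())
    hkl = t[["h", "k", "l"]].to_numpy()
    f_h, f_h_bar = heavy_atom_sf(model, cell, sg, hkl)
    if mode != "SAD":
        d = t.d.to_numpy()
        n_shells = 6
        edges = _shell_edges(d, n_shells)
        f_p2 = t.F_P.to_numpy() ** 2
        fh2 = 0.5 * (np.abs(f_h) ** 2 + np.abs(f_h_bar) ** 2)
        fph2 = t.F_PH.to_numpy() ** 2
        corr = np.ones(len(t))
        for i in range(n_shells):
            m = _shell_mask(d, edges, i)
            if m.sum() < 5 or fph2[m].mean() <= 0:
                continue
            corr[m] = np.sqrt((f_p2[m].mean() + fh2[m].mean()) / fph2[m].mean())
        for col in ("F_PH", "F_PH_plus", "F_PH_minus",
                    "sig_F_PH", "sig_F_PH_plus", "sig_F_PH_minus"):
            t[col] = t[col].to_numpy() * corr
        for col in ("sig_I_PH_plus", "sig_I_PH_minus"):
            t[col] = t[col].to_numpy() * corr**2
        t["dF_iso"] = t.F_PH - t.F_P
        t["dI_ano"] = t.F_PH_plus**2 - t.F_PH_minus**2
    centric = np.array([sg.is_centric(hh) for hh in hkl])
    phi0 = np.array([sg.centric_phase(hh) if c else 0.0 for hh, c in zip(hkl, centric)])
    return t, hkl, f_h, f_h_bar, centric, phi0


_NO_ANO_SIGMA = 1e9  # effectively removes the anomalous factor for a row


def _mode_amplitudes(t: pd.DataFrame, mode: str):
    """(f_p, fph_plus, fph_minus, sig_iso, sig_ano) for a mode's residuals.

    sig_iso/sig_ano are the propagated measurement errors of the residuals
    (isomorphous: native and Friedel-mean derivative amplitude errors;
    anomalous: both branch intensity errors).  Rows without a measured
    Bijvoet pair — centrics and single-branch acentrics — fall back to the
    Friedel-mean amplitude and get an uninformative anomalous width, so
    SIRAS phases the same reflection set as SIR plus the anomalous
    information where it exists.
    """
    if mode == "SIR":
        f_p = t.F_P.to_numpy()
        fpp = fpm = t.F_PH.to_numpy()
        sig_iso = np.sqrt(t.sig_F_P.to_numpy() ** 2 + t.sig_F_PH.to_numpy() ** 2)
        sig_ano = np.ones_like(sig_iso)  # unused by the SIR factor
        return f_p, fpp, fpm, sig_iso, sig_ano
    has = t.has_ano.to_numpy()
    f_ph = t.F_PH.to_numpy()
    fpp = np.where(has, t.F_PH_plus.to_numpy(), f_ph)
    fpm = np.where(has, t.F_PH_minus.to_numpy(), f_ph)
    # anomalous residual is on the intensity scale
    sig_ano = np.where(
        has,
        np.sqrt(
            np.nan_to_num(t.sig_I_PH_plus.to_numpy()) ** 2
            + np.nan_to_num(t.sig_I_PH_minus.to_numpy()) ** 2
        ),
        _NO_ANO_SIGMA,
    )
    if mode == "SAD":
        return None, fpp, fpm, np.ones_like(sig_ano), sig_ano
    f_p = t.F_P.to_numpy()
    sig_f_mean = np.where(
        has,
        0.5
        * np.sqrt(
            np.nan_to_num(t.sig_F_PH_plus.to_numpy()) ** 2
            + np.nan_to_num(t.sig_F_PH_minus.to_numpy()) ** 2
        ),
        t.sig_F_PH.to_numpy(),
    )
    sig_iso = np.sqrt(t.sig_F_P.to_numpy() ** 2 + sig_f_mean**2)
    return f_p, fpp, fpm, sig_iso, sig_ano


def estimate_lack_of_closure(
    scaled: ScaledPair,
    model: HeavyAtomModel,
    cell: UnitCell,
    sg: SpaceGroup,
    mode: str = "SIRAS",
    n_shells: int = 6,
    n_iterations: int = 2,
    phase_step_deg: float = 5.0,
    floor_fraction: float = 0.05,
) -> LackOfClosure:
    """Per-shell RMS lack of closure (model error only), iteratively refined.

    Initialized from RMS(dF_iso) and RMS(dF_ano); each iteration phases at
    the current total width, forms the probability-weighted mean squared
    residual per shell, subtracts the measurement variance and takes the
    square root, floored at ``floor_fraction`` of the initial estimate.
    """
    t, hkl, f_h, f_h_bar, centric, phi0 = _prepare_arrays(scaled, model, cell, sg, mode)
    d = t.d.to_numpy()
    edges = _shell_edges(d, n_shells)
    f_p, fpp, fpm, sig_iso, sig_ano = _mode_amplitudes(t, mode)
    df_iso = t.dF_iso.to_numpy()
    df_ano = fpp**2 - fpm**2  # intensity scale, matching the residual

    def shell_stat(x2, valid=None):
        """sqrt of the per-shell mean of x2, empty shells inheriting a neighbor."""
        out = np.empty(n_shells)
        for i in range(n_shells):
            m = _shell_mask(d, edges, i)
            if valid is not None:
                m = m & valid
            out[i] = np.sqrt(max(np.mean(x2[m]), 0.0)) if m.sum() >= 3 else np.nan
        for i in range(n_shells):
            if not np.isfinite(out[i]) or out[i] == 0:
                good = [out[j] for j in (i - 1, i + 1)
                        if 0 <= j < n_shells and np.isfinite(out[j]) and out[j] > 0]
                out[i] = good[0] if good else 1.0
        return np.maximum(out, 1e-9)

    has_ano = t.has_ano.to_numpy() if "has_ano" in t else np.ones(len(t), dtype=bool)
    e_iso0 = shell_stat(df_iso**2)
    e_ano0 = shell_stat(df_ano**2, valid=has_ano)
    loc = LackOfClosure(edges=edges, e_iso=e_iso0.copy(), e_ano=e_ano0.copy())

    phi = np.arange(0.0, 360.0, phase_step_deg)
    for _ in range(n_iterations):
        ei, ea = loc.per_reflection(d)
        _, prob = phase_probability(
            f_p, fpp, fpm, f_h, f_h_bar,
            np.sqrt(ei**2 + sig_iso**2), np.sqrt(ea**2 + sig_ano**2),
            mode=mode, phase_step_deg=phase_step_deg,
            centric=centric, centric_phase=phi0,
        )
        # residuals at the most probable phase: with a calibrated
        # measurement model these estimate the *model* error only (the
        # probability-weighted alternative inflates E by the posterior
        # phase spread and never converges)
        best = np.radians(phi[np.argmax(prob, axis=1)])[:, None]
        eps_iso, eps_ano = _epsilons(f_p, fpp, fpm, f_h, f_h_bar, best, mode)
        new_iso, new_ano = loc.e_iso, loc.e_ano
        if eps_iso is not None:
            mean_sq = eps_iso[:, 0] ** 2 - sig_iso**2
            new_iso = np.maximum(shell_stat(mean_sq), floor_fraction * e_iso0)
        if eps_ano is not None:
            mean_sq = eps_ano[:, 0] ** 2 - sig_ano**2
            new_ano = np.maximum(shell_stat(mean_sq, valid=has_ano), floor_fraction * e_ano0)
        loc = LackOfClosure(edges=edges, e_iso=new_iso, e_ano=new_ano)
    return loc


def phase_dataset(
    native: MergedData | None,
    derivative: MergedData,
    model: HeavyAtomModel,
    cell: UnitCell,
    sg: SpaceGroup,
    mode: str = "SIRAS",
    phase_step_deg: float = 5.0,
    n_shells: int = 6,
    loc_iterations: int = 2,
    scaled: ScaledPair | None = None,
    try_both_hands: bool = False,
    solvent_fraction: float = 0.44,
    flatten_cycles: int = 10,
) -> PhaseSet | tuple:
    """Phase a merged native/derivative pair with a heavy-atom model.

    Returns a PhaseSet; with ``try_both_hands`` both enantiomorphs are run
    through solvent flattening and the result is
    (phases_original, phases_inverted, verdict dict) where the verdict
    reports both mean FOMs and map contrasts and names the selected hand.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode != "SAD" and native is None:
        raise ValueError(f"{mode} needs native data")
    if try_both_hands:
        from .density import solvent_flatten  # local import to avoid a cycle

        results = {}
        for label, mdl in (("original", model), ("inverted", model.inverted(sg))):
            ps = phase_dataset(
                native, derivative, mdl, cell, sg, mode=mode,
                phase_step_deg=phase_step_deg, n_shells=n_shells,
                loc_iterations=loc_iterations, scaled=scaled,
            )
            flat = solvent_flatten(
                ps, cell, sg, solvent_fraction=solvent_fraction, n_cycles=flatten_cycles
            )
            results[label] = (ps, flat)
        verdict = {
            "fom_original": results["original"][0].mean_fom,
            "fom_inverted": results["inverted"][0].mean_fom,
            "contrast_original": results["original"][1].contrast,
            "contrast_inverted": results["inverted"][1].contrast,
        }
        verdict["selected"] = (
            "original"
            if verdict["contrast_original"] >= verdict["contrast_inverted"]
            else "inverted"
        )
        return results["original"][0], results["inverted"][0], verdict

    if scaled is None:
        if mode == "SAD":
            scaled = _sad_pseudo_scaled(derivative)
        else:
            scaled = scale_derivative(native, derivative, n_shells=max(n_shells, 4))

    loc = estimate_lack_of_closure(
        scaled, model, cell, sg, mode=mode, n_shells=n_shells,
        n_iterations=loc_iterations, phase_step_deg=phase_step_deg,
    )
    t, hkl, f_h, f_h_bar, centric, phi0 = _prepare_arrays(scaled, model, cell, sg, mode)
    d = t.d.to_numpy()
    ei, ea = loc.per_reflection(d)
    f_p, fpp, fpm, sig_iso, sig_ano = _mode_amplitudes(t, mode)
    phi, prob = phase_probability(
        f_p, fpp, fpm, f_h, f_h_bar,
        np.sqrt(ei**2 + sig_iso**2), np.sqrt(ea**2 + sig_ano**2),
        mode=mode, phase_step_deg=phase_step_deg,
        centric=centric, centric_phase=phi0,
    )
    best, centroid, fom = fom_and_phases(phi, prob)
    amp = f_p if mode != "SAD" else 0.5 * (fpp + fpm)
    table = pd.DataFrame(
        {
            "h": t.h, "k": t.k, "l": t.l,
            "F": amp, "phi_best": best, "phi_centroid": centroid,
            "fom": fom, "centric": centric, "d": d,
        }
    )
    return PhaseSet(table=table, prob=prob, phi_grid=phi, mode=mode)


def _sad_pseudo_scaled(derivative: MergedData) -> ScaledPair:
    """A ScaledPair view of derivative-only data for SAD phasing."""
    from .scaling import to_amplitudes

    if not derivative.friedel_separate:
        raise ValueError("SAD needs Friedel-separate merged data")
    amp = to_amplitudes(derivative)
    t = amp.table
    plus = t[t.branch == 1].set_index(["h", "k", "l"])
    minus = t[t.branch == -1].set_index(["h", "k", "l"])
    common = plus.index.intersection(minus.index)
    tab = pd.DataFrame(index=common)
    tab["F_PH_plus"] = plus.loc[common, "F"]
    tab["F_PH_minus"] = minus.loc[common, "F"]
    tab["sig_F_PH_plus"] = plus.loc[common, "sigma_F"]
    tab["sig_F_PH_minus"] = minus.loc[common, "sigma_F"]
    tab["sig_I_PH_plus"] = plus.loc[common, "sigma_I"]
    tab["sig_I_PH_minus"] = minus.loc[common, "sigma_I"]
    tab["F_PH"] = 0.5 * (tab.F_PH_plus + tab.F_PH_minus)
    tab["sig_F_PH"] = 0.5 * np.sqrt(tab.sig_F_PH_plus**2 + tab.sig_F_PH_minus**2)
    tab["F_P"] = tab.F_PH  # placeholder; SAD never reads it
    tab["sig_F_P"] = tab.sig_F_PH
    tab["dF_iso"] = 0.0
    tab["dI_ano"] = tab.F_PH_plus**2 - tab.F_PH_minus**2
    tab["d"] = plus.loc[common, "d"]
    return ScaledPair(table=tab.reset_index(), k=1.0, b_rel=0.0, r_iso=0.0)
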