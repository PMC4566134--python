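"""Intensity-to-amplitude conversion and derivative-to-native scaling.

The derivative is brought onto the native scale with a Wilson-style fit:
per resolution shell, log(<|F_P|>/<|F_PH|>) is regressed on s^2 = 1/d^2,
giving a global scale k and a relative B-factor; the scaled derivative then
yields the isomorphous differences dF_iso = |F_PH| - |F_P| and the
anomalous differences dI_ano = I(+) - I(-) that drive substructure search
and phasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .merge import MergedData, _shell_edges, _shell_mask

__all__ = [
    "AmplitudeSet",
    "ScaledPair",
    "to_amplitudes",
    "scale_derivative",
    "wilson_absolute_scale",
]


def wilson_absolute_scale(merged: MergedData, atoms, sg, n_shells: int = 8) -> MergedData:
    """Scale merged intensities to the absolute (electron) scale.

    Serial-snapshot merging leaves the data on an arbitrary scale (mean
    partiality times mean pattern scale).  Phasing against an absolute
    heavy-atom model requires absolute data, so each resolution shell is
    rescaled to the Wilson expectation for the known composition:
    <I>(s) = sum_cell (occ f)^2 exp(-B s^2 / 2) over the symmetry-expanded
    atom list — the standard composition-based absolute scaling.
    """
    t = merged.table.copy()
    d = t.d.to_numpy()
    s2 = 1.0 / d**2
    coef = np.array([(a.occupancy * a.f0) ** 2 for a in atoms])
    bvals = np.array([a.b_iso for a in atoms])
    n_ops = len(sg)
    expected = n_ops * (coef[None, :] * np.exp(-np.outer(s2, bvals) / 2.0)).sum(axis=1)
    edges = _shell_edges(d, n_shells)
    i_obs = t.I.to_numpy()
    factor = np.ones(len(t))
    for i in range(n_shells):
        m = _shell_mask(d, edges, i)
        if m.sum() < 5:
            continue
        obs_mean = i_obs[m].mean()
        if obs_mean <= 0:
            continue
        factor[m] = expected[m].mean() / obs_mean
    t["I"] = t.I * factor
    t["sigma"] = t.sigma * factor
    return MergedData(
        table=t, cell=merged.cell, sg=merged.sg, friedel_separate=merged.friedel_separate
    )


@dataclass
class AmplitudeSet:
    """Amplitudes per unique reflection/branch, from sqrt(max(I,0)).

    ``n_truncated`` counts negative intensities clipped to |F| = 0 — on
    low-noise data this should be (near) zero, making the approximation's
    cost observable.
    """

    table: pd.DataFrame  # h,k,l,branch,F,sigma_F,d,n
    n_truncated: int
    friedel_separate: bool


def to_amplitudes(merged: MergedData) -> AmplitudeSet:
    """|F| = sqrt(max(I,0)); sigma_F = sigma_I/(2|F|), or sqrt(sigma_I) at F=0."""
    t = merged.table.copy()
    neg = t.I.to_numpy() < 0
    f = np.sqrt(np.maximum(t.I.to_numpy(), 0.0))
    with np.errstate(divide="ignore"):
        sig = np.where(f > 0, t.sigma.to_numpy() / (2.0 * np.where(f > 0, f, 1.0)),
                       np.sqrt(t.sigma.to_numpy()))
    out = t[["h", "k", "l", "branch", "d", "n"]].copy()
    out["F"] = f
    out["sigma_F"] = sig
    out["sigma_I"] = t.sigma.to_numpy()
    return AmplitudeSet(
        table=out, n_truncated=int(neg.sum()), friedel_separate=merged.friedel_separate
    )


@dataclass
class ScaledPair:
    """Native/derivative amplitudes on a common scale, with differences.

    ``table`` rows are common unique reflections: F_P (native), F_PH
    (scaled derivative, Friedel-mean), F_PH_plus/F_PH_minus (scaled branch
    amplitudes where both measured, else NaN), dF_iso, dI_ano (on the scaled
    intensity scale, NaN without both branches), d.
    """

    table: pd.DataFrame
    k: float
    b_rel: float
    r_iso: float


def scale_derivative(
    native: MergedData, derivative: MergedData, n_shells: int = 8
) -> ScaledPair:
    """Scale the derivative onto the native and form difference coefficients."""
    amp_nat = to_amplitudes(native).table
    amp_der = to_amplitudes(derivative).table
    for t_ in (amp_nat, amp_der):
        t_["sig2"] = t_.sigma_F**2

    nat = amp_nat.groupby(["h", "k", "l"]).agg(
        F_P=("F", "mean"), d=("d", "first"), sig2=("sig2", "sum"), nb=("F", "size")
    )
    nat["sig_F_P"] = np.sqrt(nat.sig2) / nat.nb
    if derivative.friedel_separate:
        der_t = amp_der.copy()
        plus = der_t[der_t.branch == 1].set_index(["h", "k", "l"])
        minus = der_t[der_t.branch == -1].set_index(["h", "k", "l"])
        der = der_t.groupby(["h", "k", "l"]).agg(
            F_PH=("F", "mean"), sig2=("sig2", "sum"), nb=("F", "size")
        )
    else:
        plus = minus = None
        der = amp_der.groupby(["h", "k", "l"]).agg(
            F_PH=("F", "mean"), sig2=("sig2", "sum"), nb=("F", "size")
        )
    der["sig_F_PH"] = np.sqrt(der.sig2) / der.nb

    common = nat.index.intersection(der.index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} common reflections; need >= 10")
    tab = pd.DataFrame(index=common)
    tab["F_P"] = nat.loc[common, "F_P"]
    tab["F_PH"] = der.loc[common, "F_PH"]
    tab["sig_F_P"] = nat.loc[common, "sig_F_P"]
    tab["sig_F_PH"] = der.loc[common, "sig_F_PH"]
    tab["d"] = nat.loc[common, "d"]

    # Wilson-style relative scaling on shell means
    d = tab.d.to_numpy()
    edges = _shell_edges(d, n_shells)
    s2_mid, logratio = [], []
    for i in range(n_shells):
        m = _shell_mask(d, edges, i)
        if m.sum() < 5:
            continue
        fp = tab.F_P.to_numpy()[m].mean()
        fph = tab.F_PH.to_numpy()[m].mean()
        if fp <= 0 or fph <= 0:
            continue
        s2_mid.append(np.mean(1.0 / d[m] ** 2))
        logratio.append(np.log(fp / fph))
    if len(s2_mid) < 2:
        k = float(np.exp(np.mean(logratio))) if logratio else 1.0
        b_rel = 0.0
    else:
        slope, intercept = np.polyfit(s2_mid, logratio, 1)
        k = float(np.exp(intercept))
        b_rel = float(4.0 * slope)

    scale = k * np.exp(-b_rel * (1.0 / tab.d.to_numpy() ** 2) / 4.0)
    tab["F_PH"] = tab.F_PH.to_numpy() * scale
    tab["sig_F_PH"] = tab.sig_F_PH.to_numpy() * scale
    tab["dF_iso"] = tab.F_PH - tab.F_P

    for col in ("F_PH_plus", "F_PH_minus", "sig_F_PH_plus", "sig_F_PH_minus",
                "sig_I_PH_plus", "sig_I_PH_minus"):
        tab[col] = np.nan
    if plus is not None:
        both = common.intersection(plus.index).intersection(minus.index)
        sc = pd.Series(scale, index=common)
        tab.loc[both, "F_PH_plus"] = plus.loc[both, "F"] * sc.loc[both]
        tab.loc[both, "F_PH_minus"] = minus.loc[both, "F"] * sc.loc[both]
        tab.loc[both, "sig_F_PH_plus"] = plus.loc[both, "sigma_F"] * sc.loc[both]
        tab.loc[both, "sig_F_PH_minus"] = minus.loc[both, "sigma_F"] * sc.loc[both]
        # intensity-scale errors (scaled I = scale^2 * raw I)
        tab.loc[both, "sig_I_PH_plus"] = plus.loc[both, "sigma_I"] * sc.loc[both] ** 2
        tab.loc[both, "sig_I_PH_minus"] = minus.loc[both, "sigma_I"] * sc.loc[both] ** 2
        tab["dI_ano"] = tab.F_PH_plus**2 - tab.F_PH_minus**2
    else:
        tab["dI_ano"] = np.nan

    r_iso = float(np.sum(np.abs(tab.dF_iso)) / np.sum(np.abs(tab.F_P)))
    return ScaledPair(table=tab.reset_index(), k=k, b_rel=b_rel, r_iso=r_iso)
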