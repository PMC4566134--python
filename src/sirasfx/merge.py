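"""Pattern preselection, absorber correction, Monte-Carlo merging and the
data-quality statistics of serial snapshot data.

Merging is the plain Monte-Carlo estimator: observations are mapped to the
symmetry-reduced asymmetric unit (optionally keeping Friedel branches
distinct) and averaged arithmetically; sigma of a merged reflection is the
sample standard deviation over its observations divided by sqrt(n).  No
per-pattern scaling or partiality refinement is applied — convergence comes
from multiplicity alone.

Quality metrics: R_split and half-set correlations (CC_1/2, CC_ano) from a
random pattern halving, model-referenced correlations CC_calc and CC_anoref,
selection-rate arithmetic, and per-resolution-shell tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import UnitCell
from .reflections import ReflectionSet, asu_map
from .sfcalc import StructureFactors
from .simulate import PatternStream
from .symmetry import SpaceGroup

__all__ = [
    "MergedData",
    "preselect_patterns",
    "absorber_correct",
    "merge_patterns",
    "half_set_metrics",
    "cc_calc",
    "cc_anoref",
    "summarize_selection",
    "shell_statistics",
]


@dataclass
class MergedData:
    """Per unique reflection (and Friedel branch): mean I, sigma, count.

    ``table`` columns: h, k, l (canonical representative), branch (+1/-1),
    I, sigma, n, d.  ``friedel_separate`` records which convention was used.
    """

    table: pd.DataFrame
    cell: UnitCell
    sg: SpaceGroup
    friedel_separate: bool

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mean_multiplicity(self) -> float:
        return float(self.table.n.mean())

    @property
    def total_observations(self) -> int:
        return int(self.table.n.sum())

    def key_frame(self) -> pd.DataFrame:
        return self.table.set_index(["h", "k", "l", "branch"])

    def friedel_differences(self) -> pd.DataFrame:
        """Rows (h,k,l, dI, sigma_dI, I_plus, I_minus) where both branches exist."""
        if not self.friedel_separate:
            raise ValueError("Friedel branches were merged; no anomalous differences")
        t = self.table
        plus = t[t.branch == 1].set_index(["h", "k", "l"])
        minus = t[t.branch == -1].set_index(["h", "k", "l"])
        common = plus.index.intersection(minus.index)
        out = pd.DataFrame(index=common)
        out["I_plus"] = plus.loc[common, "I"]
        out["I_minus"] = minus.loc[common, "I"]
        out["dI"] = out.I_plus - out.I_minus
        out["sigma_dI"] = np.sqrt(
            plus.loc[common, "sigma"] ** 2 + minus.loc[common, "sigma"] ** 2
        )
        out["d"] = plus.loc[common, "d"]
        return out.reset_index()


def _record_d(records: pd.DataFrame, cell: UnitCell) -> np.ndarray:
    hkl = records[["h", "k", "l"]].to_numpy()
    return cell.d_spacing(hkl)


def preselect_patterns(
    stream: PatternStream, cell: UnitCell, adu_threshold: float, lowres_bound: float
):
    """Keep patterns whose low-resolution maximum *exceeds* the threshold.

    A pattern is kept iff max{I : d >= lowres_bound} > adu_threshold
    (a maximum exactly at the threshold is rejected, as is a pattern with
    no low-resolution records).  Returns (filtered stream, n_rejected).
    """
    if adu_threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = stream.records
    d = _record_d(df, cell)
    low = df[d >= lowres_bound]
    maxima = low.groupby("pattern_id").I.max()
    all_ids = stream.pattern_ids()
    keep_ids = maxima[maxima > adu_threshold].index
    kept = df[df.pattern_id.isin(set(keep_ids))].reset_index(drop=True)
    n_rejected = len(all_ids) - len(keep_ids)
    return PatternStream(records=kept), n_rejected


def absorber_correct(
    stream: PatternStream, cell: UnitCell, transmittance: float, d_threshold: float
) -> PatternStream:
    """Undo a low-angle absorber: I -> I/T, sigma -> sigma/T for d >= threshold.

    Not idempotent — apply exactly once to data simulated with the absorber.
    """
    if transmittance <= 0:
        raise ValueError("transmittance must be positive")
    df = stream.records.copy()
    in_region = _record_d(df, cell) >= d_threshold
    df.loc[in_region, "I"] /= transmittance
    df.loc[in_region, "sigma"] /= transmittance
    return PatternStream(records=df)


def merge_patterns(
    stream: PatternStream,
    cell: UnitCell,
    sg: SpaceGroup,
    keep_friedel_separate: bool = True,
) -> MergedData:
    """Monte-Carlo merge of a pattern stream into unique reflections."""
    df = stream.records
    if len(df) == 0:
        raise ValueError("cannot merge an empty stream")
    hkl = df[["h", "k", "l"]].to_numpy()
    rep, branch = asu_map(hkl, sg)
    if not keep_friedel_separate:
        branch = np.ones(len(rep), dtype=int)
    work = pd.DataFrame(
        {
            "h": rep[:, 0],
            "k": rep[:, 1],
            "l": rep[:, 2],
            "branch": branch,
            "I": df.I.to_numpy(),
            "sigma": df.sigma.to_numpy(),
        }
    )
    work["sig2"] = work.sigma**2
    grouped = work.groupby(["h", "k", "l", "branch"], sort=True)
    agg = grouped.agg(
        I=("I", "mean"),
        sd=("I", "std"),
        n=("I", "size"),
        sig2_sum=("sig2", "sum"),
    ).reset_index()
    # sd/sqrt(n) is the Monte-Carlo convergence estimate, but at small n the
    # sample sd is itself unreliable; never report below the propagated
    # per-observation error of the mean
    sigma_mc = (agg.sd / np.sqrt(agg.n)).fillna(0.0)
    sigma_prop = np.sqrt(agg.sig2_sum) / agg.n
    table = agg.drop(columns=["sd", "sig2_sum"])
    table["sigma"] = np.maximum(sigma_mc, sigma_prop)
    table["d"] = cell.d_spacing(table[["h", "k", "l"]].to_numpy())
    return MergedData(
        table=table, cell=cell, sg=sg, friedel_separate=keep_friedel_separate
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate (zero-variance) input to correlation")
    return float(np.corrcoef(a, b)[0, 1])


def r_split(i_a: np.ndarray, i_b: np.ndarray) -> float:
    """2^(-1/2) sum|I_A - I_B| / (0.5 sum(I_A + I_B)) over common reflections."""
    denom = 0.5 * np.sum(i_a + i_b)
    if denom == 0:
        raise ValueError("zero denominator in R_split")
    return float(np.sum(np.abs(i_a - i_b)) / (np.sqrt(2.0) * denom))


def half_set_metrics(
    stream: PatternStream,
    cell: UnitCell,
    sg: SpaceGroup,
    quantity: str = "intensity",
    seed: int = 0,
    n_shells: int | None = None,
):
    """Random-half-dataset consistency metrics.

    Patterns are randomly halved (seeded; ties at odd counts go to half A)
    and each half merged independently.  For ``quantity='intensity'``
    returns (R_split, CC_1/2[, shell table]); for 'anomalous_difference'
    returns (None, CC_ano[, shell table]) computed on I(+)-I(-) over
    reflections with both Friedel branches measured in both halves.
    """
    ids = stream.pattern_ids()
    if len(ids) < 2:
        raise ValueError("need at least two patterns to halve")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_a = (len(ids) + 1) // 2
    half_a = stream.subset(perm[:n_a])
    half_b = stream.subset(perm[n_a:])

    if quantity == "intensity":
        m_a = merge_patterns(half_a, cell, sg, keep_friedel_separate=False)
        m_b = merge_patterns(half_b, cell, sg, keep_friedel_separate=False)
        a = m_a.table.set_index(["h", "k", "l"])
        b = m_b.table.set_index(["h", "k", "l"])
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("no common reflections between the halves")
        i_a = a.loc[common, "I"].to_numpy()
        i_b = b.loc[common, "I"].to_numpy()
        d = a.loc[common, "d"].to_numpy()
        overall = (r_split(i_a, i_b), _pearson(i_a, i_b))
        pair = (i_a, i_b, d)
    elif quantity == "anomalous_difference":
        m_a = merge_patterns(half_a, cell, sg, keep_friedel_separate=True)
        m_b = merge_patterns(half_b, cell, sg, keep_friedel_separate=True)
        da = m_a.friedel_differences().set_index(["h", "k", "l"])
        db = m_b.friedel_differences().set_index(["h", "k", "l"])
        common = da.index.intersection(db.index)
        if len(common) == 0:
            raise ValueError("no common Bijvoet pairs between the halves")
        x = da.loc[common, "dI"].to_numpy()
        y = db.loc[common, "dI"].to_numpy()
        d = da.loc[common, "d"].to_numpy()
        overall = (None, _pearson(x, y))
        pair = (x, y, d)
    else:
        raise ValueError("quantity must be 'intensity' or 'anomalous_difference'")

    if n_shells is None:
        return overall

    x, y, d = pair
    edges = _shell_edges(d, n_shells)
    rows = []
    for i in range(n_shells):
        inside = _shell_mask(d, edges, i)
        if inside.sum() < 3:
            rows.append((edges[i], edges[i + 1], int(inside.sum()), np.nan, np.nan))
            continue
        rs = r_split(x[inside], y[inside]) if quantity == "intensity" else np.nan
        cc = _pearson(x[inside], y[inside])
        rows.append((edges[i], edges[i + 1], int(inside.sum()), rs, cc))
    shells = pd.DataFrame(rows, columns=["d_hi", "d_lo", "n", "r_split", "cc"])
    return overall[0], overall[1], shells


def _shell_edges(d: np.ndarray, n_shells: int, scheme: str = "volume") -> np.ndarray:
    """Shell edges descending in d: equal reciprocal volume (linear in
    1/d^3, default) or equal reflection counts."""
    if scheme == "volume":
        s3 = np.linspace((1.0 / d.max()) ** 3, (1.0 / d.min()) ** 3, n_shells + 1)
        return 1.0 / np.cbrt(s3)
    if scheme == "count":
        qs = np.quantile(np.sort(d)[::-1], np.linspace(0, 1, n_shells + 1))
        return np.sort(qs)[::-1]
    raise ValueError("scheme must be 'volume' or 'count'")


def _shell_mask(d: np.ndarray, edges: np.ndarray, i: int) -> np.ndarray:
    hi, lo = edges[i], edges[i + 1]
    if i == 0:
        return (d <= hi * (1 + 1e-12)) & (d >= lo)
    return (d < hi) & (d >= lo)


def cc_calc(merged: MergedData, model_sf: StructureFactors) -> float:
    """Pearson correlation of merged intensities with model |F|^2."""
    t = merged.table
    # branch -1 rows hold the intensity of the Friedel mate of the listed
    # representative index
    signed = t[["h", "k", "l"]].to_numpy() * t.branch.to_numpy()[:, None]
    i_calc = np.abs(model_sf.at(signed)) ** 2
    return _pearson(t.I.to_numpy(), i_calc)


def cc_anoref(merged: MergedData, model_sf: StructureFactors) -> float:
    """Correlation of observed I(+)-I(-) with the model-calculated
    anomalous intensity differences |F+|^2 - |F-|^2.

    Unlike the half-set CC_ano this references a heavy-atom-bearing model,
    so it stays informative at pattern counts where two noisy halves
    decorrelate.
    """
    if not model_sf.anomalous:
        raise ValueError("model structure factors must include anomalous terms")
    diffs = merged.friedel_differences()
    if len(diffs) < 3:
        raise ValueError("fewer than 3 Bijvoet pairs available")
    hkl = diffs[["h", "k", "l"]].to_numpy()
    f_plus = model_sf.at(hkl)
    f_minus = model_sf.at(-hkl)
    calc = np.abs(f_plus) ** 2 - np.abs(f_minus) ** 2
    return _pearson(diffs.dI.to_numpy(), calc)


def summarize_selection(collected: int, selected: int, indexed: int) -> dict:
    """Selection and indexing rates in percent (rounded half away from zero).

    selection rate = 100*selected/collected, indexing rate =
    100*indexed/selected; both are also reported unrounded.
    """
    if not (0 <= indexed <= selected <= collected):
        raise ValueError("need 0 <= indexed <= selected <= collected")
    if collected == 0 or selected == 0:
        raise ValueError("zero denominator in rate computation")
    sel = 100.0 * selected / collected
    idx = 100.0 * indexed / selected

    def _round_half_away(x: float) -> int:
        return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))

    return {
        "selection_rate_percent": _round_half_away(sel),
        "indexing_rate_percent": _round_half_away(idx),
        "selection_rate_exact": sel,
        "indexing_rate_exact": idx,
    }


def shell_statistics(
    stream: PatternStream,
    cell: UnitCell,
    sg: SpaceGroup,
    refl: ReflectionSet,
    n_shells: int = 5,
    seed: int = 0,
    scheme: str = "volume",
) -> pd.DataFrame:
    """Per-resolution-shell completeness, multiplicity, R_split, CC_1/2,
    mean I/sigma.  Shells are equal-volume in 1/d^3 by default
    (``scheme='count'`` balances reflection counts instead); empty shells
    get null statistics.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    merged = merge_patterns(stream, cell, sg, keep_friedel_separate=refl.friedel_separate)
    t = merged.table
    # theoretical unique reflections per shell
    edges = _shell_edges(refl.d, n_shells, scheme=scheme)
    try:
        _, _, half_shells = half_set_metrics(
            stream, cell, sg, "intensity", seed=seed, n_shells=n_shells
        )
    except ValueError:
        half_shells = None
    rows = []
    for i in range(n_shells):
        th_mask = _shell_mask(refl.d, edges, i)
        ob_mask = _shell_mask(t.d.to_numpy(), edges, i)
        n_theory = int(th_mask.sum())
        n_obs = int(ob_mask.sum())
        if n_obs == 0:
            rows.append(
                (edges[i], edges[i + 1], n_theory, 0, np.nan, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        completeness = 100.0 * n_obs / n_theory if n_theory else np.nan
        mult = float(t.n[ob_mask].mean())
        isig = float((t.I[ob_mask] / t.sigma[ob_mask]).mean())
        rs = cc = np.nan
        if half_shells is not None:
            rs = half_shells.r_split[i]
            cc = half_shells.cc[i]
        rows.append(
            (edges[i], edges[i + 1], n_theory, n_obs, completeness, mult, isig, rs, cc)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "d_hi", "d_lo", "n_theory", "n_obs", "completeness",
            "multiplicity", "mean_i_over_sigma", "r_split", "cc_half",
        ],
    )
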