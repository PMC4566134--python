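"""The computational experiments: pattern-count titration, resolution-cutoff
scan and anomalous-signal curves, run end-to-end on synthetic data.

All experiments subsample patterns *nested* (the first N pattern ids), so
results at a larger count are computed from a superset of the patterns used
at a smaller count — mimicking "using the first N snapshots" and removing
resampling noise from the monotone trends of interest.  A titration cell is
judged a success when the flattened map correlates with the ground-truth
F_c map above 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import evaluate_map, solvent_flatten
from .maps import default_grid_dims
from .merge import cc_anoref, half_set_metrics, merge_patterns, MergedData
from .patterson import (
    anomalous_difference_patterson,
    harker_sections,
    isomorphous_difference_patterson,
    search_sites,
)
from .phasing import HeavyAtomModel, phase_dataset, _sad_pseudo_scaled
from .scaling import scale_derivative, wilson_absolute_scale
from .simulate import GroundTruth, PatternStream, SimulationConfig, simulate_patterns

__all__ = [
    "PhasingOutcome",
    "phase_streams",
    "TitrationResult",
    "run_titration",
    "run_resolution_scan",
    "run_signal_curves",
    "simulate_default_pair",
    "DEFAULT_TITRATION_COUNTS",
]

# Default pattern-count axes for the titration experiment.  The lower end
# (25) sits below the isomorphous success boundary; the cap (300) keeps the
# anomalous-only mode clearly short of the signal it would need — the
# regime in which the three phasing modes separate.
DEFAULT_TITRATION_COUNTS = (25, 50, 100, 200, 300)


def simulate_default_pair(truth: GroundTruth, n_patterns: int, seed: int):
    """Native and derivative streams under the default noise conditions."""
    cfg_nat = SimulationConfig(seed=seed * 2 + 1, n_patterns=n_patterns)
    cfg_der = SimulationConfig(seed=seed * 2 + 2, n_patterns=n_patterns)
    native = simulate_patterns(truth, "native", cfg_nat)
    derivative = simulate_patterns(truth, "derivative", cfg_der)
    return native, derivative


@dataclass
class PhasingOutcome:
    mode: str
    n_native: int
    n_derivative: int
    map_cc: float
    success: bool
    mean_fom: float
    phase_error_deg: float
    site_error_angstrom: float
    stopped_early: bool


def _truncate(merged: MergedData, d_min: float | None) -> MergedData:
    if d_min is None:
        return merged
    t = merged.table[merged.table.d >= d_min].reset_index(drop=True)
    return MergedData(
        table=t, cell=merged.cell, sg=merged.sg, friedel_separate=merged.friedel_separate
    )


def _heavy_model_at(truth: GroundTruth, site_frac) -> HeavyAtomModel:
    template = truth.heavy_sites[0]
    return HeavyAtomModel(sites=(template.moved_to(site_frac),))


def locate_heavy_site(
    truth: GroundTruth,
    native: MergedData | None,
    derivative: MergedData,
    d_min: float | None = None,
):
    """Heavy-atom search from the difference Pattersons.

    With native data the search scores against the isomorphous difference
    Patterson (the strong signal); without it (SAD) the anomalous map is
    all there is.  ``search_sites`` accepts both maps together for the
    symmetry-minimum combination when both signals are trustworthy.
    Returns (site, score).
    """
    maps = []
    cut = d_min if d_min is not None else truth.d_min
    dims = default_grid_dims(truth.cell, cut)
    if native is not None:
        scaled = scale_derivative(native, derivative)
        tab = scaled.table[scaled.table.d >= cut]
        scaled_cut = type(scaled)(
            table=tab.reset_index(drop=True), k=scaled.k, b_rel=scaled.b_rel, r_iso=scaled.r_iso
        )
        maps.append(
            isomorphous_difference_patterson(
                scaled_cut, truth.cell, truth.sg, grid_dims=dims, d_min=cut
            )
        )
    else:
        pseudo = _sad_pseudo_scaled(derivative)
        tab = pseudo.table[pseudo.table.d >= cut]
        ano_source = type(pseudo)(table=tab.reset_index(drop=True), k=1.0, b_rel=0.0, r_iso=0.0)
        maps.append(
            anomalous_difference_patterson(
                ano_source, truth.cell, truth.sg, grid_dims=dims, d_min=cut
            )
        )
    candidates = search_sites(maps, truth.sg, d_min=cut)
    return candidates[0]["site"], candidates[0]["score"]


def phase_streams(
    truth: GroundTruth,
    native_stream: PatternStream | None,
    derivative_stream: PatternStream,
    mode: str = "SIRAS",
    d_min: float | None = None,
    use_true_site: bool = False,
    flatten_cycles: int = 10,
    solvent_fraction: float = 0.44,
) -> PhasingOutcome:
    """Merge, scale, locate, phase, flatten and score one data combination."""
    from .patterson import site_distance

    cell, sg = truth.cell, truth.sg
    derivative = _truncate(
        merge_patterns(derivative_stream, cell, sg, keep_friedel_separate=True), d_min
    )
    native = None
    if native_stream is not None:
        native = _truncate(
            merge_patterns(native_stream, cell, sg, keep_friedel_separate=True), d_min
        )
        # Wilson scaling to the absolute scale of the scattering model: the
        # derivative inherits it through the relative scaling step
        native = wilson_absolute_scale(native, truth.native_atoms, sg)
    else:
        derivative = wilson_absolute_scale(derivative, truth.derivative_atoms, sg)
    true_site = np.asarray(truth.heavy_sites[0].frac_xyz)
    if use_true_site:
        site = true_site
    else:
        site, _ = locate_heavy_site(
            truth, native if mode != "SAD" else None, derivative, d_min=d_min
        )
    site_err = site_distance(site, true_site, cell, sg)
    model = _heavy_model_at(truth, site)
    cut = d_min if d_min is not None else truth.d_min

    # A Patterson search cannot tell a substructure from its enantiomorph,
    # and only the isomorphous term is hand-blind: run both hands and keep
    # the one whose flattened map shows the better protein/solvent contrast.
    hands = (model,) if mode == "SIR" else (model, model.inverted(sg))
    flat = None
    for mdl in hands:
        phases = phase_dataset(
            native if mode != "SAD" else None, derivative, mdl, cell, sg, mode=mode
        )
        candidate = solvent_flatten(
            phases, cell, sg, solvent_fraction=solvent_fraction,
            n_cycles=flatten_cycles, d_min=cut,
        )
        if flat is None or candidate.contrast > flat.contrast:
            flat = candidate
    against = "derivative" if mode == "SAD" else "native"
    score = evaluate_map(flat.phases, truth, against=against, d_min=cut)
    return PhasingOutcome(
        mode=mode,
        n_native=native_stream.n_patterns if native_stream is not None else 0,
        n_derivative=derivative_stream.n_patterns,
        map_cc=score.cc,
        success=score.success,
        mean_fom=flat.phases.mean_fom,
        phase_error_deg=score.mean_phase_error_deg,
        site_error_angstrom=site_err,
        stopped_early=flat.stopped_early,
    )


@dataclass
class TitrationResult:
    mode: str
    table: pd.DataFrame  # n_native, n_derivative, map_cc, success, ...

    def minimal_total_patterns(self) -> float:
        """Smallest n_native + n_derivative among successful cells (inf if none)."""
        ok = self.table[self.table.success]
        if len(ok) == 0:
            return float("inf")
        return float((ok.n_native + ok.n_derivative).min())

    @property
    def n_successes(self) -> int:
        return int(self.table.success.sum())


def run_titration(
    truth: GroundTruth,
    native_stream: PatternStream,
    derivative_stream: PatternStream,
    native_counts,
    derivative_counts,
    mode: str = "SIRAS",
    use_true_site: bool = False,
    flatten_cycles: int = 10,
) -> TitrationResult:
    """Phase every (n_native, n_derivative) combination on nested subsets."""
    native_counts = sorted(int(n) for n in native_counts)
    derivative_counts = sorted(int(n) for n in derivative_counts)
    if native_counts[-1] > native_stream.n_patterns:
        raise ValueError("native grid exceeds available patterns")
    if derivative_counts[-1] > derivative_stream.n_patterns:
        raise ValueError("derivative grid exceeds available patterns")
    rows = []
    for n_der in derivative_counts:
        der_sub = derivative_stream.first_n(n_der)
        if mode == "SAD":
            out = phase_streams(
                truth, None, der_sub, mode=mode,
                use_true_site=use_true_site, flatten_cycles=flatten_cycles,
            )
            for n_nat in native_counts:
                rows.append({**out.__dict__, "n_native": n_nat})
            continue
        for n_nat in native_counts:
            nat_sub = native_stream.first_n(n_nat)
            out = phase_streams(
                truth, nat_sub, der_sub, mode=mode,
                use_true_site=use_true_site, flatten_cycles=flatten_cycles,
            )
            rows.append(out.__dict__)
    table = pd.DataFrame(rows).drop(columns=["mode"])
    return TitrationResult(mode=mode, table=table)


def run_resolution_scan(
    truth: GroundTruth,
    native_stream: PatternStream,
    derivative_stream: PatternStream,
    cutoffs,
    modes=("SIRAS", "SIR"),
    use_true_site: bool = False,
    flatten_cycles: int = 10,
) -> pd.DataFrame:
    """Repeat phasing with the reflections truncated at each d_min cutoff."""
    rows = []
    for cutoff in cutoffs:
        if cutoff is not None and cutoff < truth.d_min:
            raise ValueError(
                f"cutoff {cutoff} finer than the simulated d_min {truth.d_min}"
            )
        for mode in modes:
            out = phase_streams(
                truth,
                native_stream if mode != "SAD" else None,
                derivative_stream,
                mode=mode,
                d_min=cutoff,
                use_true_site=use_true_site,
                flatten_cycles=flatten_cycles,
            )
            rows.append(
                {
                    "cutoff": cutoff if cutoff is not None else truth.d_min,
                    "mode": mode,
                    "map_cc": out.map_cc,
                    "success": out.success,
                    "mean_fom": out.mean_fom,
                }
            )
    return pd.DataFrame(rows)


def run_signal_curves(
    truth: GroundTruth,
    derivative_stream: PatternStream,
    pattern_counts,
    seed: int = 0,
) -> pd.DataFrame:
    """CC_ano, CC_anoref and the anomalous-Patterson Harker peak vs count.

    The Patterson height is measured (sigma units) at the v=1/2 Harker
    self-vector of the true heavy site — the quantity whose growth with
    pattern count demonstrates the accumulating anomalous signal.
    """
    counts = sorted(int(n) for n in pattern_counts)
    if counts[-1] > derivative_stream.n_patterns:
        raise ValueError("pattern count exceeds available patterns")
    cell, sg = truth.cell, truth.sg
    site = np.asarray(truth.heavy_sites[0].frac_xyz)
    sections = harker_sections(sg)
    rows = []
    for n in counts:
        sub = derivative_stream.first_n(n)
        merged = merge_patterns(sub, cell, sg, keep_friedel_separate=True)
        try:
            _, cc_ano = half_set_metrics(sub, cell, sg, "anomalous_difference", seed=seed)
        except ValueError:
            cc_ano = np.nan
        try:
            ccar = cc_anoref(merged, truth.f_derivative)
        except ValueError:
            ccar = np.nan
        pseudo = _sad_pseudo_scaled(merged)
        try:
            pat = anomalous_difference_patterson(pseudo, cell, sg, d_min=truth.d_min)
            from .maps import interpolate

            heights = [
                float(interpolate(pat, section.self_vector(site))[0])
                for section in sections
            ]
            peak = heights[min(1, len(heights) - 1)]  # the v = 1/2 section
        except ValueError:
            peak = np.nan
        rows.append(
            {"n_patterns": n, "cc_ano": cc_ano, "cc_anoref": ccar, "patterson_sigma": peak}
        )
    return pd.DataFrame(rows)
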