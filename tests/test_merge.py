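"""Monte-Carlo merging and the data-quality statistics."""

import numpy as np
import pandas as pd
import pytest

from sirasfx import (
    P212121,
    SimulationConfig,
    absorber_correct,
    cc_anoref,
    cc_calc,
    half_set_metrics,
    merge_patterns,
    preselect_patterns,
    shell_statistics,
    simulate_patterns,
    summarize_selection,
)
from sirasfx.merge import r_split
from sirasfx.simulate import PatternStream


def _stream_from_rows(rows):
    return PatternStream(
        records=pd.DataFrame(rows, columns=["pattern_id", "h", "k", "l", "I", "sigma"])
    )


@pytest.fixture(scope="module")
def noisy_stream(toy_truth):
    cfg = SimulationConfig(seed=31, n_patterns=300)
    return simulate_patterns(toy_truth, "derivative", cfg)


class TestPreselection:
    def test_threshold_is_strict(self, toy_truth):
        """A low-resolution maximum exactly at the threshold is rejected."""
        rows = [(0, 1, 0, 0, 5000.0, 1.0), (1, 1, 0, 0, 5000.1, 1.0)]
        stream = _stream_from_rows(rows)
        kept, n_rej = preselect_patterns(stream, toy_truth.cell, 5000.0, 3.8)
        assert kept.pattern_ids().tolist() == [1]
        assert n_rej == 1

    def test_zero_threshold_keeps_positive_patterns(self, toy_truth):
        rows = [(0, 1, 0, 0, 0.5, 1.0)]
        kept, n_rej = preselect_patterns(_stream_from_rows(rows), toy_truth.cell, 0.0, 3.8)
        assert n_rej == 0

    def test_bimodal_stream_split_at_intermediate_threshold(self, toy_truth):
        cfg = SimulationConfig(seed=4, n_patterns=400, weak_pattern_fraction=0.5,
                               weak_scale=1e-4)
        stream = simulate_patterns(toy_truth, "native", cfg)
        strong_med = stream.records.groupby("pattern_id").I.max().median()
        kept, n_rej = preselect_patterns(stream, toy_truth.cell, strong_med * 1e-2, 3.8)
        frac_rej = n_rej / 400
        assert 0.35 < frac_rej < 0.65


class TestAbsorberCorrection:
    def test_arithmetic_of_transmission_factor(self, toy_truth):
        # 100/0.3636 = 275.03, 10/0.3636 = 27.50 (two decimals)
        rows = [(0, 1, 0, 0, 100.0, 10.0)]  # d = 30 A >= 3.8
        out = absorber_correct(_stream_from_rows(rows), toy_truth.cell, 0.3636, 3.8)
        assert out.records.I[0] == pytest.approx(275.03, abs=0.005)
        assert out.records.sigma[0] == pytest.approx(27.50, abs=0.005)

    def test_unit_transmittance_is_identity(self, noisy_stream, toy_truth):
        out = absorber_correct(noisy_stream, toy_truth.cell, 1.0, 3.8)
        assert np.allclose(out.records.I, noisy_stream.records.I)

    def test_simulate_then_correct_matches_no_absorber(self, toy_truth):
        """Correcting with the true (T, d) restores the absorber-free merge."""
        base = SimulationConfig(seed=8, n_patterns=400)
        plain = simulate_patterns(toy_truth, "derivative", base)
        with_abs = simulate_patterns(
            toy_truth, "derivative",
            SimulationConfig(seed=8, n_patterns=400, absorber=(0.3636, 3.8)),
        )
        corrected = absorber_correct(with_abs, toy_truth.cell, 0.3636, 3.8)
        m_plain = merge_patterns(plain, toy_truth.cell, P212121, True).key_frame()
        m_corr = merge_patterns(corrected, toy_truth.cell, P212121, True).key_frame()
        common = m_plain.index.intersection(m_corr.index)
        a, b = m_plain.loc[common], m_corr.loc[common]
        # identical sampling pattern, so the only differences are the noise
        # realizations scaled by 1/T; agreement within a few merged sigmas
        z = (a.I - b.I) / np.sqrt(a.sigma**2 + b.sigma**2)
        assert np.median(np.abs(z)) < 3.0

    def test_zero_transmittance_rejected(self, noisy_stream, toy_truth):
        with pytest.raises(ValueError):
            absorber_correct(noisy_stream, toy_truth.cell, 0.0, 3.8)


class TestMerging:
    def test_single_observation_passthrough(self, toy_truth):
        rows = [(0, 1, 2, 3, 42.0, 3.0)]
        m = merge_patterns(_stream_from_rows(rows), toy_truth.cell, P212121, True)
        assert len(m) == 1
        assert m.table.I[0] == pytest.approx(42.0)
        assert m.table.n[0] == 1
        assert m.table.sigma[0] == pytest.approx(3.0)

    def test_symmetry_equivalents_pool(self, toy_truth):
        # (1,2,3) and its P212121 mates with the same Friedel parity
        eq = np.einsum("j,ojk->ok", np.array([1, 2, 3]), P212121.rot_array)
        rows = [(i, *h, 10.0 + i, 1.0) for i, h in enumerate(eq)]
        m = merge_patterns(_stream_from_rows(rows), toy_truth.cell, P212121, True)
        assert len(m) == 1
        assert m.table.n[0] == 4
        assert m.table.I[0] == pytest.approx(np.mean([10.0, 11.0, 12.0, 13.0]))

    def test_noiseless_full_coverage_is_exact(self, toy_truth):
        cfg = SimulationConfig(seed=0, n_patterns=2, observed_fraction=1.0,
                               partiality_min=1.0, scale_sigma=0.0, noise_background=0.0, noise_scale=0.0)
        stream = simulate_patterns(toy_truth, "native", cfg)
        m = merge_patterns(stream, toy_truth.cell, P212121, True)
        assert len(m) == len(toy_truth.refl)  # 100% complete
        lut = {tuple(h): i for i, h in enumerate(toy_truth.refl.hkl)}
        i_true = toy_truth.true_intensities("native")
        for _, row in m.table.head(200).iterrows():
            h = (row.h, row.k, row.l) if row.branch == 1 else (-row.h, -row.k, -row.l)
            assert row.I == pytest.approx(i_true[lut[h]], rel=1e-9)

    def test_permutation_invariance(self, noisy_stream, toy_truth):
        df = noisy_stream.records
        shuffled = PatternStream(records=df.sample(frac=1.0, random_state=1))
        a = merge_patterns(noisy_stream, toy_truth.cell, P212121, True).table
        b = merge_patterns(shuffled, toy_truth.cell, P212121, True).table
        assert np.allclose(a.I.to_numpy(), b.I.to_numpy())

    def test_merged_intensity_proportional_to_squared_amplitude(
        self, noisy_stream, toy_truth
    ):
        """At high multiplicity the merged intensities regress on the true
        |F|^2 with R^2 > 0.99 (no absorber)."""
        stream = simulate_patterns(
            toy_truth, "derivative", SimulationConfig(seed=37, n_patterns=900)
        )
        m = merge_patterns(stream, toy_truth.cell, P212121, True)
        t = m.table[m.table.n >= 80]
        signed = t[["h", "k", "l"]].to_numpy() * t.branch.to_numpy()[:, None]
        i_true = np.abs(toy_truth.f_derivative.at(signed)) ** 2
        slope, intercept = np.polyfit(i_true, t.I.to_numpy(), 1)
        assert slope > 0
        pred = slope * i_true + intercept
        ss_res = np.sum((t.I.to_numpy() - pred) ** 2)
        ss_tot = np.sum((t.I.to_numpy() - t.I.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_multiplicity_conservation(self, noisy_stream, toy_truth):
        m = merge_patterns(noisy_stream, toy_truth.cell, P212121, True)
        assert m.total_observations == len(noisy_stream.records)


class TestHalfSetMetrics:
    def test_identical_halves_limit(self, toy_truth):
        # duplicate each pattern so both halves see identical data; the
        # random halving may still differ, so construct two literal copies
        rows = []
        rng = np.random.default_rng(0)
        for pid in range(2):
            rng_r = np.random.default_rng(7)
            for _ in range(50):
                h = rng_r.integers(1, 5, 3)
                rows.append((pid, *h, float(rng_r.uniform(10, 100)), 1.0))
        stream = _stream_from_rows(rows)
        rs, cc = half_set_metrics(stream, toy_truth.cell, P212121, "intensity", seed=0)
        assert rs == pytest.approx(0.0, abs=1e-12)
        assert cc == pytest.approx(1.0)

    def test_r_split_identities(self):
        a = np.array([1.0, 2.0, 3.0])
        assert r_split(a, a) == 0.0
        assert r_split(a, a * 1.1) > 0

    def test_cc_ano_antisymmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert np.corrcoef(x, -x)[0, 1] == pytest.approx(-1.0)

    def test_r_split_scales_as_inverse_sqrt_patterns(self, toy_truth):
        """Monte-Carlo convergence: log-log slope of R_split vs patterns
        per half is -0.5 within tolerance."""
        counts, values = [50, 100, 200, 400, 800], []
        cfg = SimulationConfig(seed=13, n_patterns=800)
        stream = simulate_patterns(toy_truth, "native", cfg)
        for n in counts:
            rs, _ = half_set_metrics(
                stream.first_n(n), toy_truth.cell, P212121, "intensity", seed=1
            )
            values.append(rs)
        slope = np.polyfit(np.log(counts), np.log(values), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_needs_two_patterns(self, toy_truth):
        rows = [(0, 1, 2, 3, 1.0, 1.0)]
        with pytest.raises(ValueError):
            half_set_metrics(_stream_from_rows(rows), toy_truth.cell, P212121)


class TestModelReferencedCCs:
    def test_exact_intensities_give_unity(self, toy_truth):
        cfg = SimulationConfig(seed=0, n_patterns=2, observed_fraction=1.0,
                               partiality_min=1.0, scale_sigma=0.0, noise_background=0.0, noise_scale=0.0)
        stream = simulate_patterns(toy_truth, "derivative", cfg)
        m = merge_patterns(stream, toy_truth.cell, P212121, True)
        assert cc_calc(m, toy_truth.f_derivative) == pytest.approx(1.0, abs=1e-9)
        assert cc_anoref(m, toy_truth.f_derivative) == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_data_decorrelate(self, toy_truth, noisy_stream):
        m = merge_patterns(noisy_stream, toy_truth.cell, P212121, True)
        shuffled = m.table.copy()
        rng = np.random.default_rng(3)
        shuffled["I"] = rng.permutation(shuffled.I.to_numpy())
        from sirasfx.merge import MergedData

        m2 = MergedData(table=shuffled, cell=m.cell, sg=m.sg, friedel_separate=True)
        cc = cc_calc(m2, toy_truth.f_derivative)
        assert abs(cc) < 3.0 / np.sqrt(len(shuffled))

    def test_no_anomalous_model_rejected(self, toy_truth, noisy_stream):
        m = merge_patterns(noisy_stream, toy_truth.cell, P212121, True)
        with pytest.raises(ValueError):
            cc_anoref(m, toy_truth.f_native)

    def test_cc_anoref_grows_with_patterns(self, toy_truth):
        cfg = SimulationConfig(seed=17, n_patterns=800)
        stream = simulate_patterns(toy_truth, "derivative", cfg)
        vals = []
        for n in (100, 400, 800):
            m = merge_patterns(stream.first_n(n), toy_truth.cell, P212121, True)
            vals.append(cc_anoref(m, toy_truth.f_derivative))
        assert vals[-1] > vals[0]


class TestSelectionRates:
    def test_native_counts_reproduce_printed_percentages(self):
        out = summarize_selection(133958, 26238, 10792)
        assert out["selection_rate_percent"] == 20
        assert out["indexing_rate_percent"] == 41

    def test_derivative_counts_reproduce_printed_percentages(self):
        out = summarize_selection(583291, 298061, 85747)
        assert out["selection_rate_percent"] == 51
        assert out["indexing_rate_percent"] == 29

    def test_degenerate_and_invalid(self):
        out = summarize_selection(5, 5, 5)
        assert out["selection_rate_percent"] == 100
        assert out["indexing_rate_percent"] == 100
        with pytest.raises(ValueError):
            summarize_selection(10, 20, 5)
        with pytest.raises(ValueError):
            summarize_selection(0, 0, 0)


class TestShellStatistics:
    def test_full_coverage_complete_in_every_shell(self, toy_truth):
        cfg = SimulationConfig(seed=0, n_patterns=3, observed_fraction=1.0,
                               partiality_min=1.0, scale_sigma=0.0, noise_background=0.0, noise_scale=0.0)
        stream = simulate_patterns(toy_truth, "native", cfg)
        tab = shell_statistics(stream, toy_truth.cell, P212121, toy_truth.refl, n_shells=4)
        assert np.allclose(tab.completeness, 100.0)
        assert tab.n_theory.sum() == len(toy_truth.refl)

    def test_shells_partition_reflections(self, toy_truth, noisy_stream):
        tab = shell_statistics(noisy_stream, toy_truth.cell, P212121, toy_truth.refl, 5)
        m = merge_patterns(noisy_stream, toy_truth.cell, P212121, True)
        assert tab.n_obs.sum() == len(m)
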