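"""Unit tests for the alkaline-gel densitometry pipeline."""

import math

import numpy as np
import pytest

from polfid.errors import CalibrationError, DataError, ParameterError
from polfid.gelquant import (
    Calibration,
    FragmentSizeDistribution,
    LaneProfile,
    embedded_ribos,
    fit_calibration,
    format_ribo_summary,
    fragment_count_profile,
    genome_breakpoints,
    mean_fragment_size,
    preprocess_lane,
    summarize_ribo,
    welch_t,
)
from polfid.simulate import SimConfig, render_gel_lane


def gaussian_band_lane(positions, label="M", grid=None, width=1.0):
    grid = np.linspace(-80.0, 60.0, 900) if grid is None else grid
    y = np.zeros_like(grid)
    for p in positions:
        y += np.exp(-0.5 * ((grid - p) / width) ** 2)
    return LaneProfile(distances=grid, intensities=y, label=label)


class TestLaneProfileValidation:
    def test_rejects_mismatched_and_unsorted(self):
        with pytest.raises(DataError):
            LaneProfile(distances=np.array([1.0, 2.0]), intensities=np.array([1.0]))
        with pytest.raises(DataError):
            LaneProfile(distances=np.array([2.0, 1.0]), intensities=np.array([1.0, 1.0]))
        with pytest.raises(DataError):
            LaneProfile(distances=np.array([1.0, 2.0]), intensities=np.array([1.0, -1.0]))


class TestPreprocess:
    def test_constant_profile_with_matching_background_errors(self):
        # a lane that is pure background carries no usable signal
        lane = LaneProfile(
            distances=np.linspace(0, 10, 50), intensities=np.full(50, 7.0)
        )
        with pytest.raises(DataError):
            preprocess_lane(lane, background_rule="constant", background_value=7.0)

    def test_smoother_reproduces_linear_profile(self):
        x = np.linspace(0.0, 10.0, 300)
        y = 5.0 + 2.0 * x
        lane = LaneProfile(distances=x, intensities=y)
        out = preprocess_lane(lane, background_rule="constant", background_value=0.0)
        assert out.intensities == pytest.approx(y, rel=1e-6)

    def test_output_nonnegative_on_noisy_input(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 400)
        lane = LaneProfile(distances=x, intensities=np.abs(rng.normal(5, 2, 400)))
        out = preprocess_lane(lane)
        assert np.all(out.intensities >= 0)

    def test_invalid_df(self):
        lane = LaneProfile(distances=np.linspace(0, 1, 10), intensities=np.ones(10))
        with pytest.raises(ParameterError):
            preprocess_lane(lane, df=1)


class TestCalibration:
    SIZES = (1000.0, 2000.0, 5000.0, 10000.0, 20000.0)

    def test_exact_recovery_from_noiseless_peaks(self):
        positions = [200.0 - 25.0 * math.log(s) for s in self.SIZES]
        lane = gaussian_band_lane(positions)
        calib = fit_calibration([lane], self.SIZES)
        assert calib.a == pytest.approx(200.0, abs=1e-6)
        assert calib.b == pytest.approx(-25.0, abs=1e-6)
        assert calib.r2 == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_from_manual_positions(self):
        positions = [200.0 - 25.0 * math.log(s) for s in self.SIZES]
        calib = fit_calibration([], self.SIZES, manual_positions=positions)
        assert calib.a == pytest.approx(200.0, abs=1e-9)
        assert calib.b == pytest.approx(-25.0, abs=1e-9)

    def test_symmetric_lane_offsets_average_out(self):
        positions = np.array([200.0 - 25.0 * math.log(s) for s in self.SIZES])
        delta = 0.5
        lane_plus = gaussian_band_lane(positions + delta)
        lane_minus = gaussian_band_lane(positions - delta)
        calib = fit_calibration([lane_plus, lane_minus], self.SIZES)
        assert calib.a == pytest.approx(200.0, abs=1e-3)
        assert calib.b == pytest.approx(-25.0, abs=1e-3)

    def test_noisy_peaks_recover_slope_within_standard_error(self):
        from scipy import stats as sstats

        rng = np.random.default_rng(2)
        true = np.array([200.0 - 25.0 * math.log(s) for s in self.SIZES])
        noisy = np.sort(true + rng.normal(0, 0.5, true.size))
        calib = fit_calibration([], self.SIZES, manual_positions=noisy)
        fit = sstats.linregress(np.log(sorted(self.SIZES, reverse=True)), sorted(noisy))
        assert abs(calib.b - (-25.0)) < 3 * fit.stderr

    def test_wrong_peak_count_raises(self):
        lane = gaussian_band_lane([50.0, 100.0])
        with pytest.raises(CalibrationError):
            fit_calibration([lane], self.SIZES)

    def test_needs_two_distinct_sizes(self):
        with pytest.raises(CalibrationError):
            fit_calibration([], (1000.0, 1000.0), manual_positions=[10.0, 20.0])


class TestFragmentCounting:
    CAL = Calibration(a=200.0, b=-25.0, marker_sizes=(), marker_positions=(), r2=1.0)

    def test_count_is_intensity_over_size(self):
        d1000 = 200.0 - 25.0 * math.log(1000.0)
        lane = LaneProfile(
            distances=np.array([d1000 - 1, d1000, d1000 + 1]),
            intensities=np.array([0.0, 500.0, 0.0]),
        )
        dist = fragment_count_profile(lane, self.CAL, d_max=d1000 + 1)
        assert dist.n_sz[1] == pytest.approx(0.5, rel=1e-12)
        assert dist.n_sz[0] == 0.0 and dist.n_sz[2] == 0.0

    def test_mass_identity(self):
        rng = np.random.default_rng(0)
        x = np.linspace(20, 120, 300)
        y = rng.uniform(0, 100, 300)
        lane = LaneProfile(distances=x, intensities=y)
        d_max = 100.0
        dist = fragment_count_profile(lane, self.CAL, d_max)
        kept = x <= d_max
        assert np.dot(dist.sz, dist.n_sz) == pytest.approx(y[kept].sum(), rel=1e-12)

    def test_d_max_outside_profile(self):
        lane = LaneProfile(distances=np.array([0.0, 1.0]), intensities=np.array([1.0, 1.0]))
        with pytest.raises(ParameterError):
            fragment_count_profile(lane, self.CAL, d_max=5.0)


class TestMeanFragmentSize:
    def test_two_interval_mean(self):
        dist = FragmentSizeDistribution(
            sz=np.array([1000.0, 2000.0]), n_sz=np.array([1.0, 1.0]), d_max=0, sz_min=0.0
        )
        mean_raw, mean_corr = mean_fragment_size(dist)
        assert mean_raw == 1500.0
        assert mean_corr == 1500.0  # sz_min=0 -> no correction

    def test_correction_formula(self):
        dist = FragmentSizeDistribution(
            sz=np.array([1000.0]), n_sz=np.array([2.0]), d_max=0, sz_min=1000.0
        )
        _, mean_corr = mean_fragment_size(dist)
        assert mean_corr == pytest.approx(1000.0 * math.exp(-1.0), rel=1e-12)

    def test_truncated_exponential_recovery(self):
        # fragments exponential with mean 20 knt observed above sz_min=500 nt:
        # the correction recovers the true mean within 0.5%
        rng = np.random.default_rng(0)
        lam, sz_min = 20_000.0, 500.0
        sizes = rng.exponential(lam, 400_000)
        sizes = sizes[sizes >= sz_min]
        dist = FragmentSizeDistribution(
            sz=sizes, n_sz=np.ones_like(sizes), d_max=0.0, sz_min=sz_min
        )
        _, mean_corr = mean_fragment_size(dist)
        assert mean_corr == pytest.approx(lam, rel=5e-3)

    def test_empty_distribution(self):
        dist = FragmentSizeDistribution(
            sz=np.array([1000.0]), n_sz=np.array([0.0]), d_max=0, sz_min=0.0
        )
        with pytest.raises(DataError):
            mean_fragment_size(dist)


class TestBreakpointsAndRibos:
    def test_breakpoint_arithmetic(self):
        assert genome_breakpoints(9.28e6, G=9.28e6) == pytest.approx(1.0)
        assert genome_breakpoints(20_000.0, G=9.28e6) == pytest.approx(464.0)
        # linear in G
        assert genome_breakpoints(1000.0, G=2e6) == 2 * genome_breakpoints(1000.0, G=1e6)

    def test_embedded_ribos_differencing(self):
        assert embedded_ribos(1000.0, [450.0, 460.0]) == pytest.approx(545.0)
        assert embedded_ribos(455.0, [450.0, 460.0]) == pytest.approx(0.0)

    def test_negative_result_warns_but_returns(self):
        with pytest.warns(UserWarning):
            assert embedded_ribos(100.0, [450.0]) == pytest.approx(-350.0)

    def test_empty_wildtype_list(self):
        with pytest.raises(DataError):
            embedded_ribos(100.0, [])


class TestWelch:
    def test_hand_computed_example(self):
        # brute-force evaluation of the Welch formulas
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        vx, vy = np.var(x, ddof=1) / 3, np.var(y, ddof=1) / 5
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 4)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert df == pytest.approx(df_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)

    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_symmetric_in_samples(self):
        _, _, p1 = welch_t([1, 2, 3], [4, 5, 6, 7])
        _, _, p2 = welch_t([4, 5, 6, 7], [1, 2, 3])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_requires_two_observations(self):
        with pytest.raises(DataError):
            welch_t([1.0], [1.0, 2.0])


class TestSummarizeRibo:
    def test_identical_strain_and_reference(self):
        table = summarize_ribo(
            {"ref": [450.0, 460.0], "same": [450.0, 460.0]}, reference="ref"
        )
        row = table.set_index("strain").loc["same"]
        assert row["fold"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_per_replicate_then_average_for_kb_per_rn(self):
        # 1/x averaged per replicate differs from the ratio of means
        table = summarize_ribo({"ref": [400.0, 600.0]}, reference="ref", G=9.28e6)
        row = table.iloc[0]
        expected = np.mean([9280.0 / 400.0, 9280.0 / 600.0])
        assert row["kb_per_rn_mean"] == pytest.approx(expected)
        assert row["kb_per_rn_mean"] > 9280.0 / 500.0

    def test_missing_reference(self):
        with pytest.raises(ParameterError):
            summarize_ribo({"a": [1.0]}, reference="b")

    def test_single_replicate_has_nan_p(self):
        table = summarize_ribo(
            {"ref": [450.0, 460.0], "one": [900.0]}, reference="ref"
        )
        assert math.isnan(table.set_index("strain").loc["one", "p_value"])


class TestEndToEndMonotonicity:
    def test_inferred_breakpoints_increase_with_nick_density(self):
        from polfid.gelquant import quantify_lane
        from polfid.simulate import simulate_lane_fragments

        rng = np.random.default_rng(0)
        cfg = SimConfig(seed=0)
        ladder = (48500.0, 20000.0, 10000.0, 5000.0, 2000.0, 1000.0)
        markers = [
            render_gel_lane(np.asarray(ladder), cfg, rng, uniform_mass=True)
            for _ in range(2)
        ]
        calib = fit_calibration(markers, ladder)
        Ns = []
        for rho in (1e-5, 3e-5, 6e-5):
            from dataclasses import replace

            lcfg = replace(cfg, rho=rho)
            lane = render_gel_lane(simulate_lane_fragments(lcfg, rng), lcfg, rng)
            Ns.append(quantify_lane(lane, calib).breakpoints)
        assert Ns[0] < Ns[1] < Ns[2]


def test_format_ribo_summary_rounding():
    table = summarize_ribo({"ref": [457.0], "mut": [1049.0]}, reference="ref")
    out = format_ribo_summary(table).set_index("strain")
    assert out.loc["ref", "per_mb_mean"] == 49
    assert out.loc["mut", "fold"] == pytest.approx(2.30)
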