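"""Scale grid, complex-Gaussian CWT, smoothed wavelet coherence, shuffled
pairs and profile summaries."""

import numpy as np
import pandas as pd
import pytest

from dyadnirs import (
    DyadAssignment,
    build_scale_grid,
    coherence_profile,
    cwt,
    dyad_coherence,
    generate_paradigm,
    make_shuffled_pairs,
    wavelet_coherence,
)

RATE = 8.13


def _direct_cgau_cwt(x, period, rate, order=3):
    """Independent oracle: direct convolution with an explicitly sampled
    complex-Gaussian (derivative-of-Gaussian) wavelet."""
    import pywt

    wav = pywt.ContinuousWavelet(f"cgau{order}")
    fc = pywt.central_frequency(wav)
    scale = fc * rate * period
    psi, t = wav.wavefun(length=4096)
    # sample psi at scale: psi((k - n/2)/scale) over integer lags
    half = int(np.ceil(scale * (t[-1] - t[0]) / 2))
    lags = np.arange(-half, half + 1)
    u = lags / scale + (t[0] + t[-1]) / 2
    kernel = np.interp(u, t, psi.real) + 1j * np.interp(u, t, psi.imag)
    return np.convolve(x, np.conj(kernel[::-1]), mode="same") / np.sqrt(scale)


class TestScaleGrid:
    def test_defaults_give_16_periods_from_2_5s(self):
        grid = build_scale_grid()
        assert grid.n_scales == 16
        assert grid.periods[0] == 2.5
        assert 30.0 < grid.periods[-1] < 35.0  # four octaves above 2.5 s

    def test_log_spacing_doubles_per_octave(self):
        grid = build_scale_grid()
        np.testing.assert_allclose(grid.periods[4] / grid.periods[0], 2.0)

    def test_linear_spacing_increments_by_base(self):
        grid = build_scale_grid(spacing="linear")
        np.testing.assert_allclose(np.diff(grid.periods), 2.5)
        assert grid.n_scales == 16

    def test_single_octave_single_voice(self):
        grid = build_scale_grid(octaves=1, voices_per_octave=1, base_period=4.0)
        np.testing.assert_array_equal(grid.periods, [4.0])

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            build_scale_grid(base_period=0.0)


class TestCwt:
    def test_zero_signal_gives_zero_coefficients(self):
        grid = build_scale_grid()
        w = cwt(np.zeros(400), grid, RATE)
        assert w.shape == (16, 400)
        assert np.abs(w).max() == 0.0

    def test_sinusoid_power_peaks_at_matching_period(self):
        grid = build_scale_grid()
        t = np.arange(int(RATE * 400)) / RATE
        x = np.sin(2 * np.pi * t / 10.0)  # 10 s period
        w = cwt(x, grid, RATE)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        power = (np.abs(w[:, core]) ** 2).mean(axis=1)
        assert np.argmax(power) == grid.nearest(10.0)

    def test_matches_direct_convolution_oracle(self):
        grid = build_scale_grid()
        rng = np.random.default_rng(0)
        t = np.arange(int(RATE * 200)) / RATE
        x = np.sin(2 * np.pi * t / 10.0) + 0.3 * rng.standard_normal(len(t))
        w = cwt(x, grid, RATE)
        k = grid.nearest(10.0)
        oracle = _direct_cgau_cwt(x, grid.periods[k], RATE)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        r = np.corrcoef(np.abs(w[k, core]), np.abs(oracle[core]))[0, 1]
        assert r > 0.99

    def test_linearity(self):
        grid = build_scale_grid()
        x = np.random.default_rng(1).standard_normal(300)
        np.testing.assert_allclose(cwt(3 * x, grid, RATE), 3 * cwt(x, grid, RATE),
                                   atol=1e-10)

    def test_subsample_period_rejected(self):
        grid = build_scale_grid(base_period=0.1)
        with pytest.raises(ValueError, match="2 samples"):
            cwt(np.zeros(100), grid, RATE)


class TestWaveletCoherence:
    def test_self_coherence_is_one(self):
        grid = build_scale_grid()
        x = np.random.default_rng(2).standard_normal(800)
        msc = wavelet_coherence(x, x, grid, RATE)
        np.testing.assert_allclose(msc, 1.0, atol=1e-10)

    def test_values_in_unit_interval(self):
        grid = build_scale_grid()
        rng = np.random.default_rng(3)
        msc = wavelet_coherence(rng.standard_normal(600), rng.standard_normal(600),
                                grid, RATE)
        assert msc.min() >= 0.0 and msc.max() <= 1.0

    def test_symmetry(self):
        grid = build_scale_grid()
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(500), rng.standard_normal(500)
        np.testing.assert_allclose(
            wavelet_coherence(x, y, grid, RATE),
            wavelet_coherence(y, x, grid, RATE),
            atol=1e-12,
        )

    def test_zero_variance_input_flagged_as_nan(self):
        grid = build_scale_grid()
        msc = wavelet_coherence(np.zeros(300), np.random.default_rng(5).standard_normal(300),
                                grid, RATE)
        assert np.isnan(msc).all()

    def test_unsmoothed_estimator_guarded(self):
        # without smoothing MSC would be identically 1 for any pair
        grid = build_scale_grid()
        with pytest.raises(ValueError, match="smooth"):
            wavelet_coherence(np.ones(100), np.ones(100), grid, RATE,
                              window_periods=0.0)

    def test_independent_noise_below_permutation_95th_percentile(self):
        """Mean MSC of one independent pair sits inside the permutation null."""
        grid = build_scale_grid(octaves=3)  # periods 2.5-14 s, shorter series ok
        rng = np.random.default_rng(6)
        n = 1600
        null = np.array([
            wavelet_coherence(rng.standard_normal(n), rng.standard_normal(n),
                              grid, RATE).mean()
            for _ in range(200)
        ])
        probe = wavelet_coherence(rng.standard_normal(n), rng.standard_normal(n),
                                  grid, RATE).mean()
        assert probe < np.quantile(null, 0.95)


class TestDyadCoherence:
    def test_identical_residuals_give_unit_coherence(self):
        paradigm = generate_paradigm(["live", "static"], n_repeats=1)
        grid = build_scale_grid()
        n = int(paradigm.run_length * RATE)
        x = np.random.default_rng(7).standard_normal(n)
        out = dyad_coherence(x, x, paradigm, RATE, grid)
        for cond in ("live", "static"):
            np.testing.assert_allclose(out[cond], 1.0, atol=1e-10)

    def test_one_value_per_period_per_condition(self):
        paradigm = generate_paradigm(["live", "static"], n_repeats=2)
        grid = build_scale_grid()
        n = int(paradigm.run_length * RATE)
        rng = np.random.default_rng(8)
        out = dyad_coherence(rng.standard_normal(n), rng.standard_normal(n),
                             paradigm, RATE, grid)
        assert set(out) == {"live", "static"}
        assert all(v.shape == (16,) for v in out.values())

    def test_live_only_coupling_separates_conditions_at_target_scale(self):
        from conftest import synth_residual_pair

        paradigm = generate_paradigm(["live", "static"], n_repeats=2)
        grid = build_scale_grid()
        n = int(paradigm.run_length * RATE)
        gate = paradigm.run_sample_mask("live", RATE, n).astype(float)
        rng = np.random.default_rng(9)
        x, y = synth_residual_pair(rng, n, RATE, coupling_amplitude=1.5,
                                   coupling_period_s=20.0, gate=gate)
        out = dyad_coherence(x, y, paradigm, RATE, grid)
        k = grid.nearest(20.0)
        assert out["live"][k] > out["static"][k]

    def test_missing_condition_rejected(self):
        paradigm = generate_paradigm(["live"], n_repeats=1)
        grid = build_scale_grid()
        n = int(paradigm.run_length * RATE)
        with pytest.raises(ValueError, match="static"):
            dyad_coherence(np.random.default_rng(10).standard_normal(n),
                           np.random.default_rng(11).standard_normal(n),
                           paradigm, RATE, grid, conditions=["static"])


class TestShuffledPairs:
    def _real(self, n):
        return DyadAssignment(pairs=[(i, i) for i in range(n)], kind="real")

    def test_twenty_dyads_give_twenty_nonreal_pairs(self):
        shuffled = make_shuffled_pairs(self._real(20), seed=1)
        assert len(shuffled.pairs) == 20
        real_set = set(self._real(20).pairs)
        assert all(p not in real_set for p in shuffled.pairs)
        assert all(a != b for a, b in shuffled.pairs)  # cross-site derangement

    def test_two_dyads_give_the_unique_swap(self):
        shuffled = make_shuffled_pairs(self._real(2), seed=5)
        assert sorted(shuffled.pairs) == [(0, 1), (1, 0)]

    def test_deterministic_per_seed(self):
        a = make_shuffled_pairs(self._real(10), seed=3)
        b = make_shuffled_pairs(self._real(10), seed=3)
        assert a.pairs == b.pairs

    def test_single_dyad_rejected(self):
        with pytest.raises(ValueError):
            make_shuffled_pairs(self._real(1))


class TestProfile:
    def test_single_dyad_mean_is_value_sd_zero(self):
        df = pd.DataFrame({
            "dyad": ["d1"] * 2, "kind": ["real"] * 2, "condition": ["live"] * 2,
            "period_s": [2.5, 5.0], "msc": [0.3, 0.6],
        })
        prof = coherence_profile(df)
        np.testing.assert_array_equal(prof["mean"], [0.3, 0.6])
        np.testing.assert_array_equal(prof["sd"], [0.0, 0.0])
        assert (prof["n"] == 1).all()

    def test_mean_bounded_by_dyad_extremes(self):
        rng = np.random.default_rng(12)
        rows = [
            {"dyad": f"d{d}", "kind": "real", "condition": "live",
             "period_s": p, "msc": rng.uniform()}
            for d in range(20) for p in (2.5, 5.0, 10.0)
        ]
        df = pd.DataFrame(rows)
        prof = coherence_profile(df)
        for p in (2.5, 5.0, 10.0):
            vals = df[df.period_s == p]["msc"]
            m = prof[prof.period_s == p]["mean"].iloc[0]
            assert vals.min() <= m <= vals.max()
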