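"""Grid-search estimation and sigmoid lag-time extraction tests.

Recovery tests run on the 10-species lateral model, which integrates in
milliseconds; the full-scale 2652-species recovery lives in the acceptance
suite.
"""

import dataclasses

import numpy as np
import pytest

from abkinetics import (
    ExperimentDesign,
    FitError,
    GridSpec,
    KineticParams,
    ObservableSeries,
    baseline_subtract,
    fit_sigmoid,
    generate_dls_dataset,
    grid_search,
    lag_time_comparison,
    r_squared,
    sse,
)
from abkinetics.fitting import interpolate_signal

REDUCED_GRID = GridSpec(
    forward_values=tuple(10.0 ** np.arange(-2, 3)),
    reverse_values=tuple(10.0 ** np.arange(-4, 1)),
)


def series(signal, times=None, modality="ThT", **meta):
    signal = np.asarray(signal, dtype=float)
    if times is None:
        times = np.arange(len(signal), dtype=float)
    return ObservableSeries(times=times, signal=signal, modality=modality, **meta)


class TestErrorMetrics:
    def test_sse_identical_and_offset(self):
        a = series([1.0, 2.0, 3.0, 4.0, 5.0])
        assert sse(a, a) == 0.0
        assert sse(series(a.signal + 1), a) == pytest.approx(5.0)

    def test_sse_symmetric(self):
        a, b = series([1.0, 4.0, 2.0]), series([0.0, 1.0, 7.0])
        assert sse(a, b) == sse(b, a)

    def test_modality_mismatch(self):
        with pytest.raises(ValueError, match="modality"):
            sse(series([1.0, 2.0]), series([1.0, 2.0], modality="DLS"))

    def test_r_squared_bounds(self):
        data = series([1.0, 2.0, 3.0, 6.0])
        assert r_squared(data, data) == pytest.approx(1.0)
        flat = series(np.full(4, data.signal.mean()))
        assert r_squared(flat, data) == pytest.approx(0.0)

    def test_r_squared_constant_data(self):
        with pytest.raises(FitError):
            r_squared(series([1.0, 2.0, 3.0]), series([2.0, 2.0, 2.0]))

    def test_interpolation_matches_dense_signal(self):
        t = np.linspace(0, 1, 51)
        s = series(np.sin(t * 3), times=t)
        fine = interpolate_signal(s, np.linspace(0, 1, 101))
        np.testing.assert_allclose(fine.signal, np.sin(fine.times * 3), atol=5e-4)


class TestGridSpec:
    def test_coarse_cardinality(self):
        assert GridSpec().n_coarse == 225

    def test_ladders_span_printed_ranges(self):
        g = GridSpec()
        assert g.forward_values[0] == pytest.approx(1e-6)
        assert g.forward_values[-1] == pytest.approx(1e8)
        assert g.reverse_values[0] == pytest.approx(1e-8)
        assert g.reverse_values[-1] == pytest.approx(1e6)

    def test_refine_window_contains_reported_optima(self):
        g = GridSpec()
        assert 9.0e3 in g.refine_values(1.0e4)
        assert 4.5e2 in g.refine_values(1.0e3)
        assert 6.0e-3 in g.refine_values(1.0e-2)


def make_dls_data(k_la, k_la_rev, seed=0, noise=0.0):
    params = KineticParams(k_la=k_la, k_la_rev=k_la_rev)
    design = dataclasses.replace(
        ExperimentDesign.dls_default(seed=seed),
        noise_sigma_frac=noise,
        baseline_offset_frac=0.05 if noise else 0.0,
    )
    data, _ = generate_dls_dataset(params, design)
    return baseline_subtract(data)


class TestGridSearch:
    def test_on_grid_self_recovery(self, lateral_model):
        """Noise-free data generated at an on-grid pair is recovered exactly."""
        for truth in [(1.0, 1e-2), (10.0, 1e-1)]:
            data = make_dls_data(*truth)
            res = grid_search(
                lateral_model, [data], grid=REDUCED_GRID,
                target_pair="lateral", refine=False,
            )
            assert (res.best_forward, res.best_reverse) == truth
            assert res.best_sse == 0.0
            assert res.r2_mean == pytest.approx(1.0, abs=1e-6)

    def test_coarse_scan_visits_full_grid(self, lateral_model):
        data = make_dls_data(1.0, 1e-2)
        res = grid_search(
            lateral_model, [data], grid=REDUCED_GRID,
            target_pair="lateral", refine=False,
        )
        coarse = res.sse_surface[res.sse_surface.stage == "coarse"]
        assert len(coarse) == REDUCED_GRID.n_coarse
        assert res.best_sse == res.sse_surface.sse.min()

    def test_off_grid_recovery_with_refinement(self, lateral_model):
        """Refinement reaches the off-grid generating pair (0.9, 6e-3)."""
        data = make_dls_data(0.9, 6.0e-3)
        res = grid_search(
            lateral_model, [data], grid=REDUCED_GRID, target_pair="lateral"
        )
        assert res.best_forward == pytest.approx(0.9)
        assert res.best_reverse == pytest.approx(6.0e-3)

    def test_noisy_replicate_recovery(self, lateral_model):
        """With 2% additive noise the generating on-grid pair is recovered
        in at least 95 of 100 seeded replicates."""
        truth = (1.0, 1.0)
        hits = 0
        for seed in range(100):
            data = make_dls_data(*truth, seed=seed, noise=0.02)
            res = grid_search(
                lateral_model, [data], grid=REDUCED_GRID,
                target_pair="lateral", refine=False,
            )
            hits += (res.best_forward, res.best_reverse) == truth
        assert hits >= 95

    def test_mixed_modalities_rejected(self, lateral_model):
        with pytest.raises(ValueError, match="modalities"):
            grid_search(
                lateral_model,
                [series([0.0, 1.0]), series([0.0, 1.0], modality="DLS")],
                grid=REDUCED_GRID, target_pair="lateral",
            )

    def test_requires_datasets(self, lateral_model):
        with pytest.raises(ValueError):
            grid_search(lateral_model, [], grid=REDUCED_GRID, target_pair="lateral")


class TestSigmoidFit:
    @staticmethod
    def logistic(t, y0, amp, t_half, b):
        return y0 + amp / (1 + np.exp(-(t - t_half) / b))

    def test_exact_recovery(self):
        """y0=0, A=100, t½=50 h, b=5 h → lag 40 h, k_app 0.2 /h."""
        t = np.linspace(0, 100, 201)
        fit = fit_sigmoid(series(self.logistic(t, 0, 100, 50, 5), times=t))
        assert fit.t_half == pytest.approx(50, rel=1e-4)
        assert fit.b_sig == pytest.approx(5, rel=1e-4)
        assert fit.lag_time == pytest.approx(40, rel=1e-3)
        assert fit.k_app == pytest.approx(0.2, rel=1e-3)

    def test_time_shift_equivariance(self):
        t = np.linspace(0, 100, 201)
        y = self.logistic(t, 2, 80, 45, 4)
        f0 = fit_sigmoid(series(y, times=t))
        f1 = fit_sigmoid(series(y, times=t + 10))
        assert f1.lag_time == pytest.approx(f0.lag_time + 10, rel=1e-3)
        assert f1.k_app == pytest.approx(f0.k_app, rel=1e-6)

    def test_scale_invariance(self):
        t = np.linspace(0, 100, 201)
        y = self.logistic(t, 0, 50, 60, 8)
        f0 = fit_sigmoid(series(y, times=t))
        f1 = fit_sigmoid(series(7.5 * y, times=t))
        assert f1.lag_time == pytest.approx(f0.lag_time, rel=1e-6)
        assert f1.k_app == pytest.approx(f0.k_app, rel=1e-6)

    def test_flat_series_rejected(self):
        with pytest.raises(FitError, match="flat"):
            fit_sigmoid(series(np.full(20, 3.0)))


class TestLagTimeComparison:
    INSULIN_DERIVED = KineticParams(k_nu1=1.38, k_nu_rev=1.01e-3, k_fb1=1.37e4, k_fb_rev=3.02e2)

    def test_lag_decreases_with_concentration(self):
        tab = lag_time_comparison(
            self.INSULIN_DERIVED, n=6, initial_monomer_concs_mM=[0.01, 0.05, 0.1], max_size=50
        )
        lags = tab.lag_time_h.to_numpy()
        assert np.all(np.diff(lags) < 0)

    def test_faster_kinetics_shorten_lag(self):
        fast = dataclasses.replace(
            self.INSULIN_DERIVED, k_nu1=2 * self.INSULIN_DERIVED.k_nu1, k_fb1=2 * self.INSULIN_DERIVED.k_fb1
        )
        concs = [0.01, 0.1]
        slow_tab = lag_time_comparison(self.INSULIN_DERIVED, 6, concs, max_size=50)
        fast_tab = lag_time_comparison(fast, 6, concs, max_size=50)
        assert np.all(
            fast_tab.lag_time_h.to_numpy() < slow_tab.lag_time_h.to_numpy()
        )

    def test_no_growth_raises_flat_error(self):
        dead = KineticParams(k_nu1=0.0, k_fb1=0.0)
        with pytest.raises(FitError):
            lag_time_comparison(dead, 6, [0.05], max_size=50)
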