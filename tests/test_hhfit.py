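"""Single-site Henderson-Hasselbalch fitting and F-test model selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkashift.hhfit import (
    FitError,
    TitrationCurve,
    f_test_model_selection,
    fit_hh,
    hh_model,
)
from pkashift.synth import SimulationSpec, simulate_single_site

GRID = np.linspace(1.2, 6.7, 15)


def make_curve(pka, dA=177.5, dB=180.9, n=1.0, noise=0.0, seed=0, grid=GRID):
    rng = np.random.default_rng(seed)
    shift = hh_model(grid, pka, dA, dB, n) + rng.normal(0, noise, grid.shape)
    return TitrationCurve("D2", "folded", 298.0, grid, shift)


class TestHHModel:
    def test_midpoint_is_plateau_mean(self):
        assert hh_model(4.0, 4.0, 177.0, 181.0) == pytest.approx(179.0)

    def test_plateau_limits(self):
        assert hh_model(-20.0, 4.0, 177.0, 181.0) == pytest.approx(177.0, abs=1e-9)
        assert hh_model(30.0, 4.0, 177.0, 181.0) == pytest.approx(181.0, abs=1e-9)

    def test_hand_computed_value_one_unit_above_pka(self):
        # 10^(5.17-4.17) = 10, so delta = (179.0 + 1835.0) / 11
        val = hh_model(5.17, 4.17, 179.0, 183.5, 1.0)
        assert val == pytest.approx((179.0 + 183.5 * 10.0) / 11.0, abs=1e-12)
        assert val == pytest.approx(183.0909090909, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pka=st.floats(2.0, 6.0),
        n=st.floats(0.5, 2.0),
        dpH=st.floats(0.1, 5.0),
    )
    def test_symmetric_about_midpoint(self, pka, n, dpH):
        lo = hh_model(pka - dpH, pka, 0.0, 1.0, n)
        hi = hh_model(pka + dpH, pka, 0.0, 1.0, n)
        assert lo + hi == pytest.approx(1.0, abs=1e-9)


class TestTitrationCurve:
    def test_points_sorted_on_construction(self):
        c = TitrationCurve("E6", "folded", 298.0, GRID[::-1], np.arange(15.0) + 170)
        assert np.all(np.diff(c.pH) > 0)

    @pytest.mark.parametrize(
        "ph, err",
        [
            (np.array([1, 2, 3, 4]), "at least"),
            (np.array([1, 2, 3, 4, 15.0]), r"\[0, 14\]"),
            (np.array([1, 2, 3, 4, 4.0]), "duplicate"),
        ],
    )
    def test_invalid_series_rejected(self, ph, err):
        with pytest.raises(ValueError, match=err):
            TitrationCurve("E6", "folded", 298.0, ph, np.linspace(177, 181, len(ph)))


class TestFitHH:
    @pytest.mark.parametrize("pka", [3.13, 4.19, 2.50])
    def test_noiseless_recovery_is_exact(self, pka):
        r = fit_hh(make_curve(pka), fix_hill=True)
        assert r.pka == pytest.approx(pka, abs=1e-6)
        assert r.rss == pytest.approx(0.0, abs=1e-12)

    def test_free_hill_recovers_generating_exponent(self):
        r = fit_hh(make_curve(4.0, n=1.4), fix_hill=False)
        assert r.hill == pytest.approx(1.4, abs=1e-5)
        assert not r.hill_fixed

    def test_point_order_does_not_change_the_fit(self, rng):
        c = make_curve(3.8, noise=0.03, seed=11)
        perm = rng.permutation(c.n_points)
        shuffled = TitrationCurve("D2", "folded", 298.0, c.pH[perm], c.shift[perm])
        a, b = fit_hh(c, fix_hill=True), fit_hh(shuffled, fix_hill=True)
        assert a.pka == pytest.approx(b.pka, abs=1e-12)
        assert a.rss == pytest.approx(b.rss, abs=1e-12)

    def test_optimum_beats_perturbed_parameters(self):
        c = make_curve(3.5, noise=0.05, seed=3)
        r = fit_hh(c, fix_hill=True)
        for dp in (0.05, -0.05):
            rss = np.sum((c.shift - hh_model(c.pH, r.pka + dp, r.delta_A, r.delta_B)) ** 2)
            assert r.rss <= rss

    def test_flat_curve_reports_no_transition(self):
        c = TitrationCurve(
            "D2", "folded", 298.0, GRID, np.full_like(GRID, 178.0) + 0.001 * GRID
        )
        with pytest.raises(ValueError, match="floor"):
            fit_hh(c)

    def test_extrapolated_pka_warns(self):
        c = make_curve(1.2, grid=np.linspace(2.5, 6.7, 12))
        with pytest.warns(UserWarning, match="outside the sampled"):
            fit_hh(c, fix_hill=True)

    def test_noisy_replicates_recover_truth_and_error_scale(self):
        # empirical spread of the estimator should match the reported
        # covariance-based standard error reasonably well
        truth = 3.13
        spec = SimulationSpec(
            "single_site", pka=truth, noise_sd=0.05, n_replicates=200, seed=42
        )
        fits = [fit_hh(c, fix_hill=True) for c in simulate_single_site(spec)]
        est = np.array([f.pka for f in fits])
        assert abs(est.mean() - truth) < 0.02
        reported = np.median([f.pka_err for f in fits])
        assert 0.3 < est.std() / reported < 3.0

    def test_bootstrap_error_agrees_with_covariance_error(self):
        c = make_curve(3.6, noise=0.05, seed=5)
        cov = fit_hh(c, fix_hill=True)
        boot = fit_hh(c, fix_hill=True, n_boot=200, seed=6)
        assert boot.pka_err == pytest.approx(cov.pka_err, rel=0.5)

    def test_biphasic_curve_is_flagged_for_coupled_analysis(self):
        from pkashift.synth import simulate_coupled_pair

        # sampled densely enough for the runs test to resolve the lack of fit
        spec = SimulationSpec(
            "coupled_pair", seed=2, noise_sd=0.01, ph_grid=np.linspace(1.2, 6.7, 25)
        )
        c1, c2 = simulate_coupled_pair(spec)
        assert fit_hh(c1, fix_hill=False).biphasic_candidate
        assert fit_hh(c2, fix_hill=False).biphasic_candidate

    def test_clean_single_site_curves_are_not_flagged(self):
        spec = SimulationSpec(
            "single_site", pka=3.69, noise_sd=0.03, n_replicates=50, seed=5
        )
        flags = sum(
            fit_hh(c, fix_hill=False).biphasic_candidate
            for c in simulate_single_site(spec)
        )
        assert flags <= 2  # detector stays quiet on genuinely monophasic data


class TestFTest:
    def test_equal_rss_keeps_the_simpler_model(self):
        c = make_curve(3.5)
        free, fixed = fit_hh(c, fix_hill=False), fit_hh(c, fix_hill=True)
        sel = f_test_model_selection(free, fixed)
        assert sel.chosen.hill_fixed
        assert sel.p_value > 0.99

    def test_unit_hill_data_usually_keep_fixed_model(self):
        spec = SimulationSpec(
            "single_site", pka=3.69, noise_sd=0.03, n_replicates=200, seed=9
        )
        kept = 0
        for c in simulate_single_site(spec):
            sel = f_test_model_selection(fit_hh(c, False), fit_hh(c, True), alpha=0.05)
            kept += sel.chosen.hill_fixed
        assert kept >= 180  # >= 90 % of replicates

    def test_shallow_hill_data_select_the_free_model(self):
        c = make_curve(4.0, n=0.6, noise=0.005, seed=1)
        sel = f_test_model_selection(fit_hh(c, False), fit_hh(c, True))
        assert not sel.chosen.hill_fixed
        assert sel.p_value < 0.05

    def test_insufficient_points_rejected(self):
        c = make_curve(4.0, grid=np.linspace(2, 6, 5))
        free, fixed = fit_hh(c, fix_hill=False), fit_hh(c, fix_hill=True)
        # pretend one point fewer than the 4 free parameters allow
        free.n_points = fixed.n_points = 4
        with pytest.raises(ValueError, match="points"):
            f_test_model_selection(free, fixed)
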