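"""Fitting-protocol tests: error floor, Rex filter, grid search, global
fit, Monte-Carlo and jackknife."""

import warnings

import numpy as np
import pytest

from lidex.dispersion_fit import (
    DispersionCurve,
    DispersionDataset,
    apply_error_floor,
    filter_curves,
    global_fit,
    grid_search,
    jackknife_probes,
    monte_carlo_errors,
    rex_estimate,
)
from lidex.exchange_model import (
    CpmgSchedule,
    DispersionPoint,
    ExchangeParameters,
    NucleusMode,
    ProbeParameters,
)
from lidex.synthetic_data import gen_dispersion_dataset, wt_like_truth

from conftest import make_noiseless_dataset, small_probes

SHORT_SCHEDULE = CpmgSchedule(
    NucleusMode.CH3_MQ, 0.030, tuple(n / 0.060 for n in (4, 8, 14, 24, 40, 70, 120))
)


class TestErrorFloor:
    def test_floor_engages_below_two_percent(self):
        assert apply_error_floor(50.0, 0.5) == 1.0

    def test_floor_inactive_above(self):
        assert apply_error_floor(50.0, 2.0) == 2.0

    def test_zero_rate_keeps_raw_error(self):
        assert apply_error_floor(0.0, 0.3) == 0.3

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_error_floor(-1.0, 0.1)
        with pytest.raises(ValueError):
            apply_error_floor(1.0, -0.1)


def flat_curve(pid="flat", value=20.0, field=850.0):
    pts = [DispersionPoint(field, nu, value, 0.4)
           for nu in SHORT_SCHEDULE.nu_list]
    probe = ProbeParameters(pid, NucleusMode.CH3_MQ, 0.0,
                            r2_base={field: value})
    return DispersionCurve(probe, pts)


def sloped_curve(pid, rex, base=20.0, field=850.0):
    nu = np.asarray(SHORT_SCHEDULE.nu_list)
    decay = rex * (1 - (nu - nu[0]) / (nu[-1] - nu[0]))
    pts = [DispersionPoint(field, float(v), float(base + d), 0.4)
           for v, d in zip(nu, decay)]
    probe = ProbeParameters(pid, NucleusMode.CH3_MQ, 1.0,
                            r2_base={field: base})
    return DispersionCurve(probe, pts)


class TestRexEstimateAndFilter:
    def test_flat_curve_zero(self):
        assert rex_estimate(flat_curve().points) == 0.0

    def test_difference_of_extremes(self):
        pts = [DispersionPoint(850.0, 200 / 3, 25.0, 0.5),
               DispersionPoint(850.0, 2000.0, 20.0, 0.5)]
        assert rex_estimate(pts) == pytest.approx(5.0)

    def test_matches_forward_model(self, wt_exchange, mq_schedule):
        probes = small_probes(1)
        data = make_noiseless_dataset(wt_exchange, probes)
        curve = next(iter(data.curves.values()))
        by_field = {}
        for p in curve.points:
            by_field.setdefault(p.field_MHz, []).append(p)
        expected = max(
            max(pts, key=lambda p: -p.nu_cpmg).r2eff
            - max(pts, key=lambda p: p.nu_cpmg).r2eff
            for pts in by_field.values()
        )
        assert rex_estimate(curve.points) == pytest.approx(expected, abs=1e-12)

    def test_threshold_is_inclusive(self):
        data = DispersionDataset(
            {
                "a": sloped_curve("a", 0.5),
                "b": sloped_curve("b", 2.0),
                "c": sloped_curve("c", 8.0),
            },
            {NucleusMode.CH3_MQ: SHORT_SCHEDULE},
        )
        kept = filter_curves(data, rex_min=2.0)
        assert sorted(kept.curves) == ["b", "c"]
        assert kept.excluded_probes == ["a"]

    def test_all_flat_warns_and_empties(self):
        data = DispersionDataset(
            {"a": flat_curve("a"), "b": flat_curve("b")},
            {NucleusMode.CH3_MQ: SHORT_SCHEDULE},
        )
        with pytest.warns(UserWarning):
            kept = filter_curves(data)
        assert not kept.curves

    def test_synthetic_wt_dataset_fully_retained(self, small_noisy_dataset):
        data, _ = small_noisy_dataset
        assert len(filter_curves(data).curves) == len(data.curves)


class TestGridSearch:
    def test_noise_free_node_self_consistency(self, wt_exchange):
        """Data generated exactly at a grid node: chi2 ~ 0 there and the
        argmin lands on the generating node."""
        probes = small_probes(2)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        kex_axis = np.array([1000.0, 2490.0, 5000.0])
        p_axis = np.array([0.01, 0.032, 0.08])
        grid = grid_search(data, kex_axis, p_axis)
        assert grid.argmin == (2490.0, 0.032)
        assert grid.chi2_surface[1, 1] < 1e-6

    def test_unidentifiable_flat_surface_flagged(self):
        data = DispersionDataset(
            {"a": flat_curve("a"), "b": flat_curve("b")},
            {NucleusMode.CH3_MQ: SHORT_SCHEDULE},
        )
        with pytest.warns(UserWarning, match="not identifiable"):
            grid = grid_search(data, np.array([500.0, 2000.0, 8000.0]),
                               np.array([0.01, 0.05, 0.1]))
        assert grid.warnings

    def test_fast_exchange_ridge_reported(self):
        """Data in the fast-exchange limit constrain only p*dw^2/k_ex, so
        near-minimal nodes span a wide k_ex range and are flagged."""
        truth = wt_like_truth(seed=2, n_probes=4,
                              exch=ExchangeParameters(0.1, 20000.0, 293.0))
        data = filter_curves(gen_dispersion_dataset(truth))
        with pytest.warns(UserWarning, match="fast exchange"):
            grid = grid_search(data, np.geomspace(8000, 100000, 6),
                               np.linspace(0.05, 0.4, 4))
        assert grid.warnings

    def test_axes_must_increase(self, small_noisy_dataset):
        data, _ = small_noisy_dataset
        with pytest.raises(ValueError):
            grid_search(data, np.array([2000.0, 1000.0]), np.array([0.01, 0.02]))


class TestGlobalFit:
    def test_noise_free_recovery_to_four_digits(self, wt_exchange):
        probes = small_probes(5)
        data = make_noiseless_dataset(wt_exchange, probes)
        fit = global_fit(data, (2000.0, 0.02))
        assert fit.exch.k_ex == pytest.approx(2490.0, rel=2e-4)
        assert fit.exch.p_excited == pytest.approx(0.032, rel=2e-4)
        fitted = {p.probe_id: p for p in fit.probes}
        for probe in probes:
            assert fitted[probe.probe_id].dw_X == pytest.approx(probe.dw_X,
                                                                rel=1e-3)

    def test_chi2_not_above_grid_node(self, small_noisy_dataset):
        data, _ = small_noisy_dataset
        grid = grid_search(data, np.geomspace(800, 6000, 5),
                           np.linspace(0.01, 0.08, 4))
        fit = global_fit(data, grid.argmin)
        assert fit.chi2 <= grid.chi2_min + 1e-6
        assert fit.provenance == grid.argmin

    def test_invariant_to_curve_and_point_order(self, small_noisy_dataset):
        data, _ = small_noisy_dataset
        shuffled = DispersionDataset(
            {
                pid: DispersionCurve(c.probe, list(reversed(c.points)))
                for pid, c in reversed(list(data.curves.items()))
            },
            data.schedules,
            data.temperature,
        )
        fit1 = global_fit(data, (2000.0, 0.03))
        fit2 = global_fit(shuffled, (2000.0, 0.03))
        assert fit1.exch.k_ex == pytest.approx(fit2.exch.k_ex, rel=1e-6)
        assert fit1.exch.p_excited == pytest.approx(fit2.exch.p_excited,
                                                    rel=1e-6)

    def test_duplicate_curve_leaves_parameters_unchanged(self, wt_exchange):
        probes = small_probes(3)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        fit_ref = global_fit(data, (2000.0, 0.02))
        dup = dict(data.curves)
        first = next(iter(data.curves.values()))
        dup["dup-probe"] = DispersionCurve(
            ProbeParameters("dup-probe", first.probe.nucleus_mode,
                            first.probe.dw_X, first.probe.dw_H,
                            r2_base=dict(first.probe.r2_base)),
            list(first.points),
        )
        fit_dup = global_fit(
            DispersionDataset(dup, data.schedules, data.temperature),
            (2000.0, 0.02),
        )
        assert fit_dup.exch.k_ex == pytest.approx(fit_ref.exch.k_ex, rel=1e-4)
        assert fit_dup.exch.p_excited == pytest.approx(fit_ref.exch.p_excited,
                                                       rel=1e-3)


@pytest.fixture(scope="module")
def fitted(small_noisy_dataset):
    data, _ = small_noisy_dataset
    return data, global_fit(data, (2000.0, 0.03))


class TestMonteCarlo:
    def test_same_seed_reproduces_uncertainties(self, fitted):
        data, fit = fitted
        u1 = monte_carlo_errors(data, fit, n_repeats=6, seed=42).uncertainties
        u2 = monte_carlo_errors(data, fit, n_repeats=6, seed=42).uncertainties
        assert u1 == u2

    def test_vanishing_noise_gives_vanishing_spread(self, wt_exchange):
        probes = small_probes(3)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        tiny = DispersionDataset(
            {
                pid: DispersionCurve(
                    c.probe,
                    [DispersionPoint(p.field_MHz, p.nu_cpmg, p.r2eff, 1e-6)
                     for p in c.points],
                )
                for pid, c in data.curves.items()
            },
            data.schedules,
            data.temperature,
        )
        fit = global_fit(tiny, (2490.0, 0.032))
        out = monte_carlo_errors(tiny, fit, n_repeats=4, seed=0)
        assert out.uncertainties["k_ex"] < 1.0
        assert out.uncertainties["p_excited"] < 1e-4

    def test_mc_spread_consistent_with_regeneration_spread(self, wt_exchange):
        """MC std of k_ex within a factor of ~2 of the across-seed std."""
        kex_fits = []
        for seed in range(6):
            truth = wt_like_truth(seed=100 + seed, n_probes=4,
                                  exch=wt_exchange)
            d = gen_dispersion_dataset(truth)
            kex_fits.append(global_fit(d, (2490.0, 0.032)).exch.k_ex)
        across = np.std(kex_fits)
        truth = wt_like_truth(seed=100, n_probes=4, exch=wt_exchange)
        d = gen_dispersion_dataset(truth)
        fit = global_fit(d, (2490.0, 0.032))
        mc = monte_carlo_errors(d, fit, n_repeats=10, seed=1)
        ratio = mc.uncertainties["k_ex"] / across
        assert 0.3 < ratio < 3.0


class TestJackknife:
    def test_homogeneous_dataset_unflagged(self, wt_exchange):
        probes = small_probes(4)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        fit = global_fit(data, (2490.0, 0.032))
        report = jackknife_probes(data, fit, kex_std=25.0)
        assert report.flagged == []
        assert set(report.results) == set(data.curves)

    def test_outlier_probe_flagged(self, wt_exchange):
        probes = small_probes(4)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        rogue_exch = ExchangeParameters(0.032, 5 * 2490.0, 293.0)
        rogue = make_noiseless_dataset(rogue_exch, small_probes(1, seed=99),
                                       schedule=SHORT_SCHEDULE)
        curves = dict(data.curves)
        rogue_curve = next(iter(rogue.curves.values()))
        curves["rogue"] = DispersionCurve(
            ProbeParameters("rogue", rogue_curve.probe.nucleus_mode,
                            rogue_curve.probe.dw_X, rogue_curve.probe.dw_H,
                            r2_base=dict(rogue_curve.probe.r2_base)),
            rogue_curve.points,
        )
        mixed = DispersionDataset(curves, data.schedules, data.temperature)
        fit = global_fit(mixed, (2490.0, 0.032))
        report = jackknife_probes(mixed, fit, kex_std=10.0)
        assert "rogue" in report.flagged

    def test_two_curves_rejected(self, wt_exchange):
        probes = small_probes(2)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        fit = global_fit(data, (2490.0, 0.032))
        with pytest.raises(ValueError):
            jackknife_probes(data, fit, kex_std=10.0)

    def test_requires_uncertainty(self, wt_exchange):
        probes = small_probes(3)
        data = make_noiseless_dataset(wt_exchange, probes,
                                      schedule=SHORT_SCHEDULE)
        fit = global_fit(data, (2490.0, 0.032))
        with pytest.raises(ValueError, match="monte_carlo"):
            jackknife_probes(data, fit)
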