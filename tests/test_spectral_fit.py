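"""Spectrum fitting: round trips, freezing protocol, bounds, and a grid oracle."""

import numpy as np
import pytest

from thzhyd import (
    FitConfig,
    DielectricSpectrum,
    eval_imag_on_grid,
    fit_pure_water,
    fit_solution,
    gen_spectrum,
    water_params,
)
from thzhyd.spectral_fit import InsufficientDataError


class TestPureWaterFit:
    def test_noiseless_round_trip(self, water_spectrum):
        """Amplitudes (73.8, 1.85) and A_s = 35.0 recovered within 0.1%."""
        res = fit_pure_water(water_spectrum)
        assert res.converged
        assert res.params.delta_eps_slow == pytest.approx(73.8, rel=1e-3)
        assert res.params.delta_eps_fast == pytest.approx(1.85, rel=1e-3)
        assert res.params.amp_stretch == pytest.approx(35.0, rel=1e-3)
        assert res.params.tau_slow == 9.20 and res.params.tau_fast == 0.245
        assert res.residual_rms < 1e-8

    def test_zero_fast_amplitude_pinned_at_lower_bound(self, water):
        spec = gen_spectrum(water.with_(delta_eps_fast=0.0))
        res = fit_pure_water(spec)
        assert res.params.delta_eps_fast >= 0.0
        assert res.params.delta_eps_fast == pytest.approx(0.0, abs=1e-3)
        assert res.params.delta_eps_slow == pytest.approx(73.8, rel=1e-3)

    def test_noisy_replicates_mean_within_1pct(self, water):
        ks = []
        for seed in range(50):
            spec = gen_spectrum(water, noise_sd=0.02, seed=seed)
            ks.append(fit_pure_water(spec).params.delta_eps_slow)
        assert np.mean(ks) == pytest.approx(73.8, rel=0.01)

    def test_insufficient_in_band_points(self, water):
        spec = gen_spectrum(water, grid=np.linspace(0.4, 2.4, 5))
        with pytest.raises(InsufficientDataError):
            fit_pure_water(spec)


class TestSolutionFit:
    def test_noiseless_round_trip(self, water):
        gen = water.with_(delta_eps_slow=66.42, water_volume_fraction=0.95)
        res = fit_solution(gen_spectrum(gen), composition_c=0.95)
        assert res.params.delta_eps_slow == pytest.approx(66.42, rel=1e-3)
        assert res.params.delta_eps_fast == pytest.approx(1.85, rel=1e-3)
        assert res.params.amp_stretch == 35.0  # fixed, not fitted

    def test_urea_like_amplitude_not_clipped_at_water_value(self, water):
        gen = water.with_(delta_eps_slow=77.0)
        res = fit_solution(gen_spectrum(gen), composition_c=1.0)
        assert res.params.delta_eps_slow == pytest.approx(77.0, rel=1e-3)

    def test_pure_water_identity(self, water_spectrum):
        """A water spectrum fitted as a c = 1 solution gives the water amplitudes."""
        sol = fit_solution(water_spectrum, composition_c=1.0)
        ref = fit_pure_water(water_spectrum)
        assert sol.params.delta_eps_slow == pytest.approx(
            ref.params.delta_eps_slow, rel=1e-4)
        assert sol.params.delta_eps_fast == pytest.approx(
            ref.params.delta_eps_fast, abs=1e-3)

    def test_volume_fraction_linearity(self, water):
        """Same data fitted at c = 0.5 doubles the free amplitudes exactly.

        The oscillator is removed (A_s = 0 in data and fit) so that the
        problem is purely linear in the free amplitudes; with a fixed
        nonzero A_s the c-scaled oscillator background would absorb part
        of the rescaling.
        """
        spec = gen_spectrum(water.with_(amp_stretch=0.0))
        cfg = FitConfig(amp_stretch=0.0)
        full = fit_solution(spec, composition_c=1.0, config=cfg)
        half = fit_solution(spec, composition_c=0.5, config=cfg)
        assert half.params.delta_eps_slow == pytest.approx(
            2 * full.params.delta_eps_slow, rel=1e-6)
        assert half.params.delta_eps_fast == pytest.approx(
            2 * full.params.delta_eps_fast, rel=1e-4, abs=1e-4)

    def test_invalid_volume_fraction(self, water_spectrum):
        with pytest.raises(ValueError):
            fit_solution(water_spectrum, composition_c=0.0)
        with pytest.raises(ValueError):
            fit_solution(water_spectrum, composition_c=1.2)


class TestProtocol:
    def test_band_restriction_ignores_out_of_band_points(self, water):
        """Adding samples outside 0.3-2.5 THz must not change the fit."""
        inband = gen_spectrum(water)
        wide_grid = np.concatenate([[0.1, 0.2], inband.frequencies, [2.8, 3.0]])
        wide_vals = np.concatenate([
            [5.0, 4.0],  # deliberately wrong values out of band
            inband.eps_imag, [0.0, 0.0],
        ])
        wide = DielectricSpectrum(frequencies=wide_grid, eps_imag=wide_vals)
        a = fit_pure_water(inband)
        b = fit_pure_water(wide)
        assert b.n_points == a.n_points
        assert b.params.delta_eps_slow == pytest.approx(
            a.params.delta_eps_slow, rel=1e-10)

    def test_noise_consistency(self, water):
        """Recovered spread shrinks and bias vanishes as noise decreases."""
        spreads = []
        for sd in (0.1, 0.02, 0.001):
            vals = [
                fit_pure_water(gen_spectrum(water, noise_sd=sd, seed=100 + i)
                               ).params.delta_eps_slow
                for i in range(20)
            ]
            spreads.append(np.std(vals))
            assert np.mean(vals) == pytest.approx(73.8, rel=5 * sd)
        assert spreads[0] > spreads[1] > spreads[2]

    def test_grid_search_oracle(self, rng):
        """Bounded least squares lands within one 0.01 step of a dense 2-D scan."""
        water = water_params()
        grid = np.linspace(0.3, 2.5, 45)
        for _ in range(10):
            true_s = rng.uniform(60, 80)
            true_f = rng.uniform(1.0, 3.0)
            c = rng.uniform(0.8, 1.0)
            gen = water.with_(delta_eps_slow=true_s, delta_eps_fast=true_f,
                              water_volume_fraction=c)
            spec = gen_spectrum(gen, grid=grid)
            fitted = fit_solution(spec, composition_c=c).params

            step = 0.01
            s_axis = true_s + step * np.arange(-30, 31)
            f_axis = true_f + step * np.arange(-30, 31)
            best, best_cost = None, np.inf
            base = eval_imag_on_grid(
                gen.with_(delta_eps_slow=0.0, delta_eps_fast=0.0), grid)
            unit_s = eval_imag_on_grid(
                gen.with_(delta_eps_slow=1.0, delta_eps_fast=0.0,
                          amp_stretch=0.0), grid)
            unit_f = eval_imag_on_grid(
                gen.with_(delta_eps_slow=0.0, delta_eps_fast=1.0,
                          amp_stretch=0.0), grid)
            for s in s_axis:
                resid_s = base + s * unit_s - spec.eps_imag
                for f in f_axis:
                    cost = np.sum((resid_s + f * unit_f) ** 2)
                    if cost < best_cost:
                        best, best_cost = (s, f), cost
            assert abs(fitted.delta_eps_slow - best[0]) <= step + 1e-9
            assert abs(fitted.delta_eps_fast - best[1]) <= step + 1e-9


def test_fit_config_validation():
    with pytest.raises(ValueError):
        FitConfig(fit_band=(2.5, 0.3))
    with pytest.raises(ValueError):
        FitConfig(fit_band=(-1.0, 2.5))
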