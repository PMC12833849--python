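"""Composition mass balance, hydration fraction/number, and the A_s sweep."""

import numpy as np
import pytest

from thzhyd import (
    SolutionComposition,
    fit_pure_water,
    fit_solution,
    gen_spectrum,
    gen_spectrum_for_nhyd,
    hydration_fraction,
    hydration_number,
    osmolyte_molar_mass,
    sensitivity_sweep,
    water_volume_fraction,
    waters_per_osmolyte,
)
from thzhyd.hydration import CompositionError


class TestComposition:
    def test_pure_water_identity(self):
        comp = SolutionComposition(molarity=0.0, density=0.9975,
                                   molar_mass_osmolyte=60.06)
        assert water_volume_fraction(comp) == pytest.approx(1.0, rel=1e-12)

    def test_sucrose_mass_balance(self, sucrose_composition):
        """0.75 M sucrose at 1.100 g/mL: 843.3 g/L water, c = 0.8454."""
        assert sucrose_composition.water_mass_per_liter() == pytest.approx(
            843.275, abs=0.01)
        assert water_volume_fraction(sucrose_composition) == pytest.approx(
            0.8454, abs=1e-4)

    def test_heavier_osmolyte_reduces_water_fraction(self):
        comps = [
            SolutionComposition(molarity=0.75, density=1.05,
                                molar_mass_osmolyte=m)
            for m in (120.0, 240.0, 342.3)
        ]
        cs = [water_volume_fraction(c) for c in comps]
        assert cs[0] > cs[1] > cs[2]

    def test_waters_per_osmolyte_sucrose(self, sucrose_composition):
        # 843.3 / 18.015 = 46.81 mol water per liter over 0.75 mol osmolyte
        assert waters_per_osmolyte(sucrose_composition) == pytest.approx(
            62.41, abs=0.01)

    def test_alpha_inverse_in_molarity_at_fixed_water_mass(self):
        m_w = 843.275
        comps = {
            C: SolutionComposition(
                molarity=C, density=(m_w + C * 342.30) / 1000.0,
                molar_mass_osmolyte=342.30)
            for C in (0.75, 0.375)
        }
        a_full = waters_per_osmolyte(comps[0.75])
        a_half = waters_per_osmolyte(comps[0.375])
        assert a_half == pytest.approx(2 * a_full, rel=1e-12)

    def test_hypothetical_water_mass_alpha(self):
        # C = 0.75 with m_w = 750.6 g/L -> alpha = 55.55
        comp = SolutionComposition(molarity=0.75,
                                   density=(750.6 + 0.75 * 342.30) / 1000.0,
                                   molar_mass_osmolyte=342.30)
        assert waters_per_osmolyte(comp) == pytest.approx(55.55, abs=0.01)

    def test_implausible_composition_rejected(self):
        with pytest.raises(CompositionError):
            SolutionComposition(molarity=10.0, density=0.5,
                                molar_mass_osmolyte=342.30)

    def test_alpha_undefined_for_pure_water(self):
        comp = SolutionComposition(molarity=0.0, density=0.9975,
                                   molar_mass_osmolyte=60.06)
        with pytest.raises(ValueError):
            waters_per_osmolyte(comp)


def _fit_pair(water_spectrum, d_slow_s, d_fast_s=1.85, c=1.0):
    from thzhyd import water_params

    wfit = fit_pure_water(water_spectrum)
    gen = water_params().with_(delta_eps_slow=d_slow_s, delta_eps_fast=d_fast_s,
                               water_volume_fraction=c)
    sfit = fit_solution(gen_spectrum(gen), composition_c=c)
    return wfit, sfit


class TestHydrationFraction:
    def test_identity_solution_gives_zero(self, water_spectrum):
        wfit, sfit = _fit_pair(water_spectrum, 73.8)
        assert hydration_fraction(wfit, sfit) == pytest.approx(0.0, abs=1e-6)

    def test_hand_derived_binding_case(self, water_spectrum):
        """Slow amplitude drop 73.8 -> 66.42 gives a_hyd = 0.0932."""
        wfit, sfit = _fit_pair(water_spectrum, 66.42)
        assert hydration_fraction(wfit, sfit) == pytest.approx(0.0932, abs=1e-4)

    def test_hand_derived_urea_like_case(self, water_spectrum):
        """Slow amplitude rise above water gives negative a_hyd."""
        wfit, sfit = _fit_pair(water_spectrum, 77.0)
        assert hydration_fraction(wfit, sfit) == pytest.approx(-0.0404, abs=1e-4)

    def test_monotone_decreasing_in_solution_amplitudes(self, water_spectrum):
        wfit = fit_pure_water(water_spectrum)
        a_prev = None
        for d_slow in (60.0, 66.0, 72.0, 78.0):
            _, sfit = _fit_pair(water_spectrum, d_slow)
            a = hydration_fraction(wfit, sfit)
            if a_prev is not None:
                assert a < a_prev
            a_prev = a
        b_prev = None
        for d_fast in (0.5, 1.85, 3.0):
            _, sfit = _fit_pair(water_spectrum, 70.0, d_fast_s=d_fast)
            b = hydration_fraction(wfit, sfit)
            if b_prev is not None:
                assert b < b_prev
            b_prev = b

    def test_bounded_above_by_one(self, water_spectrum, rng):
        """a_hyd <= 1, with equality only when both solution amplitudes vanish."""
        wfit = fit_pure_water(water_spectrum)
        for _ in range(25):
            _, sfit = _fit_pair(water_spectrum, rng.uniform(0.5, 90),
                                d_fast_s=rng.uniform(0.0, 5.0))
            assert hydration_fraction(wfit, sfit) <= 1.0 + 1e-9
        _, sfit = _fit_pair(water_spectrum, 1e-9, d_fast_s=0.0)
        assert hydration_fraction(wfit, sfit) == pytest.approx(1.0, abs=1e-6)


class TestHydrationNumber:
    def test_zero_fraction_zero_number(self):
        assert hydration_number(0.0, 62.41) == 0.0

    def test_hand_products(self):
        assert hydration_number(0.0932, 62.41) == pytest.approx(5.82, abs=0.01)
        assert hydration_number(-0.0404, 70.0) == pytest.approx(-2.83, abs=0.01)

    def test_scales_with_alpha(self):
        assert hydration_number(0.05, 100.0) == 2 * hydration_number(0.05, 50.0)

    def test_requires_positive_alpha(self):
        with pytest.raises(ValueError):
            hydration_number(0.1, 0.0)


class TestSensitivitySweep:
    def test_noiseless_central_matches_target_and_bounds_bracket(
            self, water_spectrum, sucrose_composition):
        target = 5.82
        spec = gen_spectrum_for_nhyd(target, sucrose_composition)
        res = sensitivity_sweep(spec, water_spectrum,
                                composition=sucrose_composition)
        assert res.converged
        assert res.n_hyd == pytest.approx(target, rel=1e-3)
        assert res.n_hyd_lo <= res.n_hyd <= res.n_hyd_hi
        assert res.n_hyd_hi - res.n_hyd_lo > 0  # A_s actually matters

    def test_degenerate_single_value_sweep(self, water_spectrum,
                                           sucrose_composition):
        spec = gen_spectrum_for_nhyd(3.0, sucrose_composition)
        res = sensitivity_sweep(spec, water_spectrum,
                                composition=sucrose_composition,
                                a_s_values=(35.0,))
        assert res.a_hyd_lo == res.a_hyd == res.a_hyd_hi

    def test_ternary_mode_reports_fraction_only(self, water_spectrum, water):
        spec = gen_spectrum(water.with_(delta_eps_slow=66.42,
                                        water_volume_fraction=0.76))
        res = sensitivity_sweep(spec, water_spectrum, c_override=0.76)
        assert res.n_hyd is None and res.alpha is None
        assert res.a_hyd == pytest.approx(0.0932, abs=1e-3)

    def test_requires_composition_or_override(self, water_spectrum):
        with pytest.raises(ValueError):
            sensitivity_sweep(water_spectrum, water_spectrum)

    def test_end_to_end_recovery_from_planted_target(self, water_spectrum,
                                                     sucrose_composition):
        """Invert the hydration relation, refit, recover n_hyd within 1%."""
        alpha = waters_per_osmolyte(sucrose_composition)
        for target in (-2.0, 1.0, 8.0):
            spec = gen_spectrum_for_nhyd(target, sucrose_composition)
            res = sensitivity_sweep(spec, water_spectrum,
                                    composition=sucrose_composition)
            assert res.n_hyd == pytest.approx(target, rel=0.01, abs=0.01)
            assert res.a_hyd == pytest.approx(target / alpha, rel=0.01,
                                              abs=1e-4)


def test_molar_mass_lookup_table():
    assert osmolyte_molar_mass("sucrose") == pytest.approx(342.30)
    assert osmolyte_molar_mass("Urea") == pytest.approx(60.06)
    with pytest.raises(KeyError):
        osmolyte_molar_mass("betaine")
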