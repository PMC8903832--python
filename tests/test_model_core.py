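"""Pointwise physics: kinetics, sensing, crowding correction, unit handling."""

import math

import numpy as np
import pytest

from chemosmooth.model_core import (
    KAPPA_PRINTED_TO_INTERNAL,
    MEDIUM_PRESETS,
    ModelParams,
    ParameterError,
    PorousMediumParams,
    mean_cell_separation,
    medium_preset,
    monod_g,
    motility_correction,
    params_from_toml,
    params_to_toml,
    reaction_terms,
    scale_estimates,
    sensing_f,
    sensing_fprime,
)


class TestMonod:
    @pytest.mark.parametrize("c,expected", [(1.0, 0.5), (0.0, 0.0), (9.0, 0.9)])
    def test_values(self, params, c, expected):
        assert monod_g(c, params) == pytest.approx(expected)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            monod_g(-1.0, params)

    def test_bounded_and_monotone(self, params):
        c = np.logspace(-3, 7, 200)
        g = monod_g(c, params)
        assert np.all((g >= 0) & (g < 1))
        assert np.all(np.diff(g) > 0)


class TestSensing:
    def test_vanishes_at_zero_both_modes(self, params):
        assert sensing_f(0.0, params) == 0.0
        assert sensing_f(0.0, params.replace(sensing_mode="linear")) == 0.0

    def test_saturation_limit_is_log_cplus_over_cminus(self, params):
        # c -> inf limit of log[(1+c/c-)/(1+c/c+)] with c-=1, c+=30 uM
        assert sensing_f(1e12, params) == pytest.approx(math.log(30.0), rel=1e-6)

    def test_linear_scale_matches_small_c_slope(self, params):
        lin = params.replace(sensing_mode="linear")
        assert lin.c_lin == pytest.approx(30.0 / 29.0)
        assert sensing_f(1.0, lin) == pytest.approx(29.0 / 30.0)
        # same slope as the logarithmic form at small c
        eps = 1e-8
        assert sensing_f(eps, params) / eps == pytest.approx(1.0 / lin.c_lin,
                                                             rel=1e-6)

    def test_fprime_values(self, params):
        assert sensing_fprime(0.0, params) == pytest.approx(29.0 / 30.0)
        assert sensing_fprime(1e9, params) == pytest.approx(0.0, abs=1e-12)
        lin = params.replace(sensing_mode="linear")
        assert sensing_fprime(123.0, lin) == pytest.approx(29.0 / 30.0)

    def test_fprime_matches_central_difference(self, params):
        c = np.logspace(-2, 6, 60)
        h = 1e-6 * (c + 1.0)
        fd = (sensing_f(c + h, params) - sensing_f(c - h, params)) / (2 * h)
        assert np.allclose(sensing_fprime(c, params), fd, rtol=1e-6)

    def test_log_concave_linear_flat(self, params):
        c = np.logspace(-2, 6, 60)
        h = 1e-4 * (c + 1.0)
        d2 = (sensing_f(c + h, params) - 2 * sensing_f(c, params)
              + sensing_f(c - h, params)) / h**2
        assert np.all(d2 < 0)
        lin = params.replace(sensing_mode="linear")
        d2l = (sensing_f(c + h, lin) - 2 * sensing_f(c, lin)
               + sensing_f(c - h, lin)) / h**2
        assert np.allclose(d2l, 0.0, atol=1e-8)

    def test_fprime_strictly_decreasing(self, params):
        c = np.logspace(-3, 6, 100)
        assert np.all(np.diff(sensing_fprime(c, params)) < 0)


class TestCrowding:
    def test_separation_diverges_at_zero_density(self, params, medium):
        assert mean_cell_separation(0.0, medium, params) == math.inf
        assert mean_cell_separation(1e-12, medium, params) > 1e3

    def test_separation_zero_at_overlap_density(self, params, medium):
        b_jam = 3 * medium.f_pore / (4 * math.pi * params.d_cell**3)
        assert b_jam == pytest.approx(0.04058, rel=1e-3)
        assert mean_cell_separation(b_jam, medium, params) == pytest.approx(0.0, abs=1e-12)

    def test_separation_equals_chord_length(self, params, medium):
        b = 3 * medium.f_pore / (4 * math.pi * (medium.l_c + params.d_cell) ** 3)
        assert b == pytest.approx(5.89e-4, rel=2e-3)
        assert mean_cell_separation(b, medium, params) == pytest.approx(medium.l_c)

    def test_correction_boundaries(self, params, medium):
        b_lc = 3 * medium.f_pore / (4 * math.pi * (medium.l_c + params.d_cell) ** 3)
        assert motility_correction(b_lc, medium, params) == pytest.approx(1.0)
        assert motility_correction(b_lc / 10, medium, params) == 1.0
        b_half = 3 * medium.f_pore / (
            4 * math.pi * (medium.l_c / 2 + params.d_cell) ** 3)
        assert motility_correction(b_half, medium, params) == pytest.approx(0.25)

    def test_packed_density_is_jammed_in_every_medium(self, params):
        for med in MEDIUM_PRESETS.values():
            assert motility_correction(params.b_pack, med, params) == 0.0

    def test_correction_non_increasing(self, params):
        b = np.logspace(-6, 0, 300)
        for med in MEDIUM_PRESETS.values():
            phi = motility_correction(b, med, params)
            assert np.all(np.diff(phi) <= 1e-15)


class TestReactionTerms:
    def test_no_cells_no_reaction(self, params):
        b = np.zeros((5, 4))
        c = np.full((5, 4), 100.0)
        cons, grow = reaction_terms((b, c), params)
        assert not cons.any() and not grow.any()

    def test_uniform_consumption_value(self, params):
        # kappa converts to 1.6e4 uM um^3/cell/s; b=0.01, c=1e4 uM
        b = np.full((3, 4), 0.01)
        c = np.full((3, 4), 1e4)
        cons, grow = reaction_terms((b, c), params)
        expected = -0.01 * 1.6e4 * (1e4 / (1e4 + 1.0))
        assert cons == pytest.approx(expected)
        assert expected == pytest.approx(-160.0, rel=1e-3)
        assert np.all(grow > 0)

    def test_growth_knockout_exact_zero(self, params):
        p = params.replace(knockout_growth=True)
        b = np.full((3, 3), 0.5)
        c = np.full((3, 3), 50.0)
        _, grow = reaction_terms((b, c), p)
        assert not grow.any()

    def test_shape_mismatch(self, params):
        with pytest.raises(ValueError):
            reaction_terms((np.zeros((3, 3)), np.zeros((3, 4))), params)


class TestUnitsAndParams:
    def test_kappa_round_trip_to_printed_units(self, params):
        assert params.kappa_printed == pytest.approx(1.6e-11, rel=1e-12)
        assert params.kappa == pytest.approx(1.6e4)
        assert KAPPA_PRINTED_TO_INTERNAL == pytest.approx(1e15)

    def test_presets_match_measured_triples(self):
        printed = {
            2.2: (2.32, 145.0, 0.36, 4.6),
            1.7: (0.93, 9.0, 0.17, 3.1),
            1.2: (0.42, 5.0, 0.04, 2.4),
        }
        for xi, (Db0, chi0, f, lc) in printed.items():
            med = medium_preset(xi)
            assert (med.Db0, med.chi0, med.f_pore, med.l_c) == (Db0, chi0, f, lc)
        with pytest.raises(ParameterError):
            medium_preset(3.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ModelParams(c_minus=30.0, c_plus=1.0)
        with pytest.raises(ParameterError):
            ModelParams(Dc=-1.0)
        with pytest.raises(ParameterError):
            ModelParams(sensing_mode="quadratic")
        with pytest.raises(ParameterError):
            PorousMediumParams(xi=1.7, Db0=0.93, chi0=9.0, f_pore=1.5, l_c=3.1)

    def test_toml_round_trip(self, params, medium):
        text = params_to_toml(params.replace(c_plus=12.5), medium)
        p2, m2 = params_from_toml(text)
        assert p2 == params.replace(c_plus=12.5)
        assert m2 == medium

    def test_knockout_effective_medium(self, params, medium):
        p = params.replace(knockout_diffusion=True)
        med = p.effective_medium(medium)
        assert med.Db0 == 0.0 and med.chi0 == medium.chi0
        p = params.replace(knockout_chemotaxis=True)
        med = p.effective_medium(medium)
        assert med.chi0 == 0.0 and med.Db0 == medium.Db0
        assert params.replace(knockout_growth=True).gamma_eff == 0.0


class TestScaleEstimates:
    def test_diffusive_smoothing_scale(self):
        t_diff, _ = scale_estimates(1000.0, 2.32, 1.0 / 3600, 300.0, 2.0)
        assert t_diff == pytest.approx(1e6 / 2.32 / 3600.0, rel=1e-12)
        assert t_diff == pytest.approx(119.7, rel=1e-3)
        t_diff_tight, _ = scale_estimates(1000.0, 0.42, 1.0 / 3600, 300.0, 2.0)
        assert t_diff_tight == pytest.approx(661.4, rel=1e-3)

    def test_proliferative_scale(self):
        _, t_grow = scale_estimates(1000.0, 1.0, 1.0 / 3600.0, 300.0, 2.0)
        assert t_grow == pytest.approx(math.log2(150.0), rel=1e-12)
        assert t_grow == pytest.approx(7.23, rel=1e-3)

    def test_amplitude_below_cell_size_rejected(self):
        with pytest.raises(ValueError):
            scale_estimates(1000.0, 1.0, 1.0, 1.0, 2.0)
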