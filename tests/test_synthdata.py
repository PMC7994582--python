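"""Generator contracts: determinism, zero-noise exactness, noise calibration."""

import numpy as np
import pytest

from ctdbind.anisofit import FourPLParams, fit_fourpl, fourpl_response
from ctdbind.aucfit import SwModelParams, integrate_sw, predict_sw
from ctdbind.equilibria import TwoSiteParams
from ctdbind.nmrtitr import compute_csp
from ctdbind.synthdata import (
    EquilibriumCompetitionSpec,
    NoiseSpec,
    gen_competition_curve,
    gen_cs_distribution,
    gen_guinier_profiles,
    gen_hsqc_titration,
    gen_sw_isotherm,
)

PARAMS = SwModelParams(0.61, 1.48, TwoSiteParams(21.5, 5990.0))


class TestZeroNoiseMatchesForwardModel:
    def test_isotherm(self):
        iso = gen_sw_isotherm(PARAMS, noise=NoiseSpec(0.0, 0))
        model = predict_sw(PARAMS, iso.peptide_total, iso.titrant_total)
        np.testing.assert_array_equal(iso.sw, model)

    def test_competition(self):
        p = FourPLParams(0.05, 0.2, 59.0, 1.0)
        curve = gen_competition_curve(p, noise=NoiseSpec(0.0, 0))
        np.testing.assert_array_equal(curve.response,
                                      fourpl_response(p, curve.competitor_total))

    def test_hsqc_roundtrips_to_exact_kd(self):
        from ctdbind.nmrtitr import fit_residue_kd
        series = gen_hsqc_titration(3, kd=25.0, noise=NoiseSpec(0.0, 0))
        for s in series:
            assert fit_residue_kd(s).Kd == pytest.approx(25.0, rel=1e-3)

    def test_guinier_profiles_follow_exact_law(self):
        from ctdbind.saxsguinier import guinier_fit
        profiles = gen_guinier_profiles(19.8, 0.31, noise=NoiseSpec(0.0, 0))
        for p in profiles:
            rg_c = 19.8 + 0.31 * p.concentration
            assert guinier_fit(p).Rg == pytest.approx(rg_c, rel=1e-3)


class TestDeterminism:
    def test_same_seed_identical_isotherm(self):
        a = gen_sw_isotherm(PARAMS, noise=NoiseSpec(0.01, 42))
        b = gen_sw_isotherm(PARAMS, noise=NoiseSpec(0.01, 42))
        np.testing.assert_array_equal(a.sw, b.sw)
        c = gen_sw_isotherm(PARAMS, noise=NoiseSpec(0.01, 43))
        assert not np.array_equal(a.sw, c.sw)

    def test_same_seed_identical_titrations_and_curves(self):
        s1 = gen_hsqc_titration(4, 25.0, noise=NoiseSpec(0.002, 5))
        s2 = gen_hsqc_titration(4, 25.0, noise=NoiseSpec(0.002, 5))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.points, b.points)
        p = FourPLParams(0.05, 0.2, 59.0, 1.0)
        c1 = gen_competition_curve(p, noise=NoiseSpec(0.002, 5))
        c2 = gen_competition_curve(p, noise=NoiseSpec(0.002, 5))
        np.testing.assert_array_equal(c1.response, c2.response)
        g1 = gen_guinier_profiles(noise=NoiseSpec(0.005, 5))
        g2 = gen_guinier_profiles(noise=NoiseSpec(0.005, 5))
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.I, b.I)

    def test_adding_residues_preserves_existing_substreams(self):
        small = gen_hsqc_titration(3, 25.0, noise=NoiseSpec(0.002, 9))
        large = gen_hsqc_titration(8, 25.0, noise=NoiseSpec(0.002, 9))
        for a, b in zip(small, large[:3]):
            np.testing.assert_array_equal(a.points, b.points)


class TestNoiseCalibration:
    def test_empirical_sd_matches_nominal(self):
        grid = np.linspace(0.5, 1000.0, 10000)
        iso = gen_sw_isotherm(PARAMS, titrant_grid=grid,
                              noise=NoiseSpec(0.02, 33))
        model = predict_sw(PARAMS, iso.peptide_total, grid)
        sd = float(np.std(iso.sw - model))
        assert sd == pytest.approx(0.02, rel=0.03)


class TestCsDistribution:
    def test_single_peak_center(self):
        d = gen_cs_distribution([(1.45, 1.0, 0.04)])
        assert integrate_sw(d) == pytest.approx(1.45, abs=1e-3)

    def test_two_equal_peaks(self):
        d = gen_cs_distribution([(1.0, 1.0, 0.05), (3.0, 1.0, 0.05)])
        assert integrate_sw(d) == pytest.approx(2.0, abs=1e-3)

    def test_areas_scale_linearly(self):
        d1 = gen_cs_distribution([(1.5, 1.0, 0.05)])
        d3 = gen_cs_distribution([(1.5, 3.0, 0.05)])
        np.testing.assert_allclose(d3.c, 3.0 * d1.c, rtol=1e-12, atol=1e-290)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            gen_cs_distribution([(1.5, 1.0, 0.0)])


class TestHsqcStructure:
    def test_endpoint_csp_fraction_matches_drawn_saturations(self):
        # with zero noise the endpoint CSP is exactly dbound * f_bound(end);
        # the over-threshold fraction must match the analytic prediction
        from ctdbind.equilibria import SingleSiteSystem, solve_single_site
        kd, p_tot = 40.0, 100.0
        series = gen_hsqc_titration(40, kd, delta_bound_range=(0.01, 0.1),
                                    noise=NoiseSpec(0.0, 13))
        l_end = series[0].points[-1, 0]
        f_end = solve_single_site(SingleSiteSystem(p_tot, l_end, kd)) / p_tot
        endpoints = np.array([compute_csp(s).endpoint_csp for s in series])
        dbounds = endpoints / f_end  # exact inversion at zero noise
        predicted = np.mean(dbounds * f_end > 0.03)
        observed = np.mean(endpoints > 0.03)
        assert observed == predicted


class TestEquilibriumCompetitionMode:
    def test_reduces_to_fourpl_when_depletion_negligible(self):
        # probe far below protein and Kds: the exact shared-site curve is
        # indistinguishable from a fitted 4PL (within 2% of the range)
        p = FourPLParams(0.05, 0.20, 50.0, 1.0)
        eq = EquilibriumCompetitionSpec(protein_total=50.0, probe_total=0.01,
                                        kd_probe=25.0, kd_comp=25.0)
        grid = np.concatenate(([0.0], np.geomspace(0.5, 2000.0, 25)))
        curve = gen_competition_curve(p, grid=grid, noise=NoiseSpec(0.0, 0),
                                      equilibrium=eq)
        fit = fit_fourpl(curve)
        resid = curve.response - fourpl_response(fit.params,
                                                 curve.competitor_total)
        assert np.max(np.abs(resid)) <= 0.02 * (p.max - p.min)
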