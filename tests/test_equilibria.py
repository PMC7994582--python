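"""Binding-equilibrium solvers vs closed forms and the grid-scan oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdbind.equilibria import (
    SingleSiteSystem,
    TwoSiteParams,
    solve_competitive,
    solve_single_site,
    solve_two_site,
)


class TestSingleSite:
    def test_no_ligand_means_no_complex(self):
        assert solve_single_site(SingleSiteSystem(100.0, 0.0, 10.0)) == 0.0

    def test_tight_binding_limit_is_stoichiometric(self):
        p, l = 80.0, 50.0
        pl = solve_single_site(SingleSiteSystem(p, l, 1e-9 * p))
        assert pl == pytest.approx(min(p, l), rel=1e-6)

    def test_symmetric_case_closed_form(self):
        # P = L = Kd = 100: [PL] = 100*(3 - sqrt(5))/2
        pl = solve_single_site(SingleSiteSystem(100.0, 100.0, 100.0))
        assert pl == pytest.approx(100.0 * (3.0 - math.sqrt(5.0)) / 2.0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            SingleSiteSystem(-1.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            SingleSiteSystem(1.0, 10.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        p=st.floats(0.01, 1e3), l=st.floats(0.0, 1e3),
        kd=st.floats(1e-3, 1e5),
    )
    def test_bound_within_physical_range_and_mass_action(self, p, l, kd):
        pl = solve_single_site(SingleSiteSystem(p, l, kd))
        assert 0.0 <= pl <= min(p, l) + 1e-12
        # mass action: (P-PL)(L-PL) = Kd*PL
        lhs = (p - pl) * (l - pl)
        assert lhs == pytest.approx(kd * pl, rel=1e-6, abs=1e-9)


class TestTwoSite:
    def test_zero_titrant(self):
        st_ = solve_two_site(50.0, 0.0, TwoSiteParams(10.0, 100.0))
        assert (st_.E, st_.SE, st_.ES, st_.SES) == (50.0, 0.0, 0.0, 0.0)

    def test_equal_kds_give_symmetric_occupancy(self):
        st_ = solve_two_site(50.0, 80.0, TwoSiteParams(25.0, 25.0))
        assert st_.SE == pytest.approx(st_.ES, rel=1e-12)

    def test_conservation_invariants(self):
        st_ = solve_two_site(50.0, 300.0, TwoSiteParams(21.5, 5990.0))
        assert st_.E_total == pytest.approx(50.0, rel=1e-9)
        assert st_.S_total == pytest.approx(300.0, rel=1e-9)
        assert min(st_.E, st_.S_free, st_.SE, st_.ES, st_.SES) >= 0.0

    def test_mass_action_relations_hold(self):
        k = TwoSiteParams(3.7, 412.0)
        st_ = solve_two_site(20.0, 55.0, k)
        assert st_.SE == pytest.approx(st_.E * st_.S_free / k.Kd1, rel=1e-10)
        assert st_.ES == pytest.approx(st_.E * st_.S_free / k.Kd2, rel=1e-10)
        assert st_.SES == pytest.approx(
            st_.E * st_.S_free ** 2 / (k.Kd1 * k.Kd2), rel=1e-10)

    def test_agrees_with_grid_scan_oracle(self, two_site_oracle):
        rng = np.random.default_rng(123)
        for _ in range(50):
            e_tot = rng.uniform(1, 500)
            s_tot = rng.uniform(1, 500)
            kd1, kd2 = 10.0 ** rng.uniform(0, 4, size=2)
            st_ = solve_two_site(e_tot, s_tot, TwoSiteParams(kd1, kd2))
            e, s, se, es, ses = two_site_oracle(e_tot, s_tot, kd1, kd2)
            assert st_.S_free == pytest.approx(s, rel=1e-6, abs=1e-9)
            assert st_.E == pytest.approx(e, rel=1e-6, abs=1e-9)
            assert st_.SES == pytest.approx(ses, rel=1e-6, abs=1e-9)

    def test_weak_second_site_reduces_to_single_site(self):
        kd1 = 12.0
        for e_tot, s_tot in [(50.0, 30.0), (50.0, 300.0), (10.0, 1000.0)]:
            st_ = solve_two_site(e_tot, s_tot, TwoSiteParams(kd1, 1e9 * kd1))
            pl = solve_single_site(SingleSiteSystem(e_tot, s_tot, kd1))
            assert st_.SE == pytest.approx(pl, rel=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(
        e_tot=st.floats(1.0, 500.0),
        kd1=st.floats(0.1, 1e4), kd2=st.floats(0.1, 1e4),
        s_a=st.floats(0.1, 999.0), ds=st.floats(0.1, 500.0),
    )
    def test_occupancy_monotone_in_titrant(self, e_tot, kd1, kd2, s_a, ds):
        k = TwoSiteParams(kd1, kd2)
        lo = solve_two_site(e_tot, s_a, k).occupancy
        hi = solve_two_site(e_tot, s_a + ds, k).occupancy
        assert hi >= lo - 1e-9

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_two_site(-1.0, 10.0, TwoSiteParams(1.0, 1.0))


class TestCompetitive:
    def test_no_competitor_reduces_to_single_site(self):
        pl_comp, pc = solve_competitive(50.0, 1.0, 0.0, 10.0, 25.0)
        pl = solve_single_site(SingleSiteSystem(50.0, 1.0, 10.0))
        assert pc == 0.0
        assert pl_comp == pytest.approx(pl, rel=1e-9)

    def test_infinitely_weak_competitor_changes_nothing(self):
        base, _ = solve_competitive(50.0, 1.0, 0.0, 10.0, 25.0)
        with_comp, _ = solve_competitive(50.0, 1.0, 300.0, 10.0, 1e12)
        assert with_comp == pytest.approx(base, rel=1e-6)

    def test_symmetric_species_bind_equally(self, two_site_oracle):
        pl, pc = solve_competitive(40.0, 60.0, 60.0, 15.0, 15.0)
        assert pl == pytest.approx(pc, rel=1e-10)
        # cross-check against mass action + conservation directly
        p_free = 40.0 - pl - pc
        assert pl == pytest.approx(60.0 * p_free / (15.0 + p_free), rel=1e-8)

    def test_all_conservation_relations(self):
        p_tot, l1, l2 = 50.0, 1.0, 120.0
        pl, pc = solve_competitive(p_tot, l1, l2, 8.0, 40.0)
        p_free = p_tot - pl - pc
        assert 0 <= pl <= l1 and 0 <= pc <= l2 and p_free >= 0
        assert pl * (8.0 + p_free) == pytest.approx(l1 * p_free, rel=1e-9)
        assert pc * (40.0 + p_free) == pytest.approx(l2 * p_free, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        comp_a=st.floats(0.0, 300.0), dcomp=st.floats(0.1, 100.0),
        kd_c=st.floats(0.5, 1e3),
    )
    def test_bound_probe_monotone_decreasing_in_competitor(self, comp_a, dcomp, kd_c):
        lo, _ = solve_competitive(50.0, 1.0, comp_a + dcomp, 10.0, kd_c)
        hi, _ = solve_competitive(50.0, 1.0, comp_a, 10.0, kd_c)
        assert lo <= hi + 1e-12
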