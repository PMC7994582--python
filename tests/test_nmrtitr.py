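"""CSP computation, per-residue Kd fits, aggregation, and classification."""

import numpy as np
import pytest

from ctdbind.nmrtitr import (
    AggregateKd,
    CSPRecord,
    ResidueFitFailure,
    TitrationSeries,
    aggregate_kd,
    assignment_completeness,
    classify_csp,
    compute_csp,
    fit_residue_kd,
    fit_residues,
)
from ctdbind.synthdata import NoiseSpec, gen_hsqc_titration


def _series(l_totals, dh, dn, p_total=100.0, broadened=None):
    pts = np.column_stack([l_totals, dh, dn])
    return TitrationSeries(1, "G", pts, p_total, broadened)


class TestComputeCsp:
    @pytest.mark.parametrize(
        "dh, dn, expected",
        [
            (0.0, 0.0, 0.0),
            (0.0, 0.5, 0.1),                      # nitrogen scaled by 5
            (0.03, 0.15, np.hypot(0.03, 0.03)),   # 0.042426...
        ],
    )
    def test_csp_formula(self, dh, dn, expected):
        s = _series([0.0, 100.0], [8.0, 8.0 + dh], [118.0, 118.0 + dn])
        rec = compute_csp(s)
        assert rec.csp[0] == 0.0
        assert rec.endpoint_csp == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_uniform_referencing_offset(self):
        l = [0.0, 50.0, 100.0, 200.0]
        dh = [8.0, 8.02, 8.05, 8.07]
        dn = [118.0, 118.2, 118.5, 118.9]
        base = compute_csp(_series(l, dh, dn)).csp
        shifted = compute_csp(_series(l, np.add(dh, 0.3), np.add(dn, -2.0))).csp
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_broadened_points_have_no_csp(self):
        s = _series([0.0, 50.0, 100.0], [8.0, 8.1, 8.2], [118.0] * 3,
                    broadened=[False, True, False])
        rec = compute_csp(s)
        assert np.isnan(rec.csp[1])
        assert not np.isnan(rec.endpoint_csp)

    def test_missing_apo_reference_rejected(self):
        with pytest.raises(ValueError, match="apo reference"):
            _series([10.0, 50.0], [8.0, 8.1], [118.0, 118.2])


class TestResidueFit:
    def test_noise_free_recovery(self):
        series = gen_hsqc_titration(1, kd=50.0, delta_bound_range=(0.2, 0.2),
                                    noise=NoiseSpec(0.0, 0))[0]
        fit = fit_residue_kd(series)
        assert fit.Kd == pytest.approx(50.0, rel=1e-3)
        assert fit.delta_bound == pytest.approx(0.2, rel=1e-3)

    def test_flat_csp_is_a_failure_not_a_kd(self):
        s = _series([0.0, 50.0, 100.0, 200.0, 300.0],
                    [8.0] * 5, [118.0] * 5)
        with pytest.raises(ValueError):
            fit_residue_kd(s)
        fits, failures = fit_residues([s])
        assert fits == [] and len(failures) == 1
        assert isinstance(failures[0], ResidueFitFailure)

    def test_stoichiometric_regime_delta_bound_equals_endpoint(self):
        # Kd << P_total: binding is essentially titration to saturation,
        # so the fitted saturation CSP matches the endpoint CSP within 1%
        series = gen_hsqc_titration(
            1, kd=0.05, delta_bound_range=(0.3, 0.3),
            ratios=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0),
            noise=NoiseSpec(0.0, 0))[0]
        endpoint = compute_csp(series).endpoint_csp
        fit = fit_residue_kd(series)
        assert fit.delta_bound == pytest.approx(endpoint, rel=0.01)

    def test_median_kd_error_small_at_default_noise(self):
        # 100 well-perturbed residues (saturation CSP 0.2-0.4 ppm),
        # P_total 100 µM, 12 ratios spanning 0-3, shift noise sd 0.002 ppm
        series = gen_hsqc_titration(100, kd=50.0,
                                    delta_bound_range=(0.2, 0.4),
                                    ratios=tuple(np.linspace(0.0, 3.0, 12)),
                                    noise=NoiseSpec(0.002, 21))
        fits, failures = fit_residues(series)
        assert len(failures) == 0
        rel_err = np.abs(np.array([f.Kd for f in fits]) - 50.0) / 50.0
        assert np.median(rel_err) <= 0.05


class TestAggregate:
    def _fit(self, rid, kd):
        from ctdbind.nmrtitr import ResidueFit
        return ResidueFit(rid, kd, 0.2, None, 0.0, 8)

    def _rec(self, rid, endpoint):
        return CSPRecord(rid, np.array([0.0, endpoint]), endpoint)

    def test_identical_kds(self):
        fits = [self._fit(i, 10.0) for i in range(3)]
        recs = [self._rec(i, 0.2) for i in range(3)]
        agg = aggregate_kd(fits, recs)
        assert (agg.mean, agg.sd) == (10.0, 0.0)
        assert agg.n == 3

    def test_population_sd(self):
        fits = [self._fit(i, kd) for i, kd in enumerate([5.0, 10.0, 15.0])]
        recs = [self._rec(i, 0.2) for i in range(3)]
        agg = aggregate_kd(fits, recs)
        assert agg.mean == pytest.approx(10.0)
        assert agg.sd == pytest.approx(np.sqrt(50.0 / 3.0))  # ~4.082

    def test_subthreshold_residues_excluded_with_reason(self):
        fits = [self._fit(1, 10.0), self._fit(2, 500.0)]
        recs = [self._rec(1, 0.2), self._rec(2, 0.02)]
        agg = aggregate_kd(fits, recs)
        assert agg.residues == (1,)
        assert agg.mean == 10.0
        assert "threshold" in agg.exclusions[2]

    def test_threshold_is_strict_inequality(self):
        fits = [self._fit(1, 10.0)]
        recs = [self._rec(1, 0.03)]  # exactly at threshold: excluded
        assert aggregate_kd(fits, recs).n == 0

    def test_empty_aggregate_is_explicit(self):
        agg = aggregate_kd([], [])
        assert isinstance(agg, AggregateKd)
        assert agg.mean is None and agg.sd is None and agg.n == 0

    def test_mean_bounded_by_contributing_kds(self):
        rng = np.random.default_rng(3)
        kds = rng.uniform(1.0, 300.0, size=12)
        fits = [self._fit(i, k) for i, k in enumerate(kds)]
        recs = [self._rec(i, 0.1) for i in range(12)]
        agg = aggregate_kd(fits, recs)
        assert kds.min() <= agg.mean <= kds.max()


class TestClassify:
    @pytest.mark.parametrize("endpoint, expected", [
        (0.2, "strong"), (0.05, "moderate"), (0.01, "none"),
        (0.1, "moderate"), (0.03, "none"),  # thresholds are strict
    ])
    def test_thresholds(self, endpoint, expected):
        rec = CSPRecord(1, np.array([0.0, endpoint]), endpoint)
        assert classify_csp(rec) == expected

    def test_broadened_dominates(self):
        rec = CSPRecord(1, np.array([0.0, 0.2]), 0.2)
        assert classify_csp(rec, broadened=True) == "broadened"


class TestCompleteness:
    @pytest.mark.parametrize("assigned, total, rounded", [
        (154, 162, 95), (141, 151, 93), (0, 100, 0), (143, 162, 88),
    ])
    def test_reported_percentages(self, assigned, total, rounded):
        exact, r = assignment_completeness(assigned, total)
        assert r == rounded
        assert exact == pytest.approx(100.0 * assigned / total)

    def test_degenerate_total_rejected(self):
        with pytest.raises(ValueError):
            assignment_completeness(0, 0)
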