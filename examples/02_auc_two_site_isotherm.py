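"""Fit the two-site sw-isotherm model to a simulated SV-AUC titration.

A 50 µM two-motif FITC peptide is titrated with protein (0.5-1000 µM); the
signal-weighted sedimentation coefficient sw rises from the free-peptide
baseline a toward a + 2b as both sites fill.  We simulate at the reported
5R constants and refit with the baseline fixed and b floated.
"""

from ctdbind import (DEFAULT_A, DEFAULT_B, SwModelParams, TwoSiteParams,
                     fit_sw_isotherm, gen_sw_isotherm, NoiseSpec)

truth = SwModelParams(a=DEFAULT_A, b=DEFAULT_B, k=TwoSiteParams(21.5, 5990.0))
iso = gen_sw_isotherm(truth, noise=NoiseSpec(sd=0.01, seed=42))

fit = fit_sw_isotherm(iso, float_b=True)
k = fit.params.k
print(f"generated with Kd1 = 21.5 uM, Kd2 = 5990 uM, b = {DEFAULT_B} S")
print(f"recovered Kd1 = {k.Kd1:.1f} uM  (tight site, WW-domain-like)")
print(f"recovered Kd2 = {fit.kd2_display} uM  (weak site, PPIase-like)")
print(f"recovered b   = {fit.params.b:.3f} S  (sw increment per bound protein)")
print(f"weighted RSS = {fit.rss:.2e} over {fit.n_points} points")
print("Kd1 within a few percent of truth shows the isotherm pins the tight")
print("site; Kd2 is softer because the weak site barely populates by 1 mM.")
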