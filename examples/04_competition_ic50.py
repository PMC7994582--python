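"""Four-parameter-logistic IC50 fit to a competition anisotropy curve.

Unlabeled competitor peptide (0-350 µM) displaces an FITC-labeled probe
from the protein; the anisotropy transition midpoint is the IC50.
"""

from ctdbind import FourPLParams, NoiseSpec, fit_fourpl, gen_competition_curve

truth = FourPLParams(min=0.05, max=0.20, IC50=59.0, Hillslope=1.0)
curve = gen_competition_curve(truth, noise=NoiseSpec(sd=0.0015, seed=3))

fit = fit_fourpl(curve)
p = fit.params
print(f"generated with IC50 = 59 uM (2R-competitor scenario)")
print(f"recovered IC50 = {p.IC50:.1f} uM  (stderr {fit.stderr['IC50']:.1f})")
print(f"Hillslope = {p.Hillslope:.2f}, asymptotes {p.min:.3f} / {p.max:.3f}")
print("A lower IC50 means the competitor displaces the probe at lower")
print("concentration, i.e. binds the protein more avidly.")
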