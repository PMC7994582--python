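"""Per-residue CSP Kd fitting and aggregation for an HSQC titration.

20 residues of a 100 µM protein are titrated with peptide to ratio 3; each
residue's chemical-shift perturbation follows the fast-exchange weighted
average with ligand depletion.  Residues with endpoint CSP > 0.03 ppm are
averaged into the aggregate Kd.
"""

from ctdbind import (NoiseSpec, aggregate_kd, classify_csp, compute_csp,
                     fit_residues, gen_hsqc_titration)

series = gen_hsqc_titration(n_residues=20, kd=9.1, noise=NoiseSpec(0.002, 7))
csps = [compute_csp(s) for s in series]
fits, failures = fit_residues(series)
agg = aggregate_kd(fits, csps, failures=failures)

print(f"generated with Kd = 9.1 uM")
print(f"aggregate Kd = {agg.mean:.2f} +/- {agg.sd:.2f} uM "
      f"(n = {agg.n} residues over threshold)")
for rid, reason in agg.exclusions.items():
    print(f"  residue {rid} excluded: {reason}")
classes = [classify_csp(c) for c in csps]
print("CSP classes:", {c: classes.count(c) for c in set(classes)})
print("The mean is taken over residues whose endpoint CSP clears 0.03 ppm;")
print("its SD reports residue-to-residue scatter, not a fit standard error.")
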