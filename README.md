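# ctdbind

Quantitative binding analysis for multivalent interactions between the
two-domain prolyl isomerase Ess1 (the yeast ortholog of human Pin1) and
phosphorylated heptad-repeat peptides from the RNA polymerase II
carboxy-terminal domain (CTD).

Ess1 carries a pSer-Pro-binding WW domain and a catalytic PPIase domain.
Whether one Ess1 molecule can engage two phospho-motifs on the same CTD
peptide — bivalent binding — is decided by orthogonal solution
measurements, each of which this package implements as a fit with a seeded
synthetic-data generator for validation:

- **SV-AUC sw isotherms.** A two-site receptor (the peptide, carrying two
  pSer5-Pro6 motifs) titrated with Ess1. The signal-weighted sedimentation
  coefficient follows

  θ = a + b·(ES + SE + 2·SES)/(E + ES + SE + SES),

  where the species come from independent-site mass action
  (SE = E·S/K_d1, ES = E·S/K_d2, SES = E·S²/(K_d1·K_d2) — the
  thermodynamic-cycle constraint), a is the free-peptide sw and b the sw
  increment per bound Ess1. Fitting recovers the microscopic K_d1, K_d2.
- **NMR CSP titrations.** Per-residue chemical-shift perturbations
  CSP = √(Δδ_H² + (Δδ_N/5)²) follow the fast-exchange weighted average
  Δδ = Δδ_bound·[PL]/[P_total], with [PL] from the single-site
  ligand-depletion quadratic. Residues with endpoint CSP > 0.03 ppm are
  averaged into an aggregate K_d ± SD.
- **Competition fluorescence anisotropy.** Displacement of an FITC-labeled
  probe by unlabeled competitor, summarized by a four-parameter logistic
  f(x) = min + (max−min)/(1 + (x/IC50)^(−Hillslope)).
- **SAXS Guinier analysis.** Iterative linear fit of ln I vs q² restricted
  to q·R_g ≤ 1.3, plus linear extrapolation of R_g to infinite dilution.
- **Peptide grammar.** CTD peptides in repeat notation, e.g.
  `AS(YSPTpSPS)(YSPTSPS)(YSPTpSPS)YS`: motif positions, motif spacing
  (7·(n−1) residues for terminal-phosphorylated nR peptides), and 280-nm
  extinction coefficients (1280 M⁻¹cm⁻¹ per Tyr).

## Worked example

Fitting a simulated 5R-peptide sw isotherm (12 points, 0.5–1000 µM Ess1
into 50 µM peptide, 0.01 S noise) with the baseline fixed and b floated:

```bash
$ python examples/02_auc_two_site_isotherm.py
generated with Kd1 = 21.5 uM, Kd2 = 5990 uM, b = 1.48 S
recovered Kd1 = 20.4 uM  (tight site, WW-domain-like)
recovered Kd2 = 4981.66 uM  (weak site, PPIase-like)
recovered b   = 1.457 S  (sw increment per bound protein)
weighted RSS = 1.04e+01 over 12 points
```

K_d1 returns within a few percent of the generative value: the isotherm
pins the tight site. K_d2 is softer because the weak site barely populates
below 1 mM titrant. The other examples (`examples/01` … `05`) walk through
the peptide grammar, the NMR aggregate K_d, the IC50 fit, and the Guinier
pipeline the same way.

The same analyses are exposed on a thin CLI:

```bash
ctdbind peptide --name NMR-5R          # motif spacing 28, eps280 7680
ctdbind simulate isotherm --kd1 21.5 --kd2 5990 --seed 1 --out iso.csv
ctdbind fit-auc iso.csv --float-b
ctdbind recover --scenario nmr-5r --seed 7
```

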