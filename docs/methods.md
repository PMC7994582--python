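# Methods

This note documents the models implemented in `ctdbind`, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the design decisions that were genuinely open.

## Binding equilibria

All concentrations are µM; all solvers are deterministic closed forms or
bracketed 1-D root problems.

**Single site with ligand depletion.** The bound complex is the physical
root of mass action with both totals conserved,

    [PL] = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / 2,

evaluated in the conjugate form 2PL/(P+L+Kd+√disc) to avoid cancellation
when [PL] is far below the totals. This matters for NMR titrations, where
protein at 100 µM is comparable to the Kds being measured and the
dilute-ligand hyperbola would bias Kd upward.

**Two-site receptor.** The sw-isotherm model treats the two-motif peptide
as a receptor E with two independent sites for the titrant S:

    SE = E·S/Kd1,  ES = E·S/Kd2,  SES = E·S²/(Kd1·Kd2).

Site independence *is* the thermodynamic-cycle constraint here: the free
energy of double occupancy is the sum of the two single-site steps
regardless of order, with no cooperativity term, so two fitted constants
describe four species. Kd1 and Kd2 are microscopic constants with no
statistical factors. Free titrant is solved by Brent's method on
[0, S_total] (the conservation residual is monotone, so the root is
unique); conservation holds to ~1e−12 relative in practice. A note on
naming: the species algebra is identical whether SES is read as one
peptide bridging two protein molecules or two ligands on one receptor; the
implementation and naming follow the two-site-receptor reading because it
makes the peptide-signal observable well-defined and saturable.

**Competition.** Probe and competitor share one site; free protein is the
root of its conservation equation on [0, P_total]. This exact model backs
the optional equilibrium mode of the competition generator; the headline
IC50 analysis is the empirical 4PL, as is standard for plate-reader
competition data.

## SV-AUC sw isotherms

The observable is θ = a + b·(occupied sites per peptide), where
occupancy ∈ [0, 2], a is the free-peptide sw and b the increment per bound
protein; θ saturates at a + 2b. Defaults a = 0.61 S and b = 1.48 S are the
values determined on the best-conditioned (5R) titration and are held
fixed unless `float_b` is set — floating b accommodates titrations where a
conformational change alters the hydrodynamics of the saturated complex
(the 4R case, which fits with b ≈ 1.04 S).

Fitting is unweighted (or 1/σ-weighted when per-point errors are present)
least squares over log10 Kd1 and log10 Kd2 within [1e−3, 1e6] µM, with
8 multistart points (one central, seven log-uniform from a fixed seed);
best RSS wins, ties break toward smaller Kd1. Fitting in Kd space is
exactly equivalent at equilibrium to the kinetic parameterization with the
association rate fixed at 1 and dissociation rates floated (Kd = koff/kon),
and avoids an ODE integrator with no observable consequence. A Kd2
converging onto the upper search bound means the isotherm carries no
information on the weak site; it is flagged and rendered as a
"> bound" string rather than reported as a measured value.

c(s) distributions are reduced to sw by trapezoidal quadrature of
s·c(s)/∫c(s) over the 0.5–4 S window, with linear interpolation at window
edges; a window containing no signal raises an explicit `NoSignalError`
rather than returning a silent zero. Computing c(s) from raw boundary
scans is out of scope — c(s) tables are consumed as produced by standard
sedimentation software.

## NMR CSP titrations

CSP = √(Δδ_H² + (Δδ_N/5)²) relative to the apo reference; the nitrogen
scale factor is fixed at 5 with no per-residue weighting. Each residue is
fit to CSP(L) = Δδ_bound·[PL]/P_total with the depletion quadratic,
Kd in log space within [0.01, 1e5] µM starting at the titration's median
ligand concentration, Δδ_bound ≥ 0 starting at the endpoint CSP and
floated per residue (fixing it at the endpoint would bias Kd low whenever
the endpoint is short of saturation). Residues broadened beyond detection
are in intermediate exchange, where the weighted-average model is invalid;
they are excluded from fitting and classified separately for structure
mapping (classes: broadened > strong CSP > 0.1 ppm > moderate > 0.03 ppm >
none; thresholds strict).

The aggregate Kd is the unweighted mean over residues whose endpoint CSP
exceeds 0.03 ppm, with the population (ddof = 0) standard deviation; the
SD describes residue-to-residue scatter, not a standard error of the mean.
No global shared-Kd fit is performed for the headline number — per-residue
averaging is the procedure being reproduced — though `fit_residues`
returns everything needed to build one as a diagnostic.

## Competition anisotropy

The 4PL is implemented exactly as written above, with the exponent
−Hillslope. Under this convention Hillslope > 0 rises from min to max with
concentration and Hillslope < 0 descends; IC50 is the midpoint either way,
and the fit tries both slope orientations among its starting points, so
curve orientation never changes the recovered IC50. min and max are
unconstrained (initialized at the observed plateaus); IC50 is fit in log
space with seeded multistart. A curve whose response range is
indistinguishable from zero is flagged degenerate and no IC50 is reported.
No Cheng-Prusoff conversion to Ki is applied anywhere in headline output:
with probe and protein at 1 and 50 µM the assay is depletion-heavy and
IC50s are comparative measures only.

## SAXS Guinier analysis

ln I is fit linearly in q², weighted by I/σ_I when errors are present,
starting from the 10 lowest-q points; the window is then shrunk to
q·Rg ≤ 1.3 and refit until Rg changes by < 0.1 %, requiring at least five
points throughout. Rg = √(−3·slope); a non-negative slope raises an
invalid-Guinier error (no decaying region), and a window that cannot hold
five points raises an insufficient-data error. The fitted window is
asserted post hoc to satisfy the qRg rule. Rg values across the
concentration series are extrapolated to c = 0 by ordinary least squares;
the slope is reported in Å per (mg/mL). Everything beyond the Guinier
region — P(r), envelopes, model curves — is out of scope.

## Synthetic-data generators

Each generator samples the exact forward model its fitter assumes plus
Gaussian noise, under the study designs: 12 log-spaced titrant points
0.5–1000 µM into 50 µM peptide (AUC); 100 µM protein with 8-point
peptide:protein ratio grids reaching 3 (multi-repeat) or 6 (1R) — the
endpoints are the documented design, the interior grid is a package
choice; 10 competitor concentrations, 0 plus log-spaced 1–350 µM; q from
0.01 to 0.12 Å⁻¹ in 60 steps at 1.57/3.19/4.78 mg/mL. Default noise
magnitudes — 0.01 S (sw), 0.002 ppm (¹H shifts, ¹⁵N scaled ×5 so the CSP
noise is isotropic), 1 % of range (anisotropy), 0.5 % multiplicative
(SAXS) — are plausible instrument-class values, configurable, and recorded
in generator sidecar output; they are not calibrated to any instrument.

Determinism: every generator is a pure function of (parameters, seed), and
per-item substreams are spawned from the one seed (`SeedSequence.spawn`),
so enlarging a residue panel never perturbs existing draws.

What the generators deliberately do **not** emulate: baseline drift or
reaction-boundary effects in sw isotherms (data are drawn from the same
equilibrium model that is fit); exchange-regime crossover, peak overlap,
or assignment errors in HSQC titrations (broadening must be flagged
explicitly); G-factor/intensity artifacts in anisotropy; beam smearing,
buffer-subtraction error, or aggregation upturns in SAXS. Passing
recovery tests therefore demonstrates the estimators are correct and
well-conditioned under their own assumptions — not that those assumptions
hold for any particular instrument record.

## Problem sizes and numerical settings

Recovery scenarios use the study-scale designs throughout (12-point
isotherms, 20-residue NMR panels, 10-point competition curves, 3-profile
Guinier series); Monte-Carlo property tests use handfuls of replicates,
which is enough to resolve the monotonic trends they assert. Optimizer
tolerances are 1e−12 (xtol/ftol/gtol) on all lmfit least-squares runs;
equilibrium root solves use Brent with near-machine rtol. Parameter
standard errors are delta-method transforms of the log-space covariance
and are absent when the Jacobian is degenerate.

## Known limitations

- The two-site model assumes the titrant signal contribution per occupied
  site is constant (a single b); strongly shape-changing complexes violate
  this unless b is floated.
- Per-residue Kd precision degrades for weakly perturbed residues
  (endpoint CSP near the 0.03 ppm threshold at 0.002 ppm noise); the
  aggregate mean is robust but individual Kds near threshold carry ~10 %+
  error.
- The 1R weak-site Kd2 is reported only as a bound, mirroring the
  information content of a single-motif isotherm.
- CSV inputs carry no unit metadata; units are fixed by the dialect
  (µM, ppm, Svedberg, Å⁻¹, mg/mL).
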