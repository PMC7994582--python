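"""NMR chemical-shift-perturbation (CSP) titration analysis.

Binding of a CTD phosphopeptide to ¹⁵N-labeled protein is followed through
¹H–¹⁵N HSQC spectra recorded at increasing peptide:protein ratios.  In fast
exchange each amide's observed shift is the population-weighted average of
its free and bound values, so the per-residue perturbation

    CSP = sqrt(ΔδH² + (ΔδN/5)²)

grows as Δδ_bound·[PL]/P_total, with [PL] from the ligand-depletion
quadratic (protein at 100 µM is comparable to the Kds being measured, so
the dilute-ligand hyperbola would be badly biased).  Fitting each residue
yields a per-residue Kd; residues whose endpoint CSP clears a significance
threshold (0.03 ppm) are averaged into the reported aggregate Kd ± SD.

Residues broadened beyond detection during the titration are in
intermediate exchange, where the weighted-average model does not hold; they
are excluded from fitting and flagged for structure mapping instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .equilibria import SingleSiteSystem, solve_single_site

__all__ = [
    "TitrationSeries",
    "CSPRecord",
    "ResidueFit",
    "ResidueFitFailure",
    "AggregateKd",
    "NITROGEN_SCALE",
    "CSP_THRESHOLD_PPM",
    "CSP_STRONG_PPM",
    "compute_csp",
    "fit_residue_kd",
    "fit_residues",
    "aggregate_kd",
    "classify_csp",
    "assignment_completeness",
]

#: ¹⁵N shift scaling in the CSP formula (amide nitrogen ppm range is ~5×
#: wider than amide proton).
NITROGEN_SCALE = 5.0

#: Endpoint CSP above which a residue is considered perturbed (ppm).
CSP_THRESHOLD_PPM = 0.03
#: Endpoint CSP above which a perturbation is classed strong (ppm).
CSP_STRONG_PPM = 0.1

KD_BOUNDS = (1e-2, 1e5)  # µM


@dataclass(frozen=True)
class TitrationSeries:
    """One residue's amide shifts across an HSQC titration.

    points[i] = (L_total µM, δH ppm, δN ppm); the first point must be the
    apo reference (L_total = 0).  broadened[i] marks resonances broadened
    beyond detection at that point (their shift entries are ignored).
    """

    residue_id: int
    residue_name: str
    points: np.ndarray          # shape (n, 3): L_total, dH, dN
    P_total: float              # µM
    broadened: np.ndarray | None = None  # bool per point

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (L_total, dH, dN)")
        br = (np.zeros(pts.shape[0], dtype=bool) if self.broadened is None
              else np.asarray(self.broadened, dtype=bool))
        object.__setattr__(self, "broadened", br)
        if br.shape != (pts.shape[0],):
            raise ValueError("broadened flags must match the number of points")
        if pts[0, 0] != 0:
            raise ValueError("first titration point must be the apo reference (L_total = 0)")
        if br[0]:
            raise ValueError("apo reference point cannot be broadened")
        if np.any(np.diff(pts[:, 0]) < 0):
            raise ValueError("L_total must be nondecreasing")

    @property
    def L_total(self) -> np.ndarray:
        return self.points[:, 0]


@dataclass(frozen=True)
class CSPRecord:
    """Per-point CSPs for one residue; NaN where the peak was broadened."""

    residue_id: int
    csp: np.ndarray        # ppm, per titration point
    endpoint_csp: float    # ppm (NaN if the final point is broadened)
    endpoint_broadened: bool = False


@dataclass(frozen=True)
class ResidueFit:
    residue_id: int
    Kd: float              # µM
    delta_bound: float     # ppm
    Kd_stderr: float | None
    rss: float
    n_points: int


@dataclass(frozen=True)
class ResidueFitFailure:
    residue_id: int
    reason: str


@dataclass(frozen=True)
class AggregateKd:
    mean: float | None     # µM; None when no residue qualifies
    sd: float | None       # µM, population SD over contributing residues
    residues: tuple[int, ...]
    exclusions: dict[int, str]

    @property
    def n(self) -> int:
        return len(self.residues)


def compute_csp(series: TitrationSeries) -> CSPRecord:
    """CSP at every titration point relative to the apo reference."""
    dh = series.points[:, 1] - series.points[0, 1]
    dn = series.points[:, 2] - series.points[0, 2]
    csp = np.sqrt(dh ** 2 + (dn / NITROGEN_SCALE) ** 2)
    csp[series.broadened] = np.nan
    endpoint_broadened = bool(series.broadened[-1])
    endpoint = float("nan") if endpoint_broadened else float(csp[-1])
    return CSPRecord(series.residue_id, csp, endpoint,
                     endpoint_broadened=endpoint_broadened)


def fit_residue_kd(series: TitrationSeries) -> ResidueFit:
    """Fit CSP(L_total) = Δδ_bound·[PL]/P_total for one residue.

    [PL] comes from the single-site quadratic with ligand depletion.  Kd is
    fit in log space within [0.01, 1e5] µM, starting from the titration's
    midpoint ligand concentration; Δδ_bound starts at the endpoint CSP.
    Raises ValueError when the series is unusable (too few points, flat
    CSP); callers running many residues should use :func:`fit_residues`.
    """
    rec = compute_csp(series)
    usable = ~series.broadened
    L = series.L_total[usable]
    y = rec.csp[usable]
    if L.size < 4:
        raise ValueError("need at least 4 usable titration points")
    endpoint = y[-1]
    if not endpoint > 0:
        raise ValueError("endpoint CSP is zero; nothing to fit")

    p_tot = series.P_total

    def model(log_kd: float, dbound: float) -> np.ndarray:
        kd = 10.0 ** log_kd
        pl = np.array([solve_single_site(SingleSiteSystem(p_tot, l, kd))
                       for l in L])
        return dbound * pl / p_tot

    pars = lmfit.Parameters()
    kd_start = max(KD_BOUNDS[0] * 10, min(float(np.median(L[L > 0])), KD_BOUNDS[1] / 10))
    pars.add("log_kd", value=np.log10(kd_start),
             min=np.log10(KD_BOUNDS[0]), max=np.log10(KD_BOUNDS[1]))
    pars.add("dbound", value=float(endpoint), min=0.0, max=10.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return y - model(p["log_kd"].value, p["dbound"].value)

    res = lmfit.minimize(residual, pars, method="least_squares",
                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not res.success:
        raise ValueError(f"residue {series.residue_id}: fit did not converge")
    kd = 10.0 ** res.params["log_kd"].value
    err = res.params["log_kd"].stderr
    return ResidueFit(
        residue_id=series.residue_id,
        Kd=float(kd),
        delta_bound=float(res.params["dbound"].value),
        Kd_stderr=None if err is None else float(math.log(10.0) * kd * err),
        rss=float(np.sum(np.asarray(res.residual) ** 2)),
        n_points=int(L.size),
    )


def fit_residues(
    series_list: list[TitrationSeries],
) -> tuple[list[ResidueFit], list[ResidueFitFailure]]:
    """Fit every residue, collecting failures instead of raising."""
    fits, failures = [], []
    for s in series_list:
        try:
            fits.append(fit_residue_kd(s))
        except (ValueError, RuntimeError) as exc:
            failures.append(ResidueFitFailure(s.residue_id, str(exc)))
    return fits, failures


def aggregate_kd(
    fits: list[ResidueFit],
    csps: list[CSPRecord],
    threshold: float = CSP_THRESHOLD_PPM,
    failures: list[ResidueFitFailure] | None = None,
) -> AggregateKd:
    """Average per-residue Kds over residues with endpoint CSP > threshold.

    The mean is unweighted; the SD is the population standard deviation of
    the contributing Kds.  Excluded residues are itemized with the reason
    (sub-threshold endpoint, broadened endpoint, or failed fit).
    """
    csp_by_id = {r.residue_id: r for r in csps}
    exclusions: dict[int, str] = {}
    kds, ids = [], []
    for f in fits:
        rec = csp_by_id.get(f.residue_id)
        if rec is None:
            exclusions[f.residue_id] = "no CSP record"
            continue
        if rec.endpoint_broadened:
            exclusions[f.residue_id] = "endpoint broadened beyond detection"
            continue
        if not rec.endpoint_csp > threshold:
            exclusions[f.residue_id] = (
                f"endpoint CSP {rec.endpoint_csp:.4f} ppm <= threshold {threshold} ppm"
            )
            continue
        kds.append(f.Kd)
        ids.append(f.residue_id)
    for fail in failures or []:
        exclusions[fail.residue_id] = f"fit failed: {fail.reason}"
    if not kds:
        return AggregateKd(None, None, (), exclusions)
    arr = np.asarray(kds)
    return AggregateKd(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        residues=tuple(ids),
        exclusions=exclusions,
    )


def classify_csp(record: CSPRecord, broadened: bool = False) -> str:
    """Structure-mapping class: broadened > strong (>0.1) > moderate (>0.03) > none."""
    if broadened or record.endpoint_broadened:
        return "broadened"
    if record.endpoint_csp > CSP_STRONG_PPM:
        return "strong"
    if record.endpoint_csp > CSP_THRESHOLD_PPM:
        return "moderate"
    return "none"


def assignment_completeness(assigned: int, total: int) -> tuple[float, int]:
    """Resonance-assignment completeness as (exact %, rounded %)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= assigned <= total:
        raise ValueError("assigned must be within [0, total]")
    exact = 100.0 * assigned / total
    return exact, round(exact)
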