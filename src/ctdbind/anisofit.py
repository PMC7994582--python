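"""Competition fluorescence-anisotropy IC50 fitting.

In the competition assay an FITC-labeled probe peptide is pre-bound to the
protein and unlabeled competitor peptides are titrated in; displacement of
the probe lowers the measured anisotropy.  Curves are summarized by the
four-parameter logistic (4PL)

    f(x) = min + (max − min) / (1 + (x / IC50)^(−Hillslope))

where x is the competitor concentration.  With this exponent convention a
positive Hillslope rises from *min* toward *max* with increasing x and a
negative Hillslope gives the mirror-image descending curve; IC50 is the
midpoint either way, so the recovered IC50 does not depend on which
orientation the data were generated or recorded in.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "FourPLParams",
    "CompetitionCurve",
    "FourPLFitResult",
    "fourpl_response",
    "fit_fourpl",
]


@dataclass(frozen=True)
class FourPLParams:
    """4PL parameters: response asymptotes, midpoint, and slope."""

    min: float        # anisotropy at the low-response asymptote
    max: float        # anisotropy at the high-response asymptote
    IC50: float       # µM
    Hillslope: float  # dimensionless

    def __post_init__(self) -> None:
        if not self.IC50 > 0:
            raise ValueError("IC50 must be positive")
        if self.max < self.min:
            raise ValueError("max must be >= min")


@dataclass(frozen=True)
class CompetitionCurve:
    """Anisotropy vs competitor concentration, plus assay composition."""

    competitor_total: np.ndarray  # µM, nondecreasing, may include 0
    response: np.ndarray          # anisotropy
    probe_total: float = 1.0      # µM
    protein_total: float = 50.0   # µM

    def __post_init__(self) -> None:
        x = np.asarray(self.competitor_total, dtype=float)
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "competitor_total", x)
        object.__setattr__(self, "response", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1-D arrays")
        if np.any(np.diff(x) < 0):
            raise ValueError("competitor concentrations must be nondecreasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")

    def __len__(self) -> int:
        return self.competitor_total.size


@dataclass(frozen=True)
class FourPLFitResult:
    params: FourPLParams | None
    stderr: dict[str, float | None]
    rss: float | None
    degenerate: bool
    degenerate_reason: str | None = None


def fourpl_response(p: FourPLParams, x) -> float | np.ndarray:
    """Evaluate the 4PL at concentration x (µM); x = 0 returns the asymptote."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("concentration must be nonnegative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(xa > 0, xa / p.IC50, np.nan)
        term = ratio ** (-p.Hillslope)
        f = p.min + (p.max - p.min) / (1.0 + term)
    # limit at x -> 0: term -> inf for Hillslope > 0 (f -> min), 0 otherwise
    zero_val = p.min if p.Hillslope > 0 else p.max
    f = np.where(xa == 0, zero_val, f)
    return float(f) if xa.ndim == 0 else f


def fit_fourpl(
    curve: CompetitionCurve,
    ic50_bounds: tuple[float, float] = (1e-3, 1e5),
    n_starts: int = 6,
    seed: int = 20201104,
) -> FourPLFitResult:
    """Least-squares 4PL fit with seeded multistart.

    min/max are unconstrained (initialized from the observed plateaus), the
    Hillslope floats with both sign orientations among the starting points,
    and IC50 is fit in log space.  A curve with no transition — response
    range indistinguishable from zero — is flagged degenerate and no IC50
    is reported.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    x, y = curve.competitor_total, curve.response
    span = float(y.max() - y.min())
    scale = max(abs(float(np.median(y))), 1e-12)
    if span < 1e-12 or span < 1e-4 * scale:
        return FourPLFitResult(None, {}, None, True,
                               "flat response: no transition to fit")

    pos = x[x > 0]
    rng = np.random.default_rng(seed)
    ic50_starts = [float(np.sqrt(pos.min() * pos.max()))]
    ic50_starts += list(10.0 ** rng.uniform(np.log10(pos.min()),
                                            np.log10(pos.max()),
                                            size=max(n_starts - 1, 0)))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        pars = FourPLParams(p["fmin"].value,
                            p["fmin"].value + p["span"].value,
                            10.0 ** p["log_ic50"].value,
                            p["hill"].value)
        return y - fourpl_response(pars, x)

    # response is monotone in x; the sign of the slope fixes the Hill sign
    ascending = y[-1] >= y[0]
    best = None
    for ic50_0 in ic50_starts:
        for hill_0 in (1.0, -1.0):
            p = lmfit.Parameters()
            p.add("fmin", value=float(y.min()))
            p.add("span", value=span, min=0.0)
            p.add("log_ic50", value=np.log10(ic50_0),
                  min=np.log10(ic50_bounds[0]), max=np.log10(ic50_bounds[1]))
            p.add("hill", value=hill_0 if ascending else -hill_0)
            try:
                res = lmfit.minimize(residual, p, method="least_squares",
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:  # noqa: BLE001
                continue
            rss = float(np.sum(np.asarray(res.residual) ** 2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        return FourPLFitResult(None, {}, None, True, "all starts failed")

    rss, res = best
    p = res.params
    ic50 = 10.0 ** p["log_ic50"].value
    fitted = FourPLParams(
        min=float(p["fmin"].value),
        max=float(p["fmin"].value + p["span"].value),
        IC50=float(ic50),
        Hillslope=float(p["hill"].value),
    )
    err = p["log_ic50"].stderr
    stderr = {
        "IC50": None if err is None else float(np.log(10.0) * ic50 * err),
        "Hillslope": (None if p["hill"].stderr is None
                      else float(p["hill"].stderr)),
        "min": None if p["fmin"].stderr is None else float(p["fmin"].stderr),
    }
    return FourPLFitResult(fitted, stderr, rss, False)
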