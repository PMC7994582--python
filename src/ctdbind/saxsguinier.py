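"""Guinier analysis of small-angle X-ray scattering profiles.

At low momentum transfer a monodisperse particle scatters as
I(q) = I(0)·exp(−q²Rg²/3), so ln I is linear in q² with slope −Rg²/3.  The
approximation holds only while q·Rg ≲ 1.3; because Rg is itself the fit
output, the window is found iteratively: fit, shrink the window to
q·Rg ≤ 1.3, refit, until Rg stabilizes.  Rg measured at several protein
concentrations is extrapolated linearly to infinite dilution to remove
interparticle-interference bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScatterProfile",
    "GuinierFit",
    "InvalidGuinierError",
    "InsufficientDataError",
    "QRG_LIMIT",
    "guinier_fit",
    "extrapolate_rg_infinite_dilution",
]

#: Guinier validity cutoff on q·Rg.
QRG_LIMIT = 1.3

_MIN_POINTS = 5
_RTOL_CONVERGED = 1e-3   # Rg relative change between window iterations
_QRG_NUMERIC_TOL = 1e-9


class InvalidGuinierError(ValueError):
    """Intensity does not decay at low q; no Guinier region exists."""


class InsufficientDataError(ValueError):
    """Too few points remain inside the qRg-limited window."""


@dataclass(frozen=True)
class ScatterProfile:
    """A 1-D scattering profile I(q) at one protein concentration."""

    q: np.ndarray              # Å⁻¹, strictly increasing, > 0
    I: np.ndarray              # arbitrary units
    I_err: np.ndarray | None = None
    concentration: float = 0.0  # mg/mL

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", i)
        if self.I_err is not None:
            object.__setattr__(self, "I_err", np.asarray(self.I_err, dtype=float))
        if q.ndim != 1 or q.shape != i.shape:
            raise ValueError("q and I must be equal-length 1-D arrays")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be positive and strictly increasing")


@dataclass(frozen=True)
class GuinierFit:
    Rg: float                    # Å
    I0: float                    # zero-angle intensity, same units as I
    q_window: tuple[float, float]
    n_points: int
    concentration: float = 0.0   # mg/mL

    def __post_init__(self) -> None:
        if not self.Rg > 0:
            raise ValueError("Rg must be positive")
        if self.q_window[1] * self.Rg > QRG_LIMIT + 1e-6 * self.Rg:
            raise ValueError("fitted window violates the qRg limit")


def _linfit(q2: np.ndarray, ln_i: np.ndarray,
            w: np.ndarray | None) -> tuple[float, float]:
    """Weighted straight line ln I = intercept + slope·q²."""
    coef = np.polyfit(q2, ln_i, 1, w=w)
    return float(coef[0]), float(coef[1])  # slope, intercept


def guinier_fit(p: ScatterProfile, qrg_limit: float = QRG_LIMIT,
                max_iter: int = 100) -> GuinierFit:
    """Iterative Guinier fit with the qRg window rule.

    Starts from the lowest-q points, estimates Rg, restricts the window to
    q·Rg ≤ *qrg_limit*, and refits until Rg changes by <0.1% between
    iterations.  Errors-weighted (w = I/σ_I in log space) when I_err is
    present.  Raises :class:`InvalidGuinierError` for non-decaying
    intensity and :class:`InsufficientDataError` when the window cannot
    hold five points.
    """
    valid = p.I > 0
    q, i = p.q[valid], p.I[valid]
    err = p.I_err[valid] if p.I_err is not None else None
    if q.size < _MIN_POINTS:
        raise InsufficientDataError("fewer than 5 positive-intensity points")

    q2 = q ** 2
    ln_i = np.log(i)
    w = (i / err) if err is not None else None  # sd of ln I is err/I

    def fit_window(mask: np.ndarray) -> tuple[float, float]:
        slope, intercept = _linfit(q2[mask], ln_i[mask],
                                   None if w is None else w[mask])
        if slope >= 0:
            raise InvalidGuinierError(
                "non-decaying intensity at low q (slope >= 0); "
                "no Guinier region"
            )
        return float(np.sqrt(-3.0 * slope)), float(np.exp(intercept))

    # initial window: the first 10 points (or all, if fewer)
    mask = np.zeros(q.size, dtype=bool)
    mask[: min(10, q.size)] = True
    rg, i0 = fit_window(mask)

    for _ in range(max_iter):
        new_mask = q * rg <= qrg_limit + _QRG_NUMERIC_TOL
        if new_mask.sum() < _MIN_POINTS:
            raise InsufficientDataError(
                f"qRg <= {qrg_limit} window holds only {int(new_mask.sum())} "
                "points; need 5"
            )
        new_rg, i0 = fit_window(new_mask)
        converged = abs(new_rg - rg) < _RTOL_CONVERGED * rg
        rg, mask = new_rg, new_mask
        if converged:
            break

    # the converged window must itself satisfy the limit
    q_in = q[mask]
    if q_in[-1] * rg > qrg_limit + _QRG_NUMERIC_TOL:
        mask = q * rg <= qrg_limit + _QRG_NUMERIC_TOL
        if mask.sum() < _MIN_POINTS:
            raise InsufficientDataError("window collapsed below 5 points")
        rg, i0 = fit_window(mask)
        q_in = q[mask]

    return GuinierFit(
        Rg=rg,
        I0=i0,
        q_window=(float(q_in[0]), float(q_in[-1])),
        n_points=int(mask.sum()),
        concentration=p.concentration,
    )


def extrapolate_rg_infinite_dilution(
    fits: list[tuple[float, float]],
) -> tuple[float, float]:
    """Extrapolate (concentration mg/mL, Rg Å) pairs to zero concentration.

    Ordinary least-squares line Rg(c) = intercept + slope·c; returns
    (intercept, slope).  The intercept is the infinite-dilution Rg.
    """
    if len(fits) < 2:
        raise ValueError("need Rg at >= 2 concentrations to extrapolate")
    c = np.asarray([f[0] for f in fits], dtype=float)
    rg = np.asarray([f[1] for f in fits], dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    slope, intercept = np.polyfit(c, rg, 1)
    return float(intercept), float(slope)
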