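"""Closed-form and numerical binding-equilibrium solvers.

Three equilibria underlie every fit in this package:

* single site with ligand depletion — the quadratic used to convert total
  concentrations into bound complex when the protein concentration is not
  negligible against the dissociation constant (NMR titrations at 100 µM
  protein are deep in this regime);
* a two-site receptor with independent microscopic sites, the model behind
  the sedimentation-velocity sw isotherms.  Site independence is the
  thermodynamic-cycle constraint: the free energy of filling both sites is
  path independent and each step uses that site's own microscopic Kd, so the
  doubly bound species is governed by the product Kd1·Kd2 with no
  cooperativity term;
* two ligands competing for one shared site, the exact generative model
  behind competition anisotropy curves.

All concentrations are in µM.  Each solver reduces to a bracketed 1-D root
problem in one free concentration, which is monotone, so the solution is
unique and found to near machine precision by Brent's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "SingleSiteSystem",
    "TwoSiteParams",
    "SpeciesState",
    "solve_single_site",
    "solve_two_site",
    "solve_competitive",
]

_XTOL = 1e-14


@dataclass(frozen=True)
class SingleSiteSystem:
    """One protein, one ligand, one site."""

    P_total: float  # µM
    L_total: float  # µM
    Kd: float       # µM

    def __post_init__(self) -> None:
        if self.P_total < 0 or self.L_total < 0:
            raise ValueError("total concentrations must be nonnegative")
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")


@dataclass(frozen=True)
class TwoSiteParams:
    """Microscopic dissociation constants of the two sites (µM).

    By convention site 1 is the tighter (WW-domain-like) site.  No
    statistical factors are applied; Kd1 and Kd2 are reported as-is.
    """

    Kd1: float
    Kd2: float

    def __post_init__(self) -> None:
        if not (self.Kd1 > 0 and self.Kd2 > 0):
            raise ValueError("dissociation constants must be positive")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species of the two-site system (µM).

    E is the free two-site molecule, S_free the free titrant; SE and ES are
    the singly occupied species (site 1 and site 2 respectively) and SES is
    doubly occupied.
    """

    E: float
    S_free: float
    SE: float
    ES: float
    SES: float

    @property
    def E_total(self) -> float:
        return self.E + self.SE + self.ES + self.SES

    @property
    def S_total(self) -> float:
        return self.S_free + self.SE + self.ES + 2.0 * self.SES

    @property
    def occupancy(self) -> float:
        """Mean number of occupied sites per two-site molecule, in [0, 2]."""
        tot = self.E_total
        if tot == 0:
            return 0.0
        return (self.SE + self.ES + 2.0 * self.SES) / tot


def solve_single_site(sys: SingleSiteSystem) -> float:
    """Bound complex [PL] (µM) from the ligand-depletion quadratic.

    [PL] = ((P+L+Kd) − sqrt((P+L+Kd)² − 4·P·L)) / 2, the physical root of
    mass action with both totals conserved; always within [0, min(P, L)].
    """
    p, l, kd = sys.P_total, sys.L_total, sys.Kd
    s = p + l + kd
    disc = s * s - 4.0 * p * l
    # conjugate form of the small root: avoids cancellation when [PL] << s
    pl = 2.0 * p * l / (s + math.sqrt(max(disc, 0.0)))
    return min(max(pl, 0.0), min(p, l))


def solve_two_site(E_total: float, S_total: float, k: TwoSiteParams) -> SpeciesState:
    """Equilibrium species of a two-site receptor titrated with S.

    Mass action with independent sites:
    SE = E·S/Kd1, ES = E·S/Kd2, SES = E·S²/(Kd1·Kd2).  Free titrant S is the
    root of its own conservation equation, bracketed on [0, S_total].
    """
    if E_total < 0 or S_total < 0:
        raise ValueError("total concentrations must be nonnegative")
    if S_total == 0 or E_total == 0:
        return SpeciesState(E=E_total, S_free=S_total, SE=0.0, ES=0.0, SES=0.0)

    kd1, kd2 = k.Kd1, k.Kd2

    def free_E(s: float) -> float:
        return E_total / (1.0 + s / kd1 + s / kd2 + s * s / (kd1 * kd2))

    def residual(s: float) -> float:
        e = free_E(s)
        bound = e * (s / kd1 + s / kd2 + 2.0 * s * s / (kd1 * kd2))
        return s + bound - S_total

    # residual(0) = -S_total < 0; residual(S_total) >= 0; monotone in s.
    try:
        s = brentq(residual, 0.0, S_total, xtol=_XTOL * max(1.0, S_total),
                   rtol=8.9e-16, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq converges here
        raise RuntimeError(
            f"two-site root solve failed (E_total={E_total}, "
            f"S_total={S_total}, Kd1={kd1}, Kd2={kd2}): {exc}"
        ) from exc
    e = free_E(s)
    return SpeciesState(
        E=e,
        S_free=s,
        SE=e * s / kd1,
        ES=e * s / kd2,
        SES=e * s * s / (kd1 * kd2),
    )


def solve_competitive(
    P_total: float,
    probe_total: float,
    competitor_total: float,
    Kd_probe: float,
    Kd_comp: float,
) -> tuple[float, float]:
    """Bound probe and bound competitor (µM) for one shared site.

    Probe and competitor bind the same site on P and mutually exclude; free
    protein is the root of its conservation equation on [0, P_total].
    """
    if min(P_total, probe_total, competitor_total) < 0:
        raise ValueError("total concentrations must be nonnegative")
    if not (Kd_probe > 0 and Kd_comp > 0):
        raise ValueError("dissociation constants must be positive")
    if P_total == 0:
        return 0.0, 0.0

    def bound(p_free: float) -> tuple[float, float]:
        pl = probe_total * p_free / (Kd_probe + p_free)
        pc = competitor_total * p_free / (Kd_comp + p_free)
        return pl, pc

    def residual(p_free: float) -> float:
        pl, pc = bound(p_free)
        return p_free + pl + pc - P_total

    try:
        p_free = brentq(residual, 0.0, P_total, xtol=_XTOL * max(1.0, P_total),
                        rtol=8.9e-16, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(
            f"competition root solve failed (P_total={P_total}): {exc}"
        ) from exc
    return bound(p_free)
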