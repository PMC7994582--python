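"""Seeded synthetic-data generators for every analysis in the package.

Each generator draws from the exact forward model its fitter assumes, plus
Gaussian noise, so parameter-recovery round trips (generate at known truth →
fit → compare) exercise the full pipeline without any instrument data.
Defaults mirror the study designs: sw isotherms titrate Ess1 0.5–1000 µM
into 50 µM FITC-peptide; HSQC titrations hold protein at 100 µM with
peptide:protein ratios up to 3 (multi-repeat peptides) or 6 (1R);
competition curves span 0–350 µM competitor; Guinier profiles are computed
at 1.57/3.19/4.78 mg/mL on a 0.01–0.12 Å⁻¹ grid.

Reproducibility contract: every generator is a deterministic function of
(parameters, seed), and per-item substreams are spawned from the one seed so
e.g. adding residues to an HSQC simulation never perturbs existing draws.
Noise magnitudes are package defaults chosen to be plausible for each
instrument class; they are configurable and recorded in generator output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anisofit import CompetitionCurve, FourPLParams, fourpl_response
from .aucfit import CsDistribution, SwIsotherm, SwModelParams, predict_sw
from .equilibria import SingleSiteSystem, solve_competitive, solve_single_site
from .nmrtitr import NITROGEN_SCALE, TitrationSeries
from .saxsguinier import ScatterProfile

__all__ = [
    "NoiseSpec",
    "EquilibriumCompetitionSpec",
    "DEFAULT_TITRANT_GRID",
    "DEFAULT_PEPTIDE_TOTAL",
    "DEFAULT_RATIOS_MULTI",
    "DEFAULT_RATIOS_1R",
    "DEFAULT_COMPETITOR_GRID",
    "DEFAULT_SAXS_CONCENTRATIONS",
    "DEFAULT_Q_GRID",
    "gen_sw_isotherm",
    "gen_cs_distribution",
    "gen_hsqc_titration",
    "gen_competition_curve",
    "gen_guinier_profiles",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise: standard deviation in the observable's units, plus seed."""

    sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


# ---- study designs -------------------------------------------------------

#: 12 log-spaced Ess1 concentrations, 0.5–1000 µM.
DEFAULT_TITRANT_GRID = np.geomspace(0.5, 1000.0, 12)
#: Fixed FITC-peptide concentration in the AUC titrations (µM).
DEFAULT_PEPTIDE_TOTAL = 50.0
#: Peptide:protein ratio grids for the HSQC titrations.
DEFAULT_RATIOS_MULTI = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)   # 4R/5R
DEFAULT_RATIOS_1R = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0)
#: Competitor grid: 0 plus 9 log-spaced points to 350 µM.
DEFAULT_COMPETITOR_GRID = np.concatenate(([0.0], np.geomspace(1.0, 350.0, 9)))
#: SAXS concentration series (mg/mL).
DEFAULT_SAXS_CONCENTRATIONS = (1.57, 3.19, 4.78)
#: Momentum-transfer grid (Å⁻¹).
DEFAULT_Q_GRID = np.linspace(0.01, 0.12, 60)

# default noise magnitudes (per observable)
SW_NOISE_SD = 0.01          # Svedberg
SHIFT_NOISE_SD = 0.002      # ppm on 1H; 15N noise is 5x (isotropic in CSP)
ANISO_NOISE_FRAC = 0.01     # fraction of (max - min)
SAXS_NOISE_FRAC = 0.005     # multiplicative


def gen_sw_isotherm(
    params: SwModelParams,
    titrant_grid: np.ndarray | None = None,
    peptide_total: float = DEFAULT_PEPTIDE_TOTAL,
    noise: NoiseSpec = NoiseSpec(SW_NOISE_SD, 0),
) -> SwIsotherm:
    """Simulate an sw isotherm: predict_sw on the design grid plus noise."""
    grid = DEFAULT_TITRANT_GRID if titrant_grid is None else np.asarray(titrant_grid, float)
    model = predict_sw(params, peptide_total, grid)
    eps = noise.rng().normal(0.0, noise.sd, size=grid.size) if noise.sd > 0 else 0.0
    err = np.full(grid.size, noise.sd) if noise.sd > 0 else None
    return SwIsotherm(titrant_total=grid, peptide_total=peptide_total,
                      sw=model + eps, sw_error=err)


def gen_cs_distribution(
    peaks: list[tuple[float, float, float]],
    grid: np.ndarray | None = None,
) -> CsDistribution:
    """Sum-of-Gaussians c(s): peaks given as (center s, area, width sd)."""
    s = np.linspace(0.0, 5.0, 2001) if grid is None else np.asarray(grid, float)
    c = np.zeros_like(s)
    for center, area, width in peaks:
        if not width > 0:
            raise ValueError("peak widths must be positive")
        c += area / (width * np.sqrt(2.0 * np.pi)) * np.exp(
            -0.5 * ((s - center) / width) ** 2
        )
    return CsDistribution(s_grid=s, c=c)


def gen_hsqc_titration(
    n_residues: int,
    kd: float,
    delta_bound_range: tuple[float, float] = (0.05, 0.4),
    p_total: float = 100.0,
    ratios: tuple[float, ...] = DEFAULT_RATIOS_MULTI,
    noise: NoiseSpec = NoiseSpec(SHIFT_NOISE_SD, 0),
) -> list[TitrationSeries]:
    """Simulate per-residue HSQC titrations under fast exchange.

    Each residue gets its own substream: a saturation CSP Δδ_bound drawn
    uniformly from *delta_bound_range*, split between the ¹H and ¹⁵N
    dimensions by a random direction so the endpoint CSP equals Δδ_bound,
    and apo peak positions in typical amide ranges.  Observed shifts are
    δ_apo + (Δδ_bound direction)·[PL]/P_total plus Gaussian noise on each
    dimension (¹⁵N noise scaled ×5 so its CSP contribution is isotropic).
    """
    if ratios[0] != 0:
        raise ValueError("ratio grid must start at the apo point (0)")
    l_totals = np.asarray(ratios, float) * p_total
    frac_bound = np.array([
        solve_single_site(SingleSiteSystem(p_total, l, kd)) / p_total
        for l in l_totals
    ])
    children = np.random.SeedSequence(noise.seed).spawn(n_residues)
    out = []
    lo, hi = delta_bound_range
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        dbound = rng.uniform(lo, hi)
        phi = rng.uniform(0.0, np.pi / 2.0)
        dh_bound = dbound * np.cos(phi)
        dn_bound = NITROGEN_SCALE * dbound * np.sin(phi)
        apo_h = rng.normal(8.3, 0.4)
        apo_n = rng.normal(118.0, 4.0)
        dh = apo_h + frac_bound * dh_bound
        dn = apo_n + frac_bound * dn_bound
        if noise.sd > 0:
            dh = dh + rng.normal(0.0, noise.sd, size=dh.size)
            dn = dn + rng.normal(0.0, NITROGEN_SCALE * noise.sd, size=dn.size)
        out.append(TitrationSeries(
            residue_id=idx + 1,
            residue_name="X",
            points=np.column_stack([l_totals, dh, dn]),
            P_total=p_total,
        ))
    return out


@dataclass(frozen=True)
class EquilibriumCompetitionSpec:
    """Exact-equilibrium competition generator settings (shared-site model)."""

    protein_total: float = 50.0   # µM
    probe_total: float = 1.0      # µM
    kd_probe: float = 10.0        # µM
    kd_comp: float = 10.0         # µM


def gen_competition_curve(
    p: FourPLParams,
    grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(0.0015, 0),
    equilibrium: EquilibriumCompetitionSpec | None = None,
) -> CompetitionCurve:
    """Simulate a competition anisotropy curve.

    Default mode evaluates the 4PL directly.  With *equilibrium* set, the
    exact shared-site equilibrium is solved instead and anisotropy is mixed
    linearly between the asymptotes by bound-probe fraction:
    r = p.min + (p.max − p.min)·(bound probe)/(probe total), normalized so
    zero competitor maps to p.max.  p.IC50 is ignored in that mode (the
    midpoint then emerges from the Kds and totals).
    """
    x = DEFAULT_COMPETITOR_GRID if grid is None else np.asarray(grid, float)
    if equilibrium is None:
        model = fourpl_response(p, x)
        probe_total, protein_total = 1.0, 50.0
    else:
        eq = equilibrium
        bound = np.array([
            solve_competitive(eq.protein_total, eq.probe_total, c,
                              eq.kd_probe, eq.kd_comp)[0]
            for c in x
        ])
        f0 = bound[x == 0][0] / eq.probe_total if np.any(x == 0) else 1.0
        frac = bound / eq.probe_total / max(f0, 1e-12)
        model = p.min + (p.max - p.min) * frac
        probe_total, protein_total = eq.probe_total, eq.protein_total
    eps = noise.rng().normal(0.0, noise.sd, size=x.size) if noise.sd > 0 else 0.0
    return CompetitionCurve(competitor_total=x, response=model + eps,
                            probe_total=probe_total, protein_total=protein_total)


def gen_guinier_profiles(
    intercept: float = 19.8,
    slope: float = 0.31,
    concentrations: tuple[float, ...] = DEFAULT_SAXS_CONCENTRATIONS,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(SAXS_NOISE_FRAC, 0),
) -> list[ScatterProfile]:
    """Simulate a Guinier-region concentration series.

    Rg(c) = intercept + slope·c (a mild interparticle-structure-factor
    trend); I(q) = I0(c)·exp(−q²Rg²/3) with I0 proportional to
    concentration, times multiplicative Gaussian noise of fractional sd
    *noise.sd*.  Profile i uses substream i of the seed.
    """
    if not intercept > 0:
        raise ValueError("intercept Rg must be positive")
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, float)
    out = []
    for stream, c in enumerate(concentrations):
        rg = intercept + slope * c
        i0 = float(c)
        ideal = i0 * np.exp(-(q * rg) ** 2 / 3.0)
        if noise.sd > 0:
            factor = 1.0 + noise.rng(stream).normal(0.0, noise.sd, size=q.size)
            intensity = ideal * factor
            err = noise.sd * ideal
        else:
            intensity, err = ideal, None
        out.append(ScatterProfile(q=q, I=intensity, I_err=err, concentration=c))
    return out
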