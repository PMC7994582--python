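"""CSV dialects for the analysis inputs and JSON report helpers.

All tabular inputs are plain headered CSV:

* sw isotherm:        ``titrant_uM, sw_S[, sw_err_S]``
* c(s) distribution:  ``s_S, c``
* HSQC peak table (one file per titration point):
  ``residue_id, residue_name, dH_ppm, dN_ppm, broadened``
  with a manifest CSV ``file, L_total_uM`` ordering the points
* competition curve:  ``competitor_uM, anisotropy``
* scattering profile: ``q_invA, I[, I_err]``
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anisofit import CompetitionCurve
from .aucfit import CsDistribution, SwIsotherm
from .nmrtitr import TitrationSeries
from .saxsguinier import ScatterProfile

__all__ = [
    "read_sw_isotherm", "write_sw_isotherm",
    "read_cs_distribution", "write_cs_distribution",
    "read_hsqc_titration", "write_hsqc_titration",
    "read_competition_curve", "write_competition_curve",
    "read_scatter_profile", "write_scatter_profile",
    "write_report",
]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


def read_sw_isotherm(path, peptide_total_uM: float = 50.0) -> SwIsotherm:
    df = pd.read_csv(path)
    _require(df, ["titrant_uM", "sw_S"], path)
    err = df["sw_err_S"].to_numpy() if "sw_err_S" in df.columns else None
    return SwIsotherm(df["titrant_uM"].to_numpy(), peptide_total_uM,
                      df["sw_S"].to_numpy(), err)


def write_sw_isotherm(iso: SwIsotherm, path) -> None:
    data = {"titrant_uM": iso.titrant_total, "sw_S": iso.sw}
    if iso.sw_error is not None:
        data["sw_err_S"] = iso.sw_error
    pd.DataFrame(data).to_csv(path, index=False)


def read_cs_distribution(path) -> CsDistribution:
    df = pd.read_csv(path)
    _require(df, ["s_S", "c"], path)
    return CsDistribution(df["s_S"].to_numpy(), df["c"].to_numpy())


def write_cs_distribution(d: CsDistribution, path) -> None:
    pd.DataFrame({"s_S": d.s_grid, "c": d.c}).to_csv(path, index=False)


def read_hsqc_titration(manifest_path, p_total_uM: float = 100.0) -> list[TitrationSeries]:
    """Assemble per-residue series from a manifest of per-point peak tables.

    Peak-table paths in the manifest are resolved relative to the manifest's
    directory.  Every table must list the same residues.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    _require(man, ["file", "L_total_uM"], manifest_path)
    man = man.sort_values("L_total_uM", kind="stable")
    tables = []
    for _, row in man.iterrows():
        p = manifest_path.parent / str(row["file"])
        df = pd.read_csv(p)
        _require(df, ["residue_id", "residue_name", "dH_ppm", "dN_ppm", "broadened"], p)
        tables.append((float(row["L_total_uM"]), df.set_index("residue_id")))
    ids = tables[0][1].index
    out = []
    for rid in ids:
        pts, flags = [], []
        for l_tot, df in tables:
            rec = df.loc[rid]
            pts.append((l_tot, float(rec["dH_ppm"]), float(rec["dN_ppm"])))
            flags.append(bool(int(rec["broadened"])))
        out.append(TitrationSeries(
            residue_id=int(rid),
            residue_name=str(tables[0][1].loc[rid, "residue_name"]),
            points=np.asarray(pts),
            P_total=p_total_uM,
            broadened=np.asarray(flags),
        ))
    return out


def write_hsqc_titration(series_list: list[TitrationSeries], out_dir,
                         prefix: str = "point") -> Path:
    """Write per-point peak tables plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_points = series_list[0].points.shape[0]
    rows_manifest = []
    for i in range(n_points):
        rows = []
        for s in series_list:
            rows.append({
                "residue_id": s.residue_id,
                "residue_name": s.residue_name,
                "dH_ppm": s.points[i, 1],
                "dN_ppm": s.points[i, 2],
                "broadened": int(s.broadened[i]),
            })
        fname = f"{prefix}_{i:02d}.csv"
        pd.DataFrame(rows).to_csv(out_dir / fname, index=False)
        rows_manifest.append({"file": fname,
                              "L_total_uM": series_list[0].points[i, 0]})
    manifest = out_dir / f"{prefix}_manifest.csv"
    pd.DataFrame(rows_manifest).to_csv(manifest, index=False)
    return manifest


def read_competition_curve(path, probe_total_uM: float = 1.0,
                           protein_total_uM: float = 50.0) -> CompetitionCurve:
    df = pd.read_csv(path)
    _require(df, ["competitor_uM", "anisotropy"], path)
    return CompetitionCurve(df["competitor_uM"].to_numpy(),
                            df["anisotropy"].to_numpy(),
                            probe_total_uM, protein_total_uM)


def write_competition_curve(c: CompetitionCurve, path) -> None:
    pd.DataFrame({"competitor_uM": c.competitor_total,
                  "anisotropy": c.response}).to_csv(path, index=False)


def read_scatter_profile(path, concentration_mgml: float = 0.0) -> ScatterProfile:
    df = pd.read_csv(path)
    _require(df, ["q_invA", "I"], path)
    err = df["I_err"].to_numpy() if "I_err" in df.columns else None
    return ScatterProfile(df["q_invA"].to_numpy(), df["I"].to_numpy(), err,
                          concentration_mgml)


def write_scatter_profile(p: ScatterProfile, path) -> None:
    data = {"q_invA": p.q, "I": p.I}
    if p.I_err is not None:
        data["I_err"] = p.I_err
    pd.DataFrame(data).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_report(obj, path) -> None:
    """Serialize a result object (dataclass/dict) to pretty JSON."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
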