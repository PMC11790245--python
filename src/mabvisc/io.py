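"""CSV/FASTA readers and writers plus the end-to-end analysis pipeline.

CSV schemas carry units in the column names (``concentration_mg_ml``,
``viscosity_cp`` ...) so that a unit mistake surfaces as a schema error.
Duplicate (molecule, concentration) viscosity rows are treated as
replicates: averaged, with the replicate standard deviation recorded.

FASTA panels pair records named ``<molecule>|VH`` and ``<molecule>|VL``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_BUFFER_VISCOSITY_CP, DEFAULT_TEMPERATURE_K
from .descriptors import FvSequence
from .dilute import DiluteViscometry, kd_fit
from .models import MODEL_REGISTRY, compare_regimes, fit_model, rank_molecules
from .pls import KneePLS, average_knee, prefilter_descriptors
from .profiles import (
    DEFAULT_REGIME_CUTOFF,
    DiluteSeries,
    DLSSeries,
    ViscosityPoint,
    ViscosityProfile,
    segment_regimes,
)

__all__ = [
    "read_viscosity_csv",
    "read_dilute_csv",
    "read_dls_csv",
    "read_fasta_panel",
    "write_fasta_panel",
    "RunConfig",
    "run_pipeline",
]

VISCOSITY_COLUMNS = ("molecule_id", "concentration_mg_ml", "viscosity_cp")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row "
                f"{int(bad[0]) + 2}"  # header + 1-based
            )
        df[col] = vals


def read_viscosity_csv(path) -> list[ViscosityProfile]:
    """Read concentration-viscosity profiles, one per molecule.

    Required columns: molecule_id, concentration_mg_ml, viscosity_cp.
    Optional: sd_cp, temperature_k (default 298.15), buffer_viscosity_cp
    (default 1.13). Duplicate (molecule, concentration) rows are merged as
    replicates.
    """
    df = pd.read_csv(path)
    _require_columns(df, VISCOSITY_COLUMNS, path)
    numcols = ["concentration_mg_ml", "viscosity_cp"]
    for opt in ("sd_cp", "temperature_k", "buffer_viscosity_cp"):
        if opt in df.columns:
            numcols.append(opt)
    _check_numeric(df, numcols, path)
    if (df["viscosity_cp"] <= 0).any():
        row = int(df.index[df["viscosity_cp"] <= 0][0]) + 2
        raise ValueError(f"{path}: non-positive viscosity at row {row}")
    profiles = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        temp = (float(grp["temperature_k"].iloc[0])
                if "temperature_k" in grp else DEFAULT_TEMPERATURE_K)
        eta0 = (float(grp["buffer_viscosity_cp"].iloc[0])
                if "buffer_viscosity_cp" in grp else DEFAULT_BUFFER_VISCOSITY_CP)
        points = []
        for c, sub in grp.groupby("concentration_mg_ml"):
            eta = sub["viscosity_cp"].to_numpy(dtype=float)
            if len(eta) > 1:
                points.append(ViscosityPoint(
                    float(c), float(eta.mean()),
                    float(eta.std(ddof=1)), len(eta),
                ))
            else:
                sd = (float(sub["sd_cp"].iloc[0])
                      if "sd_cp" in sub and pd.notna(sub["sd_cp"].iloc[0])
                      else None)
                points.append(ViscosityPoint(float(c), float(eta[0]), sd, 1))
        profiles.append(ViscosityProfile(
            str(mol), tuple(points), buffer_viscosity=eta0, temperature=temp,
        ))
    return profiles


def read_dilute_csv(path) -> list[DiluteSeries]:
    """Read dilute viscometry series.

    Required: molecule_id, concentration_mg_ml, viscosity_cp,
    buffer_viscosity_cp.
    """
    df = pd.read_csv(path)
    _require_columns(
        df, VISCOSITY_COLUMNS + ("buffer_viscosity_cp",), path
    )
    _check_numeric(
        df, ["concentration_mg_ml", "viscosity_cp", "buffer_viscosity_cp"], path
    )
    out = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        out.append(DiluteSeries(
            str(mol),
            grp["concentration_mg_ml"].to_numpy(dtype=float),
            grp["viscosity_cp"].to_numpy(dtype=float),
            buffer_viscosity=float(grp["buffer_viscosity_cp"].iloc[0]),
        ))
    return out


def read_dls_csv(path) -> list[DLSSeries]:
    """Read DLS series: molecule_id, concentration_mg_ml, dapp_um2_per_s."""
    df = pd.read_csv(path)
    _require_columns(
        df, ("molecule_id", "concentration_mg_ml", "dapp_um2_per_s"), path
    )
    _check_numeric(df, ["concentration_mg_ml", "dapp_um2_per_s"], path)
    return [
        DLSSeries(
            str(mol),
            grp["concentration_mg_ml"].to_numpy(dtype=float),
            grp["dapp_um2_per_s"].to_numpy(dtype=float),
        )
        for mol, grp in df.groupby("molecule_id", sort=True)
    ]


def read_fasta_panel(path) -> list[FvSequence]:
    """Read paired ``>id|VH`` / ``>id|VL`` FASTA records into Fv sequences."""
    records: dict[str, dict[str, str]] = {}
    name, chunks = None, []

    def flush():
        if name is None:
            return
        if "|" not in name:
            raise ValueError(
                f"{path}: record {name!r} lacks the '|VH'/'|VL' suffix"
            )
        mol, chain = name.rsplit("|", 1)
        if chain not in ("VH", "VL"):
            raise ValueError(f"{path}: record {name!r} chain must be VH or VL")
        rec = records.setdefault(mol, {})
        if chain in rec:
            raise ValueError(f"{path}: duplicate {chain} record for {mol!r}")
        rec[chain] = "".join(chunks).upper()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, chunks = line[1:].split()[0], []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line)
        flush()
    panel = []
    for mol, rec in records.items():
        if set(rec) != {"VH", "VL"}:
            missing = {"VH", "VL"} - set(rec)
            raise ValueError(
                f"{path}: molecule {mol!r} missing {sorted(missing)} record"
            )
        panel.append(FvSequence(mol, rec["VH"], rec["VL"]))
    return panel


def write_fasta_panel(panel, path) -> None:
    with open(path, "w") as fh:
        for fv in panel:
            fh.write(f">{fv.molecule_id}|VH\n{fv.vh}\n")
            fh.write(f">{fv.molecule_id}|VL\n{fv.vl}\n")


@dataclass
class RunConfig:
    """Configuration for the end-to-end fit/knee/compare pipeline."""

    viscosity_csv: str
    output_dir: str
    models: tuple[str, ...] = tuple(MODEL_REGISTRY)
    cutoff: float = DEFAULT_REGIME_CUTOFF
    ultra_inclusive: bool = True
    predict_at: float = 180.0
    ci_level: float = 0.95
    dilute_csv: str | None = None
    dls_csv: str | None = None
    descriptor_csv: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ValueError(f"unknown model(s) {unknown}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Fit all profiles per regime, derive knees, compare regimes, rank.

    Writes ``fits.csv``, ``regime_comparison.csv``, ``knees.csv`` (plus
    ``ranks.csv`` and optionally ``pls_predictions.csv``) under
    ``config.output_dir`` and returns the tables. Deterministic for fixed
    inputs and config.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = read_viscosity_csv(config.viscosity_csv)

    fit_rows, comp_rows, knee_rows = [], [], []
    fits_by_regime: dict[str, dict[str, object]] = {"high": {}, "ultra_high": {}}
    knees_by_mol: dict[str, list] = {}
    for prof in profiles:
        high, ultra = segment_regimes(prof, config.cutoff, config.ultra_inclusive)
        for regime, seg in (("high", high), ("ultra_high", ultra)):
            for model_name in config.models:
                try:
                    res = fit_model(seg, model_name)
                except (ValueError, RuntimeError) as exc:
                    raise RuntimeError(
                        f"fit stage failed for {prof.molecule_id}/"
                        f"{model_name}/{regime}: {exc}"
                    ) from exc
                eta, ci = res.predict_with_ci(config.predict_at, config.ci_level)
                kn = res.knee()
                fit_rows.append({
                    "molecule_id": prof.molecule_id,
                    "model": model_name,
                    "regime": regime,
                    **{f"param_{k}": v for k, v in res.param_dict.items()},
                    "r_squared": res.r_squared,
                    "eta_at_query_cp": eta,
                    "ci_low_cp": ci[0],
                    "ci_high_cp": ci[1],
                    "knee_mg_ml": kn.c_knee,
                    "knee_status": kn.status,
                    "n_points": res.n_points,
                })
                if regime == "ultra_high":
                    knees_by_mol.setdefault(prof.molecule_id, []).append(kn)
                fits_by_regime[regime].setdefault(prof.molecule_id, {})
                fits_by_regime[regime][prof.molecule_id][model_name] = res
        for model_name in config.models:
            hi = fits_by_regime["high"][prof.molecule_id][model_name]
            ul = fits_by_regime["ultra_high"][prof.molecule_id][model_name]
            eta_h = hi.predict(config.predict_at)
            eta_u = ul.predict(config.predict_at)
            comp_rows.append({
                "molecule_id": prof.molecule_id,
                "model": model_name,
                "eta_high_cp": eta_h,
                "eta_ultra_cp": eta_u,
                "pct_difference": compare_regimes(eta_h, eta_u),
            })
    for mol, knees in knees_by_mol.items():
        mean_knee, n_ok = average_knee(knees)
        knee_rows.append({
            "molecule_id": mol,
            "mean_knee_mg_ml": mean_knee,
            "n_models_contributing": n_ok,
        })

    tables = {
        "fits": pd.DataFrame(fit_rows),
        "regime_comparison": pd.DataFrame(comp_rows),
        "knees": pd.DataFrame(knee_rows),
    }
    if len(profiles) >= 2:
        first_model = config.models[0]
        rank_input = {
            reg: {m: fits[first_model] for m, fits in by_mol.items()}
            for reg, by_mol in fits_by_regime.items()
        }
        ranks = rank_molecules(rank_input, config.predict_at)
        rank_rho = ranks.attrs["spearman_rho"]
        tables["ranks"] = ranks.reset_index()

    if config.descriptor_csv is not None and len(knee_rows) >= 3:
        desc = pd.read_csv(config.descriptor_csv).set_index("molecule_id")
        knees_df = tables["knees"].set_index("molecule_id")
        common = desc.index.intersection(knees_df.index)
        X = desc.loc[common]
        y = knees_df.loc[common, "mean_knee_mg_ml"].to_numpy()
        keep = prefilter_descriptors(X, y, 0.5) or list(X.columns)
        res = KneePLS(X[keep], y).fit()
        tables["pls_predictions"] = pd.DataFrame({
            "molecule_id": common,
            "observed_knee_mg_ml": y,
            "predicted_knee_mg_ml": res.predict(X[keep]),
        })

    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "n_profiles": len(profiles),
        "tables": sorted(tables),
    }
    if "ranks" in tables:
        log["rank_spearman_rho"] = rank_rho
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return tables
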