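"""Empirical sequence/structure-descriptor viscosity predictors.

Three published regression models map molecular descriptors straight to a
viscosity at a reference concentration:

* Li model (150 mg/mL): relative viscosity from the structure-based pI and
  the WALTZ aggregation score, both normalised by the Fv residue count:
  ln(eta_rel)/Nres = 0.022182 - 0.55131 pI3D/Nres + 0.00087416 Pagg/Nres.
* Sharma model (180 mg/mL): log10 viscosity linear in the hydrophobic
  index, Fv net charge and Fv charge symmetry:
  eta = 10^(0.15 + 1.26 HI - 0.043 Fvcharge - 0.02 FvCSP). The published
  typesetting of this equation is ambiguous; every coefficient is exposed
  in :data:`SHARMA_DEFAULT_COEFFICIENTS` so an alternative reading can be
  swapped in.
* Tomar model (up to 180 mg/mL): ln(eta/eta0) = -0.58 + B c with
  B = -0.0044 pI3D + 0.056.

Predictions are compared with experimental model fits by Spearman rank
correlation and a 30-cP-threshold confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_BUFFER_VISCOSITY_CP
from .descriptors import ViscosityClass, accuracy_and_confusion, classify_viscosity
from .models import ViscosityFitResults

__all__ = [
    "PredictionResult",
    "li_score",
    "sharma_score",
    "tomar_score",
    "tomar_b_from_pi",
    "compare_predictions",
    "SHARMA_DEFAULT_COEFFICIENTS",
    "LI_COEFFICIENTS",
    "TOMAR_COEFFICIENTS",
]

#: Li model coefficients for ln(eta_rel)/Nres.
LI_COEFFICIENTS = {"intercept": 0.022182, "pi3d": -0.55131, "pagg": 0.00087416}

#: Default reading of the Sharma log10-viscosity regression. The source
#: typesetting interleaves extra constants (0.6, 0.015) that are read here
#: as uncertainty fragments, not coefficients.
SHARMA_DEFAULT_COEFFICIENTS = {
    "intercept": 0.15,
    "hi": 1.26,
    "fv_charge": -0.043,
    "fv_csp": -0.02,
}

#: Tomar model: fixed intercept of ln(eta/eta0) and the B(pI3D) line.
TOMAR_COEFFICIENTS = {"lnA": -0.58, "b_slope": -0.0044, "b_intercept": 0.056}


@dataclass(frozen=True)
class PredictionResult:
    """One model's viscosity prediction for one molecule."""

    model: str               # li | sharma | tomar
    molecule_id: str
    c_ref: float             # mg/mL
    eta_pred: float          # cP
    eta_rel: float | None    # dimensionless (li only)
    viscosity_class: ViscosityClass
    inputs: Mapping[str, float]


def li_score(
    pi3d: float,
    pagg_waltz: float,
    n_res: int,
    *,
    eta0: float = DEFAULT_BUFFER_VISCOSITY_CP,
    molecule_id: str = "",
) -> PredictionResult:
    """Li model relative-viscosity prediction at 150 mg/mL.

    ln(eta_rel) = 0.022182 Nres - 0.55131 pI3D + 0.00087416 Pagg. The
    absolute viscosity is eta_rel * eta0.
    """
    if n_res <= 0:
        raise ValueError("residue count must be positive")
    co = LI_COEFFICIENTS
    ln_eta_rel = (co["intercept"] * n_res + co["pi3d"] * pi3d
                  + co["pagg"] * pagg_waltz)
    eta_rel = float(np.exp(ln_eta_rel))
    eta = eta_rel * eta0
    return PredictionResult(
        "li", molecule_id, 150.0, eta, eta_rel, classify_viscosity(eta),
        {"pI3D": pi3d, "Pagg_WALTZ": pagg_waltz, "Nres": n_res, "eta0": eta0},
    )


def sharma_score(
    hi: float,
    fv_charge: float,
    fv_csp: float,
    *,
    coefficients: Mapping[str, float] = SHARMA_DEFAULT_COEFFICIENTS,
    molecule_id: str = "",
) -> PredictionResult:
    """Sharma model viscosity prediction (cP) at 180 mg/mL.

    eta = 10^(b0 + b_HI*HI + b_q*Fvcharge + b_csp*FvCSP) with the default
    coefficients (0.15, 1.26, -0.043, -0.02).
    """
    for name, v in (("HI", hi), ("fv_charge", fv_charge), ("fv_csp", fv_csp)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite descriptor {name}")
    co = coefficients
    exponent = (co["intercept"] + co["hi"] * hi
                + co["fv_charge"] * fv_charge + co["fv_csp"] * fv_csp)
    eta = float(10.0 ** exponent)
    return PredictionResult(
        "sharma", molecule_id, 180.0, eta, None, classify_viscosity(eta),
        {"HI": hi, "fv_charge": fv_charge, "fv_csp": fv_csp},
    )


def tomar_b_from_pi(pi3d: float) -> float:
    """Concentration slope B (mL/mg) from the structure-based pI."""
    co = TOMAR_COEFFICIENTS
    return co["b_slope"] * pi3d + co["b_intercept"]


def tomar_score(
    pi3d: float,
    c: float = 180.0,
    eta0: float = DEFAULT_BUFFER_VISCOSITY_CP,
    *,
    molecule_id: str = "",
) -> PredictionResult:
    """Tomar model viscosity prediction (cP) at concentration ``c``.

    eta = eta0 * exp(-0.58 + B c) with B = -0.0044 pI3D + 0.056. At c = 0
    the model returns eta0 * e^-0.58 < eta0 — a known artifact of the fixed
    intercept; the value is returned unclamped with a warning since the
    model is only meant for high concentrations.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if eta0 <= 0:
        raise ValueError("buffer viscosity must be positive")
    b = tomar_b_from_pi(pi3d)
    eta = float(eta0 * np.exp(TOMAR_COEFFICIENTS["lnA"] + b * c))
    if eta < eta0:
        warnings.warn(
            "Tomar prediction below buffer viscosity "
            f"({eta:.3g} < {eta0} cP): model artifact at low concentration"
        )
    return PredictionResult(
        "tomar", molecule_id, c, eta, None, classify_viscosity(eta),
        {"pI3D": pi3d, "B": b, "eta0": eta0},
    )


def compare_predictions(
    predictions: Mapping[str, float],
    experimental_fits: Mapping[str, ViscosityFitResults],
    c_ref: float,
    *,
    threshold: float = 30.0,
) -> pd.DataFrame:
    """Rank agreement between predicted and experimentally fitted viscosity.

    ``predictions`` maps molecule -> predicted viscosity (cP) at ``c_ref``;
    the experimental value is each fit evaluated at ``c_ref``. Returns a
    per-molecule table with an ``attrs`` dict holding the Spearman rho,
    the 30-cP confusion counts and the classification accuracy (%).
    """
    common = sorted(set(predictions) & set(experimental_fits))
    if not common:
        raise ValueError("no molecules common to predictions and fits")
    pred = np.array([predictions[m] for m in common])
    obs = np.array([experimental_fits[m].predict(c_ref) for m in common])
    table = pd.DataFrame({
        "eta_pred": pred,
        "eta_exp": obs,
        "sign": np.sign(pred - obs),
        "rank_pred": stats.rankdata(pred, method="average"),
        "rank_exp": stats.rankdata(obs, method="average"),
    }, index=pd.Index(common, name="molecule_id"))
    rho = (stats.spearmanr(pred, obs).statistic if len(common) > 1 else np.nan)
    pred_cls = ["low" if v < threshold else "high" for v in pred]
    obs_cls = ["low" if v < threshold else "high" for v in obs]
    confusion, accuracy = accuracy_and_confusion(pred_cls, obs_cls)
    table.attrs.update(
        spearman_rho=float(rho), confusion=confusion, accuracy=accuracy,
        threshold_cp=threshold,
    )
    return table
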