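"""Dilute-regime viscometry: intrinsic viscosity and interaction parameters.

From a dilute concentration series (typically 5-50 mg/mL) the analysis
derives the relative, specific and reduced viscosities

    eta_rel = eta / eta0,   eta_sp = eta_rel - 1,   eta_red = eta_sp / c

and extracts the intrinsic viscosity [eta] by four routes:

* Huggins:   eta_red = [eta] + k_H [eta]^2 c       (linear, intercept [eta]_H)
* Kraemer-style: ln(eta_rel)/c vs c                (intercept [eta]_K)
* polynomial: eta_rel = 1 + k1 c + k2 c^2          ([eta]_v = k1)
* exponential coefficient: eta_rel = exp(k_exp c)

[eta]_avg = ([eta]_H + [eta]_K)/2 and the Huggins coefficient
k_H = slope / [eta]_avg^2 with its propagated uncertainty. A companion
linear fit of DLS apparent diffusion coefficients D_app = D0 (1 + k_D c)
yields the diffusion interaction parameter k_D.

Internally the linear extrapolations are computed with c in g/mL so that
[eta] comes out in mL/g and k_H is dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .constants import MG_PER_ML_TO_G_PER_ML
from .profiles import DiluteSeries, DLSSeries

__all__ = [
    "DiluteViscometry",
    "IntrinsicViscosityResults",
    "KDResults",
    "derive_viscosity_ratios",
    "kh_uncertainty",
    "kd_fit",
    "DEFAULT_DILUTE_WINDOW",
    "DEFAULT_DLS_WINDOW",
]

#: Default concentration window (mg/mL) for dilute viscometry fits.
DEFAULT_DILUTE_WINDOW = (5.0, 50.0)
#: Default concentration window (mg/mL) for DLS k_D fits.
DEFAULT_DLS_WINDOW = (1.0, 20.0)


def derive_viscosity_ratios(series: DiluteSeries) -> pd.DataFrame:
    """Per-point eta_rel, eta_sp and eta_red (mL/g) for a dilute series.

    Rows with c = 0 keep eta_rel/eta_sp but flag eta_red as undefined (NaN).
    """
    c = series.concentrations
    eta_rel = series.relative_viscosity
    eta_sp = eta_rel - 1.0
    c_g = c * MG_PER_ML_TO_G_PER_ML  # g/mL
    with np.errstate(divide="ignore", invalid="ignore"):
        eta_red = np.where(c > 0, eta_sp / np.where(c_g > 0, c_g, np.nan), np.nan)
    return pd.DataFrame({
        "concentration_mg_ml": c,
        "eta_rel": eta_rel,
        "eta_sp": eta_sp,
        "eta_red_ml_g": eta_red,
        "eta_red_defined": c > 0,
    })


def kh_uncertainty(
    slope: float,
    slope_se: float,
    eta_avg: float,
    eta_avg_se: float,
    *,
    include_cross_term: bool = True,
) -> float:
    """Propagated uncertainty of the Huggins coefficient.

    With x the Huggins slope and [eta] the averaged intrinsic viscosity,
    k_H = x/[eta]^2 and

        sigma_kH = k_H * sqrt( (sx/x)^2 + (s2/[eta]^2)^2
                               - 2 * s2 * sx / ([eta]^2 * x) )

    where s2 = sigma([eta]^2) = [eta]^2 * 2 * sigma([eta])/[eta]. The cross
    term assumes fully correlated slope and intercept errors (as in the
    propagation formula adopted here); ``include_cross_term=False`` gives the
    standard independent-errors variant.
    """
    if eta_avg <= 0:
        raise ValueError("eta_avg must be positive")
    if slope == 0:
        return 0.0
    k_h = slope / eta_avg**2
    s2 = eta_avg**2 * 2.0 * eta_avg_se / eta_avg
    inside = (slope_se / slope) ** 2 + (s2 / eta_avg**2) ** 2
    if include_cross_term:
        inside -= 2.0 * s2 * slope_se / (eta_avg**2 * slope)
    return abs(k_h) * np.sqrt(max(inside, 0.0))


@dataclass
class IntrinsicViscosityResults:
    """Dilute-regime outputs for one molecule. All [eta] values in mL/g."""

    molecule_id: str
    eta_h: float            # Huggins intercept
    eta_h_se: float
    eta_k: float            # ln(eta_rel)/c intercept
    eta_k_se: float
    eta_avg: float
    eta_avg_se: float
    slope_x: float          # Huggins slope, (mL/g) per (g/mL)
    slope_x_se: float
    k_h: float              # dimensionless
    k_h_se: float
    k1: float               # mL/mg (polynomial route)
    k2: float               # (mL/mg)^2
    eta_v: float            # = k1 in mL/g
    k_exp: float            # mL/mg
    huggins_r_squared: float
    n_points: int
    nonphysical: bool = False

    def summary(self) -> str:
        return "\n".join([
            f"Dilute viscometry: {self.molecule_id}  (n = {self.n_points})",
            f"  [eta]_H   = {self.eta_h:8.3f} +/- {self.eta_h_se:.3f} mL/g",
            f"  [eta]_K   = {self.eta_k:8.3f} +/- {self.eta_k_se:.3f} mL/g",
            f"  [eta]_avg = {self.eta_avg:8.3f} +/- {self.eta_avg_se:.3f} mL/g",
            f"  [eta]_v   = {self.eta_v:8.3f} mL/g "
            f"(k1 = {self.k1:.5g} mL/mg, k2 = {self.k2:.5g})",
            f"  k_H       = {self.k_h:8.4f} +/- {self.k_h_se:.4f}",
            f"  k_exp     = {self.k_exp:8.5f} mL/mg",
            f"  Huggins R^2 = {self.huggins_r_squared:.4f}",
        ])


class DiluteViscometry:
    """Dilute-solution analysis model for one molecule's viscosity series.

    Parameters
    ----------
    series : DiluteSeries
        Dilute measurements; all concentrations must be positive.
    window : (float, float)
        Concentration window (mg/mL) used for the linear extrapolations.
    drop_top_k : int
        Number of highest-concentration points to exclude before fitting
        (curvature control; default 0, i.e. keep all).
    """

    def __init__(
        self,
        series: DiluteSeries,
        window: tuple[float, float] = DEFAULT_DILUTE_WINDOW,
        drop_top_k: int = 0,
    ):
        if np.any(series.concentrations <= 0):
            raise ValueError("dilute series requires strictly positive c")
        self.series = series
        self.window = window
        lo, hi = window
        c = series.concentrations
        mask = (c >= lo) & (c <= hi)
        idx = np.nonzero(mask)[0]
        if drop_top_k > 0:
            idx = idx[:-drop_top_k] if drop_top_k < len(idx) else idx[:0]
        if len(idx) < 3:
            raise ValueError(
                f"fewer than 3 points in window {window} after drop_top_k"
            )
        self._c = c[idx]                      # mg/mL
        self._eta_rel = series.relative_viscosity[idx]
        if np.any(self._eta_rel <= 0):
            raise ValueError("eta_rel must be positive for dilute analysis")

    # -- component fits -------------------------------------------------------
    def huggins_fit(self) -> tuple[float, float, float, float, float]:
        """OLS of eta_red (mL/g) on c (g/mL).

        Returns (intercept, intercept_se, slope, slope_se, r_squared).
        """
        c_g = self._c * MG_PER_ML_TO_G_PER_ML
        eta_red = (self._eta_rel - 1.0) / c_g
        res = sm.OLS(eta_red, sm.add_constant(c_g)).fit()
        return (float(res.params[0]), float(res.bse[0]),
                float(res.params[1]), float(res.bse[1]),
                float(res.rsquared))

    def kraemer_fit(self) -> tuple[float, float, float]:
        """OLS of ln(eta_rel)/c (mL/g) on c (g/mL): (intercept, se, slope)."""
        c_g = self._c * MG_PER_ML_TO_G_PER_ML
        y = np.log(self._eta_rel) / c_g
        res = sm.OLS(y, sm.add_constant(c_g)).fit()
        return float(res.params[0]), float(res.bse[0]), float(res.params[1])

    def polynomial_fit(self) -> tuple[float, float]:
        """Zero-intercept LS of eta_rel - 1 on (c, c^2), c in mg/mL.

        Returns (k1 in mL/mg, k2 in (mL/mg)^2).
        """
        c = self._c
        design = np.column_stack([c, c**2])
        if np.linalg.matrix_rank(design) < 2:
            raise ValueError("degenerate design for polynomial fit")
        coef, *_ = np.linalg.lstsq(design, self._eta_rel - 1.0, rcond=None)
        return float(coef[0]), float(coef[1])

    def kexp_fit(self, method: str = "nonlinear") -> float:
        """Exponential coefficient of eta_rel = exp(k_exp c) (mL/mg).

        ``method="nonlinear"`` minimises squared error on eta_rel;
        ``method="loglinear"`` is the zero-intercept regression of
        ln(eta_rel) on c.
        """
        c = self._c
        log_k = float(np.sum(c * np.log(self._eta_rel)) / np.sum(c * c))
        if method == "loglinear":
            return log_k
        if method != "nonlinear":
            raise ValueError(f"unknown method {method!r}")
        sol = optimize.least_squares(
            lambda k: np.exp(k[0] * c) - self._eta_rel,
            x0=np.array([log_k]), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        return float(sol.x[0])

    # -- full analysis --------------------------------------------------------
    def fit(self) -> IntrinsicViscosityResults:
        eta_h, eta_h_se, slope, slope_se, r2 = self.huggins_fit()
        eta_k, eta_k_se, _ = self.kraemer_fit()
        eta_avg = 0.5 * (eta_h + eta_k)
        # mean of two (correlated) intercept estimates; conservative SE
        eta_avg_se = 0.5 * np.sqrt(eta_h_se**2 + eta_k_se**2)
        k_h = slope / eta_avg**2 if eta_avg > 0 else np.nan
        k_h_se = (kh_uncertainty(slope, slope_se, eta_avg, eta_avg_se)
                  if eta_avg > 0 else np.nan)
        k1, k2 = self.polynomial_fit()
        k_exp = self.kexp_fit()
        nonphysical = not (eta_h > 0 and eta_avg > 0)
        if nonphysical:
            warnings.warn(
                f"{self.series.molecule_id}: non-positive intrinsic "
                "viscosity intercept; result flagged nonphysical"
            )
        return IntrinsicViscosityResults(
            molecule_id=self.series.molecule_id,
            eta_h=eta_h, eta_h_se=eta_h_se,
            eta_k=eta_k, eta_k_se=eta_k_se,
            eta_avg=eta_avg, eta_avg_se=eta_avg_se,
            slope_x=slope, slope_x_se=slope_se,
            k_h=k_h, k_h_se=k_h_se,
            k1=k1, k2=k2, eta_v=k1 * 1000.0,
            k_exp=k_exp,
            huggins_r_squared=r2,
            n_points=len(self._c),
            nonphysical=nonphysical,
        )


@dataclass
class KDResults:
    """Linear D_app(c) fit: self-diffusion and interaction parameter."""

    molecule_id: str
    d0: float          # um^2/s (intercept)
    d0_se: float
    k_d: float         # mL/mg (slope/intercept)
    k_d_se: float
    slope: float       # um^2/s per mg/mL
    slope_se: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (
            f"DLS interaction fit: {self.molecule_id}  (n = {self.n_points})\n"
            f"  D0  = {self.d0:.4g} +/- {self.d0_se:.3g} um^2/s\n"
            f"  k_D = {self.k_d:.5g} +/- {self.k_d_se:.3g} mL/mg\n"
            f"  R^2 = {self.r_squared:.4f}"
        )


def kd_fit(
    dls: DLSSeries,
    c_window: tuple[float, float] = DEFAULT_DLS_WINDOW,
) -> KDResults:
    """Fit D_app = D0 (1 + k_D c) by OLS inside ``c_window`` (mg/mL).

    k_D = slope / intercept; its standard error comes from the ratio delta
    method using the full OLS parameter covariance.
    """
    c = dls.concentrations
    mask = (c >= c_window[0]) & (c <= c_window[1])
    c, d = c[mask], dls.d_app[mask]
    if len(c) < 3:
        raise ValueError(f"fewer than 3 DLS points in window {c_window}")
    res = sm.OLS(d, sm.add_constant(c)).fit()
    d0, slope = float(res.params[0]), float(res.params[1])
    if d0 <= 0:
        raise ValueError("nonphysical fit: D0 (intercept) <= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)
    if not np.isfinite(r_squared):
        # zero-variance response: a flat line is a perfect fit
        r_squared = 1.0 if res.ssr < 1e-20 else 0.0
    cov = np.asarray(res.cov_params())
    k_d = slope / d0
    # delta method for the ratio slope/intercept
    grad = np.array([-slope / d0**2, 1.0 / d0])
    k_d_var = float(grad @ cov @ grad)
    return KDResults(
        molecule_id=dls.molecule_id,
        d0=d0, d0_se=float(res.bse[0]),
        k_d=k_d, k_d_se=np.sqrt(max(k_d_var, 0.0)),
        slope=slope, slope_se=float(res.bse[1]),
        r_squared=r_squared,
        n_points=len(c),
    )
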