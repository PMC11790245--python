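"""NIPALS partial least squares regression of the viscosity knee.

The "knee" of each molecule's concentration-viscosity curve (the
concentration where d(eta)/dc reaches 1 cP mL/mg) is averaged across the
fitted curve models and regressed on molecular descriptors with partial
least squares, estimated by the NIPALS algorithm on autoscaled data.
Component count is chosen by leave-one-out cross-validation: the model with
the lowest PRESS wins (ties go to the smaller count), and predictive power
is summarised as Q^2 = 1 - PRESS / (sum of squared deviation of y from its
mean).

The class follows the usual model/results split: build a
:class:`KneePLS` from (X, y), ``fit()`` returns :class:`KneePLSResults`
with coefficients on the original descriptor scale, the PRESS/Q^2 table and
prediction/evaluation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import KneeResult

__all__ = [
    "average_knee",
    "KneePLS",
    "KneePLSResults",
    "RegressionReport",
    "prefilter_descriptors",
]


def average_knee(knees: Sequence[KneeResult]) -> tuple[float, int]:
    """Arithmetic mean of the knees with status ``ok``.

    Returns (mean knee in mg/mL, number of contributing models). Models
    whose knee search failed are excluded; with no valid knee at all this
    is an error.
    """
    valid = [k.c_knee for k in knees if k.ok]
    if not valid:
        raise ValueError("no model produced a valid knee")
    return float(np.mean(valid)), len(valid)


def prefilter_descriptors(
    X: pd.DataFrame, y: np.ndarray, r_threshold: float = 0.5
) -> list[str]:
    """Columns of X whose |Pearson r| with y exceeds ``r_threshold``."""
    yv = np.asarray(y, dtype=float)
    keep = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r = np.corrcoef(x, yv)[0, 1]
        if abs(r) > r_threshold:
            keep.append(col)
    return keep


@dataclass
class RegressionReport:
    """Fit quality of predictions against observed knees."""

    r_squared: float
    rmse: float            # knee units, mg/mL
    pearson_r: float       # nan when predictions are constant
    predicted: np.ndarray
    observed: np.ndarray
    degenerate: bool = False

    def summary(self) -> str:
        r_txt = "n/a (constant predictions)" if self.degenerate else f"{self.pearson_r:.3f}"
        return (f"R^2 = {self.r_squared:.3f}   RMSE = {self.rmse:.2f} mg/mL"
                f"   Pearson R = {r_txt}")


class KneePLS:
    """Univariate-response PLS model of knee concentration on descriptors.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Descriptor matrix, no missing values.
    y : (n,) array
        Averaged knee per molecule (mg/mL).
    scale : bool
        Autoscale descriptors and response to unit variance (default).
    """

    def __init__(self, X, y, *, scale: bool = True):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.feature_names = [f"x{j}" for j in range(Xv.shape[1])]
        yv = np.asarray(y, dtype=float).ravel()
        if Xv.ndim != 2 or len(yv) != Xv.shape[0]:
            raise ValueError("X must be (n, p) with y of length n")
        if np.isnan(Xv).any() or np.isnan(yv).any():
            raise ValueError("missing values are not supported")
        sd = Xv.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            names = [self.feature_names[j] for j in zero]
            raise ValueError(f"zero-variance descriptor column(s): {names}")
        self.X = Xv
        self.y = yv
        self.scale = scale

    # -- NIPALS core -----------------------------------------------------------
    def _autoscale(self, X, y):
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        if self.scale:
            x_scale = X.std(axis=0, ddof=1)
            y_scale = y.std(ddof=1)
            if y_scale == 0:
                y_scale = 1.0
        else:
            x_scale = np.ones(X.shape[1])
            y_scale = 1.0
        return ((X - x_mean) / x_scale, (y - y_mean) / y_scale,
                x_mean, x_scale, y_mean, y_scale)

    @staticmethod
    def _nipals(Xc, yc, n_components, tol=1e-10, max_iter=1000):
        """NIPALS deflation for a single response.

        Returns weights W, X-loadings P, y-loadings q (per component).
        Weight vectors are unit norm at every iteration.
        """
        n, p = Xc.shape
        W = np.zeros((p, n_components))
        P = np.zeros((p, n_components))
        q = np.zeros(n_components)
        Xr, yr = Xc.copy(), yc.copy()
        for a in range(n_components):
            w = Xr.T @ yr
            norm = np.linalg.norm(w)
            if norm == 0:
                # residual X orthogonal to y: nothing left to extract
                W, P, q = W[:, :a], P[:, :a], q[:a]
                break
            w /= norm
            # with one response the weight update converges in one pass,
            # but iterate to the stated tolerance for generality
            for _ in range(max_iter):
                t = Xr @ w
                qa = float(yr @ t / (t @ t))
                w_new = Xr.T @ yr
                w_new /= np.linalg.norm(w_new)
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w = w_new
            t = Xr @ w
            tt = float(t @ t)
            pa = Xr.T @ t / tt
            qa = float(yr @ t / tt)
            W[:, a], P[:, a], q[a] = w, pa, qa
            Xr = Xr - np.outer(t, pa)
            yr = yr - qa * t
        return W, P, q

    @staticmethod
    def _coefficients(W, P, q):
        """Regression vector in the (centered, scaled) space."""
        if W.shape[1] == 0:
            return np.zeros(W.shape[0])
        return W @ np.linalg.solve(P.T @ W, q)

    def _fit_raw(self, X, y, n_components):
        Xc, yc, xm, xs, ym, ys = self._autoscale(X, y)
        W, P, q = self._nipals(Xc, yc, n_components)
        b_scaled = self._coefficients(W, P, q)
        coef = b_scaled * ys / xs
        intercept = ym - float(xm @ coef)
        return coef, intercept, (W, P, q)

    # -- public API ------------------------------------------------------------
    def fit(self, n_components: int | None = None,
            max_components: int | None = None) -> "KneePLSResults":
        """Fit the PLS model.

        With ``n_components`` given, fit exactly that many. Otherwise run
        leave-one-out cross-validation up to ``max_components`` (default
        min(p, n-2)) and keep the PRESS-minimising count.
        """
        n, p = self.X.shape
        if n_components is None:
            cap = min(p, n - 2)
            maxc = max_components if max_components is not None else cap
            if maxc > n - 2:
                import warnings
                warnings.warn(
                    f"max_components capped at {n - 2} (n - 2)"
                )
                maxc = n - 2
            maxc = min(maxc, p)
            press, q2 = self.loo_press(maxc)
            chosen = int(np.argmin(press)) + 1
        else:
            chosen = int(n_components)
            press = q2 = None
        coef, intercept, (W, P, q) = self._fit_raw(self.X, self.y, chosen)
        fitted = self.X @ coef + intercept
        resid = self.y - fitted
        sstot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else 1.0
        return KneePLSResults(
            model=self, n_components=chosen, coefficients=coef,
            intercept=intercept, x_weights=W, x_loadings=P, y_loadings=q,
            fitted_values=fitted, r_squared=r2,
            press_per_ncomp=press, q2_per_ncomp=q2,
        )

    def loo_press(self, max_components: int) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out PRESS and Q^2 for 1..max_components components.

        PRESS(a) = sum_i (y_i - yhat_{-i}(a))^2; Q^2 = 1 - PRESS/SStot with
        SStot the squared deviation of y about its mean.
        """
        n, p = self.X.shape
        if n < 3:
            raise ValueError("need at least 3 molecules for LOO")
        max_components = min(max_components, p, n - 2)
        press = np.zeros(max_components)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xtr, ytr = self.X[mask], self.y[mask]
            for a in range(1, max_components + 1):
                coef, intercept, _ = self._fit_raw(Xtr, ytr, a)
                yhat = float(self.X[i] @ coef + intercept)
                press[a - 1] += (self.y[i] - yhat) ** 2
        sstot = float(np.sum((self.y - self.y.mean()) ** 2))
        q2 = 1.0 - press / sstot
        return press, q2


@dataclass
class KneePLSResults:
    """Fitted PLS regression of knee concentration on descriptors."""

    model: KneePLS
    n_components: int
    coefficients: np.ndarray   # original descriptor scale
    intercept: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    fitted_values: np.ndarray
    r_squared: float
    press_per_ncomp: np.ndarray | None = None
    q2_per_ncomp: np.ndarray | None = None

    @property
    def q2(self) -> float | None:
        if self.q2_per_ncomp is None:
            return None
        return float(self.q2_per_ncomp[self.n_components - 1])

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.model.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"test set missing descriptor(s): {missing}")
            X = X[self.model.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept

    def evaluate(self, X_test, y_test) -> RegressionReport:
        """R^2, RMSE and Pearson R of predictions on a test set."""
        yhat = self.predict(X_test)
        yv = np.asarray(y_test, dtype=float).ravel()
        resid = yv - yhat
        sstot = float(np.sum((yv - yv.mean()) ** 2))
        ssres = float(resid @ resid)
        r2 = 1.0 - ssres / sstot if sstot > 0 else (1.0 if ssres == 0 else -np.inf)
        rmse = float(np.sqrt(np.mean(resid**2)))
        degenerate = np.std(yhat) == 0 or np.std(yv) == 0
        r = np.nan if degenerate else float(np.corrcoef(yhat, yv)[0, 1])
        return RegressionReport(r2, rmse, r, yhat, yv, degenerate)

    def summary(self) -> str:
        lines = [
            f"PLS knee regression: {self.n_components} component(s), "
            f"n = {len(self.model.y)}, p = {self.model.X.shape[1]}",
            f"Training R^2 = {self.r_squared:.3f}"
            + (f"   LOO Q^2 = {self.q2:.3f}" if self.q2 is not None else ""),
            f"Intercept = {self.intercept:.4g}",
            "Coefficients (original scale):",
        ]
        for name, b in zip(self.model.feature_names, self.coefficients):
            lines.append(f"  {name:>20s} = {b: .5g}")
        if self.press_per_ncomp is not None:
            lines.append("PRESS by component count: "
                         + ", ".join(f"{a+1}: {v:.4g}"
                                     for a, v in enumerate(self.press_per_ncomp)))
        return "\n".join(lines)
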