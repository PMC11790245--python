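"""Concentration-viscosity models for high-concentration antibody solutions.

Four models are fitted to Newtonian viscosity-concentration profiles:

* exponential growth            ``eta = Y0 * exp(k c)``
* three-parameter exponential   ``eta = exp(a1 + a2 c + a3 / T)``
* modified Ross-Minton          ``eta = eta0 * exp([eta] c / (1 - (k/v) [eta] c))``
* Tomar (log-linear)            ``ln(eta/eta0) = lnA + B c``

Each model is a class built from a :class:`~mabvisc.profiles.ViscosityProfile`;
``fit()`` performs bound-constrained nonlinear least squares from a
deterministic multi-start grid and returns a :class:`ViscosityFitResults`
carrying parameter estimates, their covariance (linearized Jacobian),
R-squared, delta-method prediction intervals, and the "knee" of the curve —
the concentration at which d(eta)/dc reaches 1 cP mL/mg, used to standardise
the onset of pseudo-exponential viscosity growth.

The high/ultra-high regime machinery (regime splitting, percent difference
between regime predictions, cross-regime rank comparison) also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .constants import DEFAULT_BUFFER_VISCOSITY_CP, DEFAULT_TEMPERATURE_K
from .profiles import ViscosityProfile

__all__ = [
    "ModelSpec",
    "KneeResult",
    "ViscosityFitResults",
    "ViscosityModel",
    "GrowthExponential",
    "ThreeParameterExponential",
    "RossMinton",
    "Tomar",
    "MODEL_REGISTRY",
    "evaluate_model",
    "fit_model",
    "compare_regimes",
    "rank_molecules",
    "KNEE_SLOPE_THRESHOLD",
]

#: Knee definition: d(eta)/dc threshold, cP mL/mg.
KNEE_SLOPE_THRESHOLD = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """A named viscosity model with a concrete parameter set.

    ``parameters`` uses the model's own names:

    * ``growth_exponential``: ``Y0`` (cP), ``k`` (mL/mg)
    * ``three_param_exponential``: ``a1`` (dimensionless), ``a2`` (mL/mg),
      ``a3`` (K); at a single temperature only the combined intercept
      ``a1 + a3/T`` is identifiable, so fits report ``a1`` as that combined
      value with ``a3 = 0``.
    * ``ross_minton``: ``intrinsic_viscosity`` (mL/mg), ``crowding_ratio``
      (k/v, dimensionless)
    * ``tomar``: ``lnA`` (dimensionless), ``B`` (mL/mg)
    """

    model_name: str
    parameters: Mapping[str, float]
    eta0: float = DEFAULT_BUFFER_VISCOSITY_CP
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {self.model_name!r}")
        expected = MODEL_REGISTRY[self.model_name].param_names
        got = tuple(self.parameters)
        if set(got) != set(expected):
            raise ValueError(
                f"{self.model_name} expects parameters {expected}, got {got}"
            )


@dataclass(frozen=True)
class KneeResult:
    """Concentration where d(eta)/dc first reaches 1 cP mL/mg."""

    c_knee: float            # mg/mL (nan when no root found)
    method: str              # "analytic" | "numeric"
    residual: float          # |d(eta)/dc - 1| at c_knee
    status: str              # "ok" | "slope_exceeds_one_at_zero" | "no_root_in_range"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _as_array(c) -> tuple[np.ndarray, bool]:
    arr = np.asarray(c, dtype=float)
    return np.atleast_1d(arr), arr.ndim == 0


class ViscosityModel:
    """Base class: one molecule's profile plus a parametric viscosity curve.

    Subclasses define ``param_names``, the curve ``_eval`` and its
    concentration derivative ``_dcurve_dc``, starting values and bounds.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, profile: ViscosityProfile):
        if profile.n_points < 3:
            raise ValueError(
                "insufficient data: at least 3 distinct concentrations "
                f"required, got {profile.n_points}"
            )
        if profile.n_points <= len(self.param_names):
            raise ValueError(
                "insufficient data: need more points than free parameters "
                f"({profile.n_points} points, {len(self.param_names)} params)"
            )
        self.profile = profile
        self.eta0 = profile.buffer_viscosity
        self.temperature = profile.temperature

    # -- curve ---------------------------------------------------------------
    def _eval(self, params: np.ndarray, c: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _dcurve_dc(self, params: np.ndarray, c: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, params: Sequence[float], c) -> np.ndarray | float:
        carr, scalar = _as_array(c)
        if np.any(carr < 0):
            raise ValueError("concentration must be non-negative")
        out = self._eval(np.asarray(params, dtype=float), carr)
        return float(out[0]) if scalar else out

    # -- fitting -------------------------------------------------------------
    def _starts(self) -> list[np.ndarray]:
        raise NotImplementedError

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    @staticmethod
    def _covariance(jac: np.ndarray, resid: np.ndarray, cov_type: str):
        """Parameter covariance from the linearized Jacobian.

        ``robust`` (default) is the HC1 heteroscedasticity-consistent
        sandwich estimator — appropriate because measurement noise scales
        with the signal while the fit is unweighted. ``classic`` is the
        usual homoscedastic sigma^2 (J'J)^-1.
        """
        n, p = jac.shape
        dof = n - p
        jtj = jac.T @ jac
        if dof <= 0 or np.linalg.matrix_rank(jtj) < p:
            return None, "unavailable"
        jtj_inv = np.linalg.inv(jtj)
        if cov_type == "classic":
            cov = float(resid @ resid) / dof * jtj_inv
        elif cov_type == "robust":
            meat = jac.T @ (jac * (resid**2)[:, None])
            cov = jtj_inv @ meat @ jtj_inv * n / dof
        else:
            raise ValueError(f"unknown cov_type {cov_type!r}")
        return cov, "ok"

    def fit(self, cov_type: str = "robust", **options) -> "ViscosityFitResults":
        c = self.profile.concentrations
        eta = self.profile.viscosities
        lb, ub = self._bounds()

        def residuals(p: np.ndarray) -> np.ndarray:
            return self._eval(p, c) - eta

        best = None
        for start in self._starts():
            start = np.clip(start, lb + 1e-12, ub - 1e-12)
            try:
                sol = optimize.least_squares(
                    residuals, start, bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, **options,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(f"{self.name}: all optimizer starts failed")

        params = best.x
        resid = residuals(params)
        sse = float(resid @ resid)
        sstot = float(np.sum((eta - eta.mean()) ** 2))
        r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
        n = len(c)
        jac = self._numeric_jacobian(params, c)
        cov, cov_flag = self._covariance(jac, resid, cov_type)
        return ViscosityFitResults(
            model=self,
            params=params,
            cov=cov,
            cov_flag=cov_flag,
            r_squared=r2,
            sse=sse,
            n_points=n,
            converged=bool(best.success),
            regime=self.profile.regime,
        )

    def _numeric_jacobian(self, params: np.ndarray, c: np.ndarray) -> np.ndarray:
        p = np.asarray(params, dtype=float)
        jac = np.empty((len(c), len(p)))
        for j in range(len(p)):
            h = 1e-7 * max(abs(p[j]), 1e-7)
            up, dn = p.copy(), p.copy()
            up[j] += h
            dn[j] -= h
            jac[:, j] = (self._eval(up, c) - self._eval(dn, c)) / (2 * h)
        return jac

    # -- knee ----------------------------------------------------------------
    def _analytic_knee(self, params: np.ndarray) -> float | None:
        """Closed-form root of d(eta)/dc = 1, or None if numeric only."""
        return None

    def knee(
        self,
        params: Sequence[float],
        search_range: tuple[float, float] = (0.0, 1000.0),
        tol: float = 1e-9,
    ) -> KneeResult:
        p = np.asarray(params, dtype=float)
        slope0 = float(self._dcurve_dc(p, np.array([0.0]))[0])
        analytic = self._analytic_knee(p)
        if analytic is not None:
            if not np.isfinite(analytic) or analytic < 0:
                status = ("slope_exceeds_one_at_zero"
                          if slope0 >= KNEE_SLOPE_THRESHOLD
                          else "no_root_in_range")
                return KneeResult(np.nan, "analytic", np.inf, status)
            resid = abs(
                float(self._dcurve_dc(p, np.array([analytic]))[0])
                - KNEE_SLOPE_THRESHOLD
            )
            return KneeResult(float(analytic), "analytic", resid, "ok")
        # numeric bisection path (Ross-Minton)
        if slope0 >= KNEE_SLOPE_THRESHOLD:
            return KneeResult(0.0, "numeric", abs(slope0 - KNEE_SLOPE_THRESHOLD),
                              "slope_exceeds_one_at_zero")
        lo, hi = search_range
        hi = min(hi, self._max_concentration(p))
        f = lambda c: float(self._dcurve_dc(p, np.array([c]))[0]) - KNEE_SLOPE_THRESHOLD
        # bracket by geometric scan up to hi
        grid = np.linspace(lo, hi, 257)[1:-1]
        c_hi = None
        for g in grid:
            if f(g) > 0:
                c_hi = g
                break
        if c_hi is None:
            return KneeResult(np.nan, "numeric", np.inf, "no_root_in_range")
        root = optimize.brentq(f, lo, c_hi, xtol=tol, rtol=8.9e-16)
        return KneeResult(float(root), "numeric", abs(f(root)), "ok")

    def _max_concentration(self, params: np.ndarray) -> float:
        """Upper end of the model's admissible concentration domain."""
        return np.inf


class GrowthExponential(ViscosityModel):
    """eta = Y0 * exp(k c)."""

    name = "growth_exponential"
    param_names = ("Y0", "k")

    def _eval(self, params, c):
        y0, k = params
        return y0 * np.exp(k * c)

    def _dcurve_dc(self, params, c):
        y0, k = params
        return y0 * k * np.exp(k * c)

    def _analytic_knee(self, params):
        y0, k = params
        if y0 <= 0 or k <= 0:
            return np.inf
        return np.log(1.0 / (y0 * k)) / k

    def _starts(self):
        c = self.profile.concentrations
        eta = self.profile.viscosities
        slope, intercept = np.polyfit(c, np.log(eta), 1)
        base = np.array([np.exp(intercept), max(slope, 1e-6)])
        return [base, base * [0.5, 2.0], base * [2.0, 0.5],
                np.array([eta[0], 0.01])]

    def _bounds(self):
        return np.array([1e-12, 0.0]), np.array([np.inf, 1.0])


class ThreeParameterExponential(ViscosityModel):
    """eta = exp(a1 + a2 c + a3 / T).

    At a single temperature a1 and a3/T are not separately identifiable, so
    the fit estimates the combined intercept (reported as ``a1``) and fixes
    ``a3 = 0``. ``a3`` is meaningful only for multi-temperature data.
    """

    name = "three_param_exponential"
    param_names = ("a1", "a2", "a3")

    def _eval(self, params, c):
        a1, a2, a3 = params
        return np.exp(a1 + a2 * c + a3 / self.temperature)

    def _dcurve_dc(self, params, c):
        a1, a2, a3 = params
        return a2 * np.exp(a1 + a2 * c + a3 / self.temperature)

    def _analytic_knee(self, params):
        a1, a2, a3 = params
        if a2 <= 0:
            return np.inf
        return (np.log(1.0 / a2) - a1 - a3 / self.temperature) / a2

    def _starts(self):
        c = self.profile.concentrations
        eta = self.profile.viscosities
        slope, intercept = np.polyfit(c, np.log(eta), 1)
        return [np.array([intercept, max(slope, 1e-6), 0.0]),
                np.array([intercept * 0.5, max(slope, 1e-6) * 2, 0.0])]

    def _bounds(self):
        # a3 pinned at 0: single-temperature identifiability
        return (np.array([-np.inf, 0.0, -1e-12]),
                np.array([np.inf, 1.0, 1e-12]))

    def fit(self, cov_type: str = "robust", **options):
        res = super().fit(cov_type=cov_type, **options)
        # a3 is pinned: only (a1, a2) are free, so the covariance and the
        # residual degrees of freedom use 2 parameters.
        c = self.profile.concentrations
        eta = self.profile.viscosities
        jac = self._numeric_jacobian(res.params, c)[:, :2]
        resid = self._eval(res.params, c) - eta
        cov2, flag = self._covariance(jac, resid, cov_type)
        if cov2 is not None:
            cov = np.zeros((3, 3))
            cov[:2, :2] = cov2
            res.cov = cov
            res.cov_flag = flag
            res._df_resid = len(c) - 2
        return res


class RossMinton(ViscosityModel):
    """Modified Ross-Minton: eta = eta0 * exp([eta] c / (1 - (k/v) [eta] c)).

    ``intrinsic_viscosity`` ([eta], mL/mg) and ``crowding_ratio`` (k/v) are
    estimated; the curve has a singularity at c = 1/((k/v) [eta]) which must
    lie beyond the data range. The fit is run in the reparametrisation
    (x1, x2) = ([eta], (k/v)[eta]) so the singularity constraint becomes the
    box bound x2 < 1/c_max.
    """

    name = "ross_minton"
    param_names = ("intrinsic_viscosity", "crowding_ratio")

    def _eval(self, params, c):
        iv, kv = params
        denom = 1.0 - kv * iv * c
        if np.any(denom <= 0):
            raise ValueError(
                "Ross-Minton singularity: 1 - (k/v)*[eta]*c <= 0 in range"
            )
        return self.eta0 * np.exp(iv * c / denom)

    def _dcurve_dc(self, params, c):
        iv, kv = params
        denom = 1.0 - kv * iv * c
        return self._eval(params, c) * iv / denom**2

    def _max_concentration(self, params):
        iv, kv = params
        if iv * kv <= 0:
            return np.inf
        return (1.0 - 1e-9) / (iv * kv)

    # fit in (x1=[eta], x2=kv*[eta]) space
    def fit(self, cov_type: str = "robust", **options):
        c = self.profile.concentrations
        eta = self.profile.viscosities
        cmax = c.max()
        lb = np.array([1e-8, 0.0])
        ub = np.array([1.0, (1.0 - 1e-6) / cmax])

        def reval(x, cc):
            x1, x2 = x
            return self.eta0 * np.exp(x1 * cc / (1.0 - x2 * cc))

        def residuals(x):
            return reval(x, c) - eta

        # deterministic start grid around the dilute log-slope
        slope = max(np.polyfit(c, np.log(eta / self.eta0), 1)[0], 1e-6)
        starts = [np.array([s * slope, f / cmax])
                  for s in (0.5, 1.0, 2.0)
                  for f in (0.0, 0.3, 0.6, 0.9)]
        best = None
        for start in starts:
            start = np.clip(start, lb + 1e-12, ub - 1e-12)
            try:
                sol = optimize.least_squares(
                    residuals, start, bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, **options,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("ross_minton: all optimizer starts failed")
        x1, x2 = best.x
        params = np.array([x1, x2 / x1])
        resid = self._eval(params, c) - eta
        sse = float(resid @ resid)
        sstot = float(np.sum((eta - eta.mean()) ** 2))
        r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
        n = len(c)
        jac = self._numeric_jacobian(params, c)
        cov, cov_flag = self._covariance(jac, resid, cov_type)
        return ViscosityFitResults(
            model=self, params=params, cov=cov, cov_flag=cov_flag,
            r_squared=r2, sse=sse, n_points=n,
            converged=bool(best.success), regime=self.profile.regime,
        )


class Tomar(ViscosityModel):
    """ln(eta/eta0) = lnA + B c, i.e. eta = eta0 * exp(lnA + B c)."""

    name = "tomar"
    param_names = ("lnA", "B")

    def _eval(self, params, c):
        lna, b = params
        return self.eta0 * np.exp(lna + b * c)

    def _dcurve_dc(self, params, c):
        lna, b = params
        return self.eta0 * b * np.exp(lna + b * c)

    def _analytic_knee(self, params):
        lna, b = params
        if b <= 0:
            return np.inf
        return np.log(1.0 / (b * self.eta0 * np.exp(lna))) / b

    def _starts(self):
        c = self.profile.concentrations
        eta = self.profile.viscosities
        slope, intercept = np.polyfit(c, np.log(eta / self.eta0), 1)
        return [np.array([intercept, slope]),
                np.array([intercept - 0.5, slope * 2])]

    def _bounds(self):
        return np.array([-np.inf, -1.0]), np.array([np.inf, 1.0])


MODEL_REGISTRY: dict[str, type[ViscosityModel]] = {
    cls.name: cls
    for cls in (GrowthExponential, ThreeParameterExponential, RossMinton, Tomar)
}


@dataclass
class ViscosityFitResults:
    """Fitted viscosity curve with uncertainty and knee diagnostics."""

    model: ViscosityModel
    params: np.ndarray
    cov: np.ndarray | None
    cov_flag: str
    r_squared: float
    sse: float
    n_points: int
    converged: bool
    regime: str
    _df_resid: int | None = None

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, map(float, self.params)))

    @property
    def df_resid(self) -> int:
        if self._df_resid is not None:
            return self._df_resid
        return self.n_points - len(self.params)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            self.model.name, self.param_dict,
            eta0=self.model.eta0, temperature=self.model.temperature,
        )

    def predict(self, c) -> np.ndarray | float:
        return self.model.predict(self.params, c)

    def predict_with_ci(
        self, c, level: float = 0.95
    ) -> tuple[np.ndarray | float, np.ndarray]:
        """Point prediction and a first-order delta-method confidence band.

        The interval uses the Student-t quantile at ``n - p`` residual
        degrees of freedom. When the covariance is unavailable the point
        estimate is returned with nan bounds.
        """
        carr, scalar = _as_array(c)
        eta = self.model.predict(self.params, carr)
        if self.cov is None:
            ci = np.full((len(carr), 2), np.nan)
        else:
            tq = stats.t.ppf(0.5 + level / 2, self.df_resid)
            half = np.empty(len(carr))
            for i, ci_ in enumerate(carr):
                g = self._pred_gradient(ci_)
                var = float(g @ self.cov @ g)
                half[i] = tq * np.sqrt(max(var, 0.0))
            ci = np.column_stack([eta - half, eta + half])
        if scalar:
            return float(np.atleast_1d(eta)[0]), ci[0]
        return eta, ci

    def _pred_gradient(self, c: float) -> np.ndarray:
        p = self.params
        g = np.empty(len(p))
        for j in range(len(p)):
            h = 1e-7 * max(abs(p[j]), 1e-7)
            up, dn = p.copy(), p.copy()
            up[j] += h
            dn[j] -= h
            g[j] = (self.model.predict(up, c) - self.model.predict(dn, c)) / (2 * h)
        return g

    def knee(self, search_range: tuple[float, float] = (0.0, 1000.0)) -> KneeResult:
        return self.model.knee(self.params, search_range)

    def summary(self) -> str:
        lines = [
            f"Model: {self.model.name}   molecule: {self.model.profile.molecule_id}",
            f"Regime: {self.regime}   n = {self.n_points}   "
            f"R^2 = {self.r_squared:.4f}   SSE = {self.sse:.4g} cP^2",
            "Parameters:",
        ]
        se = (np.sqrt(np.diag(self.cov)) if self.cov is not None
              else [np.nan] * len(self.params))
        for name, val, s in zip(self.model.param_names, self.params, se):
            lines.append(f"  {name:>22s} = {val: .6g}  (se {s:.3g})")
        kn = self.knee()
        lines.append(f"Knee (d eta/dc = 1): c = {kn.c_knee:.2f} mg/mL "
                     f"[{kn.status}]")
        return "\n".join(lines)


# --- functional layer --------------------------------------------------------

def evaluate_model(spec: ModelSpec, c) -> float | np.ndarray:
    """Evaluate a named viscosity model at concentration(s) ``c`` (mg/mL)."""
    carr, scalar = _as_array(c)
    if np.any(carr < 0):
        raise ValueError("concentration must be non-negative")
    name = spec.model_name
    p = spec.parameters
    if name == "growth_exponential":
        out = p["Y0"] * np.exp(p["k"] * carr)
    elif name == "three_param_exponential":
        out = np.exp(p["a1"] + p["a2"] * carr + p["a3"] / spec.temperature)
    elif name == "ross_minton":
        iv, kv = p["intrinsic_viscosity"], p["crowding_ratio"]
        denom = 1.0 - kv * iv * carr
        if np.any(denom <= 0):
            raise ValueError(
                "Ross-Minton singularity: 1 - (k/v)*[eta]*c <= 0"
            )
        out = spec.eta0 * np.exp(iv * carr / denom)
    else:  # tomar
        out = spec.eta0 * np.exp(p["lnA"] + p["B"] * carr)
    return float(out[0]) if scalar else out


def fit_model(
    profile: ViscosityProfile, model_name: str, **options
) -> ViscosityFitResults:
    """Fit one of the registered models to a profile (convenience wrapper)."""
    try:
        cls = MODEL_REGISTRY[model_name]
    except KeyError:
        raise ValueError(f"unknown model {model_name!r}") from None
    return cls(profile).fit(**options)


def compare_regimes(eta_high: float, eta_ultra: float) -> float:
    """Percent difference between regime predictions at one concentration.

    Defined as ``100 * (eta_ultra - eta_high) / mean(eta_ultra, eta_high)``,
    i.e. relative to the average of the two predictions, which bounds the
    result to (-200, 200) for positive viscosities.
    """
    if eta_high <= 0 or eta_ultra <= 0:
        raise ValueError("viscosities must be positive")
    return 100.0 * (eta_ultra - eta_high) / ((eta_ultra + eta_high) / 2.0)


def rank_molecules(
    fits_by_regime: Mapping[str, Mapping[str, ViscosityFitResults]],
    c_query: float,
) -> "pd.DataFrame":
    """Rank molecules by predicted viscosity at ``c_query`` in each regime.

    Returns a table with per-regime predicted viscosity and rank (1 = lowest
    viscosity; ties share the mean rank), plus a ``spearman_rho`` attribute
    with the rank correlation between the two regimes. Molecules missing
    from either regime are dropped with a warning.
    """
    import warnings

    import pandas as pd

    regimes = list(fits_by_regime)
    if len(regimes) != 2:
        raise ValueError("exactly two regimes are required")
    common = set(fits_by_regime[regimes[0]]) & set(fits_by_regime[regimes[1]])
    dropped = (set(fits_by_regime[regimes[0]])
               | set(fits_by_regime[regimes[1]])) - common
    if dropped:
        warnings.warn(
            f"molecules missing from one regime excluded: {sorted(dropped)}"
        )
    if len(common) < 2:
        raise ValueError("need at least 2 molecules present in both regimes")
    mols = sorted(common)
    data = {}
    for reg in regimes:
        eta = np.array([fits_by_regime[reg][m].predict(c_query) for m in mols])
        data[f"eta_{reg}"] = eta
        data[f"rank_{reg}"] = stats.rankdata(eta, method="average")
    table = pd.DataFrame(data, index=pd.Index(mols, name="molecule_id"))
    rho = stats.spearmanr(
        data[f"eta_{regimes[0]}"], data[f"eta_{regimes[1]}"]
    ).statistic
    table.attrs["spearman_rho"] = float(rho)
    return table
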