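"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of the study conditions:
duplicate (N=2) Newtonian viscosity measurements on a concentration grid up
to 260 mg/mL with proportional noise, quadratic-Huggins dilute series on the
5-50 mg/mL window, linear D_app(c) DLS series on 1-20 mg/mL, a wild-type
plus single-point-mutant Fv panel, and correlated descriptor matrices with
a known linear knee response for regression recovery tests.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so each generator draws from an
independent, reproducible stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_BUFFER_VISCOSITY_CP
from .descriptors import FvSequence
from .models import ModelSpec, evaluate_model
from .profiles import DiluteSeries, DLSSeries, ViscosityPoint, ViscosityProfile

__all__ = [
    "SyntheticSpec",
    "gen_viscosity_profile",
    "gen_dilute_series",
    "gen_dls_series",
    "gen_mutant_panel",
    "gen_descriptor_table",
    "DEFAULT_PROFILE_GRID",
    "DEFAULT_DILUTE_GRID",
    "DEFAULT_DLS_GRID",
]

#: Measurement grid (mg/mL) for full-range viscosity profiles: 20-260.
DEFAULT_PROFILE_GRID = tuple(float(c) for c in range(20, 261, 20))
#: Dilute-viscometry grid (mg/mL), inside the 5-50 window.
DEFAULT_DILUTE_GRID = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
#: DLS grid (mg/mL), inside the 1-20 window.
DEFAULT_DLS_GRID = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Noise and replication settings shared by the generators.

    ``sd_value`` is a fraction of the mean for the ``proportional_sd``
    noise model (default 5%, matching typical microfluidic viscometer
    repeatability) or an absolute value in measurement units for
    ``absolute_sd``. ``n_replicates=2`` mirrors duplicate measurements.
    """

    seed: int
    noise_model: str = "proportional_sd"
    sd_value: float = 0.05
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.noise_model not in ("proportional_sd", "absolute_sd"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.sd_value < 0:
            raise ValueError("sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )

    def _sd(self, mean: np.ndarray) -> np.ndarray:
        if self.noise_model == "proportional_sd":
            return self.sd_value * np.abs(mean)
        return np.full_like(mean, self.sd_value, dtype=float)


def gen_viscosity_profile(
    truth: ModelSpec,
    spec: SyntheticSpec,
    grid=DEFAULT_PROFILE_GRID,
    molecule_id: str = "synthetic",
) -> ViscosityProfile:
    """Noisy viscosity profile from a true model curve.

    Replicates are drawn per concentration, averaged into the profile, and
    the replicate standard deviation is recorded (undefined for a single
    replicate). The truth model must be admissible over the whole grid
    (Ross-Minton singularity beyond max(grid)).
    """
    c = np.asarray(grid, dtype=float)
    eta_true = np.asarray(evaluate_model(truth, c), dtype=float)
    rng = spec.rng(0)
    sd = spec._sd(eta_true)
    reps = eta_true[None, :] + sd[None, :] * rng.standard_normal(
        (spec.n_replicates, len(c))
    )
    reps = np.maximum(reps, 1e-6)  # viscosity stays positive
    mean = reps.mean(axis=0)
    rep_sd = reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else None
    points = tuple(
        ViscosityPoint(
            ci, float(mi),
            float(rep_sd[i]) if rep_sd is not None else None,
            spec.n_replicates,
        )
        for i, (ci, mi) in enumerate(zip(c, mean))
    )
    return ViscosityProfile(
        molecule_id, points,
        buffer_viscosity=truth.eta0, temperature=truth.temperature,
    )


def gen_dilute_series(
    eta_true: float,
    kh_true: float,
    eta0: float = DEFAULT_BUFFER_VISCOSITY_CP,
    grid=DEFAULT_DILUTE_GRID,
    spec: SyntheticSpec | None = None,
    molecule_id: str = "synthetic",
) -> DiluteSeries:
    """Dilute series with Huggins structure eta_red = [eta] + k_H [eta]^2 c.

    ``eta_true`` is the intrinsic viscosity in mL/g; the generated
    viscosities are eta0 * (1 + [eta] c_g + k_H [eta]^2 c_g^2) with c_g in
    g/mL, plus configured noise on eta.
    """
    if eta_true <= 0:
        raise ValueError("intrinsic viscosity must be positive")
    c = np.asarray(grid, dtype=float)  # mg/mL
    c_g = c * 1e-3
    eta_rel = 1.0 + eta_true * c_g + kh_true * eta_true**2 * c_g**2
    eta = eta0 * eta_rel
    if spec is not None and spec.sd_value > 0:
        rng = spec.rng(1)
        eta = eta + spec._sd(eta) * rng.standard_normal(len(c))
        eta = np.maximum(eta, 1e-6)
    return DiluteSeries(molecule_id, c, eta, buffer_viscosity=eta0)


def gen_dls_series(
    d0_true: float,
    kd_true: float,
    grid=DEFAULT_DLS_GRID,
    spec: SyntheticSpec | None = None,
    molecule_id: str = "synthetic",
) -> DLSSeries:
    """DLS series with linear truth D_app = D0 (1 + k_D c)."""
    if d0_true <= 0:
        raise ValueError("D0 must be positive")
    c = np.asarray(grid, dtype=float)
    d = d0_true * (1.0 + kd_true * c)
    if np.any(d <= 0):
        raise ValueError("truth parameters give non-positive D_app on grid")
    if spec is not None and spec.sd_value > 0:
        rng = spec.rng(2)
        d = d + spec._sd(d) * rng.standard_normal(len(c))
        d = np.maximum(d, 1e-9)
    return DLSSeries(molecule_id, c, d)


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])@(VH|VL)$")


def gen_mutant_panel(
    base_vh: str,
    base_vl: str,
    mutations: list[str],
    base_id: str = "WT",
) -> list[FvSequence]:
    """Wild type plus single-point mutants from "D70N@VL"-style labels.

    The stated original residue must match the base sequence at the 1-based
    position in the named chain; a mismatch is an error naming the position.
    """
    panel = [FvSequence(base_id, base_vh, base_vl, None)]
    for mut in mutations:
        m = _MUTATION_RE.match(mut)
        if not m:
            raise ValueError(
                f"malformed mutation {mut!r}; expected e.g. 'D70N@VL'"
            )
        orig, pos, new, chain = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        seq = base_vh if chain == "VH" else base_vl
        if pos < 1 or pos > len(seq):
            raise ValueError(f"{mut}: position {pos} outside {chain}")
        if seq[pos - 1] != orig:
            raise ValueError(
                f"{mut}: expected {orig} at {chain} position {pos}, "
                f"found {seq[pos - 1]}"
            )
        mutated = seq[: pos - 1] + new + seq[pos:]
        vh, vl = (mutated, base_vl) if chain == "VH" else (base_vh, mutated)
        label = mut.split("@")[0]
        panel.append(FvSequence(label, vh, vl, label))
    return panel


def gen_descriptor_table(
    n_molecules: int,
    n_descriptors: int,
    beta,
    noise_sd: float,
    seed: int,
    *,
    correlation: float = 0.3,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Correlated Gaussian descriptors with a linear knee response.

    X ~ N(0, Sigma) with pairwise correlation ``correlation``;
    y = X beta + eps, eps ~ N(0, noise_sd^2). Returns (X as DataFrame,
    y, beta) so recovery assertions can compare against the truth.
    """
    if n_molecules < 1 or n_descriptors < 1:
        raise ValueError("dimensions must be positive")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (n_descriptors,):
        raise ValueError("beta length must equal n_descriptors")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    sigma = np.full((n_descriptors, n_descriptors), correlation)
    np.fill_diagonal(sigma, 1.0)
    chol = np.linalg.cholesky(sigma)
    X = rng.standard_normal((n_molecules, n_descriptors)) @ chol.T
    y = X @ beta + noise_sd * rng.standard_normal(n_molecules)
    cols = [f"descriptor_{j+1}" for j in range(n_descriptors)]
    return pd.DataFrame(X, columns=cols), y, beta
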