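"""Measurement containers: concentration-viscosity profiles and dilute series.

A :class:`ViscosityProfile` holds one molecule's Newtonian
viscosity-concentration measurements (duplicate measurements averaged, with
the replicate standard deviation retained). Profiles can be split into the
high (<=120 mg/mL) and ultra-high (<=260 mg/mL, inclusive of the high-range
data by default) concentration regimes used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import DEFAULT_BUFFER_VISCOSITY_CP, DEFAULT_TEMPERATURE_K

__all__ = [
    "ViscosityPoint",
    "ViscosityProfile",
    "DiluteSeries",
    "DLSSeries",
    "segment_regimes",
    "DEFAULT_REGIME_CUTOFF",
]

#: Regime boundary (mg/mL): c <= cutoff is "high", above is ultra-high only.
DEFAULT_REGIME_CUTOFF = 120.0


@dataclass(frozen=True)
class ViscosityPoint:
    """A single averaged viscosity measurement."""

    concentration: float  # mg/mL
    viscosity: float      # cP
    replicate_sd: float | None = None  # cP
    n_replicates: int = 1


@dataclass(frozen=True)
class ViscosityProfile:
    """Concentration-viscosity measurements for one molecule.

    Points are sorted by concentration on construction; duplicate
    concentrations must be merged beforehand (see
    :func:`mabvisc.io.read_viscosity_csv`, which averages replicates).
    """

    molecule_id: str
    points: tuple[ViscosityPoint, ...]
    buffer_viscosity: float = DEFAULT_BUFFER_VISCOSITY_CP  # cP
    temperature: float = DEFAULT_TEMPERATURE_K             # K
    regime: str = "full"

    def __post_init__(self) -> None:
        if self.buffer_viscosity <= 0:
            raise ValueError("buffer viscosity must be positive")
        pts = tuple(sorted(self.points, key=lambda p: p.concentration))
        for p in pts:
            if p.concentration < 0:
                raise ValueError(
                    f"negative concentration {p.concentration} in profile "
                    f"{self.molecule_id!r}"
                )
            if p.viscosity <= 0:
                raise ValueError(
                    f"non-positive viscosity {p.viscosity} in profile "
                    f"{self.molecule_id!r}"
                )
        cs = [p.concentration for p in pts]
        if len(set(cs)) != len(cs):
            raise ValueError(
                f"duplicate concentrations in profile {self.molecule_id!r}; "
                "merge replicates first"
            )
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_arrays(
        cls,
        molecule_id: str,
        concentrations: Sequence[float],
        viscosities: Sequence[float],
        *,
        replicate_sd: Sequence[float] | None = None,
        n_replicates: int = 1,
        buffer_viscosity: float = DEFAULT_BUFFER_VISCOSITY_CP,
        temperature: float = DEFAULT_TEMPERATURE_K,
        regime: str = "full",
    ) -> "ViscosityProfile":
        c = np.asarray(concentrations, dtype=float)
        eta = np.asarray(viscosities, dtype=float)
        if c.shape != eta.shape:
            raise ValueError("concentration and viscosity lengths differ")
        sds: Sequence[float | None]
        if replicate_sd is None:
            sds = [None] * len(c)
        else:
            sds = list(np.asarray(replicate_sd, dtype=float))
        pts = tuple(
            ViscosityPoint(ci, ei, si, n_replicates)
            for ci, ei, si in zip(c, eta, sds)
        )
        return cls(molecule_id, pts, buffer_viscosity, temperature, regime)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points])

    @property
    def viscosities(self) -> np.ndarray:
        return np.array([p.viscosity for p in self.points])

    @property
    def n_points(self) -> int:
        return len(self.points)

    def subset(self, mask: np.ndarray, regime: str) -> "ViscosityProfile":
        pts = tuple(p for p, m in zip(self.points, mask) if m)
        return replace(self, points=pts, regime=regime)


def segment_regimes(
    profile: ViscosityProfile,
    cutoff: float = DEFAULT_REGIME_CUTOFF,
    ultra_inclusive: bool = True,
) -> tuple[ViscosityProfile, ViscosityProfile]:
    """Split a profile into high and ultra-high concentration regimes.

    ``c <= cutoff`` is assigned to the high regime. The ultra-high regime
    contains every point when ``ultra_inclusive`` (the default, matching how
    the full-range fits are defined) or only ``c > cutoff`` otherwise.
    """
    if profile.n_points == 0:
        raise ValueError("cannot segment an empty profile")
    c = profile.concentrations
    high = profile.subset(c <= cutoff, "high")
    if ultra_inclusive:
        ultra = profile.subset(np.ones_like(c, dtype=bool), "ultra_high")
    else:
        ultra = profile.subset(c > cutoff, "ultra_high")
    for name, seg in (("high", high), ("ultra_high", ultra)):
        if seg.n_points == 0:
            raise ValueError(
                f"regime {name!r} is empty for profile "
                f"{profile.molecule_id!r} at cutoff {cutoff} mg/mL"
            )
    return high, ultra


@dataclass(frozen=True)
class DiluteSeries:
    """Dilute-regime viscosity measurements (typically 5-50 mg/mL)."""

    molecule_id: str
    concentrations: np.ndarray  # mg/mL, all > 0
    viscosities: np.ndarray     # cP
    buffer_viscosity: float = DEFAULT_BUFFER_VISCOSITY_CP

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        eta = np.asarray(self.viscosities, dtype=float)
        if self.buffer_viscosity <= 0:
            raise ValueError("buffer viscosity must be positive")
        if c.shape != eta.shape:
            raise ValueError("concentration and viscosity lengths differ")
        order = np.argsort(c)
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "viscosities", eta[order])

    @property
    def relative_viscosity(self) -> np.ndarray:
        """eta_rel = eta / eta0 (dimensionless)."""
        return self.viscosities / self.buffer_viscosity

    @property
    def specific_viscosity(self) -> np.ndarray:
        """eta_sp = eta_rel - 1 (dimensionless)."""
        return self.relative_viscosity - 1.0

    @property
    def n_points(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class DLSSeries:
    """Apparent diffusion coefficients vs concentration from DLS."""

    molecule_id: str
    concentrations: np.ndarray  # mg/mL
    d_app: np.ndarray           # um^2/s
    r_h_dls: float | None = None  # nm, Z-average/2 (instrument input)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.d_app, dtype=float)
        if c.shape != d.shape:
            raise ValueError("concentration and D_app lengths differ")
        order = np.argsort(c)
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "d_app", d[order])

    @property
    def n_points(self) -> int:
        return len(self.concentrations)
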