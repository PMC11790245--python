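"""Hydrodynamic radius, volume fraction and shape descriptors.

Converts intrinsic viscosity and structure-tool outputs (molecular weight,
radius of gyration, solvent-accessible surface area, protein volume — all
supplied as inputs) into:

* r_h = (3 [eta] Mw / (10 pi N_A))^(1/3)       hydrodynamic radius (nm)
* phi = (c N_A / Mw) * (4/3) pi r_h^3          effective volume fraction
* rho = R_g / r_h                              shape ratio (~0.775 for
                                               globular spheres)
* Psi = SASA / V^(2/3), v = (Psi - 7.085)/1.454   geometric shape
                                               coefficient and shape factor

The 10*pi constant in the r_h expression embeds the Einstein coefficient
(5/2) for rigid spheres; the Psi-v calibration line is applied verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ML_TO_NM3, MG_PER_ML_TO_G_PER_NM3, N_AVOGADRO

__all__ = [
    "rh_from_intrinsic_viscosity",
    "volume_fraction",
    "shape_ratio",
    "shape_factor",
    "HydrodynamicProps",
    "CLOSE_PACKING_FRACTION",
]

#: Random close packing of spheres; phi above this is flagged as crowded.
CLOSE_PACKING_FRACTION = 0.74

#: Slope and intercept of the Psi = 1.454 v + 7.085 shape-factor calibration.
PSI_V_SLOPE = 1.454
PSI_V_INTERCEPT = 7.085


def rh_from_intrinsic_viscosity(eta: float, mw: float) -> float:
    """Hydrodynamic radius (nm) from intrinsic viscosity.

    Parameters
    ----------
    eta : float
        Intrinsic viscosity in mL/g.
    mw : float
        Molecular weight in g/mol.
    """
    if eta <= 0 or mw <= 0:
        raise ValueError("intrinsic viscosity and Mw must be positive")
    eta_nm3 = eta * ML_TO_NM3  # nm^3/g
    return (3.0 * eta_nm3 * mw / (10.0 * np.pi * N_AVOGADRO)) ** (1.0 / 3.0)


def volume_fraction(c: float, mw: float, r_h: float) -> float:
    """Effective volume fraction at concentration ``c`` (mg/mL).

    phi = (c N_A / Mw) * (4/3) pi r_h^3 with c converted to g/nm^3. Values
    at or above random close packing (0.74) trigger a crowding warning.
    """
    if c < 0 or mw <= 0 or r_h <= 0:
        raise ValueError("inputs must be positive (c may be zero)")
    c_g_nm3 = c * MG_PER_ML_TO_G_PER_NM3
    phi = (c_g_nm3 * N_AVOGADRO / mw) * (4.0 / 3.0) * np.pi * r_h**3
    if phi >= CLOSE_PACKING_FRACTION:
        warnings.warn(
            f"volume fraction {phi:.3f} exceeds close packing; "
            "crowded regime"
        )
    return phi


def shape_ratio(r_g: float, r_h: float) -> float:
    """rho = R_g / r_h. A solid uniform sphere gives sqrt(3/5) ~ 0.775."""
    if r_g <= 0 or r_h <= 0:
        raise ValueError("R_g and r_h must be positive")
    return r_g / r_h


def shape_factor(sasa: float, volume: float) -> tuple[float, float]:
    """Geometric shape coefficient Psi and shape factor v.

    Psi = SASA / V^(2/3) is scale-invariant (a sphere gives
    4 pi / (4 pi/3)^(2/3) ~ 4.836); v = (Psi - 7.085) / 1.454 per the
    empirical calibration line.
    """
    if sasa <= 0 or volume <= 0:
        raise ValueError("SASA and volume must be positive")
    psi = sasa / volume ** (2.0 / 3.0)
    v = (psi - PSI_V_INTERCEPT) / PSI_V_SLOPE
    return psi, v


@dataclass
class HydrodynamicProps:
    """Bundle of hydrodynamic descriptors for one molecule."""

    molecule_id: str
    mw: float                      # g/mol
    r_h_eta_avg: float | None = None  # nm, from [eta]_avg
    r_h_eta_v: float | None = None    # nm, from polynomial [eta]_v
    r_h_dls: float | None = None      # nm, instrument input
    r_g: float | None = None          # nm, external predictor input
    psi: float | None = None
    v_shape: float | None = None

    @classmethod
    def from_inputs(
        cls,
        molecule_id: str,
        mw: float,
        *,
        eta_avg: float | None = None,
        eta_v: float | None = None,
        r_h_dls: float | None = None,
        r_g: float | None = None,
        sasa: float | None = None,
        volume: float | None = None,
    ) -> "HydrodynamicProps":
        rh_avg = (rh_from_intrinsic_viscosity(eta_avg, mw)
                  if eta_avg is not None else None)
        rh_v = (rh_from_intrinsic_viscosity(eta_v, mw)
                if eta_v is not None else None)
        psi = v = None
        if sasa is not None and volume is not None:
            psi, v = shape_factor(sasa, volume)
        return cls(molecule_id, mw, rh_avg, rh_v, r_h_dls, r_g, psi, v)

    def shape_ratios(self) -> dict[str, float]:
        """R_g / r_h by every available r_h route."""
        if self.r_g is None:
            raise ValueError("R_g not supplied")
        out = {}
        for label, rh in (("eta_avg", self.r_h_eta_avg),
                          ("eta_v", self.r_h_eta_v),
                          ("dls", self.r_h_dls)):
            if rh is not None:
                out[label] = shape_ratio(self.r_g, rh)
        return out

    def phi(self, c: float) -> dict[str, float]:
        """Volume fraction at c (mg/mL) by every available r_h route."""
        out = {}
        for label, rh in (("eta_avg", self.r_h_eta_avg),
                          ("eta_v", self.r_h_eta_v),
                          ("dls", self.r_h_dls)):
            if rh is not None:
                out[label] = volume_fraction(c, self.mw, rh)
        return out
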