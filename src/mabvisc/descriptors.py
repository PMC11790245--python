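"""Sequence-derived descriptors and viscosity-risk classification.

Computes composition statistics of the antibody variable fragment (Fv, the
paired VH/VL domains): the Eisenberg-scale hydrophobic index, Henderson-
Hasselbalch net charges, the Fv charge symmetry parameter (FvCSP, product of
the VH and VL net charges), and a sequence pI by bisection. Structure-tool
descriptors (pI3D, WALTZ/TANGO scores, ensemble charge, patch counts) are
inputs, never computed here.

Viscosity classification uses the traffic-light bands green <= 20 cP,
amber (20, 30) cP, red >= 30 cP, with 30 cP the binary acceptability
threshold, and the ensemble-charge rule (ens_charge >= +2 predicts low
viscosity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    ACCEPTABLE_MAX_CP,
    ACIDIC_GROUPS,
    BASIC_GROUPS,
    DEFAULT_CHARGE_PH,
    DEFAULT_PKA_SET,
    EISENBERG_SCALE,
    ENS_CHARGE_LOW_RISK_MIN,
    GREEN_MAX_CP,
    HYDROPHILIC_RESIDUES,
    HYDROPHOBIC_RESIDUES,
    PKA_TABLES,
    VALID_RESIDUES,
)

__all__ = [
    "FvSequence",
    "ViscosityClass",
    "hydrophobic_index",
    "net_charge",
    "sequence_pI",
    "fv_csp",
    "classify_viscosity",
    "ens_charge_rule",
    "accuracy_and_confusion",
]


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    for i, aa in enumerate(seq):
        if aa not in VALID_RESIDUES:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1}"
            )
    return seq


@dataclass(frozen=True)
class FvSequence:
    """VH/VL amino-acid sequences for one molecule."""

    molecule_id: str
    vh: str
    vl: str
    mutation_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "vh", _validate(self.vh))
        object.__setattr__(self, "vl", _validate(self.vl))
        if self.n_residues == 0:
            raise ValueError("empty Fv sequence")

    @property
    def n_residues(self) -> int:
        return len(self.vh) + len(self.vl)


def hydrophobic_index(vh: str, vl: str = "") -> float:
    """Eisenberg-scale hydrophobic index of the concatenated Fv.

    HI = -(sum of Eisenberg scores over hydrophobic residues
           A,C,F,I,L,P,V,G,W,Y) /
          (sum over hydrophilic residues D,E,H,K,M,N,Q,R,S,T).

    A composition-only statistic: invariant to residue order.
    """
    seq = _validate(vh) + _validate(vl)
    if not seq:
        raise ValueError("empty sequence")
    num = sum(EISENBERG_SCALE[aa] for aa in seq if aa in HYDROPHOBIC_RESIDUES)
    den = sum(EISENBERG_SCALE[aa] for aa in seq if aa in HYDROPHILIC_RESIDUES)
    if den == 0:
        raise ValueError(
            "no hydrophilic residues: hydrophobic index undefined"
        )
    return -num / den


def net_charge(
    sequence: str,
    ph: float = DEFAULT_CHARGE_PH,
    pka_set: str = DEFAULT_PKA_SET,
    *,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge (elementary charges) at ``ph``.

    Sums fractional charges over D, E, C, Y (acidic), H, K, R (basic) and,
    by default, the free N- and C-termini. Strictly non-increasing in pH.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    seq = _validate(sequence)
    try:
        pka = PKA_TABLES[pka_set]
    except KeyError:
        raise ValueError(
            f"unknown pKa set {pka_set!r}; available: {sorted(PKA_TABLES)}"
        ) from None
    q = 0.0
    for aa in seq:
        if aa in BASIC_GROUPS:
            q += 1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
        elif aa in ACIDIC_GROUPS:
            q -= 1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
    if include_termini and seq:
        q += 1.0 / (1.0 + 10.0 ** (ph - pka["nterm"]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["cterm"] - ph))
    return q


def sequence_pI(
    sequence: str,
    pka_set: str = DEFAULT_PKA_SET,
    *,
    include_termini: bool = True,
    tol: float = 1e-6,
) -> float:
    """Isoelectric point: the pH in [0, 14] where the net charge is zero.

    Found by bisection; requires at least one ionizable group (termini count
    when included).
    """
    seq = _validate(sequence)
    ionizable = any(aa in BASIC_GROUPS or aa in ACIDIC_GROUPS for aa in seq)
    if not (ionizable or include_termini):
        raise ValueError("sequence has no ionizable groups")
    lo, hi = 0.0, 14.0
    q_lo = net_charge(seq, lo, pka_set, include_termini=include_termini)
    q_hi = net_charge(seq, hi, pka_set, include_termini=include_termini)
    if q_lo < 0:
        return lo
    if q_hi > 0:
        return hi
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set, include_termini=include_termini)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fv_csp(vh_charge: float, vl_charge: float) -> float:
    """Fv charge symmetry parameter: product of VH and VL net charges.

    Negative values flag opposite-signed (asymmetric) chain charges, the
    pattern associated with elevated viscosity.
    """
    return vh_charge * vl_charge


@dataclass(frozen=True)
class ViscosityClass:
    """Traffic-light viscosity band and binary acceptability."""

    value: float  # cP
    band: str     # green | amber | red
    binary: str   # acceptable | high


def classify_viscosity(value: float) -> ViscosityClass:
    """Band a viscosity: green <= 20 cP < amber < 30 cP <= red.

    Binary acceptability is value < 30 cP; exactly 30 is red/high, exactly
    20 is green.
    """
    if value < 0:
        raise ValueError("viscosity must be non-negative")
    if value <= GREEN_MAX_CP:
        band = "green"
    elif value < ACCEPTABLE_MAX_CP:
        band = "amber"
    else:
        band = "red"
    binary = "acceptable" if value < ACCEPTABLE_MAX_CP else "high"
    return ViscosityClass(value, band, binary)


def ens_charge_rule(
    ens_charge: float, observed_class: str
) -> tuple[str, str]:
    """Apply the ensemble-charge low-viscosity rule and score it.

    Predicts "low" viscosity iff ens_charge >= +2 (inclusive). The observed
    class is "low" or "high"; returns (predicted_class, outcome) where the
    outcome is TP/FP/TN/FN with "low" as the positive class.
    """
    if observed_class not in ("low", "high"):
        raise ValueError("observed_class must be 'low' or 'high'")
    predicted = "low" if ens_charge >= ENS_CHARGE_LOW_RISK_MIN else "high"
    if predicted == "low":
        outcome = "TP" if observed_class == "low" else "FP"
    else:
        outcome = "TN" if observed_class == "high" else "FN"
    return predicted, outcome


def accuracy_and_confusion(
    predictions, observations
) -> tuple[dict[str, int], float]:
    """2x2 confusion counts and accuracy (%) for low/high class labels.

    "low" is the positive class. Accuracy is returned at full precision;
    round to the nearest integer for reporting.
    """
    preds = list(predictions)
    obs = list(observations)
    if len(preds) != len(obs):
        raise ValueError("predictions and observations differ in length")
    if not preds:
        raise ValueError("empty inputs")
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for p, o in zip(preds, obs):
        if p == "low":
            counts["TP" if o == "low" else "FP"] += 1
        else:
            counts["TN" if o == "high" else "FN"] += 1
    accuracy = 100.0 * (counts["TP"] + counts["TN"]) / len(preds)
    return counts, accuracy
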