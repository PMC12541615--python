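"""Operational models of cooperative agonism and allosterism.

This module implements the forward response models used throughout the
package, in the Black–Leff operational framework extended for an allosteric
ligand acting at a class C GPCR (here, the calcium-sensing receptor, whose
orthosteric "agonist" is extracellular Ca2+):

* the *complete* operational model, parameterised by the orthosteric
  agonist's equilibrium dissociation constant KA and operational efficacy
  tau_A;
* the *comparative* (simplified) variant, in which the observed agonist
  EC50 replaces the KA/tau_A pair;
* the four-parameter logistic (4PL) used for per-curve analysis.

All concentrations are molar.  Affinity and efficacy parameters are carried
in log10 space (log_KA, log_KB, log_tauA, log_tauB, log_alphabeta), matching
the pKB / log(alpha*beta) convention of pharmacology reporting.  A negative
allosteric modulator (NAM) has composite cooperativity alphabeta < 1; a
neutral ligand has alphabeta = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "OperationalModelParams",
    "FourPLParams",
    "Concentrations",
    "effect_complete",
    "effect_comparative",
    "effect_4pl",
    "pk_to_k",
    "k_to_pk",
    "logab_to_ab",
    "ab_to_logab",
]


@dataclass(frozen=True)
class OperationalModelParams:
    """Parameter set for the operational allosteric models.

    Parameters
    ----------
    Em : float
        Maximal system response (% of the ionomycin reference response).
    log_tauA, log_tauB : float
        log10 operational efficacies of the orthosteric agonist and the
        allosteric ligand.  ``log_tauB = -1000`` gives tau_B = 0 in float64,
        i.e. no allosteric agonism.
    log_KA : float, optional
        log10 equilibrium dissociation constant of the orthosteric agonist
        (log10 mol/L).  Required by the complete model.
    logEC50 : float, optional
        log10 half-maximal agonist concentration (log10 mol/L).  Required by
        the comparative model, where it replaces the KA / tau_A pair.
    log_KB : float
        log10 equilibrium dissociation constant of the allosteric ligand
        (log10 mol/L); pKB = -log_KB.
    alpha : float
        Binding cooperativity acting on the agonist-affinity denominator
        term.  Constrained to 0 in all fits reproduced here.
    log_alphabeta : float
        log10 of the composite cooperativity alpha*beta.  < 0 for a NAM.
    nT, nB : float
        Transducer slope (occupancy -> response) and binding slope
        (concentration -> occupancy).
    C : float
        Ambient (contaminating) agonist concentration in the assay buffer,
        mol/L.
    """

    Em: float
    log_tauA: float
    log_KB: float
    log_alphabeta: float
    log_KA: Optional[float] = None
    logEC50: Optional[float] = None
    log_tauB: float = -1000.0
    alpha: float = 0.0
    nT: float = 1.0
    nB: float = 1.0
    C: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Em", "nT", "nB"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.C) or self.C < 0:
            raise ValueError(f"C must be finite and >= 0, got {self.C!r}")
        if self.log_KA is None and self.logEC50 is None:
            raise ValueError("one of log_KA (complete) or logEC50 "
                             "(comparative) is required")

    # linear-space accessors -------------------------------------------------
    @property
    def tauA(self) -> float:
        return 10.0 ** self.log_tauA

    @property
    def tauB(self) -> float:
        return 10.0 ** self.log_tauB

    @property
    def KA(self) -> float:
        if self.log_KA is None:
            raise ValueError("log_KA not set (comparative parameterisation)")
        return 10.0 ** self.log_KA

    @property
    def EC50(self) -> float:
        if self.logEC50 is None:
            raise ValueError("logEC50 not set (complete parameterisation)")
        return 10.0 ** self.logEC50

    @property
    def KB(self) -> float:
        return 10.0 ** self.log_KB

    @property
    def alphabeta(self) -> float:
        return 10.0 ** self.log_alphabeta

    @property
    def pKB(self) -> float:
        return -self.log_KB

    def with_(self, **changes) -> "OperationalModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic curve parameters.

    Bottom and Top are the lower/upper plateaus (% ionomycin), LogEC50 the
    log10 molar agonist concentration at the half-way response, HillSlope
    the steepness.
    """

    Bottom: float
    Top: float
    LogEC50: float
    HillSlope: float

    def __post_init__(self) -> None:
        for name in ("Bottom", "Top", "LogEC50", "HillSlope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class Concentrations:
    """Orthosteric agonist (A) and allosteric ligand (B) concentrations, mol/L."""

    A: float
    B: float

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        b = np.asarray(self.B, dtype=float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("concentrations must be finite")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("concentrations must be non-negative")


def _check_conc(A, B):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("concentrations must be finite")
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("concentrations must be non-negative")
    return A, B


def effect_complete(params: OperationalModelParams, conc: Concentrations):
    """Response of the complete operational model of cooperative agonism
    and allosterism.

    Effect = Em * N^nT / (D^nT + N^nT) with

        N = tauA * (A+C)^nB * (KB + alphabeta*B) + tauB * B * KA^nB
        D = (A+C)^nB * KB + KA^nB * KB + KA^nB * B + alpha * (A+C)^nB * B

    For nT = 1 this is bounded in [0, Em]; the response is 0 whenever the
    efficacy bracket N vanishes (e.g. no agonist, no ambient agonist and no
    allosteric agonism).

    Accepts scalars or broadcastable arrays in ``conc``; returns the same
    shape.
    """
    A, B = _check_conc(conc.A, conc.B)
    p = params
    KA_nB = p.KA ** p.nB
    AC_nB = (A + p.C) ** p.nB
    N = p.tauA * AC_nB * (p.KB + p.alphabeta * B) + p.tauB * B * KA_nB
    D = AC_nB * p.KB + KA_nB * p.KB + KA_nB * B + p.alpha * AC_nB * B
    return _ratio(p.Em, N, D, p.nT)


def effect_comparative(params: OperationalModelParams, conc: Concentrations):
    """Response of the comparative (EC50-parameterised) operational model.

    Effect = Em * N^nT / (EC50^(nB*nT) * (KB + B)^nT + N^nT) with

        N = tauA * (A+C)^nB * (KB + alphabeta*B) + tauB * B * EC50^nB

    At B = 0 with tauB = 0 this reduces exactly to the Hill curve
    Em * (A+C)^nB / ((A+C)^nB + EC50^nB) when tauA = 1 (the default for this
    variant).
    """
    A, B = _check_conc(conc.A, conc.B)
    p = params
    EC50_nB = p.EC50 ** p.nB
    AC_nB = (A + p.C) ** p.nB
    N = p.tauA * AC_nB * (p.KB + p.alphabeta * B) + p.tauB * B * EC50_nB
    D0 = EC50_nB * (p.KB + B)
    return _ratio(p.Em, N, D0, p.nT)


def _ratio(Em, N, D, nT):
    # Guard the all-zero corner (A=B=C=0): bracket N is 0 -> response 0.
    N = np.asarray(N, dtype=float)
    D = np.asarray(D, dtype=float)
    num = N ** nT
    den = D ** nT + num
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, Em * num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def effect_4pl(params: FourPLParams, logA):
    """Four-parameter logistic response at log10 molar agonist concentration.

    Effect = Bottom + (Top - Bottom) / (1 + 10^((LogEC50 - logA) * HillSlope))
    """
    logA = np.asarray(logA, dtype=float)
    if not np.all(np.isfinite(logA)):
        raise ValueError("logA must be finite")
    p = params
    out = p.Bottom + (p.Top - p.Bottom) / (
        1.0 + 10.0 ** ((p.LogEC50 - logA) * p.HillSlope)
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Log-parameter transforms connecting fit estimates to report tables
# ---------------------------------------------------------------------------

def pk_to_k(pK):
    """Convert a pK (-log10 molar) to the dissociation constant in nmol/L.

    ``pk_to_k(7.06) -> 87.096...``; rounding to a table's display precision
    is a separate formatting concern.
    """
    pK = np.asarray(pK, dtype=float)
    if not np.all(np.isfinite(pK)):
        raise ValueError("pK must be finite")
    out = 10.0 ** (9.0 - pK)
    return out if out.ndim else float(out)


def k_to_pk(K_nM):
    """Inverse of :func:`pk_to_k` (K in nmol/L -> pK on the log10 molar scale)."""
    K_nM = np.asarray(K_nM, dtype=float)
    if not np.all(np.isfinite(K_nM)) or np.any(K_nM <= 0):
        raise ValueError("K must be finite and > 0")
    out = 9.0 - np.log10(K_nM)
    return out if out.ndim else float(out)


def logab_to_ab(log_alphabeta):
    """Composite cooperativity alpha*beta from its log10."""
    log_alphabeta = np.asarray(log_alphabeta, dtype=float)
    if not np.all(np.isfinite(log_alphabeta)):
        raise ValueError("log_alphabeta must be finite")
    out = 10.0 ** log_alphabeta
    return out if out.ndim else float(out)


def ab_to_logab(alphabeta):
    """Inverse of :func:`logab_to_ab`."""
    alphabeta = np.asarray(alphabeta, dtype=float)
    if not np.all(np.isfinite(alphabeta)) or np.any(alphabeta <= 0):
        raise ValueError("alphabeta must be finite and > 0")
    out = np.log10(alphabeta)
    return out if out.ndim else float(out)
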