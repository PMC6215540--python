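"""Closed-form model functions for flavoenzyme characterization.

Every analysis in the package ultimately fits one of the pure functions
defined here: the quadratic (tight-binding) ligand isotherm, the
Michaelis-Menten rate law with optional competitive inhibition, the
two-pKa bell describing pH-dependent activity, the hyperbolic saturation
of the observed flavin-reduction rate on coenzyme concentration, sums of
exponential decays for stopped-flow transients, and the Beer-Lambert law.

Conventions: concentrations in µM, time in s, extinction coefficients in
M⁻¹cm⁻¹, potentials in volts internally (millivolts at interfaces).
All functions are deterministic and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BindingIsothermParams",
    "MichaelisParams",
    "PHBellParams",
    "HyperbolicReductionParams",
    "ExponentialPhases",
    "OpticalConstants",
    "quadratic_isotherm",
    "michaelis_velocity",
    "ph_bell",
    "hyperbolic_kobs",
    "exponential_decay",
    "beer_lambert",
]


@dataclass(frozen=True)
class BindingIsothermParams:
    """Parameters of the quadratic tight-binding isotherm.

    Attributes
    ----------
    dA_max : float
        Maximum absorbance change at saturation (AU).
    E0 : float
        Total enzyme (receptor) concentration (µM); fixed, not fitted.
    Kd : float
        Equilibrium dissociation constant (µM).
    """

    dA_max: float
    E0: float
    Kd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.dA_max):
            raise ValueError("dA_max must be finite")
        if not self.E0 > 0:
            raise ValueError("E0 must be positive")
        if self.Kd < 0:
            raise ValueError("Kd must be non-negative")


@dataclass(frozen=True)
class MichaelisParams:
    """Steady-state turnover parameters (kcat s⁻¹, Km µM, optional Ki µM)."""

    kcat: float
    Km: float
    Ki: float | None = None

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ValueError("kcat must be positive")
        if not self.Km > 0:
            raise ValueError("Km must be positive")
        if self.Ki is not None and not self.Ki > 0:
            raise ValueError("Ki must be positive when present")


@dataclass(frozen=True)
class PHBellParams:
    """Two-pKa bell profile: activity requires one group protonated and
    one deprotonated.  ``Y_H`` is the limiting velocity when both groups
    are in their productive ionization state; pKa_low/pKa_high are the
    acidic- and basic-limb midpoints."""

    Y_H: float
    pKa_low: float
    pKa_high: float

    def __post_init__(self) -> None:
        if not self.Y_H > 0:
            raise ValueError("Y_H must be positive")
        if not self.pKa_low < self.pKa_high:
            raise ValueError("pKa_low must be below pKa_high")


@dataclass(frozen=True)
class HyperbolicReductionParams:
    """Limiting flavin-reduction rate constant (kred s⁻¹) and coenzyme
    dissociation constant (Kd_NADPH µM)."""

    kred: float
    Kd_NADPH: float

    def __post_init__(self) -> None:
        if not self.kred > 0:
            raise ValueError("kred must be positive")
        if not self.Kd_NADPH > 0:
            raise ValueError("Kd_NADPH must be positive")


@dataclass(frozen=True)
class ExponentialPhases:
    """One or two exponential phases plus a final offset.

    ``phases`` is an ordered sequence of (amplitude AU, rate s⁻¹) pairs
    sorted by decreasing rate.  A negative amplitude describes a rising
    trace (e.g. flavin reoxidation at 440 nm).
    """

    phases: tuple[tuple[float, float], ...]
    offset: float = 0.0

    def __init__(self, phases: Sequence[Sequence[float]], offset: float = 0.0):
        phases = tuple((float(a), float(k)) for a, k in phases)
        if not 1 <= len(phases) <= 2:
            raise ValueError("need 1 or 2 phases")
        for _, k in phases:
            if not k > 0:
                raise ValueError("rates must be strictly positive")
        if len(phases) == 2 and phases[0][1] < phases[1][1]:
            phases = (phases[1], phases[0])
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "offset", float(offset))


@dataclass(frozen=True)
class OpticalConstants:
    """Spectroscopic and electrochemical constants used throughout.

    All extinction coefficients in M⁻¹cm⁻¹.  ``nernst_slope`` is the
    decadic Nernst slope at 25 °C (V); the temperature dependence is not
    modelled, but any value can be supplied.  ``Em_dye_mV`` is the
    midpoint potential of the reference dye indigo disulfonate at pH 7.0.
    """

    d_eps340: float = 6220.0        # NADPH oxidation difference coefficient
    eps450_free_fad: float = 11300.0
    eps443_holoenzyme: float = 12200.0
    nernst_slope: float = 0.0592    # V per log10 unit per electron
    Em_dye_mV: float = -116.0

    def __post_init__(self) -> None:
        for name in ("d_eps340", "eps450_free_fad", "eps443_holoenzyme",
                     "nernst_slope"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def quadratic_isotherm(L0, p: BindingIsothermParams):
    """Absorbance change ΔA at total ligand L0 (µM) under the quadratic
    tight-binding isotherm.

    ΔA = (ΔA_max / 2E0)·{E0 + L0 + Kd − √[(E0 + L0 + Kd)² − 4·E0·L0]}

    Valid when ligand depletion by the receptor is non-negligible
    (Kd comparable to E0); reduces to the rectangular hyperbola
    ΔA_max·L0/(Kd + L0) as E0 → 0.
    """
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 < 0):
        raise ValueError("ligand concentration must be non-negative")
    b = p.E0 + L0 + p.Kd
    disc = b * b - 4.0 * p.E0 * L0
    dA = (p.dA_max / (2.0 * p.E0)) * (b - np.sqrt(np.maximum(disc, 0.0)))
    return float(dA) if dA.ndim == 0 else dA


def michaelis_velocity(S, p: MichaelisParams, I=0.0):
    """Turnover rate v (s⁻¹) at substrate S (µM), optionally with a
    competitive inhibitor at I (µM):

    v = kcat·S / (Km·(1 + I/Ki) + S)
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(I > 0) and p.Ki is None:
        raise ValueError("inhibitor present but Ki not set")
    Km_app = p.Km * (1.0 + I / p.Ki) if p.Ki is not None else p.Km
    v = p.kcat * S / (Km_app + S)
    return float(v) if v.ndim == 0 else v


def ph_bell(pH, p: PHBellParams):
    """Bell-shaped pH profile Y = Y_H / (1 + H/Ka_low + Ka_high/H) with
    H = 10^(−pH).  Maximal at pH = (pKa_low + pKa_high)/2."""
    pH = np.asarray(pH, dtype=float)
    if np.any(pH <= 0) or np.any(pH >= 14):
        raise ValueError("pH must lie in (0, 14)")
    H = 10.0 ** (-pH)
    Ka_low = 10.0 ** (-p.pKa_low)
    Ka_high = 10.0 ** (-p.pKa_high)
    Y = p.Y_H / (1.0 + H / Ka_low + Ka_high / H)
    return float(Y) if Y.ndim == 0 else Y


def hyperbolic_kobs(S, p: HyperbolicReductionParams):
    """Observed flavin-reduction rate constant at coenzyme concentration
    S (µM): kobs = kred·S/(Kd + S), bounded above by kred."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("concentration must be non-negative")
    k = p.kred * S / (p.Kd_NADPH + S)
    return float(k) if k.ndim == 0 else k


def exponential_decay(t, p: ExponentialPhases):
    """Multi-exponential absorbance A(t) = offset + Σ aᵢ·exp(−kᵢ·t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    A = np.full_like(t, p.offset, dtype=float)
    for a, k in p.phases:
        A = A + a * np.exp(-k * t)
    return float(A) if A.ndim == 0 else A


def beer_lambert(conc, epsilon: float, path: float = 1.0):
    """Absorbance of ``conc`` µM of a chromophore with extinction
    coefficient ``epsilon`` (M⁻¹cm⁻¹) over ``path`` cm."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or epsilon < 0 or path < 0:
        raise ValueError("arguments must be non-negative")
    A = conc * 1e-6 * epsilon * path
    return float(A) if A.ndim == 0 else A
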