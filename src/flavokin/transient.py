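"""Stopped-flow transient analysis.

Reduction of the oxidized flavin by NADPH is followed as an absorbance
decay at 443 nm under pseudo-first-order conditions (coenzyme at least
sevenfold over enzyme); the observed rate constant saturates
hyperbolically with coenzyme concentration, giving the limiting
reduction rate constant and the coenzyme dissociation constant.
Reoxidation of the reduced enzyme by O₂ is followed at 366/440 nm; the
peroxyflavin-formation rate depends linearly on [O₂], the slope being
the bimolecular rate constant.  The kinetic isotope effect is the ratio
of fitted rate constants for protiated versus (4R)-deuterated coenzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .fitting_engine import (
    FitError,
    FitResult,
    fit_nls,
    ratio_with_uncertainty,
    select_exponential_phases,
)
from .kinetic_models import ExponentialPhases, HyperbolicReductionParams

__all__ = [
    "AbsorbanceTrace",
    "OxidativeRates",
    "LinearFit",
    "fit_reduction_trace",
    "pseudo_first_order_check",
    "fit_kobs_vs_nadph",
    "fit_kobs_vs_oxygen",
    "fit_reoxidation_trace",
    "compute_kie",
]

PSEUDO_FIRST_ORDER_MIN_RATIO = 7.0


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A time-ordered absorbance trace at one wavelength.

    ``meta`` carries post-mix concentrations (µM unless noted): keys such
    as ``enzyme_uM``, ``nadph_uM``, ``nadp_uM``, ``o2_mM``, ``ketone_uM``.
    Post-mix values are half the syringe concentrations.
    """

    wavelength: float
    t: np.ndarray
    A: np.ndarray
    path: float = 1.0
    meta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if len(t) != len(A):
            raise ValueError("t and A differ in length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("time must start >= 0 and be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "A", A)


@dataclass(frozen=True)
class OxidativeRates:
    """Rate constants of the oxidative half reaction: bimolecular O₂
    constants without/with ketone (mM⁻¹s⁻¹) and the 440 nm decay
    constants (s⁻¹, two phases without substrate, one with)."""

    k_OO: float
    k_OO_BT: float | None = None
    k_ox1: float | None = None
    k_ox2: float | None = None
    k_440: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_OO", "k_OO_BT", "k_ox1", "k_ox2", "k_440"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_ox1 is not None and self.k_ox2 is not None:
            if not self.k_ox1 > self.k_ox2:
                raise ValueError("k_ox1 must exceed k_ox2")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    slope_stderr: float
    intercept: float
    intercept_stderr: float
    r2: float
    n_obs: int


def pseudo_first_order_check(E0: float, S0: float) -> tuple[bool, float]:
    """Check the pseudo-first-order guard S0/E0 >= 7 (inclusive)."""
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    ratio = S0 / E0
    return ratio >= PSEUDO_FIRST_ORDER_MIN_RATIO, ratio


def fit_reduction_trace(trace: AbsorbanceTrace,
                        truncate_s: float = 1.0
                        ) -> tuple[ExponentialPhases, FitResult]:
    """Single-exponential fit of a 443 nm flavin-reduction trace.

    The fitted rate is the observed reduction rate constant k_obs.  If
    the trace metadata violates the pseudo-first-order guard the result
    is flagged (``pseudo_first_order_violated``), never rejected.  A flat
    trace fits with near-zero amplitude and is flagged.
    """
    mask = trace.t <= truncate_s
    fr = fit_nls("exp1", trace.t[mask], trace.A[mask])
    flags: list[str] = []
    E0 = trace.meta.get("enzyme_uM")
    S0 = trace.meta.get("nadph_uM")
    if E0 and S0 is not None:
        ok, _ = pseudo_first_order_check(E0, S0)
        if not ok:
            flags.append("pseudo_first_order_violated")
    amp = fr.params["a1"]
    scale = max(float(np.ptp(trace.A[mask])), abs(fr.params["offset"]), 1e-12)
    if abs(amp) < 1e-6 * scale:
        flags.append("near_zero_amplitude")
    if flags:
        fr = fr.with_flags(*flags)
    phases = ExponentialPhases([(amp, fr.params["k1"])], offset=fr.params["offset"])
    return phases, fr


def fit_reoxidation_trace(trace: AbsorbanceTrace, truncate_s: float = 75.0):
    """Fit a 440 nm reoxidation trace, auto-selecting 1 vs 2 phases.

    Without ketone substrate the peroxyflavin decays in two phases; with
    substrate a single phase dominates.  Phase count is chosen by AICc.
    """
    mask = trace.t <= truncate_s
    return select_exponential_phases(trace.t[mask], trace.A[mask])


def fit_kobs_vs_nadph(S, kobs) -> tuple[HyperbolicReductionParams | None, FitResult]:
    """Fit the hyperbolic saturation of k_obs on [NADPH].

    Returns the limiting rate constant kred and the coenzyme Kd.  When
    k_obs shows no concentration dependence (relative spread < 1%, the
    saturated regime seen with high-affinity variants) the hyperbola is
    unidentifiable: a constant (limiting-rate-only) fit is returned with
    flag ``concentration_independent`` and no parameter bundle.
    """
    S = np.asarray(S, dtype=float)
    kobs = np.asarray(kobs, dtype=float)
    if len(np.unique(S)) < 4:
        raise FitError("need >= 4 coenzyme concentrations spanning Kd")
    spread = float(np.ptp(kobs)) / max(float(np.mean(kobs)), 1e-300)
    if spread < 0.01:
        mean = float(np.mean(kobs))
        se = float(np.std(kobs, ddof=1) / np.sqrt(len(kobs))) if len(kobs) > 1 else 0.0
        fr = FitResult(params={"kred": mean}, stderr={"kred": se},
                       rss=float(np.sum((kobs - mean) ** 2)), r2=0.0,
                       n_obs=len(kobs), converged=True, n_iter=0,
                       init={"kred": mean},
                       flags=("concentration_independent",))
        return None, fr
    fr = fit_nls("hyperbolic", S, kobs)
    p = HyperbolicReductionParams(kred=fr.params["kred"], Kd_NADPH=fr.params["Kd"])
    return p, fr


def fit_kobs_vs_oxygen(O2_mM, kobs) -> LinearFit:
    """Ordinary least-squares line through (O₂ mM, k_obs s⁻¹) points.

    The slope is the bimolecular rate constant for the reaction of the
    reduced flavin with O₂ (mM⁻¹s⁻¹); the intercept absorbs any
    O₂-independent decay.
    """
    O2 = np.asarray(O2_mM, dtype=float)
    k = np.asarray(kobs, dtype=float)
    if len(np.unique(O2)) < 3:
        raise FitError("need >= 3 distinct O2 concentrations")
    order = np.lexsort((k, O2))
    res = stats.linregress(O2[order], k[order])
    pred = res.slope * O2 + res.intercept
    tss = float(np.sum((k - np.mean(k)) ** 2))
    rss = float(np.sum((k - pred) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return LinearFit(slope=float(res.slope), slope_stderr=float(res.stderr),
                     intercept=float(res.intercept),
                     intercept_stderr=float(res.intercept_stderr),
                     r2=r2, n_obs=len(k))


def compute_kie(fit_H: FitResult, fit_D: FitResult) -> tuple[float, float]:
    """Kinetic isotope effect: ratio of the protiated to deuterated
    single-exponential rate constants, with propagated uncertainty."""
    for fr in (fit_H, fit_D):
        fr.ensure_converged()
        if "k1" not in fr.params or "k2" in fr.params:
            raise FitError("KIE requires single-phase fits")
    se_H = fit_H.stderr["k1"]
    se_D = fit_D.stderr["k1"]
    se_H = 0.0 if not np.isfinite(se_H) else se_H
    se_D = 0.0 if not np.isfinite(se_D) else se_D
    return ratio_with_uncertainty(fit_H.params["k1"], se_H,
                                  fit_D.params["k1"], se_D)
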