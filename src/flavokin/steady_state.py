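"""Steady-state analysis: initial velocities from A340 progress curves,
Michaelis-Menten and competitive-inhibition fitting, catalytic
efficiencies, pH profiles and thermostability summaries.

Velocities are handled internally as turnover numbers (s⁻¹); raw rates
in µM/s are converted using the enzyme concentration.  NADPH consumption
is followed at 340 nm with a difference extinction coefficient of
6.22 mM⁻¹cm⁻¹, so a negative A340 slope corresponds to a positive
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fitting_engine import FitError, FitResult, fit_nls, ratio_with_uncertainty
from .kinetic_models import MichaelisParams, OpticalConstants, PHBellParams

__all__ = [
    "VelocityRecord",
    "SteadyStateSummary",
    "trace_to_velocity",
    "fit_michaelis_dataset",
    "fit_competitive_inhibition",
    "fold_change",
    "fit_ph_profile",
    "thermostability_summary",
]


@dataclass(frozen=True)
class VelocityRecord:
    """One initial-velocity measurement.

    ``unit`` is ``"per_s"`` for turnover (s⁻¹) or ``"uM_per_s"`` for a
    raw rate; :func:`turnover` converts using the enzyme concentration.
    """

    substrate_id: str
    S: float
    I: float
    E0: float
    v: float
    unit: str = "per_s"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.S < 0 or self.I < 0 or self.E0 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.unit not in ("per_s", "uM_per_s"):
            raise ValueError("unit must be 'per_s' or 'uM_per_s'")

    def turnover(self) -> float:
        if self.unit == "per_s":
            return self.v
        if self.E0 <= 0:
            raise ValueError("E0 required to convert µM/s to turnover")
        return self.v / self.E0


@dataclass(frozen=True)
class SteadyStateSummary:
    """Per-substrate Michaelis constants with catalytic efficiency
    (M⁻¹s⁻¹, first-order error propagation from kcat and Km)."""

    substrate_id: str
    kcat: float
    kcat_stderr: float
    Km: float
    Km_stderr: float
    kcat_over_Km: float          # M^-1 s^-1
    kcat_over_Km_stderr: float
    Ki_NADP: float | None = None
    k_unc: float | None = None
    flags: tuple[str, ...] = ()


def trace_to_velocity(
    t,
    A,
    E0: float,
    substrate_id: str = "",
    S: float = 0.0,
    I: float = 0.0,
    window_fraction: float = 0.10,
    window_seconds: float = 30.0,
    constants: OpticalConstants = OpticalConstants(),
    path: float = 1.0,
) -> VelocityRecord:
    """Initial velocity from an A340 progress curve.

    The slope is taken by linear regression over the initial window —
    the first ``window_fraction`` of the total absorbance change or the
    first ``window_seconds``, whichever is shorter — and converted to
    µM NADPH/s via Δε340, then to turnover (s⁻¹) with ``E0`` (µM).
    A non-monotone early segment is flagged, not rejected.
    """
    t = np.asarray(t, dtype=float)
    A = np.asarray(A, dtype=float)
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    total = A[-1] - A[0]
    if abs(total) > 0:
        target = A[0] + window_fraction * total
        crossed = np.nonzero((A - target) * np.sign(total) >= 0)[0]
        t_frac = t[crossed[0]] if len(crossed) else t[-1]
    else:
        t_frac = t[-1]
    t_end = min(t_frac, window_seconds)
    mask = t <= t_end
    if np.count_nonzero(mask) < 5:
        raise FitError("initial window contains fewer than 5 points")
    res = stats.linregress(t[mask], A[mask])
    flags: list[str] = []
    if abs(total) > 0 and abs(res.rvalue) < 0.9:
        flags.append("non_monotone_initial_segment")
    v_uM = -res.slope / (constants.d_eps340 * path) * 1e6
    return VelocityRecord(substrate_id=substrate_id, S=S, I=I, E0=E0,
                          v=v_uM / E0, unit="per_s", flags=tuple(flags))


def _as_arrays(records: Sequence[VelocityRecord]):
    S = np.array([r.S for r in records], dtype=float)
    I = np.array([r.I for r in records], dtype=float)
    v = np.array([r.turnover() for r in records], dtype=float)
    return S, I, v


def _efficiency(kcat, se_kcat, Km, se_Km) -> tuple[float, float]:
    # Km in µM -> efficiency in M^-1 s^-1
    eff, se = ratio_with_uncertainty(kcat, se_kcat, Km * 1e-6, se_Km * 1e-6)
    return eff, se


def fit_michaelis_dataset(
    records: Sequence[VelocityRecord],
) -> tuple[MichaelisParams, FitResult, SteadyStateSummary]:
    """Fit the Michaelis-Menten rate law to one substrate's velocities.

    Requires at least 5 distinct substrate concentrations.  If the
    highest concentration does not exceed the fitted Km the result is
    flagged ``saturation_not_reached``.
    """
    if not records:
        raise FitError("empty dataset")
    S, I, v = _as_arrays(records)
    if np.any(I > 0):
        raise FitError("inhibited records present; use fit_competitive_inhibition")
    if len(np.unique(S)) < 5:
        raise FitError("need >= 5 distinct substrate concentrations")
    fr = fit_nls("michaelis", S, v)
    flags = []
    if float(np.max(S)) < fr.params["Km"]:
        flags.append("saturation_not_reached")
    if flags:
        fr = fr.with_flags(*flags)
    eff, eff_se = _efficiency(fr.params["kcat"], fr.stderr["kcat"],
                              fr.params["Km"], fr.stderr["Km"])
    sid = records[0].substrate_id
    summary = SteadyStateSummary(
        substrate_id=sid, kcat=fr.params["kcat"], kcat_stderr=fr.stderr["kcat"],
        Km=fr.params["Km"], Km_stderr=fr.stderr["Km"],
        kcat_over_Km=eff, kcat_over_Km_stderr=eff_se, flags=fr.flags)
    return MichaelisParams(kcat=fr.params["kcat"], Km=fr.params["Km"]), fr, summary


def fit_competitive_inhibition(
    records: Sequence[VelocityRecord],
) -> tuple[MichaelisParams, FitResult]:
    """Global fit of v = kcat·S/(Km(1+I/Ki)+S) across an (S, I) grid.

    All records are fit simultaneously with shared kcat, Km and Ki.
    Requires at least two inhibitor levels including I = 0.
    """
    if not records:
        raise FitError("empty dataset")
    S, I, v = _as_arrays(records)
    levels = np.unique(I)
    if len(levels) < 2:
        raise FitError("Ki unidentifiable: need >= 2 inhibitor levels")
    if 0.0 not in levels:
        raise FitError("need uninhibited (I = 0) records")
    fr = fit_nls("competitive", (S, I), v)
    return (MichaelisParams(kcat=fr.params["kcat"], Km=fr.params["Km"],
                            Ki=fr.params["Ki"]), fr)


def fold_change(a: float, b: float) -> float:
    """Simple ratio a/b (e.g. Km fold-difference between substrates)."""
    if b == 0:
        raise ZeroDivisionError("denominator is zero")
    return a / b


def fit_ph_profile(pH, v) -> tuple[PHBellParams, FitResult]:
    """Fit the two-pKa bell to (pH, velocity) points on the velocity
    scale.  The fitted limbs are returned in canonical order
    (pKa_low < pKa_high); a pH range that does not descend to half-max
    on a limb leaves that pKa flagged ``pKa_extrapolated``.
    """
    pH = np.asarray(pH, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(pH) < 6:
        raise FitError("need >= 6 pH points spanning both limbs")
    fr = fit_nls("ph_bell", pH, v)
    lo, hi = fr.params["pKa_low"], fr.params["pKa_high"]
    if lo > hi:  # canonical ordering
        params = dict(fr.params)
        errs = dict(fr.stderr)
        params["pKa_low"], params["pKa_high"] = hi, lo
        errs["pKa_low"], errs["pKa_high"] = errs["pKa_high"], errs["pKa_low"]
        fr = FitResult(params, errs, fr.rss, fr.r2, fr.n_obs, fr.converged,
                       fr.n_iter, fr.init, fr.flags)
        lo, hi = hi, lo
    flags = []
    if lo < float(np.min(pH)):
        flags.append("pKa_low_extrapolated")
    if hi > float(np.max(pH)):
        flags.append("pKa_high_extrapolated")
    if flags:
        fr = fr.with_flags(*flags)
    p = PHBellParams(Y_H=fr.params["Y_H"], pKa_low=lo, pKa_high=hi)
    return p, fr


def thermostability_summary(temperature, activity,
                            decline_threshold: float = 0.4,
                            decline_temp: float = 25.0):
    """Normalize residual activities to the lowest-temperature reference.

    Returns a list of dicts with keys ``T_C``, ``activity``, ``fraction``
    and a ``declined`` flag set when the fraction at T >= 25 °C falls
    below 0.4 (i.e. more than 60% activity loss after incubation).
    """
    T = np.asarray(temperature, dtype=float)
    a = np.asarray(activity, dtype=float)
    if len(T) == 0:
        raise ValueError("empty input")
    order = np.argsort(T)
    T, a = T[order], a[order]
    ref = a[0]
    if ref <= 0:
        raise ValueError("reference (lowest-temperature) activity must be positive")
    rows = []
    for Ti, ai in zip(T, a):
        frac = ai / ref
        rows.append({
            "T_C": float(Ti),
            "activity": float(ai),
            "fraction": float(frac),
            "declined": bool(Ti >= decline_temp and frac < decline_threshold),
        })
    return rows
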