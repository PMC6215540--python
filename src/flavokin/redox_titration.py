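"""Redox potentiometry by dye equilibration, ligand-binding titrations,
and extinction-coefficient determination.

The midpoint potential of the enzyme-bound flavin is measured by slowly
reducing enzyme and a reference dye together (xanthine/xanthine oxidase)
and reading both couples spectrophotometrically: the enzyme at the
dye's isosbestic wavelength (458 nm), the dye at 610 nm where neither
oxidized nor fully reduced flavin absorbs.  At equilibrium the two
couples share one solution potential, so

    log10(E_red/E_ox) = ne(E°_e − E°_d)/0.0592 + (ne/nd)·log10(D_red/D_ox)

and an OLS line through the log-log points yields ne/nd from the slope
and the enzyme midpoint potential from the intercept.  Logs are decadic
throughout (the 0.0592/n slope form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting_engine import FitError, FitResult, fit_nls
from .kinetic_models import BindingIsothermParams, OpticalConstants

__all__ = [
    "SpectralCalibration",
    "RedoxSeries",
    "RedoxFit",
    "TitrationSeries",
    "extract_redox_fractions",
    "nernst_fit",
    "fit_binding_titration",
    "extinction_coefficient",
]


@dataclass(frozen=True)
class SpectralCalibration:
    """Endpoint absorbances and total concentrations for the two-couple
    readout: enzyme at 458 nm, dye at 610 nm."""

    A458_ox: float
    A458_red: float
    A610_ox: float
    A610_red: float
    E_total: float   # µM enzyme
    D_total: float   # µM dye

    def __post_init__(self) -> None:
        if self.A458_ox == self.A458_red:
            raise ValueError("equal 458 nm endpoints: enzyme not calibratable")
        if self.A610_ox == self.A610_red:
            raise ValueError("equal 610 nm endpoints: dye not calibratable")
        if self.E_total <= 0 or self.D_total <= 0:
            raise ValueError("totals must be positive")


@dataclass(frozen=True)
class RedoxSeries:
    """Oxidized/reduced concentrations of enzyme and dye per timepoint.

    ``usable`` marks points where both couples lie in the 10-90%
    reduced window; points outside are retained but excluded from the
    Nernst regression (log-ratios diverge at the endpoints).
    """

    E_ox: np.ndarray
    E_red: np.ndarray
    D_ox: np.ndarray
    D_red: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        for name in ("E_ox", "E_red", "D_ox", "D_red"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} has negative concentrations")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "usable", np.asarray(self.usable, dtype=bool))


@dataclass(frozen=True)
class RedoxFit:
    """Result of the log-log Nernst regression."""

    slope: float
    slope_stderr: float
    intercept: float
    intercept_stderr: float
    E0_enzyme_mV: float
    E0_enzyme_stderr_mV: float
    E0_dye_mV: float
    ne: int
    nd: int
    n_used: int
    r2: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TitrationSeries:
    """Sequential-addition ligand titration read as ΔA at one wavelength."""

    L0: np.ndarray   # µM, non-decreasing, starts at 0
    dA: np.ndarray   # AU
    E0: float        # µM enzyme, known

    def __post_init__(self) -> None:
        L0 = np.asarray(self.L0, dtype=float)
        dA = np.asarray(self.dA, dtype=float)
        if len(L0) != len(dA):
            raise ValueError("L0 and dA differ in length")
        if len(L0) == 0 or L0[0] != 0 or dA[0] != 0:
            raise ValueError("titration must start at L0 = 0 with dA = 0")
        if np.any(np.diff(L0) < 0):
            raise ValueError("L0 must be non-decreasing")
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        object.__setattr__(self, "L0", L0)
        object.__setattr__(self, "dA", dA)


def extract_redox_fractions(A458, A610, cal: SpectralCalibration,
                            window: tuple[float, float] = (0.10, 0.90)
                            ) -> RedoxSeries:
    """Convert the two-wavelength readout into couple concentrations.

    Reduced fractions come from linear interpolation between the
    calibration endpoints; points where either couple is outside the
    ``window`` (default 10-90% reduced) are flagged unusable.
    """
    A458 = np.asarray(A458, dtype=float)
    A610 = np.asarray(A610, dtype=float)
    f_e = (cal.A458_ox - A458) / (cal.A458_ox - cal.A458_red)
    f_d = (cal.A610_ox - A610) / (cal.A610_ox - cal.A610_red)
    f_e = np.clip(f_e, 0.0, 1.0)
    f_d = np.clip(f_d, 0.0, 1.0)
    lo, hi = window
    usable = (f_e >= lo) & (f_e <= hi) & (f_d >= lo) & (f_d <= hi)
    return RedoxSeries(
        E_ox=(1.0 - f_e) * cal.E_total, E_red=f_e * cal.E_total,
        D_ox=(1.0 - f_d) * cal.D_total, D_red=f_d * cal.D_total,
        usable=usable)


def nernst_fit(series: RedoxSeries, E0_dye_mV: float = -116.0,
               nd: int = 2, ne: int = 2,
               nernst_slope_V: float = 0.0592) -> RedoxFit:
    """OLS regression of log10(E_red/E_ox) on log10(D_red/D_ox).

    The slope estimates ne/nd; the enzyme midpoint potential follows
    from the intercept as E°_e = E°_d + (nernst_slope/ne)·intercept
    (reported in mV).  Points with a zero concentration on either side
    of either couple are excluded (flag ``points_excluded_zero``).
    """
    mask = series.usable.copy()
    nonzero = (series.E_ox > 0) & (series.E_red > 0) & \
              (series.D_ox > 0) & (series.D_red > 0)
    flags: list[str] = []
    if np.any(mask & ~nonzero):
        flags.append("points_excluded_zero")
    mask &= nonzero
    if np.count_nonzero(mask) < 4:
        raise FitError("need >= 4 usable points for the Nernst regression")
    x = np.log10(series.D_red[mask] / series.D_ox[mask])
    y = np.log10(series.E_red[mask] / series.E_ox[mask])
    order = np.lexsort((y, x))
    res = stats.linregress(x[order], y[order])
    pred = res.slope * x + res.intercept
    tss = float(np.sum((y - np.mean(y)) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    slope_V_per_log = nernst_slope_V * 1000.0 / ne   # mV per log10 unit
    return RedoxFit(
        slope=float(res.slope), slope_stderr=float(res.stderr),
        intercept=float(res.intercept),
        intercept_stderr=float(res.intercept_stderr),
        E0_enzyme_mV=E0_dye_mV + slope_V_per_log * float(res.intercept),
        E0_enzyme_stderr_mV=slope_V_per_log * float(res.intercept_stderr),
        E0_dye_mV=E0_dye_mV, ne=ne, nd=nd,
        n_used=int(np.count_nonzero(mask)),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        flags=tuple(flags))


def fit_binding_titration(series: TitrationSeries
                          ) -> tuple[BindingIsothermParams, FitResult]:
    """Fit the quadratic tight-binding isotherm to a ΔA titration.

    The total enzyme concentration is fixed at the known value, not
    co-fitted.  If the ligand range never exceeds E0 the result is
    flagged ``saturation_not_reached``; an all-zero ΔA series leaves Kd
    unidentifiable (flag ``Kd_unidentifiable``).
    """
    if len(series.L0) < 5:
        raise FitError("need >= 5 ligand levels")
    if np.allclose(series.dA, 0.0):
        fr = FitResult(params={"dA_max": 0.0, "Kd": float("nan"),
                               "E0": series.E0},
                       stderr={"dA_max": 0.0, "Kd": float("nan"), "E0": 0.0},
                       rss=0.0, r2=float("nan"), n_obs=len(series.L0),
                       converged=True, n_iter=0,
                       init={"dA_max": 0.0, "Kd": float("nan"),
                             "E0": series.E0},
                       flags=("Kd_unidentifiable",))
        return BindingIsothermParams(dA_max=0.0, E0=series.E0, Kd=0.0), fr
    fr = fit_nls("isotherm", series.L0, series.dA, fixed={"E0": series.E0})
    if float(np.max(series.L0)) < series.E0:
        fr = fr.with_flags("saturation_not_reached")
    p = BindingIsothermParams(dA_max=fr.params["dA_max"], E0=series.E0,
                              Kd=max(fr.params["Kd"], 0.0))
    return p, fr


def extinction_coefficient(A_holo: float, A_released: float,
                           dilution: float,
                           eps_free: float = OpticalConstants().eps450_free_fad,
                           path: float = 1.0) -> float:
    """Holoenzyme extinction coefficient from SDS-released free FAD.

    The flavin is released by SDS, its concentration read from the free
    FAD absorbance (ε450 = 11,300 M⁻¹cm⁻¹ by default), corrected for the
    dilution incurred by SDS addition, and the original holoenzyme
    absorbance divided by that concentration.
    """
    if A_holo <= 0 or A_released <= 0 or eps_free <= 0 or path <= 0:
        raise ValueError("inputs must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    conc_released = A_released / (eps_free * path)     # M
    conc_holo = conc_released * dilution               # M, pre-dilution
    return A_holo / (conc_holo * path)
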