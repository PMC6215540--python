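"""Seeded generators for every input the analysis pipeline consumes.

Two generators carry real mechanism: a mass-action ODE simulator of the
type I Baeyer-Villiger monooxygenase catalytic cycle (oxidized enzyme ->
NADPH Michaelis complex -> reduced flavin·NADP⁺ -> C4a-peroxyflavin ->
[Criegee] -> C4a-hydroxyflavin -> oxidized enzyme, with an uncoupling
branch from the peroxyflavin to H₂O₂), and a quasi-static two-couple
Nernst equilibration for dye-referenced redox potentiometry.  The rest
evaluate the closed-form models directly and add Gaussian noise.

All generators are bit-reproducible under a fixed seed and grid.  The
module-level :data:`ACMO_REFERENCE` dict is the package's reference
parameter set for acetone monooxygenase, used as generator ground truth
in round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetic_models import (
    BindingIsothermParams,
    ExponentialPhases,
    MichaelisParams,
    PHBellParams,
    exponential_decay,
    michaelis_velocity,
    ph_bell,
    quadratic_isotherm,
)
from .redox_titration import SpectralCalibration, TitrationSeries
from .steady_state import VelocityRecord
from .transient import AbsorbanceTrace

__all__ = [
    "ACMO_REFERENCE",
    "MechanismParams",
    "NoiseSpec",
    "CycleResult",
    "MasseySeries",
    "simulate_cycle",
    "generate_reduction_trace",
    "generate_exponential_trace",
    "generate_massey_series",
    "generate_progress_curve",
    "generate_velocity_dataset",
    "generate_titration",
    "generate_ph_dataset",
]

# Reference characterization of acetone monooxygenase (wild type), used
# as ground truth for parameter-recovery round trips.  Units: rates s^-1,
# concentrations µM unless suffixed, potentials mV, efficiencies via
# kcat/Km.
ACMO_REFERENCE: dict[str, float] = {
    "kobs_red_NADPH": 28.4,      # 443 nm reduction, protiated coenzyme
    "kobs_red_NADPD": 7.5,       # 443 nm reduction, (4R)-deuterated
    "kie": 3.8,
    "kred": 59.0,                # limiting flavin-reduction rate constant
    "Kd_NADPH": 121.0,           # stopped-flow coenzyme dissociation constant
    "kcat_NADPH": 2.0,
    "Km_NADPH": 6.7,
    "kcat_acetone": 1.4,
    "Km_acetone": 170.0,
    "kcat_butanone": 2.1,
    "Km_butanone": 0.34,
    "Ki_NADP": 166.0,
    "k_unc": 0.26,               # uncoupled NADPH oxidation
    "k_OO_mM": 40.1,             # bimolecular O2 constant, no substrate
    "k_OO_BT_mM": 44.2,          # with butanone
    "k_ox1": 0.47,               # 440 nm reoxidation, fast phase
    "k_ox2": 0.06,               # 440 nm reoxidation, slow phase
    "k_440": 0.80,               # 440 nm with butanone, single phase
    "pKa_low": 5.6,
    "pKa_high": 9.2,
    "Kd_NADP_titration": 21.1,   # quadratic-isotherm NADP+ Kd, wild type
    "E0_enzyme_mV": -166.0,
    "E0_dye_mV": -116.0,         # indigo disulfonate, pH 7.0
    "o2_air_post_mix_mM": 0.13,  # air-saturated buffer halved on mixing
}

SPECIES = ("E_ox", "E_NADPH", "E_red", "E_per", "E_criegee", "E_hydroxy",
           "NADPH", "NADP", "O2", "ketone", "product")
_ENZYME_SPECIES = SPECIES[:6]

# Per-wavelength, per-species extinction coefficients (M^-1 cm^-1).
# The oxidized flavin dominates at 440/443 nm; the C4a-peroxyflavin is
# read at 366 nm (its coefficient there is a documented assumption, the
# intermediate's spectrum is not pinned down); reduced flavin and the
# hydroxyflavin are taken as transparent at 443 nm; the Criegee adduct
# is treated as spectrally silent.  NADPH contributes at 340 nm.
EPS_DEFAULT: dict[float, dict[str, float]] = {
    443.0: {"E_ox": 12200.0, "E_NADPH": 12200.0},
    440.0: {"E_ox": 12200.0, "E_NADPH": 12200.0},
    366.0: {"E_per": 8000.0, "E_ox": 4000.0, "E_NADPH": 4000.0},
    340.0: {"NADPH": 6220.0, "E_NADPH": 6220.0},
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: SD in observable units plus RNG seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.array(values, dtype=float)
        return values + self.rng().normal(0.0, self.sigma, size=np.shape(values))


@dataclass(frozen=True)
class MechanismParams:
    """Microscopic rate constants of the catalytic cycle.

    kon_NADPH (µM⁻¹s⁻¹) / koff_NADPH (s⁻¹) set a rapid-equilibrium
    coenzyme binding step with Kd = koff/kon; k_red is the hydride
    transfer; k_O2 (mM⁻¹s⁻¹) the reaction of reduced flavin with O₂;
    k_sub (µM⁻¹s⁻¹) the peroxyflavin-ketone step; k_collapse the Criegee
    collapse (0 lumps the Criegee into the substrate step); k_release
    the hydroxyflavin dehydration / NADP⁺ release (rate-limiting);
    k_uncouple the peroxyflavin decay to H₂O₂.
    """

    kon_NADPH: float = 1000.0 / 121.0
    koff_NADPH: float = 1000.0
    k_red: float = 59.0
    k_O2: float = 40.1
    k_sub: float = 0.05
    k_collapse: float = 0.0
    k_release: float = 6.8
    k_uncouple: float = 0.47
    eps: Mapping[float, Mapping[str, float]] = field(
        default_factory=lambda: EPS_DEFAULT)

    def __post_init__(self) -> None:
        for name in ("kon_NADPH", "koff_NADPH", "k_red", "k_O2", "k_sub",
                     "k_collapse", "k_release", "k_uncouple"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def Kd_NADPH(self) -> float:
        return self.koff_NADPH / self.kon_NADPH

    @classmethod
    def with_Kd(cls, Kd_NADPH: float, koff: float = 1000.0, **kw
                ) -> "MechanismParams":
        """Rapid-equilibrium binding with the requested Kd (µM)."""
        return cls(kon_NADPH=koff / Kd_NADPH, koff_NADPH=koff, **kw)


@dataclass(frozen=True)
class CycleResult:
    """Trajectories of all species (µM) on the requested time grid."""

    t: np.ndarray
    conc: np.ndarray                 # shape (n_species, n_times)
    params: MechanismParams
    success: bool
    message: str

    def species(self, name: str) -> np.ndarray:
        return self.conc[SPECIES.index(name)]

    def enzyme_total(self) -> np.ndarray:
        return self.conc[:6].sum(axis=0)

    def nicotinamide_total(self) -> np.ndarray:
        # NADP(H) bound to post-hydride enzyme states counts as NADP+
        bound = self.conc[1:6].sum(axis=0)
        return self.species("NADPH") + self.species("NADP") + bound

    def absorbance(self, wavelength: float, path: float = 1.0) -> np.ndarray:
        eps = self.params.eps.get(float(wavelength))
        if eps is None:
            raise KeyError(f"no extinction coefficients at {wavelength} nm")
        A = np.zeros_like(self.t, dtype=float)
        for name, e in eps.items():
            A += self.species(name) * 1e-6 * e * path
        return A


def simulate_cycle(p: MechanismParams, init: Mapping[str, float],
                   times, rtol: float = 1e-9, atol: float = 1e-12
                   ) -> CycleResult:
    """Integrate the mass-action catalytic-cycle ODEs.

    ``init`` gives initial concentrations in µM (keys from
    :data:`SPECIES`; omitted species start at 0; enzyme is typically all
    ``E_ox``).  O₂ is carried in µM internally although its bimolecular
    constant is quoted per mM.  Enzyme and nicotinamide totals are
    conserved by construction; the integrator tolerances keep the drift
    below ~1e-8 relative.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing with >= 2 points")
    y0 = np.zeros(len(SPECIES))
    for key, val in init.items():
        if key not in SPECIES:
            raise KeyError(f"unknown species {key!r}")
        if val < 0:
            raise ValueError(f"negative initial concentration for {key}")
        y0[SPECIES.index(key)] = float(val)

    k_o2_uM = p.k_O2 / 1000.0
    lump_criegee = p.k_collapse == 0.0

    def rhs(_t, y):
        Eox, EN, Ered, Eper, Ecri, Ehyd, NADPH, NADP, O2, ket, _prod = y
        v_on = p.kon_NADPH * Eox * NADPH
        v_off = p.koff_NADPH * EN
        v_red = p.k_red * EN
        v_ox = k_o2_uM * Ered * O2
        v_sub = p.k_sub * Eper * ket
        v_col = 0.0 if lump_criegee else p.k_collapse * Ecri
        v_rel = p.k_release * Ehyd
        v_unc = p.k_uncouple * Eper
        to_hydroxy = v_sub if lump_criegee else v_col
        return [
            -v_on + v_off + v_rel + v_unc,          # E_ox
            v_on - v_off - v_red,                   # E_NADPH
            v_red - v_ox,                           # E_red (FADH-·NADP+)
            v_ox - v_sub - v_unc,                   # E_per
            0.0 if lump_criegee else v_sub - v_col,  # E_criegee
            to_hydroxy - v_rel,                     # E_hydroxy
            -v_on + v_off,                          # NADPH
            v_rel + v_unc,                          # NADP
            -v_ox,                                  # O2
            -v_sub,                                 # ketone
            to_hydroxy,                             # product ester
        ]

    sol = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")
    if np.min(sol.y) < -100 * atol:
        raise RuntimeError(
            f"negative concentrations beyond tolerance: min={np.min(sol.y):.3e}")
    return CycleResult(t=times, conc=sol.y, params=p, success=True,
                       message=sol.message)


def generate_reduction_trace(E0: float, NADPH0: float,
                             p: MechanismParams | None = None,
                             noise: NoiseSpec = NoiseSpec(),
                             times=None, wavelength: float = 443.0
                             ) -> AbsorbanceTrace:
    """Anaerobic (O₂ = 0) flavin-reduction trace at 443 nm.

    Wraps :func:`simulate_cycle`; with O₂ absent the reduced state is
    absorbing, so in the pseudo-first-order regime the trace is a single
    exponential with rate k_red·[NADPH]/(Kd + [NADPH]).
    """
    p = p or MechanismParams()
    if times is None:
        times = np.linspace(0.0, 1.0, 501)
    res = simulate_cycle(p, {"E_ox": E0, "NADPH": NADPH0}, times)
    A = noise.apply(res.absorbance(wavelength))
    return AbsorbanceTrace(wavelength=wavelength, t=np.asarray(times, float),
                           A=A, meta={"enzyme_uM": E0, "nadph_uM": NADPH0,
                                      "o2_mM": 0.0})


def generate_exponential_trace(phases: ExponentialPhases, times,
                               noise: NoiseSpec = NoiseSpec(),
                               wavelength: float = 443.0,
                               meta: Mapping[str, float] | None = None
                               ) -> AbsorbanceTrace:
    """Direct multi-exponential trace at stated phase rates/amplitudes."""
    times = np.asarray(times, dtype=float)
    A = noise.apply(exponential_decay(times, phases))
    return AbsorbanceTrace(wavelength=wavelength, t=times, A=A,
                           meta=dict(meta or {}))


def _reduced_fraction(E: float, E0: float, n: int, slope: float) -> float:
    logratio = n * (E0 - E) / slope
    r = 10.0 ** logratio
    return r / (1.0 + r)


@dataclass(frozen=True)
class MasseySeries:
    """Quasi-static two-couple equilibration read at 458/610 nm."""

    A458: np.ndarray
    A610: np.ndarray
    cal: SpectralCalibration
    schedule: np.ndarray     # delivered reducing equivalents, µM-equiv
    f_enzyme: np.ndarray     # true reduced fractions
    f_dye: np.ndarray
    potential_V: np.ndarray  # common solution potential per point


def generate_massey_series(E0_enzyme_mV: float = -166.0, ne: int = 2,
                           C_enzyme: float = 20.0,
                           E0_dye_mV: float = -116.0, nd: int = 2,
                           C_dye: float = 20.0,
                           schedule=None,
                           cal: SpectralCalibration | None = None,
                           noise: NoiseSpec = NoiseSpec(),
                           nernst_slope_V: float = 0.0592) -> MasseySeries:
    """Simulate slow co-reduction of enzyme and reference dye.

    At each delivered-reducing-equivalent value R the common solution
    potential E is found by bisection from the conservation condition
    ne·C_e·f_e(E) + nd·C_d·f_d(E) = R, where f is the n-electron Nernst
    reduced fraction.  Concentrations are projected to 458/610 nm
    absorbances through the endpoint calibration (458 nm is the dye's
    isosbestic point, so only the enzyme moves it; 610 nm sees only the
    dye).
    """
    total = ne * C_enzyme + nd * C_dye
    if schedule is None:
        schedule = np.linspace(0.01, 0.99, 150) * total
    schedule = np.asarray(schedule, dtype=float)
    if np.any(schedule < 0) or np.any(schedule > total):
        raise ValueError("schedule outside [0, total reducing equivalents]")
    if cal is None:
        cal = SpectralCalibration(
            A458_ox=C_enzyme * 1e-6 * 12200.0, A458_red=C_enzyme * 1e-6 * 900.0,
            A610_ox=C_dye * 1e-6 * 20000.0, A610_red=C_dye * 1e-6 * 400.0,
            E_total=C_enzyme, D_total=C_dye)
    E0e, E0d = E0_enzyme_mV / 1000.0, E0_dye_mV / 1000.0

    f_e = np.empty_like(schedule)
    f_d = np.empty_like(schedule)
    pot = np.empty_like(schedule)
    for i, R in enumerate(schedule):
        if R == 0.0:
            f_e[i], f_d[i], pot[i] = 0.0, 0.0, np.inf
            continue
        if R == total:
            f_e[i], f_d[i], pot[i] = 1.0, 1.0, -np.inf
            continue

        def excess(E, R=R):
            return (ne * C_enzyme * _reduced_fraction(E, E0e, ne, nernst_slope_V)
                    + nd * C_dye * _reduced_fraction(E, E0d, nd, nernst_slope_V)
                    - R)

        E = brentq(excess, -2.0, 1.5, xtol=1e-14)
        pot[i] = E
        f_e[i] = _reduced_fraction(E, E0e, ne, nernst_slope_V)
        f_d[i] = _reduced_fraction(E, E0d, nd, nernst_slope_V)

    A458 = cal.A458_ox - f_e * (cal.A458_ox - cal.A458_red)
    A610 = cal.A610_ox - f_d * (cal.A610_ox - cal.A610_red)
    if noise.sigma > 0:
        rng = noise.rng()
        A458 = A458 + rng.normal(0.0, noise.sigma, size=A458.shape)
        A610 = A610 + rng.normal(0.0, noise.sigma, size=A610.shape)
    return MasseySeries(A458=A458, A610=A610, cal=cal, schedule=schedule,
                        f_enzyme=f_e, f_dye=f_d, potential_V=pot)


def generate_velocity_dataset(p: MichaelisParams, S_grid,
                              I_grid=(0.0,),
                              noise: NoiseSpec = NoiseSpec(),
                              E0: float = 0.03,
                              substrate_id: str = "substrate"
                              ) -> list[VelocityRecord]:
    """Initial-velocity records on an (S, I) grid from the rate law."""
    S_grid = np.asarray(S_grid, dtype=float)
    I_grid = np.asarray(I_grid, dtype=float)
    if S_grid.size == 0 or I_grid.size == 0:
        raise ValueError("empty concentration grid")
    S, I = np.meshgrid(S_grid, I_grid, indexing="ij")
    S, I = S.ravel(), I.ravel()
    v = noise.apply(michaelis_velocity(S, p, I))
    return [VelocityRecord(substrate_id=substrate_id, S=float(s), I=float(i),
                           E0=E0, v=float(vi), unit="per_s")
            for s, i, vi in zip(S, I, v)]


def generate_progress_curve(p: MichaelisParams, S0: float, E0: float,
                            NADPH0: float, times,
                            noise: NoiseSpec = NoiseSpec(),
                            d_eps340: float = 6220.0,
                            A_offset: float = 0.05) -> AbsorbanceTrace:
    """A340 progress curve of NADPH consumption during ketone turnover.

    Integrates ketone depletion under the Michaelis-Menten rate law
    (dS/dt = −E0·kcat·S/(Km+S), NADPH consumed 1:1) and projects the
    remaining NADPH to absorbance via Δε340.  Initial-velocity analysis
    is accurate while substrate depletion stays within ~10%.
    """
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(lambda _t, y: [-E0 * michaelis_velocity(max(y[0], 0.0), p)],
                    (times[0], times[-1]), [S0], t_eval=times,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(sol.message)
    consumed = S0 - sol.y[0]
    nadph = np.maximum(NADPH0 - consumed, 0.0)
    A = noise.apply(A_offset + nadph * 1e-6 * d_eps340)
    return AbsorbanceTrace(wavelength=340.0, t=times, A=A,
                           meta={"enzyme_uM": E0, "nadph_uM": NADPH0,
                                 "ketone_uM": S0})


def generate_titration(p: BindingIsothermParams, L0_grid,
                       noise: NoiseSpec = NoiseSpec()) -> TitrationSeries:
    """ΔA titration from the quadratic isotherm.  The grid must start at
    zero added ligand; the first point defines the ΔA baseline and stays
    exactly zero even under noise."""
    L0 = np.asarray(L0_grid, dtype=float)
    if L0.size == 0 or L0[0] != 0.0:
        raise ValueError("titration grid must start at L0 = 0")
    dA = noise.apply(quadratic_isotherm(L0, p))
    dA[0] = 0.0
    return TitrationSeries(L0=L0, dA=dA, E0=p.E0)


def generate_ph_dataset(p: PHBellParams, pH_grid,
                        noise: NoiseSpec = NoiseSpec()
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(pH, velocity) pairs from the two-pKa bell."""
    pH = np.asarray(pH_grid, dtype=float)
    if pH.size == 0:
        raise ValueError("empty pH grid")
    return pH, noise.apply(ph_bell(pH, p))
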