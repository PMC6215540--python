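"""Nonlinear least-squares machinery shared by all analysis modules.

Wraps lmfit's Levenberg-Marquardt minimizer behind a single entry point,
``fit_nls``, with documented, scale-free initialization heuristics per
model, asymptotic (curvature-based) standard errors, and explicit
convergence reporting.  Model selection between one- and two-exponential
transients uses the corrected Akaike information criterion with ties
broken toward the simpler model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import lmfit

__all__ = [
    "FitResult",
    "ModelSelection",
    "FitError",
    "NotConvergedError",
    "fit_nls",
    "select_exponential_phases",
    "ratio_with_uncertainty",
    "MODELS",
    "CONVERGENCE",
]


class FitError(ValueError):
    """Raised for under-determined or structurally invalid fit requests."""


class NotConvergedError(RuntimeError):
    """Raised when a downstream consumer requires a converged fit."""


# Convergence thresholds; mutable so a config file can override them.
CONVERGENCE: dict[str, float | int] = {
    "ftol": 1e-12,   # relative RSS change
    "xtol": 1e-12,
    "max_iter": 500,
}


@dataclass(frozen=True)
class FitResult:
    """Fitted-parameter bundle with uncertainties and diagnostics.

    ``stderr`` entries are asymptotic errors from the inverse curvature
    at the optimum (NaN when the covariance could not be estimated).
    ``converged=False`` forbids downstream use unless explicitly
    overridden (see :meth:`ensure_converged`).
    """

    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    r2: float
    n_obs: int
    converged: bool
    n_iter: int
    init: dict[str, float]
    flags: tuple[str, ...] = ()

    def ensure_converged(self, allow_unconverged: bool = False) -> "FitResult":
        if not self.converged and not allow_unconverged:
            raise NotConvergedError(
                "fit did not converge; pass allow_unconverged=True to override"
            )
        return self

    def with_flags(self, *new: str) -> "FitResult":
        return FitResult(self.params, self.stderr, self.rss, self.r2,
                         self.n_obs, self.converged, self.n_iter, self.init,
                         self.flags + tuple(new))

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "rss": self.rss,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "init": dict(self.init),
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of 1- vs 2-exponential model comparison."""

    candidate_models: tuple[int, ...]
    aicc: dict[int, float]
    chosen: int
    fits: dict[int, FitResult]
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# model registry: func(x, **params), parameter names, init heuristic, bounds

def _half_point(x: np.ndarray, y: np.ndarray) -> float:
    """x at which y first crosses half its maximum (linear interpolation)."""
    ymax = float(np.max(y))
    if ymax <= 0:
        return float(np.median(x))
    half = ymax / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    above = np.nonzero(ys >= half)[0]
    if len(above) == 0:
        return float(xs[-1])
    i = above[0]
    if i == 0:
        return float(max(xs[0], np.min(xs[xs > 0], initial=xs[0])))
    x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def _mm(x, kcat, Km):
    return kcat * np.asarray(x, float) / (Km + np.asarray(x, float))


def _mm_init(x, y):
    return {"kcat": 1.2 * float(np.max(y)), "Km": max(_half_point(x, y), 1e-9)}


def _competitive(x, kcat, Km, Ki):
    S, I = x
    return kcat * S / (Km * (1.0 + I / Ki) + S)


def _competitive_init(x, y):
    S, I = x
    base = I == np.min(I)
    g = _mm_init(S[base], y[base])
    g["Ki"] = max(float(np.max(I)), 1.0)
    return g


def _isotherm(x, dA_max, Kd, E0):
    L0 = np.asarray(x, float)
    b = E0 + L0 + Kd
    return (dA_max / (2.0 * E0)) * (b - np.sqrt(np.maximum(b * b - 4.0 * E0 * L0, 0.0)))


def _isotherm_init(x, y):
    return {"dA_max": float(np.max(y)), "Kd": max(_half_point(x, y), 1e-9),
            "E0": float(np.max(x)) / 2.0}


def _bell(x, Y_H, pKa_low, pKa_high):
    H = 10.0 ** (-np.asarray(x, float))
    return Y_H / (1.0 + H / 10.0 ** (-pKa_low) + 10.0 ** (-pKa_high) / H)


def _bell_init(x, y):
    ymax = float(np.max(y))
    imax = int(np.argmax(y))
    acid = x <= x[imax]
    base = x >= x[imax]
    half = ymax / 2.0

    def limb(mask, default):
        xs, ys = x[mask], y[mask]
        if len(xs) < 2:
            return default
        below = ys <= half
        if not np.any(below):
            return default
        # nearest half-max crossing to the peak on this limb
        idx = np.nonzero(below)[0]
        return float(xs[idx[np.argmin(np.abs(xs[idx] - x[imax]))]])

    lo = limb(acid, float(np.min(x)) - 0.5)
    hi = limb(base, float(np.max(x)) + 0.5)
    if lo >= hi:
        lo, hi = float(np.min(x)) - 0.5, float(np.max(x)) + 0.5
    return {"Y_H": ymax, "pKa_low": lo, "pKa_high": hi}


def _hyperbola(x, kred, Kd):
    return kred * np.asarray(x, float) / (Kd + np.asarray(x, float))


def _hyperbola_init(x, y):
    return {"kred": 1.2 * float(np.max(y)), "Kd": max(_half_point(x, y), 1e-9)}


def _exp1(x, a1, k1, offset):
    return offset + a1 * np.exp(-k1 * np.asarray(x, float))


def _exp2(x, a1, k1, a2, k2, offset):
    t = np.asarray(x, float)
    return offset + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _loglinear_rate(t, resid, span):
    """Rate from log-linear regression of |residual| over ``span`` indices."""
    mask = np.abs(resid[span]) > 1e-3 * np.max(np.abs(resid) + 1e-300)
    ts, rs = t[span][mask], np.abs(resid[span][mask])
    if len(ts) < 2 or np.ptp(ts) == 0:
        return None, None
    slope, intercept = np.polyfit(ts, np.log(rs), 1)
    if slope >= 0:
        return None, None
    sign = math.copysign(1.0, float(np.mean(resid[span][mask])))
    return -float(slope), sign * float(np.exp(intercept))


def _exp_init(n_phases):
    def init(x, y):
        t = np.asarray(x, float)
        tail = max(3, len(y) // 20)
        offset = float(np.mean(y[-tail:]))
        resid = y - offset
        span_all = slice(0, len(t))
        k, a = _loglinear_rate(t, resid, span_all)
        if k is None:  # flat or non-decaying trace
            k, a = 1.0 / max(float(t[-1]), 1e-6), float(resid[0])
        if n_phases == 1:
            return {"a1": a, "k1": k, "offset": offset}
        # peel: slow phase from the tail half, fast phase from the remainder
        half = len(t) // 2
        ks, As = _loglinear_rate(t, resid, slice(half, len(t)))
        if ks is None:
            ks, As = k / 10.0, a / 2.0
        peeled = resid - As * np.exp(-ks * t)
        kf, Af = _loglinear_rate(t, peeled, slice(0, max(half, 4)))
        if kf is None or kf <= ks:
            kf, Af = ks * 20.0, a - As
        return {"a1": Af, "k1": kf, "a2": As, "k2": ks, "offset": offset}
    return init


def _linear(x, slope, intercept):
    return slope * np.asarray(x, float) + intercept


def _linear_init(x, y):
    if np.ptp(x) == 0:
        return {"slope": 0.0, "intercept": float(np.mean(y))}
    s, i = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)
    return {"slope": float(s), "intercept": float(i)}


_POS = (1e-12, np.inf)

@dataclass(frozen=True)
class _ModelSpec:
    func: Callable
    param_names: tuple[str, ...]
    init: Callable
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: tuple[str, ...] = ()


MODELS: dict[str, _ModelSpec] = {
    "michaelis": _ModelSpec(_mm, ("kcat", "Km"), _mm_init,
                            {"kcat": _POS, "Km": _POS}),
    "competitive": _ModelSpec(_competitive, ("kcat", "Km", "Ki"),
                              _competitive_init,
                              {"kcat": _POS, "Km": _POS, "Ki": _POS}),
    "isotherm": _ModelSpec(_isotherm, ("dA_max", "Kd", "E0"), _isotherm_init,
                           {"Kd": (0.0, np.inf), "E0": _POS}, fixed=("E0",)),
    "ph_bell": _ModelSpec(_bell, ("Y_H", "pKa_low", "pKa_high"), _bell_init,
                          {"Y_H": _POS, "pKa_low": (0.0, 14.0),
                           "pKa_high": (0.0, 14.0)}),
    "hyperbolic": _ModelSpec(_hyperbola, ("kred", "Kd"), _hyperbola_init,
                             {"kred": _POS, "Kd": _POS}),
    "exp1": _ModelSpec(_exp1, ("a1", "k1", "offset"), _exp_init(1),
                       {"k1": _POS}),
    "exp2": _ModelSpec(_exp2, ("a1", "k1", "a2", "k2", "offset"),
                       _exp_init(2), {"k1": _POS, "k2": _POS}),
    "linear": _ModelSpec(_linear, ("slope", "intercept"), _linear_init),
}


def _presort(x, y):
    """Deterministic ordering so fits are invariant to row shuffling."""
    y = np.asarray(y, dtype=float)
    if isinstance(x, tuple):
        cols = [np.asarray(c, dtype=float) for c in x]
        order = np.lexsort(tuple(reversed(cols + [y])))
        return tuple(c[order] for c in cols), y[order]
    x = np.asarray(x, dtype=float)
    order = np.lexsort((y, x))
    return x[order], y[order]


def fit_nls(
    model: str,
    x,
    y,
    init: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit a registered model to (x, y) by unweighted least squares.

    Parameters
    ----------
    model : str
        Key into :data:`MODELS`.
    x : array or tuple of arrays
        Independent variable(s); a tuple for multi-variable models such
        as ``"competitive"`` (S, I).
    init, bounds : optional
        Overrides for the per-model initialization heuristic and default
        bounds.
    fixed : optional
        Parameters to hold constant (e.g. the known enzyme concentration
        ``E0`` in the tight-binding isotherm).

    Raises
    ------
    FitError
        If fewer than (free parameters + 1) observations are supplied or
        any value is non-finite.
    """
    if model not in MODELS:
        raise FitError(f"unknown model {model!r}")
    spec = MODELS[model]
    x, y = _presort(x, y)
    xcheck = np.concatenate([np.ravel(c) for c in x]) if isinstance(x, tuple) else x
    if not (np.all(np.isfinite(xcheck)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in data")

    fixed = dict(fixed or {})
    for name in spec.fixed:
        if name not in fixed:
            raise FitError(f"model {model!r} requires fixed parameter {name!r}")
    n_free = len(spec.param_names) - len(fixed)
    if len(y) < n_free + 1:
        raise FitError(
            f"under-determined: {len(y)} observations for {n_free} free parameters"
        )

    guesses = spec.init(x, y)
    guesses.update(fixed)
    if init:
        guesses.update(init)
    all_bounds = dict(spec.bounds)
    if bounds:
        all_bounds.update(bounds)

    params = lmfit.Parameters()
    for name in spec.param_names:
        lo, hi = all_bounds.get(name, (-np.inf, np.inf))
        val = float(guesses[name])
        val = min(max(val, lo), hi) if np.isfinite(lo) or np.isfinite(hi) else val
        if np.isfinite(lo) and val <= lo:
            val = lo + (1e-9 if not np.isfinite(hi) else (hi - lo) * 1e-9)
        params.add(name, value=val, min=lo, max=hi, vary=name not in fixed)

    def residual(p):
        vals = {name: p[name].value for name in spec.param_names}
        return y - spec.func(x, **vals)

    out = lmfit.minimize(
        residual, params, method="leastsq",
        ftol=CONVERGENCE["ftol"], xtol=CONVERGENCE["xtol"],
        max_nfev=int(CONVERGENCE["max_iter"]) * (n_free + 2),
    )

    est = {name: float(out.params[name].value) for name in spec.param_names}
    err = {}
    flags: list[str] = []
    for name in spec.param_names:
        if name in fixed:
            err[name] = 0.0
        else:
            se = out.params[name].stderr
            err[name] = float(se) if se is not None else float("nan")
    if any(math.isnan(v) for v in err.values()):
        flags.append("stderr_unavailable")

    rss = float(np.sum(np.asarray(out.residual) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-30 else float("nan"))
    converged = bool(out.success)
    if not converged:
        flags.append("not_converged")
    return FitResult(
        params=est, stderr=err, rss=rss, r2=r2, n_obs=int(len(y)),
        converged=converged, n_iter=int(out.nfev),
        init={k: float(v) for k, v in guesses.items()}, flags=tuple(flags),
    )


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def select_exponential_phases(t, A) -> ModelSelection:
    """Fit 1- and 2-exponential models to a transient and choose by AICc.

    Ties (ΔAICc within 1e-9) go to the single phase.  A chosen two-phase
    fit whose rates are separated by less than threefold is flagged
    ``poorly_identifiable``; a near-zero total amplitude is flagged
    ``near_zero_amplitude``.
    """
    t = np.asarray(t, dtype=float)
    A = np.asarray(A, dtype=float)
    if len(t) < 8:
        raise FitError("need at least 8 points for phase selection")
    fits: dict[int, FitResult] = {}
    aicc: dict[int, float] = {}
    fits[1] = fit_nls("exp1", t, A)
    # two-phase fit: try the peeling heuristic and a rate-split of the
    # single-phase optimum, keep the lower-RSS start (rate-collapse is a
    # common local minimum for poorly separated inits)
    f1 = fits[1].params
    split_init = {"a1": f1["a1"] / 2, "k1": 4.0 * f1["k1"],
                  "a2": f1["a1"] / 2, "k2": f1["k1"] / 4.0,
                  "offset": f1["offset"]}
    candidates = [fit_nls("exp2", t, A), fit_nls("exp2", t, A, init=split_init)]
    fits[2] = min(candidates, key=lambda fr: fr.rss)
    for n_ph in (1, 2):
        aicc[n_ph] = _aicc(fits[n_ph].rss, fits[n_ph].n_obs, n_ph * 2 + 1)
    chosen = 1 if aicc[1] <= aicc[2] + 1e-9 else 2
    flags: list[str] = []
    if chosen == 2:
        k1, k2 = fits[2].params["k1"], fits[2].params["k2"]
        if max(k1, k2) < 3.0 * min(k1, k2):
            flags.append("poorly_identifiable")
    amp = sum(fits[chosen].params[a] for a in ("a1", "a2")
              if a in fits[chosen].params)
    scale = max(float(np.ptp(A)), abs(float(np.mean(A))), 1e-12)
    if abs(amp) < 1e-6 * scale or abs(amp) < 1e-12:
        flags.append("near_zero_amplitude")
    return ModelSelection(candidate_models=(1, 2), aicc=aicc, chosen=chosen,
                          fits=fits, flags=tuple(flags))


def ratio_with_uncertainty(a: float, sa: float, b: float, sb: float
                           ) -> tuple[float, float]:
    """a/b with first-order (quadrature) error propagation.

    stderr = sqrt((sa/b)² + (a·sb/b²)²), the standard formula for a
    ratio of independent estimates.
    """
    if b == 0:
        raise ZeroDivisionError("denominator is zero")
    ratio = a / b
    stderr = math.sqrt((sa / b) ** 2 + (a * sb / b ** 2) ** 2)
    return ratio, stderr
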