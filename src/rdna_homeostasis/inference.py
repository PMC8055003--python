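"""Fit the feedback model to copy-number-vs-generation trajectories.

The deterministic ODE is used as a surrogate for the stochastic mean: the
experiment it mirrors starts a population at the steady state of its original
volume, steps the volume (e.g. two-fold for a fresh *cln3* mutant) and follows
the repeat count over ~200 generations.  Parameters are estimated by bounded
nonlinear least squares on the repeats series (linear scale by default, log
scale optionally), with residual-resampling bootstrap confidence intervals.

Identifiability: at most three parameters may be freed per fit (k_amp and
k_loss jointly set both the timescale and the balance point S*, and together
with sir2_K and uaf_conc a four-parameter fit on a single trajectory is
confounded).  ``fitness_width`` only exists in the stochastic selection model
and has no effect on the ODE surrogate, so freeing it is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.optimize import least_squares

from .exceptions import (IdentifiabilityError, InsufficientDataError,
                         UnconvergedFitError)
from .feedback_model import (DEFAULT_WT_VOLUME, FeedbackParams,
                             VolumeSchedule, amplification_gate,
                             sir2_synthesis, solve_free_uaf, steady_state)

__all__ = ["FitResult", "fit_trajectories", "predict_setpoint",
           "FREE_PARAM_NAMES"]

#: Parameters the public contract allows to be freed.
FREE_PARAM_NAMES = ("k_amp", "k_loss", "sir2_K", "uaf_conc", "fitness_width")
_ODE_PARAMS = ("k_amp", "k_loss", "sir2_K", "uaf_conc")
MAX_FREE_PARAMS = 3


@dataclass
class FitResult:
    """Point estimates, bootstrap CIs and diagnostics of one fit."""

    estimates: dict
    ci: dict                     # name -> (lower, upper)
    level: float
    loss: float
    converged: bool
    loss_trace: np.ndarray       # best-so-far SSR per function evaluation
    n_boot: int
    seed: Optional[int]
    params: FeedbackParams       # base params with estimates substituted
    base: FeedbackParams

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append({"parameter": name, "estimate": est,
                         "ci_lower": lo, "ci_upper": hi,
                         "ci_level": self.level})
        return pd.DataFrame(rows)


def _normalize_series(observed):
    """Accept one series or a list of series; each as (t, y) arrays or a
    DataFrame with generation/repeats columns."""
    def one(s):
        if isinstance(s, pd.DataFrame):
            t = s["generation"].to_numpy(dtype=float)
            y = s["repeats"].to_numpy(dtype=float)
        else:
            t, y = s
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("each series must be 1-D (generation, repeats)")
        return t, y

    if isinstance(observed, pd.DataFrame) or (
            isinstance(observed, (tuple, list)) and len(observed) == 2
            and np.ndim(observed[0]) == 1 and not isinstance(observed[0],
                                                             (tuple, list))):
        series = [one(observed)]
    else:
        series = [one(s) for s in observed]
    for t, _ in series:
        if len(t) < 4:
            raise InsufficientDataError(
                f"need >= 4 time points per series, got {len(t)}")
    return series


def _ode_repeats(p: FeedbackParams, initial_volume: float,
                 schedule: VolumeSchedule, times: np.ndarray) -> np.ndarray:
    """Fast piecewise integration of (N, S) returning repeats at `times`.

    Uses the FORTRAN lsoda wrapper for low per-call overhead; the initial
    state is the steady state of the *candidate* parameters at the pre-step
    volume, matching the design of the evolution experiment.
    """
    ss = steady_state(p, initial_volume)
    y0 = np.array([ss.repeats, ss.sir2])

    # scalar-math RHS: this sits in the innermost loop of the optimiser and
    # bootstrap, so numpy call overhead is avoided deliberately
    import math
    U, k, ks2, h = p.uaf_conc, p.k_rdna, p.k_sir2, p.hill_h
    alpha, delta = p.sir2_alpha, p.sir2_delta
    ka, kl, K, m = p.k_amp, p.k_loss, p.sir2_K, p.sir2_m

    def rhs(y, t, vol):
        n, s = y
        if n < 1e-12:
            n = 1e-12
        if s < 0.0:
            s = 0.0
        b = k + n / vol - U
        disc = math.sqrt(b * b + 4.0 * k * U)
        f = 2.0 * k * U / (b + disc) if b > 0 else 0.5 * (disc - b)
        synth = alpha / (1.0 + (f / ks2) ** h)
        gate = 1.0 / (1.0 + (s / K) ** m)
        return (n * (ka * gate - kl), synth - delta * s)

    first_bp = schedule.breakpoints[0][0]
    cuts = [bt for bt, _ in schedule.breakpoints if times[0] < bt < times[-1]]
    edges = [times[0], *cuts, times[-1]]
    out = np.empty_like(times)
    for a, b in zip(edges, edges[1:]):
        vol = initial_volume if a < first_bp else schedule.volume_at(a)
        mask = (times >= a) & (times <= b) if a == edges[0] else \
               (times > a) & (times <= b)
        t_seg = np.concatenate(([a], times[mask], [b]))
        t_seg = np.unique(t_seg)
        sol = odeint(rhs, y0, t_seg, args=(vol,), rtol=1e-6, atol=1e-8)
        out[mask] = np.interp(times[mask], t_seg, sol[:, 0])
        y0 = sol[-1]
    return out


def fit_trajectories(observed, free_params: Sequence[str],
                     base_params: FeedbackParams | None = None,
                     schedule: VolumeSchedule | None = None,
                     initial_volume: float = DEFAULT_WT_VOLUME,
                     bounds: dict | None = None,
                     n_boot: int = 200, seed: Optional[int] = None,
                     ci_level: float = 0.90,
                     log_residuals: bool = False) -> FitResult:
    """Least-squares fit of the feedback model to repeat-count series.

    Parameters
    ----------
    observed
        One or more (generation, repeats) series (array pairs or DataFrames
        with ``generation``/``repeats`` columns); at least 4 points each.
    free_params
        Names of the parameters to estimate (at most 3; see module notes).
    bounds
        Optional ``{name: (lo, hi)}``; defaults to a factor of 10 around the
        base value.  Optimisation runs in log10 space.
    n_boot
        Residual-resampling bootstrap replicates for the CIs (0 disables).
    """
    free = tuple(free_params)
    for name in free:
        if name not in FREE_PARAM_NAMES:
            raise ValueError(f"unknown free parameter {name!r}")
    if "fitness_width" in free:
        raise IdentifiabilityError(
            "fitness_width only affects the stochastic selection model; the "
            "deterministic fitting surrogate does not contain it")
    if len(free) == 0:
        raise ValueError("free_params must name at least one parameter")
    if len(free) > MAX_FREE_PARAMS:
        raise IdentifiabilityError(
            f"at most {MAX_FREE_PARAMS} parameters may be freed per fit "
            "(joint k_amp/k_loss/sir2_K/uaf_conc fits are confounded)")

    series = _normalize_series(observed)
    base = base_params if base_params is not None else FeedbackParams()
    if schedule is None:
        schedule = VolumeSchedule.constant(initial_volume)

    x0 = np.array([np.log10(getattr(base, name)) for name in free])
    if bounds is None:
        bounds = {}
    lo = np.array([np.log10(bounds.get(n, (getattr(base, n) / 10,
                                           getattr(base, n) * 10))[0])
                   for n in free])
    hi = np.array([np.log10(bounds.get(n, (getattr(base, n) / 10,
                                           getattr(base, n) * 10))[1])
                   for n in free])

    all_t = [t for t, _ in series]
    all_y = np.concatenate([y for _, y in series])

    def model_vector(x) -> np.ndarray:
        p = replace(base, **{n: 10.0 ** xi for n, xi in zip(free, x)})
        cache: dict[bytes, np.ndarray] = {}  # replicate series share one solve
        parts = []
        for t in all_t:
            key = t.tobytes()
            if key not in cache:
                cache[key] = _ode_repeats(p, initial_volume, schedule, t)
            parts.append(cache[key])
        return np.concatenate(parts)

    trace: list[float] = []

    def residuals(x, y_target):
        m = model_vector(x)
        r = (np.log(m) - np.log(y_target)) if log_residuals else m - y_target
        if y_target is all_y:
            trace.append(float(np.sum((m - all_y) ** 2)))
        return r

    # diff_step must sit well above the ODE solver's rtol-induced noise
    # floor, or the finite-difference jacobian degenerates to noise
    res = least_squares(residuals, x0, bounds=(lo, hi), args=(all_y,),
                        method="trf", xtol=1e-10, ftol=1e-10, diff_step=1e-3)
    converged = bool(res.status > 0)
    x_hat = res.x
    estimates = {n: 10.0 ** xi for n, xi in zip(free, x_hat)}
    fitted = replace(base, **estimates)
    y_hat = model_vector(x_hat)
    loss = float(np.sum((y_hat - all_y) ** 2))
    loss_trace = np.minimum.accumulate(np.asarray(trace))

    rng = np.random.default_rng(seed)
    ci = {}
    boot = []
    if n_boot > 0 and converged:
        # resample residuals on the scale the fit used, so multiplicative
        # noise is regenerated multiplicatively under log_residuals
        resid = (np.log(all_y) - np.log(y_hat)) if log_residuals \
            else all_y - y_hat
        for _ in range(n_boot):
            draw = rng.choice(resid, size=len(resid), replace=True)
            y_star = y_hat * np.exp(draw) if log_residuals \
                else np.maximum(y_hat + draw, 1.0)
            r = least_squares(residuals, x_hat, bounds=(lo, hi),
                              args=(y_star,), method="trf",
                              xtol=1e-8, ftol=1e-8, diff_step=1e-3)
            boot.append(10.0 ** r.x)
        boot = np.asarray(boot)
        alpha = (1.0 - ci_level) / 2.0
        for j, name in enumerate(free):
            lo_q, hi_q = np.quantile(boot[:, j], [alpha, 1.0 - alpha])
            est = estimates[name]
            ci[name] = (min(lo_q, est), max(hi_q, est))

    return FitResult(estimates=estimates, ci=ci, level=ci_level, loss=loss,
                     converged=converged, loss_trace=loss_trace,
                     n_boot=n_boot, seed=seed, params=fitted, base=base)


def predict_setpoint(fit: FitResult, volume: float) -> float:
    """Steady-state repeat count of the fitted model at `volume` (linear in
    volume: the set point is a repeat *concentration*)."""
    if not fit.converged:
        raise UnconvergedFitError(
            "cannot predict a set point from an unconverged fit")
    return steady_state(fit.params, volume).repeats
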