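"""Deterministic core of the volume-controlled rDNA copy-number feedback loop.

Budding yeast keeps the concentration of ribosomal-DNA repeats (and hence the
rRNA synthesis rate per unit volume) constant across cell sizes.  The control
architecture modelled here is a transcription-factor titration ("musical
chairs") switch closed through the chromosomal repeat count:

* The upstream activator factor (UAF) is present at a fixed cellular
  concentration and binds the rDNA promoter with very high affinity, so almost
  all UAF is sequestered on the repeats and the free pool is tiny.
* Free UAF also binds the much weaker *SIR2* promoter, repressing it.  When
  the cell enlarges at fixed repeat number, total UAF molecules scale with
  volume while binding sites do not, free UAF rises and *SIR2* is repressed.
* Sir2 silences unequal sister-chromatid recombination between repeats, so low
  Sir2 permits net repeat amplification.  Amplification proceeds until the new
  repeats re-sequester the excess UAF — an integral feedback in which the
  repeat count accumulates the free-UAF error, giving perfect adaptation of
  the repeat *concentration* (and of Sir2) to any volume change.

State variables: ``N`` chromosomal repeats, ``S`` Sir2 activity, exogenous
volume ``V`` (fL), with the free-UAF concentration ``f`` slaved to ``(N, V)``
through one-site binding at quasi-steady state.  Time is measured in
generations, the natural clock of recombination (one opportunity per genome
replication).

Dynamics::

    f : f + (N/V) * f / (k_rdna + f) = uaf_conc          (binding conservation)
    dS/dt = sir2_alpha / (1 + (f/k_sir2)**hill_h) - sir2_delta * S
    dN/dt = N * (k_amp / (1 + (S/sir2_K)**sir2_m) - k_loss)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import CalibrationError, IntegrationError, ParameterError

__all__ = [
    "DEFAULT_WT_VOLUME",
    "DEFAULT_WT_REPEATS",
    "FeedbackParams",
    "CellState",
    "VolumeSchedule",
    "Trajectory",
    "SteadyState",
    "Transcription",
    "solve_free_uaf",
    "sir2_synthesis",
    "sir2_balance",
    "repeat_drift",
    "steady_state",
    "setpoint_concentration",
    "calibrate",
    "integrate_model",
    "predict_transcription",
]

#: Median cell volume of the wild-type haploid reference (fL).
DEFAULT_WT_VOLUME = 42.0
#: Chromosomal rDNA repeat count of the wild-type haploid reference.
DEFAULT_WT_REPEATS = 125.0


def solve_free_uaf(uaf_conc, repeat_conc, k_rdna):
    """Free UAF concentration from one-site binding conservation.

    Solves ``f + R * f / (k + f) = U`` for ``f >= 0`` (each repeat promoter
    binds at most one UAF molecule).  The unique non-negative root of the
    quadratic ``f**2 + (k + R - U) f - k U = 0`` is evaluated in a
    cancellation-safe form.  Accepts scalars or arrays (broadcast).

    Parameters
    ----------
    uaf_conc
        Total UAF concentration, molecules/fL.
    repeat_conc
        rDNA promoter concentration, promoters/fL.
    k_rdna
        UAF–rDNA promoter dissociation constant, molecules/fL.
    """
    u = np.asarray(uaf_conc, dtype=float)
    r = np.asarray(repeat_conc, dtype=float)
    k = np.asarray(k_rdna, dtype=float)
    if np.any(u < 0) or np.any(r < 0) or np.any(k < 0):
        raise ValueError("solve_free_uaf: all arguments must be non-negative")
    b = k + r - u
    disc = np.sqrt(b * b + 4.0 * k * u)
    # root = (-b + disc) / 2, computed without cancellation when b > 0
    f = np.where(b > 0, np.divide(2.0 * k * u, b + disc,
                                  out=np.zeros_like(disc), where=(b + disc) > 0),
                 (disc - b) / 2.0)
    if f.ndim == 0:
        return float(f)
    return f


@dataclass(frozen=True)
class FeedbackParams:
    """Kinetic and binding constants of the UAF/Sir2/rDNA control loop.

    Defaults are calibrated so that the steady state at the 42 fL wild-type
    volume is 125 chromosomal repeats; rate constants give a copy-number
    relaxation time of a few tens of generations, matching the ~200-generation
    evolution experiment the stochastic module emulates.

    Units: concentrations in molecules/fL, rates per generation, Sir2 in
    arbitrary activity units.
    """

    uaf_conc: float = None  # molecules/fL; default computed post-init
    k_rdna: float = 1.0e-5
    k_sir2: float = 1.0e-2
    hill_h: float = 2.0
    sir2_alpha: float = 2.0
    sir2_delta: float = 0.5
    k_amp: float = 0.08
    k_loss: float = 0.02
    sir2_K: float = 1.0
    sir2_m: float = 2.0
    pol1_rate: float = 1.0
    pol2_fraction: float = 0.25
    n_floor: int = 20

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if name == "uaf_conc" and value is None:
                continue
            if not value > 0:
                raise ParameterError(f"FeedbackParams.{name} must be > 0, got {value!r}")
        if not self.k_rdna < self.k_sir2:
            raise ParameterError(
                "UAF must bind the rDNA promoter more tightly than the SIR2 "
                f"promoter: k_rdna={self.k_rdna} >= k_sir2={self.k_sir2}")
        if not 0 < self.pol2_fraction < 1:
            raise ParameterError("pol2_fraction must lie in (0, 1)")
        if not self.k_loss < self.k_amp:
            raise ParameterError(
                "k_loss must be < k_amp (a Sir2-derepressed state must allow "
                "net amplification)")
        if self.uaf_conc is None:
            try:
                object.__setattr__(self, "uaf_conc",
                                   _calibrated_uaf(self, DEFAULT_WT_VOLUME,
                                                   DEFAULT_WT_REPEATS))
            except CalibrationError as exc:
                raise ParameterError(str(exc)) from exc
        # a positive homeostatic steady state must exist
        self.free_uaf_setpoint()

    # -- derived steady-state quantities ------------------------------------

    def sir2_setpoint(self) -> float:
        """Sir2 activity S* at which amplification and loss exactly balance."""
        return self.sir2_K * (self.k_amp / self.k_loss - 1.0) ** (1.0 / self.sir2_m)

    def free_uaf_setpoint(self) -> float:
        """Free UAF concentration f* at which Sir2 settles at S*."""
        s_star = self.sir2_setpoint()
        ratio = self.sir2_alpha / (self.sir2_delta * s_star)
        if ratio <= 1.0:
            raise ParameterError(
                "no positive steady state: maximal SIR2 synthesis cannot "
                f"sustain the balancing Sir2 activity S*={s_star:.4g}")
        f_star = self.k_sir2 * (ratio - 1.0) ** (1.0 / self.hill_h)
        if not self.uaf_conc > f_star:
            raise ParameterError(
                f"no positive steady state: total UAF ({self.uaf_conc:.4g}) "
                f"does not exceed the free set point f*={f_star:.4g}")
        return f_star


def _calibrated_uaf(p: FeedbackParams, volume: float, repeats: float) -> float:
    """Total UAF concentration placing the steady state at `repeats`@`volume`.

    Works on a params object whose uaf_conc may be unset; uses only the other
    constants.  From binding conservation at f = f*:
    ``U = f* + (N/V) * f* / (k_rdna + f*)``.
    """
    s_star = p.sir2_K * (p.k_amp / p.k_loss - 1.0) ** (1.0 / p.sir2_m)
    ratio = p.sir2_alpha / (p.sir2_delta * s_star)
    if ratio <= 1.0:
        raise CalibrationError(
            "calibration impossible: SIR2 synthesis cannot reach the "
            "recombination balance point")
    f_star = p.k_sir2 * (ratio - 1.0) ** (1.0 / p.hill_h)
    conc = repeats / volume
    return f_star + conc * f_star / (p.k_rdna + f_star)


@dataclass
class CellState:
    """Instantaneous state of one (average) cell.

    volume in fL; repeats is the chromosomal rDNA copy count (real-valued in
    the ODE context, integer in the stochastic module); erc counts
    extrachromosomal rDNA circles; sir2 is Sir2 activity.
    """

    volume: float
    repeats: float
    sir2: float
    erc: float = 0.0

    def __post_init__(self):
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if not self.repeats > 0:
            raise ValueError(f"repeats must be > 0, got {self.repeats}")
        if self.sir2 < 0 or self.erc < 0:
            raise ValueError("sir2 and erc must be non-negative")

    @classmethod
    def at_steady_state(cls, p: FeedbackParams, volume: float) -> "CellState":
        ss = steady_state(p, volume)
        return cls(volume=volume, repeats=ss.repeats, sir2=ss.sir2)


@dataclass(frozen=True)
class VolumeSchedule:
    """Piecewise-constant, right-continuous cell-volume input.

    ``breakpoints`` is an ordered tuple of ``(time, volume)`` pairs; the first
    volume also applies to any earlier time.  Models instantaneous enlargement
    such as a wild-type cell becoming a large *cln3* mutant at t = 0.
    """

    breakpoints: tuple

    def __post_init__(self):
        bps = tuple((float(t), float(v)) for t, v in self.breakpoints)
        if not bps:
            raise ValueError("VolumeSchedule needs at least one breakpoint")
        times = [t for t, _ in bps]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(v <= 0 for _, v in bps):
            raise ValueError("volumes must be > 0")
        object.__setattr__(self, "breakpoints", bps)

    @classmethod
    def constant(cls, volume: float, start: float = 0.0) -> "VolumeSchedule":
        return cls(((start, volume),))

    @classmethod
    def step(cls, volume_after: float, at: float = 0.0) -> "VolumeSchedule":
        """Single step to `volume_after` at time `at` (the pre-step volume
        lives in the initial CellState)."""
        return cls(((at, volume_after),))

    def volume_at(self, t: float) -> float:
        v = self.breakpoints[0][1]
        for bt, bv in self.breakpoints:
            if t >= bt:
                v = bv
            else:
                break
        return v


class SteadyState(NamedTuple):
    repeats: float
    sir2: float
    free_uaf: float


class Transcription(NamedTuple):
    ntr_total: float
    ntr_per_genome: float
    sr: float


@dataclass
class Trajectory:
    """Time course of the feedback model on a generation grid."""

    times: np.ndarray
    volume: np.ndarray
    repeats: np.ndarray
    sir2: np.ndarray
    free_uaf: np.ndarray
    ntr_total: np.ndarray
    sr: np.ndarray

    def __post_init__(self):
        arrays = [self.times, self.volume, self.repeats, self.sir2,
                  self.free_uaf, self.ntr_total, self.sr]
        n = len(self.times)
        if any(len(a) != n for a in arrays):
            raise ValueError("Trajectory series must have equal lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for a in arrays:
            if not np.all(np.isfinite(a)) or np.any(np.asarray(a) < 0):
                raise ValueError("Trajectory series must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "volume": self.volume, "repeats": self.repeats,
            "sir2": self.sir2, "free_uaf": self.free_uaf,
            "ntr_total": self.ntr_total, "sr": self.sr,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sir2_synthesis(free_uaf, p: FeedbackParams):
    """SIR2 synthesis rate under Hill repression by free UAF.

    ``sir2_alpha / (1 + (f / k_sir2)**hill_h)``; strictly decreasing in f.
    """
    f = np.asarray(free_uaf, dtype=float)
    if np.any(f < 0):
        raise ValueError("free_uaf must be non-negative")
    out = p.sir2_alpha / (1.0 + (f / p.k_sir2) ** p.hill_h)
    return float(out) if out.ndim == 0 else out


def sir2_balance(p: FeedbackParams) -> float:
    """Sir2 activity S* at which net repeat drift vanishes."""
    return p.sir2_setpoint()


def amplification_gate(sir2, p: FeedbackParams):
    """Hill gate ``1 / (1 + (S/sir2_K)**sir2_m)`` shared by the ODE drift and
    the stochastic recombination probability."""
    s = np.asarray(sir2, dtype=float)
    out = 1.0 / (1.0 + (s / p.sir2_K) ** p.sir2_m)
    return float(out) if out.ndim == 0 else out


def repeat_drift(state: CellState, p: FeedbackParams) -> float:
    """Net chromosomal repeat drift dN/dt (repeats per generation).

    ``N * (k_amp * gate(S) - k_loss)``: positive when Sir2 is below the
    balance activity S*, zero exactly at S*.
    """
    return _drift(state.repeats, state.sir2, p)


def _drift(repeats, sir2, p: FeedbackParams):
    out = np.asarray(repeats, dtype=float) * (
        p.k_amp * amplification_gate(sir2, p) - p.k_loss)
    return float(out) if out.ndim == 0 else out


def setpoint_concentration(p: FeedbackParams) -> float:
    """Volume-independent repeat-concentration set point (repeats/fL).

    From conservation at the free-UAF set point:
    ``(U - f*) * (k_rdna + f*) / f*``.
    """
    f_star = p.free_uaf_setpoint()
    return (p.uaf_conc - f_star) * (p.k_rdna + f_star) / f_star


def steady_state(p: FeedbackParams, volume: float) -> SteadyState:
    """Homeostatic fixed point at a given volume.

    Sir2* and free-UAF* are volume-independent; repeats* scales linearly with
    volume so the repeat concentration is constant.
    """
    if not volume > 0:
        raise ValueError("volume must be > 0")
    f_star = p.free_uaf_setpoint()
    return SteadyState(repeats=setpoint_concentration(p) * volume,
                       sir2=p.sir2_setpoint(), free_uaf=f_star)


def calibrate(p: FeedbackParams | None = None,
              V_wt: float = DEFAULT_WT_VOLUME,
              N_wt: float = DEFAULT_WT_REPEATS) -> FeedbackParams:
    """Pin the steady state to ``N_wt`` repeats at volume ``V_wt``.

    Adjusts only the total UAF concentration; all other constants are kept.
    Idempotent: calibrating an already-calibrated parameter set is a no-op.
    """
    if not (V_wt > 0 and N_wt > 0):
        raise CalibrationError("V_wt and N_wt must be > 0")
    if p is None:
        p = FeedbackParams()
    return replace(p, uaf_conc=_calibrated_uaf(p, V_wt, N_wt))


def predict_transcription(state: CellState, p: FeedbackParams,
                          ploidy: int = 1) -> Transcription:
    """RNA pol I transcription predictions for a cell state.

    RNA pol I is in excess and its targets (open repeats) are limiting, so the
    total nascent transcription rate is proportional to the repeat count;
    the synthesis rate SR is the nTR divided by cell volume.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    ntr_total = p.pol1_rate * state.repeats
    return Transcription(ntr_total=ntr_total,
                         ntr_per_genome=ntr_total / ploidy,
                         sr=ntr_total / state.volume)


def _rhs(t, y, volume, p: FeedbackParams):
    n, s = y
    n = max(n, 1e-12)
    s = max(s, 0.0)
    f = solve_free_uaf(p.uaf_conc, n / volume, p.k_rdna)
    ds = sir2_synthesis(f, p) - p.sir2_delta * s
    dn = n * (p.k_amp * amplification_gate(s, p) - p.k_loss)
    return (dn, ds)


def integrate_model(initial: CellState, schedule: VolumeSchedule,
                    p: FeedbackParams, t_grid: Sequence[float],
                    ploidy: int = 1) -> Trajectory:
    """Integrate the feedback ODE over a volume schedule.

    Stiff-safe adaptive integration (LSODA, rtol 1e-6 / atol 1e-8), restarted
    at every volume breakpoint so the discontinuous input is handled exactly.
    Free UAF is evaluated from binding conservation at every step.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be an increasing 1-D grid")
    first_bp = schedule.breakpoints[0][0]
    cuts = [bt for bt, _ in schedule.breakpoints if t[0] < bt < t[-1]]
    seg_edges = [t[0], *cuts, t[-1]]

    def vol_in_segment(a):
        # before the first breakpoint the initial state's volume applies
        return initial.volume if a < first_bp else schedule.volume_at(a)

    ys = np.empty((2, len(t)))
    ys[:, 0] = (initial.repeats, initial.sir2)
    y0 = [initial.repeats, initial.sir2]
    for a, b in zip(seg_edges, seg_edges[1:]):
        vol = vol_in_segment(a)
        mask = (t > a) & (t <= b)
        # always evaluate at the segment end so the next segment restarts there
        t_eval = np.union1d(t[mask], [b])
        sol = solve_ivp(_rhs, (a, b), y0, method="LSODA", t_eval=t_eval,
                        rtol=1e-6, atol=1e-8, args=(vol, p))
        if not sol.success:
            t_fail = sol.t[-1] if len(sol.t) else a
            raise IntegrationError(
                f"integration failed at t = {t_fail:.6g} generations: "
                f"{sol.message}")
        ys[:, mask] = sol.y[:, np.isin(t_eval, t[mask])]
        y0 = list(sol.y[:, -1])

    volume = np.array([initial.volume if ti < first_bp
                       else schedule.volume_at(ti) for ti in t])
    repeats = ys[0]
    sir2 = np.maximum(ys[1], 0.0)
    free_uaf = solve_free_uaf(p.uaf_conc, repeats / volume, p.k_rdna)
    ntr_total = p.pol1_rate * repeats
    sr = ntr_total / volume
    return Trajectory(times=t, volume=volume, repeats=repeats, sir2=sir2,
                      free_uaf=np.atleast_1d(free_uaf), ntr_total=ntr_total,
                      sr=sr)
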