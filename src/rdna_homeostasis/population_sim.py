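"""Stochastic serial-passage simulator of rDNA copy-number evolution.

Emulates the ~200-generation laboratory evolution of freshly made large-cell
(*cln3*) mutants: every generation each lineage may undergo a Sir2-gated
unequal sister-chromatid recombination event (symmetric +/-Delta repeats by
default; direction emerges through selection), repeats can pop out as
extrachromosomal rDNA circles (ERCs), ERCs are diluted by imperfect
inheritance, and lineages are resampled in proportion to a Gaussian fitness
centred on the volume-set repeat-concentration demand.  Daily bottlenecks
(dilution into fresh medium) are multinomial, fitness-weighted samples.

The simulation is lineage-based: a "lineage" stands for an exponentially
growing clone, and the population cap plus bottleneck sampling preserve the
drift statistics of the 1e4 -> 1e8 cells/day regime at desk scale.
All randomness flows through an explicit numpy Generator, so a run is a pure
function of (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import SimulationError
from .feedback_model import (CellState, FeedbackParams, amplification_gate,
                             setpoint_concentration, sir2_synthesis,
                             solve_free_uaf, steady_state)

__all__ = [
    "EvolutionParams", "PassageRegime", "Population", "PassageResult",
    "division_step", "fitness", "run_passage", "colony_generations",
    "erc_fraction",
]


@dataclass(frozen=True)
class EvolutionParams:
    """Stochastic event rates and selection settings.

    p_rec_max is the per-division probability of an unequal-recombination
    event in the fully Sir2-derepressed state; the realised probability is
    ``p_rec_max / (1 + (S/sir2_K)**sir2_m)``, the same Hill gate that throttles
    net amplification in the deterministic model.  Event sizes Delta are
    geometric (mean ``1/delta_geom_p`` repeats).  ERC pop-out is a per-repeat,
    per-division excision probability, and each ERC copy is lost (not
    inherited) with probability ``erc_loss_prob`` per division, which makes
    the stationary ERC pool proportional to the chromosomal copy number and
    the ERC *percentage* copy-number invariant.  ``fitness_width`` is the SD
    (repeats/fL) of the Gaussian fitness penalty around the set-point
    concentration.
    """

    feedback: FeedbackParams = field(default_factory=FeedbackParams)
    p_rec_max: float = 0.5
    delta_geom_p: float = 0.1
    erc_popout_prob: float = 0.005
    erc_loss_prob: float = 0.1
    fitness_width: float = 0.6
    biased_events: bool = False
    lethal_floor: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("p_rec_max", "erc_popout_prob", "erc_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.delta_geom_p <= 1.0:
            raise ValueError("delta_geom_p must lie in (0, 1]")
        if not self.fitness_width > 0:
            raise ValueError("fitness_width must be > 0")


@dataclass(frozen=True)
class PassageRegime:
    """Serial-dilution design: daily regrowth and bottleneck.

    Defaults follow the published experiment: 11 generations per daily
    passage, 18 passages (198 ~ 200 generations), with a desk-scale lineage
    census (cap 1000) and a 100-lineage bottleneck standing in for the 1e4
    cells/mL inoculum.
    """

    bottleneck_cells: int = 100
    generations_per_passage: int = 11
    n_passages: int = 18
    population_cap: int = 1000

    def __post_init__(self):
        for name in ("bottleneck_cells", "generations_per_passage",
                     "n_passages", "population_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bottleneck_cells > self.population_cap:
            raise ValueError("bottleneck_cells must not exceed population_cap")

    @property
    def total_generations(self) -> int:
        return self.generations_per_passage * self.n_passages


@dataclass
class Population:
    """A collection of lineages with aligned per-lineage arrays."""

    repeats: np.ndarray   # int64, chromosomal copies
    erc: np.ndarray       # int64, ERC copies
    sir2: np.ndarray      # float64, Sir2 activity
    volume: np.ndarray    # float64, fL
    generation: int = 0

    def __post_init__(self):
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        self.erc = np.asarray(self.erc, dtype=np.int64)
        self.sir2 = np.asarray(self.sir2, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = len(self.repeats)
        if n == 0:
            raise ValueError("Population must be non-empty")
        if any(len(a) != n for a in (self.erc, self.sir2, self.volume)):
            raise ValueError("per-lineage arrays must have equal lengths")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")

    @classmethod
    def from_steady_state(cls, ep: EvolutionParams, volume: float,
                          n_lineages: int) -> "Population":
        """Clonal population at the deterministic steady state for `volume`,
        with the ERC pool at its stochastic stationary mean."""
        ss = steady_state(ep.feedback, volume)
        n0 = int(round(ss.repeats))
        erc = np.zeros(n_lineages, dtype=np.int64)
        if ep.erc_loss_prob > 0:
            # stationary mean of the pop-out/dilution balance: dilution acts
            # on freshly excised circles too, hence the (1 - loss) factor
            mean_erc = (n0 * ep.erc_popout_prob
                        * (1.0 - ep.erc_loss_prob) / ep.erc_loss_prob)
            base = int(np.floor(mean_erc))
            n_extra = int(round((mean_erc - base) * n_lineages))
            erc[:] = base
            erc[:n_extra] += 1  # population mean matches mean_erc exactly
        return cls(repeats=np.full(n_lineages, n0),
                   erc=erc,
                   sir2=np.full(n_lineages, ss.sir2, dtype=float),
                   volume=np.full(n_lineages, float(volume)))

    @property
    def size(self) -> int:
        return len(self.repeats)

    def mean_repeats(self) -> float:
        return float(self.repeats.mean())

    def median_repeats(self) -> float:
        return float(np.median(self.repeats))

    def sd_repeats(self) -> float:
        return float(self.repeats.std(ddof=1)) if self.size > 1 else 0.0

    def mean_sir2(self) -> float:
        return float(self.sir2.mean())

    def erc_percent(self) -> float:
        return erc_fraction(self)

    def copy(self) -> "Population":
        return Population(self.repeats.copy(), self.erc.copy(),
                          self.sir2.copy(), self.volume.copy(),
                          self.generation)


def erc_fraction(population: Population) -> float:
    """ERC share as a percentage of chromosomal repeat copies (pooled over
    lineages), mirroring the Southern-blot ERC/genomic band ratio."""
    total_chrom = population.repeats.sum()
    return 100.0 * population.erc.sum() / total_chrom


def fitness(state: CellState, ep: EvolutionParams) -> float:
    """Relative fitness: Gaussian in repeat concentration around the set
    point, maximal (1.0) exactly at the volume-set demand."""
    return float(_fitness(np.asarray([state.repeats], dtype=float),
                          np.asarray([state.volume], dtype=float), ep)[0])


def _fitness(repeats, volume, ep: EvolutionParams):
    c_star = setpoint_concentration(ep.feedback)
    z = (repeats / volume - c_star) / ep.fitness_width
    return np.exp(-0.5 * z * z)


def _log_fitness(repeats, volume, ep: EvolutionParams):
    c_star = setpoint_concentration(ep.feedback)
    z = (repeats / volume - c_star) / ep.fitness_width
    return -0.5 * z * z


def _step_arrays(repeats, erc, sir2, volume, ep: EvolutionParams,
                 rng: np.random.Generator):
    """One synchronous division for all lineages.  Returns updated
    (repeats, erc, sir2, alive, n_events)."""
    p = ep.feedback
    n = len(repeats)
    gate = amplification_gate(sir2, p)
    event = rng.random(n) < ep.p_rec_max * gate
    delta = rng.geometric(ep.delta_geom_p, size=n)

    if ep.biased_events:
        # Sign bias constructed so the expected per-division change equals
        # the deterministic drift N*(k_amp*gate - k_loss); used for
        # mean-field sensitivity analyses.
        drift = repeats * (p.k_amp * gate - p.k_loss)
        q = ep.p_rec_max * gate
        mean_step = q / ep.delta_geom_p
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = 0.5 * (1.0 + np.where(mean_step > 0, drift / mean_step, 0.0))
        pi = np.clip(pi, 0.0, 1.0)
        sign = np.where(rng.random(n) < pi, 1, -1)
    else:
        sign = rng.integers(0, 2, size=n) * 2 - 1

    candidate = repeats + np.where(event, sign * delta, 0)
    viable = candidate >= p.n_floor
    alive = np.ones(n, dtype=bool)
    if ep.lethal_floor:
        repeats = np.where(event, candidate, repeats)
        alive = repeats >= p.n_floor
        repeats = np.maximum(repeats, 1)  # placeholder for dead lineages
    else:
        # events that would cross the viability floor are rejected
        repeats = np.where(event & viable, candidate, repeats)
    n_events = int((event & (viable | ep.lethal_floor)).sum())

    # ERC pop-out: per-repeat excision, capped so the floor is respected
    if ep.erc_popout_prob > 0:
        popped = rng.binomial(repeats, ep.erc_popout_prob)
        popped = np.minimum(popped, np.maximum(repeats - p.n_floor, 0))
        repeats = repeats - popped
        erc = erc + popped
    # ERC dilution: each circle inherited with prob 1 - erc_loss_prob
    if ep.erc_loss_prob > 0:
        erc = rng.binomial(erc, 1.0 - ep.erc_loss_prob)

    # Sir2 relaxes toward its quasi-steady value over one generation
    f = solve_free_uaf(p.uaf_conc, repeats / volume, p.k_rdna)
    s_inf = sir2_synthesis(f, p) / p.sir2_delta
    decay = math.exp(-p.sir2_delta)
    sir2 = s_inf + (sir2 - s_inf) * decay
    return repeats, erc, sir2, alive, n_events


def division_step(state: CellState, ep: EvolutionParams,
                  rng: np.random.Generator) -> CellState:
    """One stochastic division of a single lineage (see module docstring)."""
    r, e, s, alive, _ = _step_arrays(
        np.asarray([int(round(state.repeats))], dtype=np.int64),
        np.asarray([int(round(state.erc))], dtype=np.int64),
        np.asarray([state.sir2], dtype=float),
        np.asarray([state.volume], dtype=float), ep, rng)
    if ep.lethal_floor and not alive[0]:
        raise SimulationError("lineage fell below the viability floor",
                              generation=None)
    return CellState(volume=state.volume, repeats=float(r[0]),
                     sir2=float(s[0]), erc=float(e[0]))


@dataclass
class PassageResult:
    """Per-generation summaries plus the endpoint population."""

    summaries: pd.DataFrame
    final: Population


def _summarize(pop: Population, n_events: int) -> dict:
    return {
        "generation": pop.generation,
        "n_lineages": pop.size,
        "mean_repeats": pop.mean_repeats(),
        "median_repeats": pop.median_repeats(),
        "sd_repeats": pop.sd_repeats(),
        "erc_percent": pop.erc_percent(),
        "mean_sir2": pop.mean_sir2(),
        "mean_volume": float(pop.volume.mean()),
        "rec_events": n_events,
    }


def _select(idx_weights_rng, size):
    logw, rng = idx_weights_rng
    w = np.exp(logw - logw.max())
    prob = w / w.sum()
    return rng.choice(len(prob), size=size, replace=True, p=prob)


def run_passage(initial: Population, regime: PassageRegime,
                ep: EvolutionParams,
                rng: np.random.Generator | None = None) -> PassageResult:
    """Run the serial-passage experiment.

    Alternates growth phases (synchronous divisions; offspring retained up to
    the population cap with probability proportional to fitness) with
    fitness-weighted multinomial bottlenecks.  Deterministic given
    ``ep.seed`` (or an explicit Generator).
    """
    if rng is None:
        rng = np.random.default_rng(ep.seed)
    repeats = initial.repeats.copy()
    erc = initial.erc.copy()
    sir2 = initial.sir2.copy()
    volume = initial.volume.copy()
    generation = initial.generation

    pop = Population(repeats, erc, sir2, volume, generation)
    rows = [_summarize(pop, 0)]

    for _ in range(regime.n_passages):
        for _ in range(regime.generations_per_passage):
            repeats, erc, sir2, alive, n_events = _step_arrays(
                repeats, erc, sir2, volume, ep, rng)
            if ep.lethal_floor:
                if not alive.any():
                    raise SimulationError(
                        f"population extinct at generation {generation + 1}",
                        generation=generation + 1)
                repeats, erc, sir2, volume = (a[alive] for a in
                                              (repeats, erc, sir2, volume))
            generation += 1
            # growth doubling with cap, fitness-proportional retention
            target = min(regime.population_cap, 2 * len(repeats))
            keep = _select((_log_fitness(repeats, volume, ep), rng), target)
            repeats, erc, sir2, volume = (a[keep] for a in
                                          (repeats, erc, sir2, volume))
            pop = Population(repeats, erc, sir2, volume, generation)
            rows.append(_summarize(pop, n_events))
        # daily bottleneck: fitness-weighted multinomial sample of lineages
        keep = _select((_log_fitness(repeats, volume, ep), rng),
                       min(regime.bottleneck_cells, len(repeats)))
        repeats, erc, sir2, volume = (a[keep] for a in
                                      (repeats, erc, sir2, volume))

    final = Population(repeats, erc, sir2, volume, generation)
    return PassageResult(summaries=pd.DataFrame(rows), final=final)


def colony_generations(cell_count: float) -> int:
    """Generations elapsed for a colony grown from a single cell:
    ``round(log2(cell_count))`` (a 1 mm colony of ~2e5 cells is ~18
    generations old)."""
    if cell_count < 1:
        raise ValueError(f"cell_count must be >= 1, got {cell_count}")
    return int(round(math.log2(cell_count)))
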