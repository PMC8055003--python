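"""Forward simulators and estimators for every assay used to measure the
rDNA copy-number system.

Each generator produces synthetic measurements from a ground-truth cell state
or population, with the noise model appropriate to its scale (Gaussian in Cq
space for qPCR, multiplicative lognormal for intensity-type readouts), and
each estimator inverts its noise-free generator exactly:

* qPCR of the 5.8S amplicon vs the single-copy *ACT1* control, inverted by an
  efficiency-explicit delta-delta-Cq estimator calibrated to the NOY408-1b
  strain (150 repeats).
* Filter run-on (TCA/Total incorporation): total nascent transcription with
  RNA pol II contributing a fixed 25% share at the wild-type reference and
  the pol I component proportional to repeat count.
* A135 ChIP at the 25S and 18S amplicons, ACT1-normalised: nTR per genome
  copy, proportional to repeats/ploidy.
* Southern blot of undigested DNA: genomic rDNA band, ERC multimer bands and
  ACT1 band; copy number from the 18S/ACT1 ratio against the 125-repeat
  wild-type internal standard; ERC percentage from the band ratio.
* RT-qPCR of SIR2 and UAF30 relative to ACT1.
* Western blot of the A135/A190 RNA pol I subunits per total protein
  (constant across volumes by construction: pol I concentration does not
  scale with cell size).

All generators take an explicit numpy Generator and record their noise
settings, so outputs are reproducible from (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .feedback_model import (CellState, FeedbackParams, sir2_synthesis,
                             solve_free_uaf)

__all__ = [
    "QpcrAssay", "AssayObservation", "RunOnResult", "ChipResult",
    "SouthernBlot", "ExpressionResult", "WesternResult",
    "simulate_qpcr", "estimate_copy_number", "simulate_run_on",
    "simulate_chip", "simulate_southern", "estimate_copy_number_southern",
    "estimate_erc_percent", "simulate_expression", "simulate_western",
]

#: Cq that a single template copy would give (instrument baseline), cycles.
CQ_BASELINE_RDNA = 30.0
CQ_BASELINE_ACT1 = 30.0
#: Southern internal standard: wild-type 18S/ACT1 ratio corresponds to 125
#: chromosomal repeats.
SOUTHERN_REF_COPIES = 125.0
SOUTHERN_REF_RATIO = 125.0
#: Fraction of total run-on signal from RNA pol III at the wild-type
#: reference (pol II is 25%; pol I carries the rest).
DEFAULT_POL3_FRACTION = 0.15
#: Scales raw transcription signal into a TCA/Total incorporation ratio.
INCORPORATION_SCALE = 1.0e-3
#: ERC multimer bands resolved on the gel (monomer .. tetramer).
ERC_BAND_WEIGHTS = np.array([0.5, 0.25, 0.15, 0.10])


@dataclass(frozen=True)
class QpcrAssay:
    """qPCR protocol constants for rDNA copy-number quantification."""

    efficiency_rdna: float = 2.0
    efficiency_act1: float = 2.0
    cq_noise_sd: float = 0.1
    reference_copies: float = 150.0
    reference_name: str = "NOY408-1b"

    def __post_init__(self):
        for name in ("efficiency_rdna", "efficiency_act1"):
            e = getattr(self, name)
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name} must lie in (1, 2], got {e}")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if not self.reference_copies > 0:
            raise ValueError("reference_copies must be > 0")


@dataclass
class AssayObservation:
    """One synthetic measurement: assay type, strain and replicate values."""

    strain: str
    assay: str
    values: np.ndarray
    units: str
    meta: dict = field(default_factory=dict)

    _ASSAYS = ("qpcr_rdna", "run_on", "chip_a135", "erc_southern",
               "rtqpcr_expr", "western_pol1")

    def __post_init__(self):
        if self.assay not in self._ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if len(self.values) < 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be >= 1 finite replicates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strain": self.strain, "assay": self.assay,
            "replicate": np.arange(1, len(self.values) + 1),
            "value": self.values, "units": self.units,
            "seed": self.meta.get("seed"),
        })


# ---------------------------------------------------------------------------
# qPCR copy-number assay and delta-delta-Cq estimator

def simulate_qpcr(true_repeats: float, assay: QpcrAssay, n_reps: int,
                  rng: np.random.Generator, ploidy: int = 1) -> pd.DataFrame:
    """Paired (5.8S, ACT1) quantification cycles for a genomic DNA sample.

    Cq falls by one cycle per doubling of template at perfect efficiency:
    ``Cq = C0 - log(copies) / log(efficiency)``, plus Gaussian cycle noise.
    """
    if not true_repeats > 0:
        raise ValueError("true_repeats must be > 0")
    cq_rdna = (CQ_BASELINE_RDNA
               - np.log(true_repeats) / np.log(assay.efficiency_rdna)
               + assay.cq_noise_sd * rng.standard_normal(n_reps))
    cq_act1 = (CQ_BASELINE_ACT1
               - np.log(float(ploidy)) / np.log(assay.efficiency_act1)
               + assay.cq_noise_sd * rng.standard_normal(n_reps))
    return pd.DataFrame({"cq_rdna": cq_rdna, "cq_act1": cq_act1})


def _cq_pair(cq) -> tuple[float, float]:
    """Reduce a Cq input (pair, array or replicate frame) to mean values."""
    if isinstance(cq, pd.DataFrame):
        return float(cq["cq_rdna"].mean()), float(cq["cq_act1"].mean())
    arr = np.asarray(cq, dtype=float)
    if arr.ndim == 2:
        arr = arr.mean(axis=0)
    if arr.shape != (2,):
        raise ValueError("Cq input must be a (rdna, act1) pair")
    return float(arr[0]), float(arr[1])


def estimate_copy_number(sample_cq, reference_cq, assay: QpcrAssay) -> float:
    """Efficiency-explicit delta-delta-Cq rDNA copy-number estimate.

    ``reference_copies * E_rdna**(Cq_ref_rdna - Cq_samp_rdna)
    / E_act1**(Cq_ref_act1 - Cq_samp_act1)``.  With both efficiencies equal
    to 2 this is the familiar ``reference_copies * 2**(-ddCq)``.  Replicate
    Cq values are averaged in cycle space before exponentiation, so the
    estimator is asymptotically unbiased as replicates grow.
    """
    s_rdna, s_act1 = _cq_pair(sample_cq)
    r_rdna, r_act1 = _cq_pair(reference_cq)
    for v in (s_rdna, s_act1, r_rdna, r_act1):
        if not np.isfinite(v):
            raise ValueError("Cq values must be finite")
    return (assay.reference_copies
            * assay.efficiency_rdna ** (r_rdna - s_rdna)
            / assay.efficiency_act1 ** (r_act1 - s_act1))


# ---------------------------------------------------------------------------
# Run-on (TCA/Total) and ChIP

@dataclass
class RunOnResult:
    total_counts: np.ndarray
    tca_counts: np.ndarray
    ntr: np.ndarray              # TCA/Total incorporation ratio
    ntr_per_genome: np.ndarray
    pol1_component: float        # noise-free expected signal components
    pol2_component: float
    pol3_component: float


def _lognormal_factor(noise_cv: float, rng: np.random.Generator, size) :
    """Multiplicative lognormal noise with unit mean and CV = noise_cv."""
    if noise_cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_run_on(state: CellState, p: FeedbackParams, noise_cv: float,
                    rng: np.random.Generator, n_reps: int = 3,
                    ploidy: int = 1,
                    pol3_fraction: float = DEFAULT_POL3_FRACTION,
                    total_counts: float = 1.0e6) -> RunOnResult:
    """Filter run-on: radioactive incorporation TCA/Total.

    The pol I component is proportional to the repeat count; pol II and
    pol III components are fixed at their wild-type shares (25% and 15% of
    the total at the 125-repeat reference), since their nTR does not scale
    with rDNA copies.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    pol1 = p.pol1_rate * state.repeats
    pol1_ref = p.pol1_rate * 125.0
    pol1_share = 1.0 - p.pol2_fraction - pol3_fraction
    pol2 = pol1_ref * p.pol2_fraction / pol1_share
    pol3 = pol1_ref * pol3_fraction / pol1_share
    expected = (pol1 + pol2 + pol3) * INCORPORATION_SCALE
    totals = np.full(n_reps, total_counts) * _lognormal_factor(noise_cv, rng,
                                                               n_reps)
    tca = totals * expected * _lognormal_factor(noise_cv, rng, n_reps)
    ntr = tca / totals
    return RunOnResult(total_counts=totals, tca_counts=tca, ntr=ntr,
                       ntr_per_genome=ntr / ploidy,
                       pol1_component=pol1 * INCORPORATION_SCALE,
                       pol2_component=pol2 * INCORPORATION_SCALE,
                       pol3_component=pol3 * INCORPORATION_SCALE)


@dataclass
class ChipResult:
    enrichment_25s: np.ndarray
    enrichment_18s: np.ndarray


#: ChIP scale: wild-type haploid (125 repeats) defines relative enrichment 1.
CHIP_SCALE = 1.0 / 125.0


def simulate_chip(state: CellState, p: FeedbackParams, noise_cv: float,
                  rng: np.random.Generator, n_reps: int = 3,
                  ploidy: int = 1) -> ChipResult:
    """A135 ChIP enrichment at the 25S and 18S amplicons, ACT1-normalised.

    Both amplicons sit in the same transcription unit, so their expectations
    are identical: proportional to repeats per genome copy.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    expected = CHIP_SCALE * state.repeats / ploidy
    return ChipResult(
        enrichment_25s=expected * _lognormal_factor(noise_cv, rng, n_reps),
        enrichment_18s=expected * _lognormal_factor(noise_cv, rng, n_reps))


# ---------------------------------------------------------------------------
# Southern blot: genomic band, ERC bands, ACT1 band

@dataclass
class SouthernBlot:
    genomic_band: float
    erc_bands: np.ndarray
    act1_band: float
    copy_number: float = None
    erc_percent: float = None

    def __post_init__(self):
        self.erc_bands = np.asarray(self.erc_bands, dtype=float)
        if self.copy_number is None:
            self.copy_number = estimate_copy_number_southern(self)
        if self.erc_percent is None:
            self.erc_percent = estimate_erc_percent(self)


def simulate_southern(population, noise_cv: float,
                      rng: np.random.Generator, ploidy: int = 1,
                      intensity_scale: float = 1.0) -> SouthernBlot:
    """Southern blot of undigested genomic DNA from a population.

    Genomic band intensity is proportional to the mean chromosomal repeat
    count, the ERC pool partitions over resolved multimer bands, and the ACT1
    band is proportional to genome count; the ratios invert to the derived
    copy number and ERC percentage.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    n_genomes = population.size * ploidy
    per_genome_repeats = population.repeats.sum() / n_genomes
    per_genome_erc = population.erc.sum() / n_genomes
    s = intensity_scale
    genomic = s * per_genome_repeats * float(_lognormal_factor(noise_cv, rng, ()))
    erc_bands = (s * per_genome_erc * ERC_BAND_WEIGHTS
                 * _lognormal_factor(noise_cv, rng, len(ERC_BAND_WEIGHTS)))
    act1 = s * 1.0 * float(_lognormal_factor(noise_cv, rng, ()))
    return SouthernBlot(genomic_band=genomic, erc_bands=erc_bands,
                        act1_band=act1)


def estimate_copy_number_southern(blot: SouthernBlot) -> float:
    """Copy number from the 18S/ACT1 band ratio, scaled to the 125-repeat
    wild-type internal standard."""
    ratio = blot.genomic_band / blot.act1_band
    return SOUTHERN_REF_COPIES * ratio / SOUTHERN_REF_RATIO


def estimate_erc_percent(blot: SouthernBlot) -> float:
    """Percentage of ERCs: sum of ERC bands over the genomic band (invariant
    to any global intensity rescaling)."""
    return 100.0 * float(np.sum(blot.erc_bands)) / blot.genomic_band


# ---------------------------------------------------------------------------
# RT-qPCR expression and Western blot

@dataclass
class ExpressionResult:
    sir2_rel: np.ndarray
    uaf30_rel: np.ndarray


def simulate_expression(state: CellState, p: FeedbackParams, noise_cv: float,
                        rng: np.random.Generator,
                        n_reps: int = 3) -> ExpressionResult:
    """SIR2/ACT1 and UAF30/ACT1 mRNA levels relative to the wild type.

    UAF30 is volume-invariant (constant concentration); SIR2 follows the
    Hill repression by free UAF, normalised to the steady-state baseline, so
    a freshly enlarged cell reads low and a fully re-adapted one reads 1.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    f = solve_free_uaf(p.uaf_conc, state.repeats / state.volume, p.k_rdna)
    f_ref = p.free_uaf_setpoint()
    sir2_expected = sir2_synthesis(f, p) / sir2_synthesis(f_ref, p)
    return ExpressionResult(
        sir2_rel=sir2_expected * _lognormal_factor(noise_cv, rng, n_reps),
        uaf30_rel=1.0 * _lognormal_factor(noise_cv, rng, n_reps))


@dataclass
class WesternResult:
    a135_rel: np.ndarray
    a190_rel: np.ndarray


def simulate_western(volume: float, noise_cv: float,
                     rng: np.random.Generator, n_reps: int = 3) -> WesternResult:
    """RNA pol I subunit abundance per total protein, relative to wild type.

    Constant across cell volumes by construction: RNA pol I concentration
    does not change with cell size.
    """
    if not volume > 0:
        raise ValueError("volume must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    return WesternResult(
        a135_rel=1.0 * _lognormal_factor(noise_cv, rng, n_reps),
        a190_rel=1.0 * _lognormal_factor(noise_cv, rng, n_reps))
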