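# Methods

## The feedback model

State variables are the chromosomal rDNA repeat count `N` (real-valued in
the ODE, integer in the stochastic simulator), Sir2 activity `S` (arbitrary
units; mRNA, protein and deacetylase activity are deliberately collapsed
into one pool), and the exogenous cell volume `V` in fL, supplied as a
piecewise-constant schedule.  The free-UAF concentration `f` is slaved to
`(N, V)` by one-site binding conservation,

    f + (N/V) · f / (k_rdna + f) = U,

solved in closed form as the positive root of the quadratic (a bisection
oracle backs this in the tests).  Binding is treated at quasi-steady state:
high-affinity promoter binding equilibrates well within one cell cycle,
much faster than Sir2 turnover or copy-number change.

    dS/dt = sir2_alpha / (1 + (f/k_sir2)^hill_h) − sir2_delta · S
    dN/dt = N · ( k_amp / (1 + (S/sir2_K)^sir2_m) − k_loss )

The structure makes the circuit an integral controller: at steady state
`dN/dt = 0` fixes `S* = sir2_K·(k_amp/k_loss − 1)^(1/sir2_m)`, `dS/dt = 0`
then fixes `f*`, and conservation turns `f*` into a volume-independent
repeat-concentration set point `(U − f*)(k_rdna + f*)/f*`.  Any volume
change is perfectly adapted: `N*` scales linearly with `V`, while `S`, `f`,
and the synthesis rate `SR = nTR/V` return exactly to their set points.
The functional forms (Hill repression, Hill-gated net amplification) are a
reconstruction; the integral-control behaviour, not the particular forms,
is the contract the tests pin down.

### Parameters, units, defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `uaf_conc` | total UAF, molecules/fL | calibrated (≈2.985) | set so `N* = 125` at `V = 42 fL` |
| `k_rdna` | UAF–rDNA dissociation, molecules/fL | 1e-5 | ≪ `k_sir2`: rDNA sites effectively stoichiometric |
| `k_sir2` | UAF–SIR2-promoter dissociation | 1e-2 | 1000-fold weaker site |
| `hill_h`, `sir2_m` | Hill coefficients | 2 | mild cooperativity |
| `sir2_alpha`, `sir2_delta` | SIR2 synthesis / decay, per generation | 2.0, 0.5 | Sir2 relaxes in ~2 generations |
| `k_amp`, `k_loss` | max amplification / loss rate, per generation | 0.08, 0.02 | copy-number relaxation over tens of generations, matching the ~200-generation experiment |
| `pol1_rate` | nTR per repeat | 1.0 | arbitrary transcription unit |
| `pol2_fraction` | pol II share of total run-on signal | 0.25 | measured share at the wild type |
| `n_floor` | minimal viable repeat count | 20 | only binds in the stochastic module |

The wild-type calibration volume (42 fL) is a standard haploid figure and
half the measured 83 fL of the large *cln3* mutant, so the "cell becomes a
mutant" scenario is exactly a two-fold step.  `calibrate()` adjusts only
`uaf_conc` and is idempotent and invariant to rescaling the time unit.

Integration uses LSODA (stiff-safe; the titration switch makes the gate
nearly discontinuous in `N` near the set point) with rtol 1e-6 / atol 1e-8,
restarted at every volume breakpoint.  The inference module carries a
scalar-math twin of the right-hand side on the FORTRAN `odeint` wrapper,
because the optimiser and bootstrap call it thousands of times; both
integrators agree within the solver tolerances.

## Stochastic serial passage

Lineages — not cells — are simulated: a lineage stands for an exponentially
growing clone, and 1000 lineages with 100-lineage daily bottlenecks
preserve the drift statistics of the 10^4→10^8 cells/day dilution regime at
desk scale.  Each generation, every lineage:

1. undergoes an unequal-recombination event with probability
   `p_rec_max / (1 + (S/sir2_K)^sir2_m)` — the same Hill gate as the ODE —
   of size Δ ~ Geometric(`delta_geom_p`, mean 10 repeats) and symmetric
   sign; directionality emerges through selection.  Events that would cross
   `n_floor` are rejected (a `lethal_floor` switch turns them fatal);
2. excises repeats into the ERC pool with per-repeat probability
   `erc_popout_prob` (0.005) and loses each ERC copy with probability
   `erc_loss_prob` (0.1) per division.  The per-repeat formulation makes
   the stationary ERC pool proportional to `N`, so the ERC *percentage*
   (~4.5%) is copy-number invariant — the observed dissociation between
   constant ERC share and chromosomal amplification;
3. relaxes Sir2 one generation toward its quasi-steady value (exact
   exponential update);
4. is resampled in proportion to a Gaussian fitness in repeat
   concentration, `exp(−(N/V − c*)²/(2·fitness_width²))` with
   `fitness_width = 0.6 repeats/fL`, centred on the volume-set demand.

Bottlenecks are fitness-weighted multinomial samples of 100 lineages every
11 generations, 18 passages ≈ 200 generations.  All randomness flows
through one explicit numpy Generator, so runs are bit-reproducible from
(inputs, seed).

A `biased_events` switch replaces the symmetric sign with a bias chosen so
the expected per-division change equals the ODE drift exactly; it exists
for mean-field analysis and sensitivity checks, not as the default biology.

### What the simulator does and does not emulate

It reproduces the wild-type 100–200 stability band, the ~250-repeat
endpoint after a volume doubling with wide clone-to-clone spread, the flat
ERC share, and colony-age arithmetic (`round(log2(2e5)) = 18`).  It does
not model mother/daughter ERC retention asymmetry, post-diauxic phases
(treated as growth-equivalent, since most divisions happen in exponential
phase), replication-fork mechanics, or re-integration of circles into the
array.  Passing tests therefore speak to the feedback-plus-selection logic,
not to those mechanisms.

Two discretisation facts matter when comparing the ensemble to the ODE:
the division kernel reads Sir2 from the previous generation, so the
discrete process lags the ODE by about one update (the mean-field test
allows half a repeat for this); and fitness-proportional resampling
collapses genealogy, so the cross-lineage SD underestimates the ensemble
mean's uncertainty — mean-field comparisons are therefore run on
independent lineages stepped with the division kernel directly.  After a
volume step the ERC pool (10-generation turnover) transiently dips while
`N` climbs, producing a small, real, transient trend in the share; the
stationarity checks exclude the first four turnover times.

## Synthetic assays

Noise models: Gaussian in Cq space for qPCR (cycle noise is additive on
that scale); unit-mean multiplicative lognormal for intensity-type readouts
(run-on counts, ChIP enrichment, blot bands), so replicate averages
converge to the noise-free expectation.  Every estimator inverts its
noise-free generator exactly; the ΔΔCq estimator averages replicate Cq in
cycle space before exponentiating, which removes the exponentiation bias
as replicates grow.

Calibration chains are kept distinct, as in the laboratory protocols: qPCR
copy numbers are anchored to the 150-repeat NOY408-1b strain; Southern
copy numbers to the 125-repeat wild-type internal standard.  Run-on signal
composition fixes pol II at 25% and pol III at 15% of the wild-type total
(pol III is an assumption; only the pol II share is measured), with the pol
I component proportional to `N`.  ChIP expectations are identical for the
25S and 18S amplicons (one transcription unit).  *UAF30* expression is
volume-invariant by construction; *SIR2* expression follows the Hill
repression by free UAF normalised to baseline, so a freshly enlarged cell
reads low and a re-adapted one reads 1.  The pol I Western observable is
constant across volumes by construction (concentration does not scale with
size).

## Inference

The deterministic ODE serves as surrogate for the stochastic mean; the
fitted experiment starts at the steady state of the *candidate* parameters
at the pre-step volume, then steps the volume.  Estimation is bounded
nonlinear least squares in log10 parameter space (trf), residuals on the
repeat scale by default with a log-scale option for multiplicative noise.
The finite-difference step is set to 1e-3 in log10 units, well above the
integrator's noise floor — with the default machine-epsilon step the
Jacobian degenerates to solver noise and the optimiser stalls far from the
minimum.  Confidence intervals come from residual-resampling bootstrap
(200 replicates by default), resampling on the same scale the fit used and
refitting warm-started from the point estimate.

At most three parameters may be freed per fit: `k_amp`/`k_loss` jointly set
both the timescale and the balance point, and adding `sir2_K` and
`uaf_conc` on a single trajectory is confounded.  `fitness_width` exists
only in the stochastic selection model and is refused with an
identifiability error.  The loss trace logged in `FitResult` is the
best-so-far squared error per function evaluation, non-increasing by
construction.

## Cohort analysis

Class bins follow the printed legend literally: 80–200 (normal), 299–400
(high), >450 strictly (very high); strains in the 201–298 and 401–450 gaps
are reported `unclassified` rather than bridged.  Group comparisons use
Welch (unequal-variance) t-tests; the degenerate all-identical case is
reported as t = 0, p = 1 rather than 0/0.  The growth filter removes
records with relative growth below 1/fold.  The synthetic cohort generator
places its slow growers exactly at the mean volume of their class's
fast growers, so filtering provably cannot move class means — the control
for growth-rate confounding.

## Problem sizes

Defaults throughout are the study conditions: 1000-lineage populations,
100-lineage bottlenecks, 11 generations × 18 passages, 4 replicate
populations for evolution endpoints.  The parameter-recovery study runs 50
simulation rounds of 4 replicate series (19 time points, 5% lognormal
noise) with 60 bootstrap refits per round.  The full test suite completes
in about four minutes on one CPU; the acceptance script in under a minute.

## Known limitations

The S1-appendix-level equations behind the published simulation are not
reproduced verbatim; this package's formulation is a reconstruction that
matches the described behaviour (sudden Sir2 drop, recovery in parallel
with amplification, volume-proportional set point).  Sir2 is a single
well-mixed pool — nucleolar/telomeric partitioning and its silencing side
effects are out of scope.  Volume is exogenous and piecewise constant;
cell-cycle-resolved growth is not modelled.  The fitness function is a
stated assumption (Gaussian in repeat concentration), not a measured
quantity; only its mode and the direction of selection are constrained by
the data the simulator reproduces.
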