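"""Stochastic serial-passage simulator tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from dataclasses import replace

from rdna_homeostasis import feedback_model as fm
from rdna_homeostasis import population_sim as ps
from rdna_homeostasis.exceptions import SimulationError

from conftest import WT_REPEATS, WT_VOLUME


def wt_population(ep, n=1000, volume=WT_VOLUME):
    return ps.Population.from_steady_state(ep, volume, n)


class TestDivisionStep:
    def test_no_events_leaves_repeats_unchanged(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params, p_rec_max=0.0,
                                erc_popout_prob=0.0)
        state = fm.CellState(volume=WT_VOLUME, repeats=125.0, sir2=1.7)
        for seed in range(5):
            out = ps.division_step(state, ep, np.random.default_rng(seed))
            assert out.repeats == 125.0

    def test_high_sir2_suppresses_events(self, wt_params, rng):
        ep = ps.EvolutionParams(feedback=wt_params, erc_popout_prob=0.0)
        state = fm.CellState(volume=WT_VOLUME, repeats=125.0, sir2=1e6)
        changed = sum(
            ps.division_step(state, ep, np.random.default_rng(s)).repeats
            != 125.0 for s in range(200))
        assert changed == 0

    def test_event_frequency_matches_hill_gate(self, wt_params, rng):
        # 1e5 lineages at a fixed Sir2; empirical event rate vs the gate
        ep = ps.EvolutionParams(feedback=wt_params, erc_popout_prob=0.0,
                                erc_loss_prob=0.0)
        n = 100_000
        sir2 = np.full(n, 1.0)
        repeats = np.full(n, 1000, dtype=np.int64)  # floor never binds
        _, _, _, _, n_events = ps._step_arrays(
            repeats, np.zeros(n, dtype=np.int64), sir2,
            np.full(n, WT_VOLUME), ep, rng)
        p_expected = ep.p_rec_max / (
            1 + (1.0 / wt_params.sir2_K) ** wt_params.sir2_m)
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(n_events / n - p_expected) < 3 * se

    def test_floor_events_rejected(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params, p_rec_max=1.0,
                                delta_geom_p=1.0, erc_popout_prob=0.0)
        state = fm.CellState(volume=WT_VOLUME,
                             repeats=float(wt_params.n_floor), sir2=0.0)
        for seed in range(20):
            out = ps.division_step(state, ep, np.random.default_rng(seed))
            assert out.repeats >= wt_params.n_floor


class TestFitness:
    def test_maximal_at_setpoint(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params)
        c_star = fm.setpoint_concentration(wt_params)
        state = fm.CellState(volume=WT_VOLUME, repeats=c_star * WT_VOLUME,
                             sir2=1.0)
        assert ps.fitness(state, ep) == pytest.approx(1.0)

    def test_symmetric_around_setpoint(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params)
        c_star = fm.setpoint_concentration(wt_params)
        d = 0.4
        lo = fm.CellState(volume=WT_VOLUME,
                          repeats=(c_star - d) * WT_VOLUME, sir2=1.0)
        hi = fm.CellState(volume=WT_VOLUME,
                          repeats=(c_star + d) * WT_VOLUME, sir2=1.0)
        assert ps.fitness(lo, ep) == pytest.approx(ps.fitness(hi, ep))

    def test_doubled_volume_favours_doubled_repeats(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params)
        big_adapted = fm.CellState(volume=2 * WT_VOLUME, repeats=250.0, sir2=1.0)
        big_lagging = fm.CellState(volume=2 * WT_VOLUME, repeats=125.0, sir2=1.0)
        assert ps.fitness(big_adapted, ep) > ps.fitness(big_lagging, ep)


class TestRunPassage:
    def test_wild_type_median_stays_in_range(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params, seed=11)
        regime = ps.PassageRegime()
        res = ps.run_passage(wt_population(ep), regime, ep)
        med = res.summaries["median_repeats"]
        assert med.min() >= 100 and med.max() <= 200

    def test_identical_seed_bit_identical(self, wt_params):
        ep = ps.EvolutionParams(feedback=wt_params, seed=42)
        regime = ps.PassageRegime(n_passages=3)
        a = ps.run_passage(wt_population(ep, 200), regime, ep).summaries
        b = ps.run_passage(wt_population(ep, 200), regime, ep).summaries
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_endpoint_variability(self, wt_params):
        finals = []
        for seed in range(4):
            ep = ps.EvolutionParams(feedback=wt_params, seed=seed)
            pop = wt_population(ep, 300)
            res = ps.run_passage(pop, ps.PassageRegime(n_passages=6,
                                                       population_cap=300,
                                                       bottleneck_cells=50), ep)
            finals.append(res.final.mean_repeats())
        assert np.std(finals) > 0

    def test_extinction_raises_with_generation(self, wt_params):
        # two lineages one repeat above a lethal floor, guaranteed events:
        # each division kills with probability 1/2, so a two-lineage census
        # goes extinct within a few generations
        p = replace(wt_params, n_floor=124)
        ep = ps.EvolutionParams(feedback=p, p_rec_max=1.0, delta_geom_p=1.0,
                                lethal_floor=True, seed=1)
        pop = ps.Population(repeats=np.full(2, 125), erc=np.zeros(2),
                            sir2=np.zeros(2), volume=np.full(2, WT_VOLUME))
        with pytest.raises(SimulationError) as err:
            ps.run_passage(pop, ps.PassageRegime(population_cap=2,
                                                 bottleneck_cells=1), ep)
        assert err.value.generation is not None

    def test_raising_sir2_lowers_event_counts(self, wt_params):
        # doubling SIR2 synthesis raises baseline Sir2, tightening the gate
        strong = fm.calibrate(replace(wt_params, uaf_conc=None,
                                      sir2_alpha=2 * wt_params.sir2_alpha))
        counts = {}
        for tag, p in (("base", wt_params), ("strong", strong)):
            ep = ps.EvolutionParams(feedback=p, seed=5)
            res = ps.run_passage(
                ps.Population.from_steady_state(ep, WT_VOLUME, 500),
                ps.PassageRegime(n_passages=6, population_cap=500), ep)
            counts[tag] = res.summaries["rec_events"].sum()
        assert counts["strong"] < counts["base"]


class TestMeanField:
    def test_biased_ensemble_tracks_ode(self, wt_params):
        """With drift-matched (biased) events and no selection, the mean of
        independent lineages follows the deterministic trajectory.

        Design notes: lineages are stepped independently (no resampling, so
        cross-lineage SE is a valid uncertainty for the ensemble mean); slow
        copy-number kinetics and a soft titration switch keep the drift
        nearly linear over the population spread; Sir2 turnover is fast so
        it is quasi-static in both descriptions.  The discrete process reads
        Sir2 from the previous generation, so a half-repeat discretisation
        allowance is added to the 3-SE band.
        """
        p = fm.calibrate(replace(wt_params, uaf_conc=None, k_amp=0.008,
                                 k_loss=0.002, k_sir2=2.0, k_rdna=2e-4,
                                 sir2_alpha=16.0, sir2_delta=4.0))
        ep = ps.EvolutionParams(feedback=p, biased_events=True,
                                delta_geom_p=0.25, erc_popout_prob=0.0,
                                erc_loss_prob=0.0, fitness_width=1e6, seed=9)
        n = 500
        rng = np.random.default_rng(9)
        pop = ps.Population.from_steady_state(ep, WT_VOLUME, n)
        repeats, erc, sir2 = pop.repeats, pop.erc, pop.sir2
        volume = np.full(n, 2 * WT_VOLUME)
        means, sds = [repeats.mean()], [0.0]
        for _ in range(200):
            repeats, erc, sir2, _, _ = ps._step_arrays(
                repeats, erc, sir2, volume, ep, rng)
            means.append(repeats.mean())
            sds.append(repeats.std(ddof=1))
        means, sds = np.asarray(means), np.asarray(sds)

        init = fm.CellState(volume=WT_VOLUME, repeats=float(pop.repeats[0]),
                            sir2=float(pop.sir2[0]))
        traj = fm.integrate_model(init, fm.VolumeSchedule.step(2 * WT_VOLUME),
                                  p, np.arange(201, dtype=float))
        se = sds / np.sqrt(n)
        gap = np.abs(means - traj.repeats)
        assert traj.repeats[-1] > 1.4 * traj.repeats[0]  # nontrivial transient
        assert np.all(gap[1:] <= 3 * se[1:] + 0.5)


class TestErcDynamics:
    def test_erc_share_stationary_while_repeats_amplify(self, wt_params):
        """ERC percentage has no trend while chromosomal repeats amplify.

        Copy-number kinetics are slowed so amplification spans the whole
        experiment while the ERC pool (turnover 1/erc_loss_prob = 10
        generations) tracks quasi-statically; pop-out/loss stay at their
        balanced defaults.  The summary series is autocorrelated, so the
        slope CI uses Newey-West errors.
        """
        ep = ps.EvolutionParams(feedback=wt_params, fitness_width=1.5,
                                seed=7)
        pop = ps.Population.from_steady_state(ep, WT_VOLUME, 1000)
        pop.volume[:] = 2 * WT_VOLUME
        res = ps.run_passage(pop, ps.PassageRegime(), ep)
        s = res.summaries
        # chromosomal repeats nearly double over the experiment ...
        assert s["mean_repeats"].iloc[-1] > 1.6 * s["mean_repeats"].iloc[0]
        # ... and the ERC share ends where it started
        assert abs(s["erc_percent"].iloc[-1]
                   - s["erc_percent"].iloc[0]) < 1.0
        # ... with no significant trend once the pool has turned over after
        # the volume step (four turnover times of 1/erc_loss_prob = 10
        # generations), repeats still amplifying inside the window
        w = s[s["generation"] >= 40]
        assert w["mean_repeats"].iloc[-1] > 1.05 * w["mean_repeats"].iloc[0]
        x = sm.add_constant(w["generation"].to_numpy(dtype=float))
        ols = sm.OLS(w["erc_percent"].to_numpy(), x).fit(
            cov_type="HAC", cov_kwds={"maxlags": 20})
        lo, hi = ols.conf_int()[1]
        assert lo <= 0.0 <= hi

    def test_erc_share_constant_between_early_and_late(self, wt_params):
        early, late = [], []
        for seed in range(4):
            ep = ps.EvolutionParams(feedback=wt_params, seed=seed + 100)
            pop = wt_population(ep, 500)
            pop.volume[:] = 2 * WT_VOLUME
            s = ps.run_passage(pop, ps.PassageRegime(population_cap=500),
                               ep).summaries
            early.append(s.loc[s.generation == 22, "erc_percent"].iloc[0])
            late.append(s["erc_percent"].iloc[-1])
        diff = np.mean(late) - np.mean(early)
        se = np.sqrt(np.var(late, ddof=1) / 4 + np.var(early, ddof=1) / 4)
        assert abs(diff) < 3 * se


class TestSmallOps:
    @pytest.mark.parametrize("cells,expected", [
        (2e5, 18),   # a 1 mm colony
        (1, 0),
        (1024, 10),
    ])
    def test_colony_generations(self, cells, expected):
        assert ps.colony_generations(cells) == expected

    def test_colony_generations_domain(self):
        with pytest.raises(ValueError):
            ps.colony_generations(0)

    def test_erc_fraction_limits(self, wt_params):
        pop = ps.Population(repeats=np.full(3, 100), erc=np.zeros(3),
                            sir2=np.ones(3), volume=np.full(3, 42.0))
        assert ps.erc_fraction(pop) == 0.0
        pop.erc[:] = 100
        assert ps.erc_fraction(pop) == 100.0

    def test_regime_validation(self):
        with pytest.raises(ValueError):
            ps.PassageRegime(bottleneck_cells=2000, population_cap=1000)
        with pytest.raises(ValueError):
            ps.EvolutionParams(p_rec_max=1.5)
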