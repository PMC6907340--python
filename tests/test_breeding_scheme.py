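"""Population dynamics: cohort bookkeeping, mating regimes, selection."""

import math

import numpy as np
import pytest

from apiselect.breeding_scheme import (
    PopulationState,
    SchemeConfig,
    Simulation,
    round_half_up,
)
from apiselect.genetics import VarianceComponents
from apiselect.pedigree import OBS_QUEEN


def make_sim(seed=1, **kwargs):
    kwargs.setdefault("vc", VarianceComponents())
    return Simulation(SchemeConfig(**kwargs), seed)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N_p=math.inf, q=0.5),
            dict(N_p=0, q=0.25),
            dict(q=1.5, N_p=100),
            dict(N_s=-1),
            dict(N_b=0),
            dict(model="genomic"),
        ],
    )
    def test_invalid_configs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SchemeConfig(vc=VarianceComponents(), **kwargs)

    @pytest.mark.parametrize("x, expected", [(0.5, 1), (1.49, 1), (1.5, 2), (2.5, 3)])
    def test_counts_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestInitialization:
    def test_two_base_cohorts_of_constant_size_near_zero_mean(self):
        sim = make_sim(seed=3, N_b=500, N_p=200, N_s=5, years=20, q=0.0)
        state = sim.initialize_population()
        for year in (1, 2):
            bq = state.cohort(year, "BQ")
            assert bq.n == 500
            tot = bq.tbv.sum(axis=1)
            assert abs(tot.mean()) < 3 * tot.std() / np.sqrt(bq.n)
            assert np.all(bq.F == 0)
            assert state.cohort(year, "PQ").n == 200

    def test_infinite_passive_population_is_not_instantiated(self):
        sim = make_sim(seed=3, N_b=100, N_p=math.inf, N_s=0, years=5)
        state = sim.initialize_population()
        assert (1, "PQ") not in state.cohorts and (2, "PQ") not in state.cohorts

    def test_same_seed_gives_identical_state(self):
        a = make_sim(seed=11, N_b=80, N_p=40, N_s=2, years=6).initialize_population()
        b = make_sim(seed=11, N_b=80, N_p=40, N_s=2, years=6).initialize_population()
        assert np.array_equal(a.cohort(1, "BQ").tbv, b.cohort(1, "BQ").tbv)
        assert np.array_equal(a.cohort(2, "PQ").mate_tbv, b.cohort(2, "PQ").mate_tbv)


class TestSelection:
    def test_twenty_percent_of_1000_gives_200_dams_and_1000_daughters(self):
        sim = make_sim(seed=5, N_b=1000, N_s=5, years=20, selection="random")
        sim.initialize_population()
        cohort = sim.state.cohort(2, "BQ")
        cohort.crit = np.zeros(cohort.n)
        sim.config.__dict__  # frozen; selection uses config.n_dams
        object.__setattr__(sim.config, "selection", "blup")
        dams, dam_rows = sim.select_dams(cohort)
        assert len(dams) == 200
        assert len(dam_rows) == 1000
        counts = np.bincount(dam_rows, minlength=cohort.n)
        assert set(counts[counts > 0]) == {5}

    def test_equal_criteria_select_lowest_ids(self):
        sim = make_sim(seed=5, N_b=50, N_s=0, years=20)
        sim.initialize_population()
        cohort = sim.state.cohort(2, "BQ")
        cohort.crit = np.zeros(cohort.n)
        dams, _ = sim.select_dams(cohort)
        assert np.array_equal(np.sort(cohort.full_ids[dams]), np.sort(cohort.full_ids)[:10])

    def test_selection_matches_brute_force_top_k(self):
        sim = make_sim(seed=5, N_b=200, N_s=0, years=20)
        sim.initialize_population()
        cohort = sim.state.cohort(2, "BQ")
        rng = np.random.default_rng(0)
        cohort.crit = rng.standard_normal(cohort.n)
        dams, _ = sim.select_dams(cohort)
        expected = np.argsort(-cohort.crit)[:40]
        assert set(dams.tolist()) == set(expected.tolist())


class TestMatingRegimes:
    def test_stations_carry_eight_sister_dpqs(self):
        sim = make_sim(seed=9, N_b=100, N_s=3, years=8, selection="random")
        sim.run()
        year = sim.state.year
        stations = sim.setup_mating_stations(year + 1)
        assert len(stations) == 3
        full = sim.state.full
        for st in stations:
            dpq = st.dpq_cohort
            assert dpq.n == 8
            assert np.all(dpq.dam_full == st.source_queen_full)
            # sisters: half sibs at least, kinship >= 1/8 (shared dam)
            k = full.graph.a_submatrix(dpq.full_ids[:3]) / 2.0
            assert k[0, 1] >= 0.125 - 1e-9

    def test_controlled_mating_samples_dpqs_uniformly_within_one_station(self):
        sim = make_sim(seed=9, N_b=600, N_s=2, years=5, selection="random")
        sim.run()
        cohort = sim.state.cohort(sim.state.year, "BQ")
        station_ids = np.unique(cohort.station_of)
        assert set(station_ids) <= set(st for st in cohort.station_of)
        # every queen's 12 drone dams belong to the DPQ set of her station
        by_station = {}
        for key, c in sim.state.cohorts.items():
            if isinstance(key[1], str) and key[1].startswith("DPQ") and key[0] == sim.state.year:
                sid = int(key[1][3:])
                by_station[sid] = set(c.full_ids.tolist())
        counts = {sid: np.zeros(8) for sid in by_station}
        for i in range(cohort.n):
            sid = int(cohort.station_of[i])
            dpqs = by_station[sid]
            assert set(cohort.mate_dronedam[i].tolist()) <= dpqs
            ordered = sorted(dpqs)
            for d in cohort.mate_dronedam[i]:
                counts[sid][ordered.index(d)] += 1
        # multinomial check: each DPQ drawn with frequency 1/8 within 3 SE
        for sid, c in counts.items():
            n = c.sum()
            se = np.sqrt((1 / 8) * (7 / 8) / n)
            assert np.all(np.abs(c / n - 1 / 8) < 4 * se)  # 8 cells jointly

    def test_uncontrolled_drone_dams_mix_populations_at_rate_p(self):
        sim = make_sim(seed=13, N_b=400, N_p=400, N_s=0, years=5, q=0.0, selection="random")
        sim.run()
        state = sim.state
        cohort = state.cohort(state.year, "BQ")
        bq_ids = set()
        for age in (1, 2, 3):
            bq_ids |= set(state.cohort(state.year - age, "BQ").full_ids.tolist())
        frac = np.isin(cohort.mate_dronedam, list(bq_ids)).mean()
        n = cohort.mate_dronedam.size
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)
        # age structure: all drone dams are 1-3 years old
        pools = set()
        for kind in ("BQ", "PQ"):
            for age in (1, 2, 3):
                pools |= set(state.cohort(state.year - age, kind).full_ids.tolist())
        assert set(cohort.mate_dronedam.ravel().tolist()) <= pools

    def test_no_passive_population_means_all_bq_drone_dams(self):
        sim = make_sim(seed=13, N_b=150, N_p=0, N_s=0, years=4, selection="random")
        sim.run()
        state = sim.state
        cohort = state.cohort(state.year, "BQ")
        bq_ids = set()
        for age in (1, 2, 3):
            c = state.cohorts.get((state.year - age, "BQ"))
            if c is not None:
                bq_ids |= set(c.full_ids.tolist())
        assert set(cohort.mate_dronedam.ravel().tolist()) <= bq_ids

    def test_infinite_passive_drones_have_base_variance(self, vc):
        sim = make_sim(seed=17, N_b=800, N_p=math.inf, N_s=0, years=3, selection="random")
        sim.run()
        cohort = sim.state.cohort(3, "BQ")
        assert np.all(cohort.mate_dronedam == -1)  # no pedigree links
        tot = cohort.mate_tbv.sum(axis=2).ravel()
        var = tot.var()
        expect = (2 * vc.sigma_A).sum()  # Var(m + d) under 2 Sigma_A
        se = expect * np.sqrt(2.0 / tot.size)
        assert abs(var - expect) < 3 * se

    def test_uncontrolled_observed_pedigree_has_all_sires_unknown(self):
        sim = make_sim(seed=19, N_b=100, N_p=0, N_s=0, years=6)
        sim.run()
        obs = sim.state.obs
        for i in range(obs.n):
            if obs.kind[i] == OBS_QUEEN:
                assert obs.sire_ref[i] == -1


class TestOffspringAndPassive:
    def test_zero_variance_offspring_are_exact_midparents(self):
        vc0 = VarianceComponents(0.0, 0.0, 0.0, 0.0)
        sim = make_sim(seed=2, N_b=30, N_s=0, years=4, vc=vc0, selection="random")
        sim.initialize_population()
        dam_cohort = sim.state.cohort(1, "BQ")
        dam_cohort.tbv[:] = 1.0
        dam_cohort.mate_tbv[:] = 1.0
        out = sim.produce_offspring_queens(dam_cohort, np.arange(5), "BQ", 3, observed=False)
        assert np.allclose(out.tbv, 1.0)

    def test_base_cross_offspring_are_not_inbred(self):
        sim = make_sim(seed=2, N_b=50, N_s=0, years=4, selection="random")
        sim.initialize_population()
        out = sim.produce_offspring_queens(
            sim.state.cohort(1, "BQ"), np.arange(10), "BQ", 3, observed=False
        )
        assert np.all(out.F == 0)

    @pytest.mark.parametrize("q, n_p, expected_bq_dams", [(0.0, 200, 0), (1.0, 200, 200), (0.5, 201, 101)])
    def test_passive_dam_source_counts_follow_q(self, q, n_p, expected_bq_dams):
        sim = make_sim(seed=23, N_b=100, N_p=n_p, N_s=0, years=3, q=q, selection="random")
        sim.run()
        state = sim.state
        pq = state.cohort(3, "PQ")
        assert pq.n == n_p
        bq_ids = set()
        for age in (1, 2, 3):
            c = state.cohorts.get((3 - age, "BQ"))
            if c is not None:
                bq_ids |= set(c.full_ids.tolist())
        n_from_bq = int(np.isin(pq.dam_full, list(bq_ids)).sum())
        assert n_from_bq == expected_bq_dams

    def test_passive_queens_are_invisible_to_blup(self):
        sim = make_sim(seed=23, N_b=60, N_p=60, N_s=0, years=6, q=0.5)
        sim.run()
        # observed pedigree holds BQ-side entities only: every queen node is
        # either a base BQ or has a BQ dam
        obs = sim.state.obs
        n_obs_queens = sum(1 for k in obs.kind if k in (0, 1))
        n_bq = 6 * 60
        assert n_obs_queens == n_bq


class TestYearlyCycle:
    def test_cohort_sizes_are_conserved_every_year(self):
        sim = make_sim(seed=29, N_b=120, N_p=80, N_s=2, years=9, q=0.25)
        state = sim.run()
        for year in range(1, 10):
            assert state.cohort(year, "BQ").n == 120
            assert state.cohort(year, "PQ").n == 80
            assert state.cohort(year, "BQ").phenotype is not None
            assert state.cohort(year, "PQ").phenotype is None

    def test_replicates_are_bit_reproducible(self):
        t1 = make_sim(seed=31, N_b=80, N_p=50, N_s=2, years=7, q=0.5).run()
        t2 = make_sim(seed=31, N_b=80, N_p=50, N_s=2, years=7, q=0.5).run()
        for year in range(1, 8):
            assert np.array_equal(t1.cohort(year, "BQ").tbv, t2.cohort(year, "BQ").tbv)
            assert np.array_equal(t1.cohort(year, "PQ").F, t2.cohort(year, "PQ").F)

    def test_mean_inbreeding_accumulates_under_controlled_mating(self):
        sim = make_sim(seed=37, N_b=100, N_s=2, years=14)
        state = sim.run()
        mean_f = np.array([state.cohort(y, "BQ").F.mean() for y in range(1, 15)])
        assert np.all(mean_f >= -1e-12)
        # monotone accumulation up to Monte-Carlo wiggle: the running max
        # never drops by more than a trivial amount
        running = np.maximum.accumulate(mean_f)
        assert np.all(mean_f[-5:] > 0)  # finite N_s: relatedness has built up
        assert mean_f[-3:].mean() > mean_f[:7].mean()
        assert mean_f[-1] >= 0.5 * running[-1] - 1e-9

    def test_queen_accessor_returns_consistent_view(self):
        sim = make_sim(seed=41, N_b=40, N_s=0, years=4, selection="random")
        state = sim.run()
        q = state.queen((4, "BQ", 0))
        c = state.cohort(4, "BQ")
        assert q.tbv.m == c.tbv[0, 0] and q.tbv.d == c.tbv[0, 1]
        assert q.n_mates == 12
        assert q.phenotype == pytest.approx(float(c.phenotype[0]))
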