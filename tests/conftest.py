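import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


ROOT_SEED = 1234


@pytest.fixture(scope="session")
def runs():
    """Lazily computed, shared replicate trajectories per setting."""
    from apiselect import experiment as xp

    cache: dict = {}

    def get(setting, reps):
        trajs = cache.setdefault(setting, [])
        while len(trajs) < reps:
            trajs.append(xp.run_replicate(setting, xp.replicate_seed(ROOT_SEED, len(trajs))))
        return trajs[:reps]

    return get


@pytest.fixture
def vc():
    """The study's moderate-correlation variance components."""
    from apiselect.genetics import VarianceComponents

    return VarianceComponents(sigma2_Am=1.0, sigma2_Ad=2.0, sigma_Amd=-0.75, sigma2_E=1.0)


@pytest.fixture
def vc_strong():
    from apiselect.genetics import VarianceComponents

    return VarianceComponents(sigma2_Am=1.0, sigma2_Ad=2.0, sigma_Amd=-1.25, sigma2_E=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_full_pedigree(seed: int, n_base: int = 8, generations: int = 5, per_gen: int = 8):
    """A random haplodiploid pedigree for oracle comparisons."""
    from apiselect.pedigree import FullPedigree

    rng = np.random.default_rng(seed)
    ped = FullPedigree()
    pool = [ped.add_base_queen() for _ in range(n_base)]
    for _ in range(generations):
        new = []
        for _ in range(per_gen):
            dam = pool[rng.integers(len(pool))]
            drone = ped.add_drone(pool[rng.integers(len(pool))])
            new.append(ped.add_queen(dam, drone))
        pool = pool[-3:] + new
    return ped


def random_observed_pedigree(seed: int, n_base: int = 14, n_stations: int = 2, n_daughters: int = 24):
    """A random observed pedigree mixing station and unknown matings."""
    from apiselect.pedigree import ObservedPedigree

    rng = np.random.default_rng(seed)
    obs = ObservedPedigree()
    base = [obs.add_base_queen(1) for _ in range(n_base)]
    for q in base:
        obs.add_unknown_mating(q)
    matings = []
    year = 2
    for s in range(n_stations):
        mother = base[rng.integers(len(base))]
        dpqs = [obs.add_queen(mother, year) for _ in range(8)]
        row = obs.station_row(dpqs)
        for _ in range(3):
            q = obs.add_queen(base[rng.integers(len(base))], year)
            matings.append(obs.add_station_mating(q, dpqs, station_id=s + 1, _row=row))
    queens = [i for i in range(obs.n) if obs.kind[i] in (0, 1) and obs.mating[i] != -1]
    for _ in range(n_daughters):
        dam = queens[rng.integers(len(queens))]
        child = obs.add_queen(dam, year + 1)
        if rng.random() < 0.5:
            obs.add_unknown_mating(child)
            queens.append(child)
    return obs
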