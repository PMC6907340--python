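"""Yearly honeybee breeding-population dynamics.

Three mutually exclusive queen categories are simulated:

* **BQ** (breeding queens): performance-tested, BLUP-evaluated, selected.
  Each year the best 20% of the 2-year-old BQ (by the worker-group total-EBV
  criterion) become dams of the next ``N_b`` breeding queens.
* **DPQ** (drone-producing queens): under controlled mating, the ``N_s`` best
  3-year-old BQ each produce a sister group of 8 unmated DPQs that stock one
  isolated mating station for the year; every new queen mated on a station
  receives 12 drones whose dams are drawn uniformly among its 8 DPQs.
* **PQ** (passive queens): an unselected surrounding population of constant
  yearly size ``N_p``; a fraction ``q`` of each PQ cohort has BQ dams.  PQ
  carry and transmit true breeding values but are never tested or evaluated.

Under uncontrolled mating (``N_s = 0``) every new queen's 12 drones have dams
picked uniformly from all living queens aged 1-3 in *both* populations, so a
drone's dam is a BQ with probability ``p = N_b / (N_b + N_p)``; with an
infinite passive population the drones are drawn as if from the base
population and carry no pedigree links.  In the BLUP view those sires are
unknown.

Timing convention: cohorts born in years 1-2 are the unselected, unrelated
base population; a queen born in year ``t`` is mated and (BQ only) tested in
year ``t``, may be selected as a dam at age 2 and as a station mother at age
3, and is retired after age 3.  In year 3, when no 3-year-olds exist yet,
station mothers are taken from the oldest available (2-year-old) cohort.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from . import genetics as gen
from .blup import assemble_mme, solve_mme
from .genetics import LocusModel, VarianceComponents, init_locus_model
from .pedigree import FullPedigree, ObservedPedigree

__all__ = ["SchemeConfig", "Queen", "MatingStation", "Cohort", "PopulationState", "Simulation", "round_half_up"]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class SchemeConfig:
    """One simulation setting (a row of the parameter grid).

    ``N_p`` may be ``0``, a positive integer, or ``math.inf``; the degenerate
    values are only meaningful with ``q = 0`` (there is no passive population
    to seed, or it is unaffected by construction).
    """

    N_b: int = 500
    N_p: float = 0
    N_s: int = 0
    q: float = 0.0
    vc: VarianceComponents = dataclasses.field(default_factory=VarianceComponents)
    years: int = 20
    dam_fraction: float = 0.20
    daughters_per_dam: int = 5
    drones_per_mating: int = 12
    dpq_per_station: int = 8
    model: str = "infinitesimal"  # or "finite-locus"
    n_loci: int = 400
    selection: str = "blup"  # "random" gives an unselected drift control

    def __post_init__(self) -> None:
        if self.N_b <= 0:
            raise ValueError("N_b must be positive")
        if not (self.N_p == math.inf or (self.N_p >= 0 and float(self.N_p).is_integer())):
            raise ValueError("N_p must be a non-negative integer or infinity")
        if self.N_p in (0, math.inf) and self.q != 0:
            raise ValueError("N_p in {0, inf} is only valid in combination with q = 0")
        if not 0 <= self.q <= 1:
            raise ValueError("q must lie in [0, 1]")
        if self.N_s < 0:
            raise ValueError("N_s must be non-negative (0 = uncontrolled mating)")
        if self.years < 2:
            raise ValueError("at least the two base years must be simulated")
        if self.model not in ("infinitesimal", "finite-locus"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        if self.selection not in ("blup", "random"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if not 0 < self.dam_fraction <= 1:
            raise ValueError("dam_fraction must lie in (0, 1]")

    @property
    def controlled(self) -> bool:
        return self.N_s > 0

    @property
    def n_dams(self) -> int:
        return round_half_up(self.dam_fraction * self.N_b)


@dataclasses.dataclass
class Queen:
    """Scalar view of one simulated queen (convenience accessor)."""

    id: int
    category: str
    birth_year: int
    tbv: gen.BreedingValue
    F: float
    dam_id: int
    n_mates: int
    phenotype: Optional[float]


@dataclasses.dataclass
class MatingStation:
    """One year's isolated mating station: a sister group of 8 DPQs."""

    station_id: int
    year: int
    source_queen_full: int
    dpq_cohort: "Cohort"
    obs_row: tuple  # precomputed ObservedPedigree.station_row result


@dataclasses.dataclass
class Cohort:
    """One (birth year, category) group, stored as parallel arrays."""

    year: int
    kind: str  # "BQ" | "PQ" | "DPQ"
    tbv: np.ndarray  # (n, 2)
    full_ids: np.ndarray  # (n,) full-pedigree node ids
    F: np.ndarray  # (n,) true inbreeding
    dam_full: np.ndarray  # (n,) full id of the dam, -1 for base
    obs_ids: Optional[np.ndarray] = None  # BQ/DPQ only
    hap_mat: Optional[np.ndarray] = None  # finite-locus haplotypes (n, L)
    hap_pat: Optional[np.ndarray] = None
    mate_tbv: Optional[np.ndarray] = None  # (n, 12, 2)
    mate_hap: Optional[np.ndarray] = None  # (n, 12, L)
    mate_dronedam: Optional[np.ndarray] = None  # (n, 12) full id of drone dams, -1 base
    mate_father_node: Optional[np.ndarray] = None  # lazily created drone nodes
    mating_obs: Optional[np.ndarray] = None  # (n,) observed mating node
    station_of: Optional[np.ndarray] = None  # (n,) station id, -1 if none
    phenotype: Optional[np.ndarray] = None
    crit: Optional[np.ndarray] = None  # latest BLUP selection criterion

    @property
    def n(self) -> int:
        return self.tbv.shape[0]

    def free_heavy(self) -> None:
        """Drop reproduction state once the cohort can no longer reproduce."""
        self.mate_tbv = None
        self.mate_hap = None
        self.hap_mat = None
        self.hap_pat = None


class _InfinitesimalEngine:
    uses_haplotypes = False

    def __init__(self, vc: VarianceComponents):
        self.vc = vc
        self._b = vc.chol

    def _phi(self, shape, rng):
        return rng.standard_normal(tuple(shape) + (2,)) @ self._b.T

    def base_queens(self, n, rng):
        return self._phi((n,), rng), None, None

    def base_drones(self, shape, rng):
        # a gamete of a virtual non-inbred base dam, on the doubled scale
        return math.sqrt(2.0) * self._phi(shape, rng), None

    def drones(self, dam_tbv, dam_F, dam_mat, dam_pat, rng):
        phi = self._phi(dam_tbv.shape[:-1], rng)
        return dam_tbv + np.sqrt(1.0 - dam_F)[..., None] * phi, None

    def offspring(self, dam_tbv, dam_F, dam_mat, dam_pat, father_tbv, father_hap, rng):
        phi = self._phi(dam_tbv.shape[:-1], rng)
        tbv = 0.5 * (father_tbv + dam_tbv + np.sqrt(1.0 - dam_F)[..., None] * phi)
        return tbv, None, None


class _FiniteLocusEngine:
    uses_haplotypes = True

    def __init__(self, model: LocusModel):
        self.model = model

    def _tbv_diploid(self, mat, pat):
        return gen.haplotypes_tbv(mat, pat, self.model)

    def _tbv_drone(self, hap):
        return gen.haplotypes_tbv(hap, None, self.model)

    def _base_hap(self, shape, rng):
        return (rng.random(tuple(shape) + (self.model.n_loci,)) < self.model.init_freq).astype(np.uint8)

    def base_queens(self, n, rng):
        mat = self._base_hap((n,), rng)
        pat = self._base_hap((n,), rng)
        return self._tbv_diploid(mat, pat), mat, pat

    def base_drones(self, shape, rng):
        hap = self._base_hap(shape, rng)
        return self._tbv_drone(hap.reshape(-1, self.model.n_loci)).reshape(tuple(shape) + (2,)), hap

    def drones(self, dam_tbv, dam_F, dam_mat, dam_pat, rng):
        flat_shape = (-1, self.model.n_loci)
        hap = gen.sample_gametes(dam_mat.reshape(flat_shape), dam_pat.reshape(flat_shape), rng)
        tbv = self._tbv_drone(hap)
        lead = dam_mat.shape[:-1]
        return tbv.reshape(lead + (2,)), hap.reshape(lead + (self.model.n_loci,))

    def offspring(self, dam_tbv, dam_F, dam_mat, dam_pat, father_tbv, father_hap, rng):
        mat = gen.sample_gametes(dam_mat, dam_pat, rng)
        pat = father_hap.copy()
        return self._tbv_diploid(mat, pat), mat, pat


@dataclasses.dataclass
class PopulationState:
    """Living cohorts plus both pedigree views and the accumulated records."""

    config: SchemeConfig
    year: int
    cohorts: dict  # (year, kind) -> Cohort
    full: FullPedigree
    obs: ObservedPedigree
    records: tuple  # growing lists (queen_obs, mating_obs, y)

    def cohort(self, year: int, kind: str) -> Cohort:
        return self.cohorts[(year, kind)]

    def living(self, kind: str, year: int | None = None):
        """Cohorts of the given kind aged 1-3 in the given (default current) year."""
        y = self.year if year is None else year
        out = []
        for age in (1, 2, 3):
            c = self.cohorts.get((y - age, kind))
            if c is not None:
                out.append(c)
        return out

    def queen(self, kind_year_row) -> Queen:
        year, kind, row = kind_year_row
        c = self.cohort(year, kind)
        return Queen(
            id=int(c.full_ids[row]),
            category=kind,
            birth_year=year,
            tbv=gen.BreedingValue(*c.tbv[row]),
            F=float(c.F[row]),
            dam_id=int(c.dam_full[row]),
            n_mates=0 if c.mate_tbv is None else c.mate_tbv.shape[1],
            phenotype=None if c.phenotype is None else float(c.phenotype[row]),
        )


class Simulation:
    """One replicate of one setting; deterministic given (config, seed).

    All randomness flows from a single root seed through three named
    substreams: ``genetics`` (breeding-value and gamete draws), ``mating``
    (every discrete mating/selection choice) and ``residual`` (phenotype
    noise).
    """

    def __init__(self, config: SchemeConfig, seed: int):
        self.config = config
        self.vc = config.vc
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(4)
        self.rng_gen = np.random.default_rng(kids[0])
        self.rng_mat = np.random.default_rng(kids[1])
        self.rng_res = np.random.default_rng(kids[2])
        if config.model == "finite-locus":
            model = init_locus_model(config.vc, config.n_loci, np.random.default_rng(kids[3]))
            self.engine = _FiniteLocusEngine(model)
        else:
            self.engine = _InfinitesimalEngine(config.vc)
        self.state = PopulationState(
            config=config,
            year=0,
            cohorts={},
            full=FullPedigree(),
            obs=ObservedPedigree(),
            records=([], [], []),
        )
        self._station_counter = 0
        self._warm = None  # (ebv_m, ebv_d, mean) of the previous BLUP solve
        self.log: dict[str, list] = {
            "year": [], "S_crit": [], "S_true": [], "n_solver_entities": []
        }

    # -- small helpers ------------------------------------------------------

    def _new_full_queens(self, dam_full, father_nodes):
        full = self.state.full
        ids = np.empty(len(dam_full), dtype=np.int64)
        for i, (d, f) in enumerate(zip(dam_full, father_nodes)):
            ids[i] = full.add_queen(int(d), int(f))
        return ids

    def _base_full_queens(self, n):
        full = self.state.full
        return np.asarray([full.add_base_queen() for _ in range(n)], dtype=np.int64)

    def _father_nodes(self, dam_cohort: Cohort, dam_rows, slots):
        """Full-pedigree drone nodes for chosen (dam row, mate slot) pairs, created lazily."""
        full = self.state.full
        cache = dam_cohort.mate_father_node
        out = np.empty(len(dam_rows), dtype=np.int64)
        for i, (r, s) in enumerate(zip(dam_rows, slots)):
            node = cache[r, s]
            if node < 0:
                dd = dam_cohort.mate_dronedam[r, s]
                node = full.add_base_drone() if dd < 0 else full.add_drone(int(dd))
                cache[r, s] = node
            out[i] = node
        return out

    def _record_phenotypes(self, cohort: Cohort) -> None:
        worker = gen.worker_group_tbv(cohort.tbv, cohort.mate_tbv)
        cohort.phenotype = gen.colony_phenotype(worker, cohort.tbv, self.vc, self.rng_res)
        q, m, y = self.state.records
        q.extend(cohort.obs_ids.tolist())
        m.extend(cohort.mating_obs.tolist())
        y.extend(cohort.phenotype.tolist())

    # -- mating -------------------------------------------------------------

    def _mate_to_base(self, cohort: Cohort, observed: bool) -> None:
        """Mate a cohort to unrecorded base drones (base years; N_p = inf)."""
        n, k = cohort.n, self.config.drones_per_mating
        tbv, hap = self.engine.base_drones((n, k), self.rng_gen)
        cohort.mate_tbv = tbv
        cohort.mate_hap = hap
        cohort.mate_dronedam = np.full((n, k), -1, dtype=np.int64)
        cohort.mate_father_node = np.full((n, k), -1, dtype=np.int64)
        cohort.station_of = np.full(n, -1, dtype=np.int64)
        if observed:
            obs = self.state.obs
            cohort.mating_obs = np.asarray(
                [obs.add_unknown_mating(int(i)) for i in cohort.obs_ids], dtype=np.int64
            )

    def mate_uncontrolled(self, cohort: Cohort, observed: bool) -> None:
        """12 drones per queen, dams uniform among all living queens aged 1-3."""
        if self.config.N_p == math.inf:
            self._mate_to_base(cohort, observed)
            return
        pools = self.state.living("BQ") + self.state.living("PQ")
        if not pools:
            raise RuntimeError("no queens aged 1-3 available as drone dams")
        pool_tbv = np.concatenate([c.tbv for c in pools])
        pool_F = np.concatenate([c.F for c in pools])
        pool_ids = np.concatenate([c.full_ids for c in pools])
        if self.engine.uses_haplotypes:
            pool_mat = np.concatenate([c.hap_mat for c in pools])
            pool_pat = np.concatenate([c.hap_pat for c in pools])
        n, k = cohort.n, self.config.drones_per_mating
        pick = self.rng_mat.integers(0, pool_tbv.shape[0], size=(n, k))
        dm = pool_mat[pick] if self.engine.uses_haplotypes else None
        dp = pool_pat[pick] if self.engine.uses_haplotypes else None
        tbv, hap = self.engine.drones(pool_tbv[pick], pool_F[pick], dm, dp, self.rng_gen)
        cohort.mate_tbv = tbv
        cohort.mate_hap = hap
        cohort.mate_dronedam = pool_ids[pick]
        cohort.mate_father_node = np.full((n, k), -1, dtype=np.int64)
        cohort.station_of = np.full(n, -1, dtype=np.int64)
        if observed:
            obs = self.state.obs
            cohort.mating_obs = np.asarray(
                [obs.add_unknown_mating(int(i)) for i in cohort.obs_ids], dtype=np.int64
            )

    def mate_controlled(self, cohort: Cohort, stations: list[MatingStation]) -> None:
        """Mate each queen on one station drawn uniformly among this year's stations."""
        n, k = cohort.n, self.config.drones_per_mating
        pick = self.rng_mat.integers(0, len(stations), size=n)
        cohort.mate_tbv = np.empty((n, k, 2))
        if self.engine.uses_haplotypes:
            cohort.mate_hap = np.empty((n, k, self.engine.model.n_loci), dtype=np.uint8)
        cohort.mate_dronedam = np.empty((n, k), dtype=np.int64)
        cohort.mate_father_node = np.full((n, k), -1, dtype=np.int64)
        cohort.station_of = np.empty(n, dtype=np.int64)
        cohort.mating_obs = np.empty(n, dtype=np.int64)
        obs = self.state.obs
        for s_idx, st in enumerate(stations):
            rows = np.nonzero(pick == s_idx)[0]
            if rows.size == 0:
                continue
            dpq = st.dpq_cohort
            didx = self.rng_mat.integers(0, dpq.n, size=(rows.size, k))
            dm = dpq.hap_mat[didx] if self.engine.uses_haplotypes else None
            dp = dpq.hap_pat[didx] if self.engine.uses_haplotypes else None
            tbv, hap = self.engine.drones(dpq.tbv[didx], dpq.F[didx], dm, dp, self.rng_gen)
            cohort.mate_tbv[rows] = tbv
            if hap is not None:
                cohort.mate_hap[rows] = hap
            cohort.mate_dronedam[rows] = dpq.full_ids[didx]
            cohort.station_of[rows] = st.station_id
            for r in rows:
                cohort.mating_obs[r] = obs.add_station_mating(
                    int(cohort.obs_ids[r]),
                    list(dpq.obs_ids),
                    st.station_id,
                    _row=st.obs_row,
                )

    # -- reproduction -------------------------------------------------------

    def produce_offspring_queens(
        self, dam_cohort: Cohort, dam_rows, kind: str, year: int, observed: bool
    ) -> Cohort:
        """Daughter queens: one father each, drawn uniformly from the dam's 12 mates."""
        if dam_cohort.mate_tbv is None:
            raise RuntimeError("dams must be mated before producing offspring")
        dam_rows = np.asarray(dam_rows, dtype=np.int64)
        n = dam_rows.size
        slots = self.rng_mat.integers(0, self.config.drones_per_mating, size=n)
        father_nodes = self._father_nodes(dam_cohort, dam_rows, slots)
        father_tbv = dam_cohort.mate_tbv[dam_rows, slots]
        father_hap = (
            dam_cohort.mate_hap[dam_rows, slots] if self.engine.uses_haplotypes else None
        )
        dm = dam_cohort.hap_mat[dam_rows] if self.engine.uses_haplotypes else None
        dp = dam_cohort.hap_pat[dam_rows] if self.engine.uses_haplotypes else None
        tbv, mat, pat = self.engine.offspring(
            dam_cohort.tbv[dam_rows],
            dam_cohort.F[dam_rows],
            dm,
            dp,
            father_tbv,
            father_hap,
            self.rng_gen,
        )
        full_ids = self._new_full_queens(dam_cohort.full_ids[dam_rows], father_nodes)
        F = self.state.full.compute_inbreeding(full_ids)
        cohort = Cohort(
            year=year,
            kind=kind,
            tbv=tbv,
            full_ids=full_ids,
            F=F,
            dam_full=dam_cohort.full_ids[dam_rows],
            hap_mat=mat,
            hap_pat=pat,
        )
        if observed:
            obs = self.state.obs
            dam_obs = dam_cohort.obs_ids[dam_rows]
            obs.compute_inbreeding(np.unique(dam_obs))  # batch before the row-wise adds
            cohort.obs_ids = np.asarray(
                [obs.add_queen(int(d), year) for d in dam_obs], dtype=np.int64
            )
        return cohort

    # -- selection ----------------------------------------------------------

    def _ranking(self, cohort: Cohort) -> np.ndarray:
        """Row order by descending criterion; ties broken by ascending id."""
        if self.config.selection == "random":
            return self.rng_mat.permutation(cohort.n)
        if cohort.crit is None:
            raise RuntimeError("no BLUP criterion available for selection")
        return np.lexsort((cohort.full_ids, -cohort.crit))

    def select_dams(self, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
        """Best dams of a 2-year-old BQ cohort and the per-daughter dam rows.

        Daughters are spread as evenly as possible over the selected dams
        (exactly ``daughters_per_dam`` each when the replacement arithmetic
        is consistent, e.g. 20% x 5 = 1).
        """
        if cohort.n == 0:
            raise RuntimeError("cannot select dams from an empty cohort")
        n_dams = min(self.config.n_dams, cohort.n)
        order = self._ranking(cohort)
        dams = order[:n_dams]
        counts = np.full(n_dams, self.config.N_b // n_dams, dtype=np.int64)
        counts[: self.config.N_b - counts.sum()] += 1
        dam_rows = np.repeat(dams, counts)
        return dams, dam_rows

    def setup_mating_stations(self, year: int) -> list[MatingStation]:
        """Sister groups of the N_s best 3-year-old queens (oldest cohort in year 3)."""
        cfg = self.config
        source = self.state.cohorts.get((year - 3, "BQ"))
        if source is None:  # bootstrap: no 3-year-olds exist yet
            source = self.state.cohorts.get((year - 2, "BQ"))
        if source is None or source.n < cfg.N_s:
            raise RuntimeError("not enough queens to stock the mating stations")
        order = self._ranking(source)
        stations = []
        for r in order[: cfg.N_s]:
            self._station_counter += 1
            dpq = self.produce_offspring_queens(
                source, np.full(cfg.dpq_per_station, r), "DPQ", year, observed=True
            )
            row = self.state.obs.station_row(list(dpq.obs_ids))
            for qid in dpq.obs_ids:
                self.state.obs.dpq_station[int(qid)] = self._station_counter
            stations.append(
                MatingStation(
                    station_id=self._station_counter,
                    year=year,
                    source_queen_full=int(source.full_ids[r]),
                    dpq_cohort=dpq,
                    obs_row=row,
                )
            )
            self.state.cohorts[(year, f"DPQ{self._station_counter}")] = dpq
        return stations

    def breed_passive_cohort(self, year: int) -> Optional[Cohort]:
        """New PQ cohort: ``round(q N_p)`` BQ-dam daughters, the rest PQ-dam."""
        cfg = self.config
        if cfg.N_p in (0, math.inf):
            return None
        n_p = int(cfg.N_p)
        n_from_bq = round_half_up(cfg.q * n_p)
        parts = []
        for kind, count in (("BQ", n_from_bq), ("PQ", n_p - n_from_bq)):
            if count == 0:
                continue
            pools = self.state.living(kind, year)
            if not pools:
                raise RuntimeError(f"no {kind} aged 1-3 available as passive dams")
            sizes = np.asarray([c.n for c in pools])
            offsets = np.concatenate([[0], np.cumsum(sizes)])
            pick = self.rng_mat.integers(0, sizes.sum(), size=count)
            for ci, c in enumerate(pools):
                rows = pick[(pick >= offsets[ci]) & (pick < offsets[ci + 1])] - offsets[ci]
                if rows.size:
                    parts.append(
                        self.produce_offspring_queens(c, rows, "PQ", year, observed=False)
                    )
        cohort = _concat_cohorts(parts, year, "PQ")
        self.mate_uncontrolled(cohort, observed=False)
        return cohort

    # -- evaluation ---------------------------------------------------------

    def run_blup(self) -> None:
        """Yearly mixed-model evaluation; refreshes every BQ cohort's criterion."""
        q, m, y = self.state.records
        obs = self.state.obs
        mme = assemble_mme(
            (np.asarray(q), np.asarray(m), np.asarray(y)), obs.graph.a_inverse(), self.vc
        )
        x0 = None
        if self._warm is not None:
            em, ed, mu = self._warm
            n = obs.n
            x0 = np.zeros(1 + 2 * n)
            x0[0] = mu
            x0[1 : 1 + em.size] = em
            x0[1 + n : 1 + n + ed.size] = ed
        ebv = solve_mme(mme, x0=x0, year=self.state.year)
        self._warm = (ebv.ebv_m, ebv.ebv_d, ebv.mean)
        self.log["n_solver_entities"].append(obs.n)
        for (cy, kind), cohort in self.state.cohorts.items():
            if kind == "BQ" and cohort.obs_ids is not None and cohort.mating_obs is not None:
                cohort.crit = ebv.criterion(cohort.obs_ids, cohort.mating_obs)

    # -- the yearly cycle ---------------------------------------------------

    def initialize_population(self) -> PopulationState:
        """Create and mate the base cohorts of years 1 and 2."""
        for year in (1, 2):
            self._base_year(year)
        self.state.year = 2
        return self.state

    def _base_year(self, year: int) -> None:
        cfg = self.config
        tbv, mat, pat = self.engine.base_queens(cfg.N_b, self.rng_gen)
        full_ids = self._base_full_queens(cfg.N_b)
        bq = Cohort(
            year=year,
            kind="BQ",
            tbv=tbv,
            full_ids=full_ids,
            F=np.zeros(cfg.N_b),
            dam_full=np.full(cfg.N_b, -1, dtype=np.int64),
            hap_mat=mat,
            hap_pat=pat,
            obs_ids=np.asarray(
                [self.state.obs.add_base_queen(year) for _ in range(cfg.N_b)], dtype=np.int64
            ),
        )
        self._mate_to_base(bq, observed=True)
        self._record_phenotypes(bq)
        self.state.cohorts[(year, "BQ")] = bq
        if cfg.N_p not in (0, math.inf):
            n_p = int(cfg.N_p)
            tbv, mat, pat = self.engine.base_queens(n_p, self.rng_gen)
            pq = Cohort(
                year=year,
                kind="PQ",
                tbv=tbv,
                full_ids=self._base_full_queens(n_p),
                F=np.zeros(n_p),
                dam_full=np.full(n_p, -1, dtype=np.int64),
                hap_mat=mat,
                hap_pat=pat,
            )
            self._mate_to_base(pq, observed=False)
            self.state.cohorts[(year, "PQ")] = pq
        self.log["year"].append(year)
        self.log["S_crit"].append(np.nan)
        self.log["S_true"].append(np.nan)

    def advance_year(self) -> PopulationState:
        """One full breeding year: evaluate, select, mate, test, retire."""
        state = self.state
        cfg = self.config
        year = state.year + 1
        state.year = year

        if cfg.selection == "blup":
            self.run_blup()

        dam_cohort = state.cohort(year - 2, "BQ")
        dams, dam_rows = self.select_dams(dam_cohort)
        if cfg.selection == "blup":
            cmean = dam_cohort.crit.mean()
            self.log["S_crit"].append(float(dam_cohort.crit[dams].mean() - cmean))
        else:
            self.log["S_crit"].append(np.nan)
        tot = dam_cohort.tbv.sum(axis=1)
        self.log["S_true"].append(float(tot[dams].mean() - tot.mean()))
        self.log["year"].append(year)

        stations = self.setup_mating_stations(year) if cfg.controlled else []

        new_bq = self.produce_offspring_queens(dam_cohort, dam_rows, "BQ", year, observed=True)
        if cfg.controlled:
            self.mate_controlled(new_bq, stations)
        else:
            self.mate_uncontrolled(new_bq, observed=True)
        self._record_phenotypes(new_bq)
        state.cohorts[(year, "BQ")] = new_bq

        pq = self.breed_passive_cohort(year)
        if pq is not None:
            state.cohorts[(year, "PQ")] = pq

        for (cy, kind), cohort in state.cohorts.items():
            if year - cy > 3:
                cohort.free_heavy()
        return state

    def run(self) -> PopulationState:
        self.initialize_population()
        while self.state.year < self.config.years:
            self.advance_year()
        return self.state


def _concat_cohorts(parts: list[Cohort], year: int, kind: str) -> Cohort:
    def cat(field):
        vals = [getattr(p, field) for p in parts]
        return None if vals[0] is None else np.concatenate(vals)

    return Cohort(
        year=year,
        kind=kind,
        tbv=cat("tbv"),
        full_ids=cat("full_ids"),
        F=cat("F"),
        dam_full=cat("dam_full"),
        hap_mat=cat("hap_mat"),
        hap_pat=cat("hap_pat"),
    )
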