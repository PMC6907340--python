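"""Configuration grids, replicate management and summary statistics.

The study design crosses breeding-population size ``N_b`` in {500, 1000,
2000}, passive-population size ``N_p`` in {0, 500, 1000, 2000, inf}, station
count ``N_s`` in {0, 5, 10, 20}, passive-coupling fraction ``q`` in
{0, 0.25, 0.5, 0.75, 1} and the maternal-direct covariance in
{-0.75, -1.25}; the degenerate passive sizes (0 and infinity) pair only with
``q = 0``, giving 408 settings in total.  Every setting is simulated over 20
years and summarized by

* the genetic gain in mean total true breeding value of the yearly BQ birth
  cohorts between years 5 and 20, and its maternal/direct decomposition;
* the genetic lag, in years, by which the passive population trails the
  breeding population (mean cohort-mean gap over a steady-state window
  divided by the breeding population's fitted yearly gain over that window);
* the correlation, across free-mating settings, between the gain and the
  proportion ``p = N_b / (N_b + N_p)`` of breeding queens in the population.

Replicates use common random numbers across settings (the replicate index,
not the setting, keys the seed stream), which pairs the comparisons the
monotonicity analyses rely on.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .breeding_scheme import SchemeConfig, Simulation
from .genetics import VarianceComponents

__all__ = [
    "Setting",
    "ReplicateTrajectory",
    "SummaryStats",
    "run_replicate",
    "accumulated_gain",
    "genetic_gain",
    "decompose_gain",
    "genetic_lag",
    "gain_p_correlation",
    "study_grid",
    "grid_settings",
    "run_grid",
    "run_long_term",
    "summarize_replicates",
    "write_results",
    "replicate_seed",
]

BASE_VC = dict(sigma2_Am=1.0, sigma2_Ad=2.0, sigma2_E=1.0)

GRID_N_B = (500, 1000, 2000)
GRID_N_P = (0, 500, 1000, 2000, math.inf)
GRID_N_S = (0, 5, 10, 20)
GRID_Q = (0.0, 0.25, 0.5, 0.75, 1.0)
GRID_COV = (-0.75, -1.25)


@dataclasses.dataclass(frozen=True)
class Setting:
    """One point of the simulation grid (trait variances fixed at the study values)."""

    N_b: int = 1000
    N_p: float = 0
    N_s: int = 0
    q: float = 0.0
    sigma_Amd: float = -0.75
    years: int = 20
    model: str = "infinitesimal"
    selection: str = "blup"
    dam_fraction: float = 0.20
    n_loci: int = 400

    def config(self) -> SchemeConfig:
        vc = VarianceComponents(sigma_Amd=self.sigma_Amd, **BASE_VC)
        return SchemeConfig(
            N_b=self.N_b,
            N_p=self.N_p,
            N_s=self.N_s,
            q=self.q,
            vc=vc,
            years=self.years,
            model=self.model,
            selection=self.selection,
            dam_fraction=self.dam_fraction,
        )

    @property
    def p(self) -> float:
        """Proportion of breeding queens among all queens, N_b / (N_b + N_p)."""
        if self.N_p == math.inf:
            return 0.0
        return self.N_b / (self.N_b + self.N_p)

    def label(self) -> dict:
        np_label = "inf" if self.N_p == math.inf else int(self.N_p)
        return dict(
            N_b=self.N_b, N_p=np_label, N_s=self.N_s, q=self.q, sigma_Amd=self.sigma_Amd
        )


@dataclasses.dataclass
class ReplicateTrajectory:
    """Per-year birth-cohort summaries of one replicate."""

    setting: Setting
    seed: int
    years: np.ndarray
    bq_mean_m: np.ndarray
    bq_mean_d: np.ndarray
    bq_mean_total: np.ndarray
    bq_sd_total: np.ndarray
    bq_mean_F: np.ndarray
    bq_census_total: np.ndarray
    pq_mean_m: np.ndarray
    pq_mean_d: np.ndarray
    pq_mean_total: np.ndarray
    pq_census_total: np.ndarray
    S_crit: np.ndarray
    S_true: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        d = dataclasses.asdict(self)
        d.pop("setting")
        seed = d.pop("seed")
        df = pd.DataFrame(d)
        for k, v in self.setting.label().items():
            df[k] = v
        df["seed"] = seed
        return df

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"trajectory does not cover year {year}")
        return int(idx[0])


def replicate_seed(root_seed: int, replicate: int) -> int:
    """Derived seed; deliberately independent of the setting (common random numbers)."""
    return int(
        np.random.SeedSequence([int(root_seed), int(replicate)]).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_replicate(setting: Setting, seed: int) -> ReplicateTrajectory:
    """Simulate one replicate of one setting; bit-reproducible given (setting, seed)."""
    sim = Simulation(setting.config(), seed)
    state = sim.run()
    years = np.arange(1, setting.years + 1)
    nan = np.full(years.size, np.nan)
    out = dict(
        bq_mean_m=nan.copy(), bq_mean_d=nan.copy(), bq_mean_total=nan.copy(),
        bq_sd_total=nan.copy(), bq_mean_F=nan.copy(),
        pq_mean_m=nan.copy(), pq_mean_d=nan.copy(), pq_mean_total=nan.copy(),
    )
    for i, y in enumerate(years):
        for kind, prefix in (("BQ", "bq"), ("PQ", "pq")):
            c = state.cohorts.get((int(y), kind))
            if c is None:
                continue
            tot = c.tbv.sum(axis=1)
            out[f"{prefix}_mean_m"][i] = c.tbv[:, 0].mean()
            out[f"{prefix}_mean_d"][i] = c.tbv[:, 1].mean()
            out[f"{prefix}_mean_total"][i] = tot.mean()
            if kind == "BQ":
                out["bq_sd_total"][i] = tot.std(ddof=1)
                out["bq_mean_F"][i] = c.F.mean()
    s_crit = np.asarray(sim.log["S_crit"])
    s_true = np.asarray(sim.log["S_true"])
    # census mean: average total TBV over the cohorts alive in each year
    # (the youngest three; cohort sizes are constant by construction)
    for prefix in ("bq", "pq"):
        coh = out[f"{prefix}_mean_total"]
        cen = np.full(years.size, np.nan)
        for i in range(years.size):
            window = coh[max(0, i - 2) : i + 1]
            if not np.isnan(window).any():
                cen[i] = window.mean()
        out[f"{prefix}_census_total"] = cen
    return ReplicateTrajectory(
        setting=setting, seed=seed, years=years,
        S_crit=s_crit, S_true=s_true, **out
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def accumulated_gain(traj: ReplicateTrajectory, year: int = 5) -> float:
    """Accumulated gain by a given year: mean total TBV of the BQ alive then.

    The yearly population mean averages the three youngest cohorts (the
    queens alive during the year); the base level is zero by construction.
    """
    return float(traj.bq_census_total[traj.year_index(year)])


def genetic_gain(traj: ReplicateTrajectory, from_year: int = 5, to_year: int = 20) -> float:
    """Gain in mean total TBV of BQ birth cohorts between two years."""
    return float(
        traj.bq_mean_total[traj.year_index(to_year)]
        - traj.bq_mean_total[traj.year_index(from_year)]
    )


def decompose_gain(
    traj: ReplicateTrajectory, from_year: int = 5, to_year: int = 20
) -> tuple[float, float, Optional[float]]:
    """(maternal gain, direct gain, larger:smaller ratio or None if degenerate)."""
    i0, i1 = traj.year_index(from_year), traj.year_index(to_year)
    gm = float(traj.bq_mean_m[i1] - traj.bq_mean_m[i0])
    gd = float(traj.bq_mean_d[i1] - traj.bq_mean_d[i0])
    lo, hi = sorted([abs(gm), abs(gd)])
    ratio = None if lo < 1e-12 else hi / lo
    return gm, gd, ratio


def genetic_lag(
    breeding, passive=None, years=None, window: tuple[int, int] = (10, 20)
) -> Optional[float]:
    """Time displacement (years) of the passive behind the breeding trajectory.

    Estimated as the mean breeding-minus-passive cohort-mean gap over the
    window divided by the breeding population's fitted linear slope over the
    same window.  Returns ``None`` (flagged undefined) if the slope is not
    positive.  Accepts either a :class:`ReplicateTrajectory` or explicit
    ``(breeding, passive, years)`` arrays.
    """
    if isinstance(breeding, ReplicateTrajectory):
        traj = breeding
        years = traj.years
        b = traj.bq_mean_total
        p = traj.pq_mean_total
    else:
        b = np.asarray(breeding, dtype=float)
        p = np.asarray(passive, dtype=float)
        years = np.arange(1, b.size + 1) if years is None else np.asarray(years)
    lo, hi = window
    m = (years >= lo) & (years <= hi)
    if m.sum() < 2 or np.any(np.isnan(p[m])):
        raise ValueError("both trajectories must cover the lag window")
    gap = float(np.mean(b[m] - p[m]))
    slope = float(np.polyfit(years[m], b[m], 1)[0])
    if slope <= 0:
        return None
    return gap / slope


def gain_p_correlation(ps, gains) -> Optional[float]:
    """Pearson correlation between p = N_b/(N_b+N_p) and genetic gain."""
    ps = np.asarray(ps, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if ps.size < 3:
        raise ValueError("at least three settings are required")
    if np.std(ps) == 0 or np.std(gains) == 0:
        return None
    return float(np.corrcoef(ps, gains)[0, 1])


@dataclasses.dataclass
class SummaryStats:
    """Replicate-averaged summary of one setting."""

    gain_total: float
    gain_total_se: float
    gain_maternal: float
    gain_direct: float
    gain_year5: float
    lag_years: Optional[float]
    lag_years_se: Optional[float]
    n_replicates: int


def summarize_replicates(trajs: Sequence[ReplicateTrajectory],
                         from_year: int = 5, to_year: int = 20) -> SummaryStats:
    gains = np.asarray([genetic_gain(t, from_year, to_year) for t in trajs])
    parts = np.asarray([decompose_gain(t, from_year, to_year)[:2] for t in trajs])
    y5 = np.asarray([accumulated_gain(t, min(5, to_year)) for t in trajs])
    lags = None
    if not np.isnan(trajs[0].pq_mean_total).all():
        vals = [genetic_lag(t) for t in trajs]
        lags = np.asarray([np.nan if v is None else v for v in vals])
    n = len(trajs)
    return SummaryStats(
        gain_total=float(gains.mean()),
        gain_total_se=float(gains.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        gain_maternal=float(parts[:, 0].mean()),
        gain_direct=float(parts[:, 1].mean()),
        gain_year5=float(y5.mean()),
        lag_years=None if lags is None else float(np.nanmean(lags)),
        lag_years_se=None
        if lags is None or n < 2
        else float(np.nanstd(lags, ddof=1) / np.sqrt(n)),
        n_replicates=n,
    )


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def grid_settings(
    N_b=GRID_N_B, N_p=GRID_N_P, N_s=GRID_N_S, q=GRID_Q, sigma_Amd=GRID_COV,
    years: int = 20, model: str = "infinitesimal",
) -> list[Setting]:
    """Cross the parameter lists, honouring the degenerate-N_p footnote."""
    out = []
    for nb in N_b:
        for np_ in N_p:
            for ns in N_s:
                for qq in q:
                    if np_ in (0, math.inf) and qq != 0:
                        continue
                    for cov in sigma_Amd:
                        out.append(
                            Setting(
                                N_b=nb, N_p=np_, N_s=ns, q=qq,
                                sigma_Amd=cov, years=years, model=model,
                            )
                        )
    return out


def study_grid(years: int = 20) -> list[Setting]:
    """The full 408-setting study grid."""
    return grid_settings(years=years)


def run_grid(
    settings: Sequence[Setting],
    replicates: int = 10,
    root_seed: int = 1,
    out_dir=None,
) -> pd.DataFrame:
    """Run every setting x replicate and tabulate per-replicate and mean rows."""
    rows = []
    for setting in settings:
        trajs = []
        for rep in range(replicates):
            seed = replicate_seed(root_seed, rep)
            traj = run_replicate(setting, seed)
            trajs.append(traj)
            gm, gd, _ = decompose_gain(traj, 5, min(20, setting.years))
            lag = None
            if not np.isnan(traj.pq_mean_total).all() and setting.years >= 20:
                lag = genetic_lag(traj)
            rows.append(
                dict(
                    **setting.label(),
                    p=setting.p,
                    replicate=rep,
                    seed=seed,
                    gain_5_20=genetic_gain(traj, 5, min(20, setting.years)),
                    gain_maternal=gm,
                    gain_direct=gd,
                    gain_year5=accumulated_gain(traj, min(5, setting.years)),
                    lag_years=np.nan if lag is None else lag,
                    mean_F_final=float(traj.bq_mean_F[-1]),
                )
            )
        s = summarize_replicates(trajs, 5, min(20, setting.years))
        rows.append(
            dict(
                **setting.label(),
                p=setting.p,
                replicate="mean",
                seed=np.nan,
                gain_5_20=s.gain_total,
                gain_maternal=s.gain_maternal,
                gain_direct=s.gain_direct,
                gain_year5=s.gain_year5,
                lag_years=np.nan if s.lag_years is None else s.lag_years,
                mean_F_final=np.nan,
            )
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        write_results(df, out_dir, manifest=dict(root_seed=root_seed, replicates=replicates,
                                                 n_settings=len(settings)))
    return df


def run_long_term(
    N_b: int = 500,
    N_p: float = 1000,
    q: float = 0.5,
    sigma_Amd: float = -0.75,
    years: int = 100,
    replicates: int = 20,
    root_seed: int = 1,
    model: str = "finite-locus",
    schemes: Optional[Sequence[tuple[str, int, float]]] = None,
) -> pd.DataFrame:
    """Long-horizon comparison of mating schemes under the finite-locus model.

    Runs (by default) the three schemes of the 100-year comparison --
    uncontrolled; controlled with 20 stations and 20% of BQ as dams;
    controlled with 50 stations and 50% of BQ as dams -- and reports the
    final genetic response and the percentage loss of the initial genetic
    standard deviation of queens' total TBV.  Variance erosion requires
    segregating loci, so selecting the infinitesimal model is a
    configuration error.
    """
    if model != "finite-locus":
        raise ValueError("long-term variance erosion requires the finite-locus model")
    if schemes is None:
        schemes = [("uncontrolled", 0, 0.20), ("controlled", 20, 0.20), ("controlled-relaxed", 50, 0.50)]
    rows = []
    for name, n_s, dam_fraction in schemes:
        for rep in range(replicates):
            seed = replicate_seed(root_seed, rep)
            setting = Setting(
                N_b=N_b, N_p=N_p, N_s=n_s, q=q, sigma_Amd=sigma_Amd,
                years=years, model=model, dam_fraction=dam_fraction,
            )
            traj = run_replicate(setting, seed)
            sd0 = traj.bq_sd_total[traj.year_index(2)]
            sd1 = traj.bq_sd_total[-1]
            rows.append(
                dict(
                    scheme=name, N_s=n_s, dam_fraction=dam_fraction, replicate=rep,
                    response=float(traj.bq_mean_total[-1] - traj.bq_mean_total[traj.year_index(2)]),
                    sd_initial=float(sd0), sd_final=float(sd1),
                    sd_loss_pct=float(100.0 * (1.0 - sd1 / sd0)),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def read_results(path) -> pd.DataFrame:
    """Read back a results CSV bit-exactly (round-trip float parsing)."""
    return pd.read_csv(path, float_precision="round_trip")


def write_results(results: pd.DataFrame, out_dir, manifest: Optional[dict] = None) -> dict:
    """Write a results CSV (full float precision) and a JSON run manifest."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    results.to_csv(csv_path, index=False, float_format="%.17g")
    paths = {"results": str(csv_path)}
    manifest = dict(manifest or {})
    try:
        from importlib.metadata import version

        manifest["apiselect_version"] = version("apiselect")
    except Exception:  # pragma: no cover
        pass
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(man_path)
    return paths
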