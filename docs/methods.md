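# Methods

This note documents the model, the numerical choices and the deliberate
design decisions behind `apiselect`, in the order the simulation uses them.

## Genetic model

Queens are diploid; drones arise from unfertilized eggs and are haploid —
genetically a single maternal gamete. All breeding values are bivariate
(maternal `m`, direct `d`) and drone values live on the *diploid-equivalent*
scale (twice the gametic value). On that scale the inheritance rules are

    drone D of queen Q:     u_D = u_Q + sqrt(1 - F_Q) * Phi,
    queen R of Q x D:       u_R = (u_D + u_Q + sqrt(1 - F_Q) * Phi) / 2,
    worker group of Q:      u_W = (u_Q + mean(u_D over the 12 mates)) / 2,

with `Phi ~ N(0, Sigma_A)` independent per event and `F_Q` the dam's exact
inbreeding coefficient. Only the dam's side carries Mendelian noise in the
queen rule: the drone is a clone of one gamete, so his contribution is
fixed. These rules make an unselected, random-mating, non-inbred population
exactly stationary: `Var(u_R) = (2 Sigma_A + Sigma_A + Sigma_A)/4 =
Sigma_A`. A drone's total variance at base is `2 Sigma_A`, and a queen's
self-relationship is `1 + F` as in diploid theory.

Defaults follow the study conditions: `sigma2_Am = 1`, `sigma2_Ad = 2`,
`sigma_Amd = -0.75` or `-1.25` (correlations −0.53 / −0.88), `sigma2_E = 1`.
Phenotypes are `y = u_m(queen) + u_d(worker group) + e`; one record per
tested colony, no fixed effects beyond an overall mean, no repeated
records — the simplest model consistent with the stated variance
components.

### Finite-locus variant

For horizons beyond ~20 years the infinitesimal model is too forgiving: it
cannot lose variance. The finite-locus engine uses 400 unlinked biallelic
loci, initial allele frequency 0.5 and linkage equilibrium, with bivariate
effects drawn normal and then linearly transformed so the base genetic
covariance equals `Sigma_A` to machine precision (well inside the 1%
tolerance the model promises). Meiosis is free recombination; there is no
mutation, dominance or epistasis. Inbreeding needs no explicit bookkeeping
here — it emerges from allele identity.

## Pedigrees and relationship matrices

Two views of ancestry are kept per run:

* the **full pedigree** records each queen's dam and her actual father
  drone (drones are nodes: one parent, residual relationship variance
  `1 - F_dam`). Exact inbreeding coefficients — required by the
  `sqrt(1-F)` factors above — are computed by a generalized
  Meuwissen–Luo back-substitution over each individual's ancestor set
  (numba-compiled; O(ancestors) per query). An independent recursive
  kinship oracle and Monte-Carlo gene-dropping validate it in the tests.

* the **observed pedigree** holds only what a breeder records and is the
  basis of the BLUP relationship matrix. Its nodes are queens and
  per-colony drone groups ("matings"). Derived from the simulator's own
  mating mechanics (8 equally likely DPQ dams per drone, 12 drones per
  mating, one father per daughter, all sampled uniformly with
  replacement), the Henderson rows are:

      base queen:              parents {},                v = 1
      station mating M:        parents {8 DPQs, 1/8 each}, v = (2 - A_SS)/12
      unknown mating:          parents {},                v = 1/6
      queen, dam station-mated: {dam 1/2, dam's mating 1/2},
                               v = (2 - A_MM)/4 + (1 - F_dam)/4
      queen, dam free-mated:   {dam 1/2},                 v = 3/4 - F_dam/4

  where `A_SS` is the self-relationship of the DPQ average and `A_MM` that
  of the mating node. Worker groups (`(queen + mating)/2`) and station
  averages are *exact* linear combinations of existing nodes; they are
  absorbed by substitution rather than stored, because their conditional
  variance is zero and a matrix row for them would make `A` singular.
  Their EBVs are recovered post hoc from the same combinations. With these
  rows, Henderson's sparse-inverse accumulation is exact: on every test
  pedigree (≤ 200 entities) the sparse inverse times the densely built
  matrix is the identity to 1e−8, and dense entries match gene-dropping
  under the same mechanics to Monte-Carlo precision.

Free matings are recorded as *unknown sires*: a daughter of a free-mated
dam links to the dam only, her father treated as an unrelated base drone.
In truth her sisters share fathers, but that information is not available
without mating control — modelling the loss of it is the point. Her
dam's own drone-group node remains in the equations because the dam's
worker group is a real, observed colony.

## Breeding scheme

Yearly cycle (years 1–2 create unrelated base cohorts, mated to base
drones, tested): run BLUP on all records to date; select the best 20% of
2-year-old breeding queens (BQ) as dams, each contributing (as evenly as
possible) five daughters; stock `N_s` stations with sister groups of eight
DPQs bred from the `N_s` best 3-year-old queens; create and mate the new
BQ cohort (station drawn uniformly per queen under controlled mating, 12
drones with dams uniform over all living queens aged 1–3 otherwise);
create the passive cohort (`round(q N_p)` from BQ dams, the rest from PQ
dams, all free-mated); form worker groups and phenotypes for the new BQ;
retire queens older than three. Passive queens carry and transmit TBVs but
are never tested or evaluated. With an infinite passive population drones
are drawn as if from the base population, `N(0, 2 Sigma_A)`, without
pedigree links.

Bootstrap choices where the yearly schedule is underdetermined: in year 3
no 3-year-olds exist, so station mothers come from the oldest available
(2-year-old) cohort, possibly overlapping the dam set in that single year;
station mothers are otherwise ranked by the same criterion as dams but
drawn from the full 3-year-old cohort. Counts round half-up. The selection
criterion is the worker group's total EBV (`EBV_m + EBV_d`); trajectories
additionally record the true-TBV selection differential of the chosen
dams, which is what the infinite-passive plateau bound constrains.

## Summary statistics

* **Cohort vs census.** Birth-cohort means of queens' total TBV are the
  primary trajectory; the "accumulated gain by year t" uses the *census*
  mean — the average over the three cohorts alive in year t. The two were
  disambiguated against the study's own numbers: the 5→20 gains reproduce
  the printed per-setting values with cohort means, while the year-5
  accumulated-gain band (0.63–0.81) matches the census series.
* **Genetic lag**: mean breeding-minus-passive gap over years 10–20
  divided by the breeding population's fitted linear slope over the same
  window; undefined (flagged `None`) when the slope is not positive. The
  estimator itself is a documented choice — the study reports lags without
  defining one.
* **Gain–p correlation**: Pearson correlation across free-mating `q = 0`
  settings between gain 5→20 and `p = N_b/(N_b + N_p)` (`p = 0` for the
  infinite passive population).
* **Percent reduction**: `100 (1 − gain_uncontrolled / gain_controlled)`,
  the controlled reference averaged over the positive station counts.

## Numerics and reproducibility

The mixed-model equations (order `[mu, u_m(1..n), u_d(1..n)]`, 
`G^{-1} = Sigma_A^{-1} ⊗ A^{-1}`, known variance components) are solved by
conjugate gradients to a 1e−8 relative residual with a 2×2 block-Jacobi
preconditioner over each entity's (m, d) pair — the strong maternal–direct
correlation makes that coupling the dominant structure — warm-started from
the previous year's solution, with a sparse LU fallback if CG stalls. Ties
in selection break by ascending id. All randomness flows from one root
seed through three named substreams (genetics, mating choices, residuals),
so a replicate is bit-reproducible given (setting, seed); replicate seeds
are derived from the replicate index only, giving common random numbers
across settings for paired comparisons.

Problem sizes in the shipped tests and acceptance script are reduced
relative to the full study — 5–10 replicates instead of 100, and the
smaller population variants where a bound (not a point value) is checked —
with tolerances of three replicate standard errors; the full grid remains
available through `apiselect grid` and the `--full` flags.

## What the generator does and does not emulate

The synthetic populations reproduce the study conditions: constant cohort
sizes, equal age representation (ages 1–3) among drone dams and passive
dams, 12 mates per queen, no culling, no natural selection on the trait,
known variance components, a single un-structured environment. Real
programmes have uneven age pyramids, colony losses and requeening,
environmental fixed effects, estimated (not known) variance components and
possible subspecies admixture — none of which are modelled, so passing
tests certify the selection-theoretic behaviour of the schemes, not
field-level forecasts.

## Known limitations

* The first selected years are sensitive to bootstrap details that the
  study design leaves open; our free-mating settings approach their
  selection plateau slightly more slowly (year-5 census about 0.57–0.60
  rather than ≥ 0.63) and retain a little more late gain in the
  infinite-passive limit. The steady-state rates — the primary results —
  are unaffected.
* At low station counts the maternal share of the controlled-mating gain
  is somewhat larger here than reported (direct:maternal ≈ 1.5 at
  `N_s = 10` vs a reported 2.01–2.88 across settings; ≈ 2.6 at
  `N_s = 20`, inside the band).
* The relationship rules are derived from this simulator's mating
  mechanics rather than transcribed from the honeybee BLUP literature;
  they are internally exact (oracle-validated) but may differ in constants
  from published bee-specific inverses.
* REML/variance-component estimation, genomic evaluation, mutation,
  linkage, dominance and inbreeding depression are out of scope.
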