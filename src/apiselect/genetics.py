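"""Bivariate maternal/direct genetic model with haplodiploid inheritance.

A colony-level trait is influenced by two additive genetic effects: a
*maternal* effect expressed by the queen and a *direct* effect expressed by
her worker group.  Every genetic entity therefore carries a bivariate
breeding value ``(m, d)``.  Queens are diploid; drones develop from
unfertilized eggs and are haploid clones of a single maternal gamete.  Drone
breeding values are kept on the *diploid-equivalent* scale (twice the gametic
value), which makes a drone's Mendelian-sampling variance around his dam
exactly ``(1 - F_dam) * Sigma_A`` and an offspring queen the plain average of
her dam and her father drone.

Inheritance rules (infinitesimal model):

* drone ``D`` of queen ``Q``:      ``TBV_D = TBV_Q + sqrt(1 - F_Q) * Phi``
* queen ``R`` of ``Q`` x drone ``D``:
  ``TBV_R = (TBV_D + TBV_Q + sqrt(1 - F_Q) * Phi) / 2``
* worker group of ``Q`` mated to drones ``D_1..D_k``:
  ``TBV_W = (TBV_Q + mean(TBV_D)) / 2``

with ``Phi ~ N(0, Sigma_A)`` an independent Mendelian-sampling draw and
``F_Q`` the dam's inbreeding coefficient.  With these rules an unselected,
random-mating, non-inbred population is stationary at ``Sigma_A``:
``Var(R) = (2*Sigma_A + Sigma_A + Sigma_A) / 4 = Sigma_A``.

A finite-locus alternative (:class:`LocusModel`) represents the same base
variance with 400 unlinked biallelic loci so that long-horizon runs erode
genetic variance through drift and selection, which the infinitesimal model
cannot do.

Breeding values are plain ``numpy`` arrays whose last axis has length 2 in
the order ``(maternal, direct)``; all samplers are vectorized over leading
axes.  :class:`BreedingValue` is a scalar convenience view.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

__all__ = [
    "MATERNAL",
    "DIRECT",
    "VarianceComponents",
    "BreedingValue",
    "sample_base_queens",
    "mendelian_samples",
    "make_drone_tbv",
    "make_queen_offspring_tbv",
    "worker_group_tbv",
    "total_breeding_value",
    "colony_phenotype",
    "LocusModel",
    "Genotype",
    "init_locus_model",
    "sample_gamete",
    "genotype_tbv",
]

MATERNAL = 0
DIRECT = 1


class BreedingValue(NamedTuple):
    """Scalar (maternal, direct) breeding value in trait units."""

    m: float
    d: float

    @property
    def total(self) -> float:
        return self.m + self.d

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.d], dtype=float)


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    """Additive (co)variances of the maternal/direct effects and the residual.

    Parameters
    ----------
    sigma2_Am, sigma2_Ad : float
        Additive maternal / direct variances (trait units squared).
    sigma_Amd : float
        Additive maternal-direct covariance.  The implied correlation
        ``r_md = sigma_Amd / sqrt(sigma2_Am * sigma2_Ad)`` must lie in
        [-1, 1]; the 2x2 matrix ``Sigma_A`` must be positive semi-definite.
    sigma2_E : float
        Residual variance of the colony phenotype.
    """

    sigma2_Am: float = 1.0
    sigma2_Ad: float = 2.0
    sigma_Amd: float = -0.75
    sigma2_E: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_E < 0:
            raise ValueError("sigma2_E must be non-negative")
        s = self.sigma_A
        if self.sigma2_Am < 0 or self.sigma2_Ad < 0:
            raise ValueError("additive variances must be non-negative")
        # PSD <=> non-negative determinant for a symmetric 2x2 with
        # non-negative diagonal (allow a tiny tolerance for round-off).
        det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        if det < -1e-12 * max(1.0, s[0, 0] * s[1, 1]):
            raise ValueError(
                "Sigma_A is not positive semi-definite "
                f"(sigma_Amd={self.sigma_Amd} too large in magnitude)"
            )

    @property
    def sigma_A(self) -> np.ndarray:
        """The 2x2 additive covariance matrix ``Sigma_A``."""
        return np.array(
            [[self.sigma2_Am, self.sigma_Amd], [self.sigma_Amd, self.sigma2_Ad]]
        )

    @property
    def r_md(self) -> float:
        """Implied maternal-direct genetic correlation."""
        denom = np.sqrt(self.sigma2_Am * self.sigma2_Ad)
        if denom == 0:
            return 0.0
        return self.sigma_Amd / denom

    @property
    def chol(self) -> np.ndarray:
        """A factor ``B`` with ``B @ B.T = Sigma_A`` (PSD-safe)."""
        s = self.sigma_A
        try:
            return np.linalg.cholesky(s)
        except np.linalg.LinAlgError:
            w, vec = np.linalg.eigh(s)
            return vec * np.sqrt(np.clip(w, 0.0, None))


def _phi(shape, vc: VarianceComponents, rng: np.random.Generator) -> np.ndarray:
    """Mendelian sample term(s) ``Phi ~ N(0, Sigma_A)`` of the given leading shape."""
    z = rng.standard_normal(tuple(np.atleast_1d(shape)) + (2,))
    return z @ vc.chol.T


def sample_base_queens(
    n: int, vc: VarianceComponents, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` unrelated, non-inbred base-queen breeding values.

    Returns an ``(n, 2)`` array of independent ``N(0, Sigma_A)`` draws.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return _phi(n, vc, rng)


def mendelian_samples(
    n: int, vc: VarianceComponents, rng: np.random.Generator
) -> np.ndarray:
    """``n`` independent Mendelian-sampling terms ``Phi ~ N(0, Sigma_A)``."""
    return _phi(n, vc, rng)


def _check_f(F) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("inbreeding coefficients must lie in [0, 1]")
    return F


def make_drone_tbv(queen_bv, F_Q, vc: VarianceComponents, rng: np.random.Generator):
    """Breeding value(s) of drone(s) of queen(s) with inbreeding ``F_Q``.

    ``TBV_D = TBV_Q + sqrt(1 - F_Q) * Phi`` on the diploid-equivalent scale.
    Broadcasts over leading axes of ``queen_bv`` (last axis length 2).
    """
    q = np.asarray(queen_bv, dtype=float)
    F = _check_f(F_Q)
    phi = _phi(q.shape[:-1] if q.ndim > 1 else 1, vc, rng).reshape(q.shape)
    return q + np.sqrt(1.0 - F)[..., None] * phi if q.ndim > 1 else (
        q + np.sqrt(1.0 - float(F)) * phi.reshape(2)
    )


def make_queen_offspring_tbv(
    queen_bv, drone_bv, F_Q, vc: VarianceComponents, rng: np.random.Generator
):
    """Breeding value(s) of offspring queen(s) of dam(s) x father drone(s).

    ``TBV_R = (TBV_D + TBV_Q + sqrt(1 - F_Q) * Phi) / 2`` where ``F_Q`` is the
    *dam's* inbreeding coefficient (the drone contributes a fixed gamete, so
    only the dam's side carries Mendelian noise).
    """
    q = np.asarray(queen_bv, dtype=float)
    d = np.asarray(drone_bv, dtype=float)
    F = _check_f(F_Q)
    phi = _phi(q.shape[:-1] if q.ndim > 1 else 1, vc, rng).reshape(q.shape)
    if q.ndim > 1:
        return 0.5 * (d + q + np.sqrt(1.0 - F)[..., None] * phi)
    return 0.5 * (d + q + np.sqrt(1.0 - float(F)) * phi.reshape(2))


def worker_group_tbv(queen_bv, drone_bvs) -> np.ndarray:
    """Worker-group breeding value: mean of the queen's TBV and her mates'.

    ``drone_bvs`` has shape ``(..., k, 2)`` with ``k >= 1`` mates.
    """
    d = np.asarray(drone_bvs, dtype=float)
    if d.ndim < 2 or d.shape[-2] == 0:
        raise ValueError("at least one drone is required for a worker group")
    q = np.asarray(queen_bv, dtype=float)
    return 0.5 * (q + d.mean(axis=-2))


def total_breeding_value(bv) -> np.ndarray:
    """Total breeding value ``m + d`` (the queen-level summary the trajectories track)."""
    return np.asarray(bv, dtype=float).sum(axis=-1)


def colony_phenotype(
    worker_bv, queen_bv, vc: VarianceComponents, rng: np.random.Generator
):
    """One performance record per colony.

    ``y = d(worker group) + m(queen) + e`` with ``e ~ N(0, sigma2_E)``; no
    fixed effects beyond the overall mean handled at evaluation time.
    """
    w = np.asarray(worker_bv, dtype=float)
    q = np.asarray(queen_bv, dtype=float)
    genetic = w[..., DIRECT] + q[..., MATERNAL]
    e = rng.standard_normal(genetic.shape) * np.sqrt(vc.sigma2_E)
    return genetic + e


# ---------------------------------------------------------------------------
# finite-locus alternative
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LocusModel:
    """Unlinked biallelic loci whose summed effects reproduce ``Sigma_A``.

    ``effects[l]`` is the bivariate allele-substitution effect of locus ``l``
    and ``init_freq[l]`` its base allele frequency.  Effects are rescaled at
    construction so that a linkage-equilibrium base population has genetic
    covariance exactly ``Sigma_A``:  ``sum_l 2 p_l q_l a_l a_l^T = Sigma_A``.
    """

    effects: np.ndarray  # (L, 2)
    init_freq: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        if self.effects.ndim != 2 or self.effects.shape[1] != 2:
            raise ValueError("effects must have shape (n_loci, 2)")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if np.any((self.init_freq <= 0) | (self.init_freq >= 1)):
            raise ValueError("initial allele frequencies must lie in (0, 1)")

    @property
    def n_loci(self) -> int:
        return self.effects.shape[0]

    def base_covariance(self) -> np.ndarray:
        w = 2.0 * self.init_freq * (1.0 - self.init_freq)
        return (self.effects.T * w) @ self.effects


@dataclasses.dataclass
class Genotype:
    """Per-locus allele indicators; queens carry two haplotypes, drones one."""

    maternal_haplotype: np.ndarray  # (L,) uint8 in {0, 1}
    paternal_haplotype: np.ndarray | None = None  # queens only

    @property
    def is_queen(self) -> bool:
        return self.paternal_haplotype is not None


def init_locus_model(
    vc: VarianceComponents,
    n_loci: int = 400,
    rng: np.random.Generator | None = None,
    init_freq: float = 0.5,
) -> LocusModel:
    """Draw bivariate locus effects and rescale them to hit ``Sigma_A`` exactly.

    Effects are drawn i.i.d. bivariate normal and then linearly transformed so
    the base-population genetic covariance equals ``Sigma_A`` (to machine
    precision, i.e. well within the 1% tolerance the model promises).  A
    degenerate ``Sigma_A = 0`` yields all-zero effects.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    rng = np.random.default_rng() if rng is None else rng
    freq = np.full(n_loci, float(init_freq))
    raw = rng.standard_normal((n_loci, 2))
    w = 2.0 * freq * (1.0 - freq)
    m = (raw.T * w) @ raw  # realized base covariance of the raw effects
    s = np.asarray(VarianceComponents(
        vc.sigma2_Am, vc.sigma2_Ad, vc.sigma_Amd, vc.sigma2_E
    ).sigma_A)
    if np.allclose(s, 0.0):
        return LocusModel(np.zeros((n_loci, 2)), freq)
    # transform T with T m T' = Sigma_A; both matrices are PD here
    bs = VarianceComponents(vc.sigma2_Am, vc.sigma2_Ad, vc.sigma_Amd, vc.sigma2_E).chol
    bm = np.linalg.cholesky(m)
    t = bs @ np.linalg.inv(bm)
    return LocusModel(raw @ t.T, freq)


def sample_gamete(genotype: Genotype, rng: np.random.Generator) -> np.ndarray:
    """Free-recombination meiosis of a queen: one allele per locus, i.i.d.

    Drones reproduce by clonal copy of their single haplotype, not by
    sampling; calling this on a drone genotype is a domain error.
    """
    if not genotype.is_queen:
        raise ValueError("drones have a single haplotype; copy it instead of sampling")
    pick = rng.integers(0, 2, size=genotype.maternal_haplotype.shape[0])
    return np.where(pick == 0, genotype.maternal_haplotype, genotype.paternal_haplotype).astype(np.uint8)


def genotype_tbv(genotype: Genotype, model: LocusModel) -> np.ndarray:
    """Map a genotype to a breeding value on the diploid-equivalent scale.

    Queens sum both haplotypes; a drone's single haplotype counts twice.
    Allele counts are centered at ``2 * init_freq`` so the base mean is zero.
    """
    if genotype.maternal_haplotype.shape[0] != model.n_loci:
        raise ValueError("genotype locus count does not match the locus model")
    if genotype.is_queen:
        counts = genotype.maternal_haplotype.astype(float) + genotype.paternal_haplotype.astype(float)
    else:
        counts = 2.0 * genotype.maternal_haplotype.astype(float)
    return (counts - 2.0 * model.init_freq) @ model.effects


def haplotypes_tbv(mat: np.ndarray, pat: np.ndarray | None, model: LocusModel) -> np.ndarray:
    """Vectorized :func:`genotype_tbv` over ``(n, L)`` haplotype arrays."""
    if pat is None:
        counts = 2.0 * mat.astype(float)
    else:
        counts = mat.astype(float) + pat.astype(float)
    return (counts - 2.0 * model.init_freq) @ model.effects


def sample_gametes(mat: np.ndarray, pat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized meiosis for ``(n, L)`` queen haplotype arrays."""
    pick = rng.integers(0, 2, size=mat.shape, dtype=np.uint8)
    return np.where(pick == 0, mat, pat)
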