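"""Haplodiploid pedigree bookkeeping and relationship matrices.

Two pedigree views are maintained per simulation run:

* the **full pedigree** knows every queen's actual father drone (and that
  drone's dam).  It provides the *true* inbreeding coefficients that scale
  Mendelian-sampling variance during simulation.  Drones are haploid: a drone
  is a single gamete of his dam, so his two "alleles" coincide and his
  self-relationship on the diploid-equivalent scale is exactly 2.

* the **observed pedigree** contains only what a breeder records: queens with
  their dams, and the mating each queen underwent -- an isolated mating
  station (a sister group of 8 drone-producing queens, DPQ) or an uncontrolled
  mating whose drone dams are unknown and treated as base-population draws.
  This is the view from which the BLUP relationship inverse is built.

Both views are instances of :class:`GeneticGraph`: a DAG in which every node
``i`` satisfies ``a_i = sum_p b_ip a_p + e_i`` with independent residuals of
variance ``v_i`` (in units of the base additive covariance ``Sigma_A``).  The
relationship matrix is then ``A = (I-B)^-1 D (I-B)^-T`` and its sparse inverse
follows Henderson's rule: each node contributes
``(1/v_i) * [1, -b] [1, -b]^T`` on ``(i, parents)``.

Observed-pedigree node rules, derived from the simulation's mating mechanics
(8 equally likely DPQ dams per drone, 12 drones per mating, one father per
daughter, drawn uniformly with replacement):

* base queen: no parents, ``v = 1``;
* mating of a queen on a station with DPQs ``k = 1..8``: the node represents
  the realized mean of her 12 drones; parents are the DPQs with coefficient
  1/8 each and ``v = (2 - A_SS) / 12`` where ``A_SS = mean(A[dpq, dpq])`` is
  the self-relationship of the station average;
* uncontrolled (or base) mating: drone dams unknown, treated as base, so the
  12-drone mean has no parents and ``v = 2/12 = 1/6``;
* queen with dam ``Q`` and dam's mating ``M``:
  parents ``{Q: 1/2, M: 1/2}`` and ``v = (2 - A_MM)/4 + (1 - F_Q)/4``.

Worker groups (``1/2 queen + 1/2 mating``) and station means (mean of the 8
DPQs) are *exact* linear combinations of existing nodes, so they are absorbed
rather than stored as rows (a zero-variance row would make ``A`` singular).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _kernels

__all__ = [
    "GeneticGraph",
    "FullPedigree",
    "ObservedPedigree",
    "SireEntity",
    "true_inbreeding",
    "kinship",
    "kinship_recursive",
    "gene_drop_kinship",
    "build_relationship_dense",
    "build_a_inverse",
    "write_pedigree_csv",
    "read_pedigree_csv",
]

DENSE_CAP = 500


class GeneticGraph:
    """Generalized pedigree: linear recursion with per-node residual variance.

    Stored in amortized growable arrays so that node insertion and kernel
    queries stay O(size actually touched) even for six-figure pedigrees.
    """

    def __init__(self) -> None:
        self._n = 0
        self._ne = 0
        self._nt = 0
        self._indptr = np.zeros(1025, dtype=np.int64)
        self._parents = np.empty(4096, dtype=np.int64)
        self._coefs = np.empty(4096, dtype=np.float64)
        self._v = np.empty(1024, dtype=np.float64)
        # Henderson triplets, accumulated as nodes are added
        self._ti = np.empty(8192, dtype=np.int64)
        self._tj = np.empty(8192, dtype=np.int64)
        self._tx = np.empty(8192, dtype=np.float64)
        # kernel scratch, grown alongside the node arrays
        self._mark = np.zeros(1024, dtype=np.int64)
        self._stack = np.empty(1024, dtype=np.int64)
        self._anc = np.empty(1024, dtype=np.int64)
        self._x = np.zeros(1024, dtype=np.float64)
        self._pos = np.empty(1024, dtype=np.int64)
        self._stamp = 0

    @property
    def n(self) -> int:
        return self._n

    @staticmethod
    def _grow(arr: np.ndarray, need: int, fill=None) -> np.ndarray:
        if need <= arr.shape[0]:
            return arr
        cap = max(need, 2 * arr.shape[0])
        if fill is None:
            new = np.empty(cap, dtype=arr.dtype)
        else:
            new = np.full(cap, fill, dtype=arr.dtype)
        new[: arr.shape[0]] = arr
        return new

    def add(self, parents, coefs, v: float) -> int:
        i = self._n
        if v <= 0:
            raise ValueError(f"node {i}: residual variance must be positive, got {v}")
        parents = list(parents)
        coefs = list(coefs)
        k = len(parents)
        if k != len(coefs):
            raise ValueError("parents and coefs must have equal length")
        for p in parents:
            if not (0 <= p < i):
                raise ValueError(f"node {i}: parent {p} must precede it")
        self._indptr = self._grow(self._indptr, i + 2)
        self._v = self._grow(self._v, i + 1)
        self._parents = self._grow(self._parents, self._ne + k)
        self._coefs = self._grow(self._coefs, self._ne + k)
        self._parents[self._ne : self._ne + k] = parents
        self._coefs[self._ne : self._ne + k] = coefs
        self._ne += k
        self._indptr[i + 1] = self._ne
        self._v[i] = v
        # kernel scratch
        self._mark = self._grow(self._mark, i + 1, fill=0)
        self._stack = self._grow(self._stack, i + 1)
        self._anc = self._grow(self._anc, i + 1)
        self._x = self._grow(self._x, i + 1, fill=0.0)
        self._pos = self._grow(self._pos, i + 1)
        # Henderson contribution (1/v) [1, -b][1, -b]^T on (i, parents)
        w = 1.0 / v
        idx = [i] + parents
        val = [1.0] + [-c for c in coefs]
        m = len(idx) ** 2
        self._ti = self._grow(self._ti, self._nt + m)
        self._tj = self._grow(self._tj, self._nt + m)
        self._tx = self._grow(self._tx, self._nt + m)
        t = self._nt
        for a in range(len(idx)):
            for b in range(len(idx)):
                self._ti[t] = idx[a]
                self._tj[t] = idx[b]
                self._tx[t] = w * val[a] * val[b]
                t += 1
        self._nt = t
        self._n = i + 1
        return i

    # -- kernel plumbing ----------------------------------------------------
    def _views(self):
        n, ne = self._n, self._ne
        return (
            self._indptr[: n + 1],
            self._parents[:ne],
            self._coefs[:ne],
            self._v[:n],
        )

    def a_diagonal_of(self, nodes) -> np.ndarray:
        """A_ii for the given nodes."""
        nodes = np.asarray(nodes, dtype=np.int64)
        if nodes.size == 0:
            return np.empty(0)
        indptr, parents, coefs, v = self._views()
        out, stamp = _kernels.a_self_many(
            indptr, parents, coefs, v, nodes, self._mark, self._stamp,
            self._stack, self._anc, self._x,
        )
        self._stamp = stamp
        return out

    def a_submatrix(self, nodes) -> np.ndarray:
        """Dense relationship block over a small set of distinct nodes."""
        nodes = np.asarray(nodes, dtype=np.int64)
        if np.unique(nodes).size != nodes.size:
            raise ValueError("nodes must be distinct")
        if nodes.size == 0:
            return np.empty((0, 0))
        indptr, parents, coefs, v = self._views()
        self._stamp += 1
        return _kernels.a_cross(
            indptr, parents, coefs, v, nodes, self._mark, self._stamp,
            self._stack, self._anc, self._pos,
        )

    # -- oracles / exports --------------------------------------------------
    def to_dense(self, cap: int = DENSE_CAP) -> np.ndarray:
        """Tabular forward construction of the full relationship matrix.

        Quadratic in pedigree size; reserved for small pedigrees where it
        serves as the oracle against the sparse inverse.
        """
        n = self.n
        if n > cap:
            raise ValueError(f"dense relationship matrix capped at {cap} entities (got {n})")
        a = np.zeros((n, n))
        for i in range(n):
            lo, hi = self._indptr[i], self._indptr[i + 1]
            for k in range(lo, hi):
                a[i, :i] += self._coefs[k] * a[self._parents[k], :i]
            a[:i, i] = a[i, :i]
            aii = self._v[i]
            for k in range(lo, hi):
                aii += self._coefs[k] * a[i, self._parents[k]]
            a[i, i] = aii
        return a

    def a_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of the relationship matrix (Henderson accumulation)."""
        n, nt = self.n, self._nt
        m = sp.coo_matrix(
            (self._tx[:nt], (self._ti[:nt], self._tj[:nt])), shape=(n, n)
        ).tocsr()
        m.sum_duplicates()
        return m

    def parents_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self._indptr[i], self._indptr[i + 1]
        return (
            np.asarray(self._parents[lo:hi], dtype=np.int64),
            np.asarray(self._coefs[lo:hi], dtype=np.float64),
        )

    @property
    def residual_variances(self) -> np.ndarray:
        return np.asarray(self._v[: self._n], dtype=float)


# ---------------------------------------------------------------------------
# full pedigree (simulation truth)
# ---------------------------------------------------------------------------

BASE_QUEEN, QUEEN, DRONE, BASE_DRONE = 0, 1, 2, 3


class FullPedigree:
    """True pedigree with actual father drones; provides exact inbreeding.

    Node kinds: base queen (founder), queen (dam x father drone), drone
    (haploid son of a queen) and base drone (gamete of a virtual base dam,
    used where drones come from outside the recorded population).
    """

    def __init__(self) -> None:
        self.graph = GeneticGraph()
        self.kind: list[int] = []
        self.dam: list[int] = []  # -1 for founders
        self.sire: list[int] = []  # father drone id; -1 if n/a
        self._Fbuf = np.empty(1024)  # cached inbreeding, aligned with nodes

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def _F(self) -> np.ndarray:
        return self._Fbuf[: self.n]

    def _grow_f(self, value: float) -> None:
        i = len(self.kind) - 1
        self._Fbuf = GeneticGraph._grow(self._Fbuf, i + 1)
        self._Fbuf[i] = value

    def add_base_queen(self) -> int:
        i = self.graph.add([], [], 1.0)
        self.kind.append(BASE_QUEEN)
        self.dam.append(-1)
        self.sire.append(-1)
        self._grow_f(0.0)
        return i

    def add_base_drone(self) -> int:
        # one gamete of an unrecorded, non-inbred base dam: A_DD = 2
        i = self.graph.add([], [], 2.0)
        self.kind.append(BASE_DRONE)
        self.dam.append(-1)
        self.sire.append(-1)
        self._grow_f(np.nan)
        return i

    def _dam_f(self, dam: int) -> float:
        if self.kind[dam] not in (BASE_QUEEN, QUEEN):
            raise ValueError("dam must be a queen")
        f = self._F[dam]
        if np.isnan(f):
            f = float(self.compute_inbreeding([dam])[0])
        return f

    def add_drone(self, dam: int) -> int:
        f = self._dam_f(dam)
        i = self.graph.add([dam], [1.0], 1.0 - f)
        self.kind.append(DRONE)
        self.dam.append(dam)
        self.sire.append(-1)
        self._grow_f(np.nan)
        return i

    def add_queen(self, dam: int, father: int) -> int:
        f = self._dam_f(dam)
        if self.kind[father] not in (DRONE, BASE_DRONE):
            raise ValueError("queen father must be a drone")
        i = self.graph.add([dam, father], [0.5, 0.5], 0.25 * (1.0 - f))
        self.kind.append(QUEEN)
        self.dam.append(dam)
        self.sire.append(father)
        self._grow_f(np.nan)
        return i

    def compute_inbreeding(self, nodes) -> np.ndarray:
        """Exact F for the given queen nodes (cached); F = A_ii - 1."""
        nodes = np.asarray(nodes, dtype=np.int64)
        todo = nodes[np.isnan(self._F[nodes])]
        if todo.size:
            self._F[todo] = self.graph.a_diagonal_of(todo) - 1.0
        return self._F[nodes]

    def inbreeding(self, queen_id: int) -> float:
        if not (0 <= queen_id < self.n):
            raise KeyError(f"unknown pedigree id {queen_id}")
        k = self.kind[queen_id]
        if k not in (BASE_QUEEN, QUEEN):
            raise ValueError("inbreeding is defined for queens")
        return float(self.compute_inbreeding([queen_id])[0])

    def kinship(self, a: int, b: int) -> float:
        """Coancestry f(a, b); relationship and kinship relate by A = 2 f."""
        for i in (a, b):
            if not (0 <= i < self.n):
                raise KeyError(f"unknown pedigree id {i}")
        if a == b:
            return float(self.graph.a_diagonal_of([a])[0]) / 2.0
        return float(self.graph.a_submatrix([a, b])[0, 1]) / 2.0


def true_inbreeding(full_pedigree: FullPedigree, queen_id: int) -> float:
    """Inbreeding coefficient of a queen from the full (true) pedigree."""
    return full_pedigree.inbreeding(queen_id)


def kinship(full_pedigree: FullPedigree, id_a: int, id_b: int) -> float:
    """Coancestry of two pedigree entities (kernel-backed)."""
    return full_pedigree.kinship(id_a, id_b)


def kinship_recursive(ped: FullPedigree, a: int, b: int, _memo=None) -> float:
    """Independent recursive kinship oracle (haplodiploid rules).

    Used to cross-validate the back-substitution kernel; quadratic-ish, for
    small pedigrees only.
    """
    if _memo is None:
        _memo = {}
    for i in (a, b):
        if not (0 <= i < ped.n):
            raise KeyError(f"unknown pedigree id {i}")
    if a > b:
        a, b = b, a
    key = (a, b)
    if key in _memo:
        return _memo[key]
    kb = ped.kind[b]
    if a == b:
        if kb in (DRONE, BASE_DRONE):
            val = 1.0
        elif kb == BASE_QUEEN:
            val = 0.5
        else:
            val = 0.5 * (1.0 + kinship_recursive(ped, ped.dam[b], ped.sire[b], _memo))
    else:
        # recurse on the younger (larger id); parents always precede children
        if kb in (BASE_QUEEN, BASE_DRONE):
            val = 0.0
        elif kb == DRONE:
            val = kinship_recursive(ped, a, ped.dam[b], _memo)
        else:
            val = 0.5 * (
                kinship_recursive(ped, a, ped.dam[b], _memo)
                + kinship_recursive(ped, a, ped.sire[b], _memo)
            )
    _memo[key] = val
    return val


def gene_drop_kinship(ped: FullPedigree, pairs, n_reps: int = 100_000, seed: int = 0):
    """Monte-Carlo gene-dropping estimate of kinship for id pairs.

    Drops founder alleles through the actual transmission mechanics (a drone
    is one maternal gamete; a queen receives one maternal gamete plus her
    father drone's allele) and estimates f(a, b) as the probability that a
    random allele of ``a`` is identical by descent to a random allele of
    ``b``.  Returns (estimates, standard errors).
    """
    kinds = np.asarray(ped.kind, dtype=np.int64)
    dam = np.asarray(ped.dam, dtype=np.int64)
    sire = np.asarray(ped.sire, dtype=np.int64)
    a1, a2 = _kernels.gene_drop_full(kinds, dam, sire, n_reps, seed)
    est = []
    se = []
    for (i, j) in pairs:
        if i == j:
            # P(two independent random alleles of i are IBD)
            m = 0.5 * (1.0 + (a1[i] == a2[i]).astype(float))
        else:
            m = 0.25 * (
                (a1[i] == a1[j]).astype(float)
                + (a1[i] == a2[j]).astype(float)
                + (a2[i] == a1[j]).astype(float)
                + (a2[i] == a2[j]).astype(float)
            )
        est.append(m.mean())
        se.append(m.std(ddof=1) / np.sqrt(n_reps))
    return np.asarray(est), np.asarray(se)


# ---------------------------------------------------------------------------
# observed pedigree (BLUP view)
# ---------------------------------------------------------------------------

OBS_BASE_QUEEN, OBS_QUEEN, OBS_MATING_UNKNOWN, OBS_MATING_STATION = 0, 1, 2, 3

UNKNOWN_MATING_V = 2.0 / 12.0  # variance of a mean of 12 unrelated base drones


@dataclasses.dataclass(frozen=True)
class SireEntity:
    """A mating station: a sister group of 8 DPQs providing 12 drones per mating."""

    station_id: int
    dpq_ids: tuple[int, ...]  # observed-pedigree ids of the DPQs
    n_drones_per_mating: int = 12

    def __post_init__(self) -> None:
        if len(self.dpq_ids) != 8:
            raise ValueError("a mating station carries exactly 8 DPQs")


class ObservedPedigree:
    """Breeder-visible pedigree: queens, their dams, and mating events."""

    def __init__(self) -> None:
        self.graph = GeneticGraph()
        self.kind: list[int] = []
        self.dam: list[int] = []
        self.mating: list[int] = []  # the queen's *own* mating node (-1 until mated)
        self.sire_ref: list[int] = []  # station id for station matings; -1 otherwise
        self.birth_year: list[int] = []
        self.a_mm: dict[int, float] = {}  # self-relationship of mating nodes
        self.dpq_station: dict[int, int] = {}  # DPQ node -> station id it serves on
        self._Fbuf = np.empty(1024)

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def _F(self) -> np.ndarray:
        return self._Fbuf[: len(self.kind)]

    def _push(self, kind, dam, sire_ref, year, f) -> None:
        self.kind.append(kind)
        self.dam.append(dam)
        self.mating.append(-1)
        self.sire_ref.append(sire_ref)
        self.birth_year.append(year)
        i = len(self.kind) - 1
        self._Fbuf = GeneticGraph._grow(self._Fbuf, i + 1)
        self._Fbuf[i] = f

    def add_base_queen(self, year: int = 0) -> int:
        i = self.graph.add([], [], 1.0)
        self._push(OBS_BASE_QUEEN, -1, -1, year, 0.0)
        return i

    def add_unknown_mating(self, queen: int) -> int:
        """Mating with unrecorded drone dams (uncontrolled or base)."""
        i = self.graph.add([], [], UNKNOWN_MATING_V)
        self._push(OBS_MATING_UNKNOWN, -1, -1, self.birth_year[queen], np.nan)
        self.a_mm[i] = UNKNOWN_MATING_V
        if self.mating[queen] != -1:
            raise ValueError("queen already mated")
        self.mating[queen] = i
        return i

    def station_row(self, dpq_ids) -> tuple[list[int], list[float], float, float]:
        """Parent row and variance shared by all matings on one station."""
        dpq_ids = list(dpq_ids)
        if len(dpq_ids) != 8:
            raise ValueError("a mating station carries exactly 8 DPQs")
        a8 = self.graph.a_submatrix(dpq_ids)
        a_ss = float(a8.mean())  # self-relationship of the DPQ average
        v = (2.0 - a_ss) / 12.0
        return dpq_ids, [1.0 / 8.0] * 8, v, a_ss

    def add_station_mating(self, queen: int, dpq_ids, station_id: int, _row=None) -> int:
        """Mating of ``queen`` on the station formed by ``dpq_ids``.

        ``_row`` may carry a precomputed :meth:`station_row` result so the
        DPQ relationship block is evaluated once per station and year.
        """
        parents, coefs, v, a_ss = _row if _row is not None else self.station_row(dpq_ids)
        for q in dpq_ids:
            self.dpq_station[q] = station_id
        i = self.graph.add(parents, coefs, v)
        self._push(OBS_MATING_STATION, -1, station_id, self.birth_year[queen], np.nan)
        self.a_mm[i] = a_ss + v
        if self.mating[queen] != -1:
            raise ValueError("queen already mated")
        self.mating[queen] = i
        return i

    def add_queen(self, dam: int, year: int) -> int:
        """Queen with a recorded dam.

        If the dam was mated on a station, the daughter's sire side is the
        dam's mating node (the drone group is identified).  If the dam's
        mating was uncontrolled, the sire is unknown and treated as an
        unrelated base drone: the daughter links to her dam only, and in
        particular shares no recorded sire-side covariance with her full
        sisters or her dam's worker group.
        """
        if self.kind[dam] not in (OBS_BASE_QUEEN, OBS_QUEEN):
            raise ValueError("dam must be a queen")
        m = self.mating[dam]
        if m == -1:
            raise ValueError("dam has no recorded mating")
        f_dam = self._F[dam]
        if np.isnan(f_dam):
            f_dam = float(self.graph.a_diagonal_of([dam])[0] - 1.0)
            self._F[dam] = f_dam
        if self.kind[m] == OBS_MATING_UNKNOWN:
            # father = base drone (A_DD = 2, unrelated): A_RR = 1, F_R = 0
            v = 0.75 - 0.25 * f_dam
            i = self.graph.add([dam], [0.5], v)
            self._push(OBS_QUEEN, dam, -1, year, 0.0)
            return i
        v = 0.25 * (2.0 - self.a_mm[m]) + 0.25 * (1.0 - f_dam)
        i = self.graph.add([dam, m], [0.5, 0.5], v)
        self._push(OBS_QUEEN, dam, self.sire_ref[m], year, np.nan)
        return i

    def compute_inbreeding(self, nodes) -> np.ndarray:
        """Observed-pedigree F (used in the queens' Henderson rows)."""
        nodes = np.asarray(nodes, dtype=np.int64)
        todo = nodes[np.isnan(self._F[nodes])]
        if todo.size:
            self._F[todo] = self.graph.a_diagonal_of(todo) - 1.0
        return self._F[nodes]


def build_relationship_dense(observed, cap: int = DENSE_CAP) -> np.ndarray:
    """Dense relationship matrix (oracle) for a small pedigree view.

    Accepts an :class:`ObservedPedigree`, :class:`FullPedigree` or a raw
    :class:`GeneticGraph`.
    """
    graph = getattr(observed, "graph", observed)
    return graph.to_dense(cap)


def build_a_inverse(observed) -> sp.csr_matrix:
    """Sparse inverse relationship matrix for the BLUP equations."""
    graph = getattr(observed, "graph", observed)
    return graph.a_inverse()


# ---------------------------------------------------------------------------
# gene-dropping oracle for the observed view (station mechanics included)
# ---------------------------------------------------------------------------


def gene_drop_observed(obs: ObservedPedigree, n_reps: int = 20_000, seed: int = 0):
    """Simulate the latent mating mechanics behind an observed pedigree.

    Returns per-node allele arrays: queens -> (n_reps, 2); matings ->
    (n_reps, 12) drone alleles.  Station drones pick a DPQ dam uniformly and
    inherit one of her gametes; a queen's father is drawn uniformly among her
    dam's 12 drones.  Unknown matings yield unrelated founder alleles.
    """
    rng = np.random.default_rng(seed)
    alleles: list[np.ndarray] = []
    counter = [0]

    def fresh(shape):
        lo = counter[0]
        size = int(np.prod(shape))
        counter[0] += size
        return np.arange(lo, lo + size, dtype=np.int64).reshape(shape)

    for i in range(obs.n):
        k = obs.kind[i]
        if k == OBS_BASE_QUEEN:
            alleles.append(fresh((1, 2)) + np.zeros((n_reps, 1), dtype=np.int64))
        elif k == OBS_MATING_UNKNOWN:
            alleles.append(fresh((1, 12)) + np.zeros((n_reps, 1), dtype=np.int64))
        elif k == OBS_MATING_STATION:
            dpqs, _ = obs.graph.parents_of(i)
            dam_pick = rng.integers(0, len(dpqs), size=(n_reps, 12))
            gam = rng.integers(0, 2, size=(n_reps, 12))
            out = np.empty((n_reps, 12), dtype=np.int64)
            for c, q in enumerate(dpqs):
                mask = dam_pick == c
                out[mask] = alleles[q][np.nonzero(mask)[0], gam[mask]]
            alleles.append(out)
        else:  # queen: dam gamete + father drone
            dam = obs.dam[i]
            m = -1 if dam == -1 else obs.mating[dam]
            if dam == -1:
                alleles.append(fresh((1, 2)) + np.zeros((n_reps, 1), dtype=np.int64))
                continue
            gam = rng.integers(0, 2, size=n_reps)
            mat = alleles[dam][np.arange(n_reps), gam]
            if m != -1 and obs.kind[m] == OBS_MATING_STATION:
                # father drawn uniformly among the dam's 12 station drones
                pick = rng.integers(0, 12, size=n_reps)
                pat = alleles[m][np.arange(n_reps), pick]
            else:
                # sire assumed unknown: an unrelated base drone per daughter
                pat = fresh((1,)) + np.zeros(n_reps, dtype=np.int64)
            alleles.append(np.stack([mat, pat], axis=1))
    return alleles


def gene_drop_observed_relationship(obs, pairs, n_reps: int = 20_000, seed: int = 0):
    """Monte-Carlo estimate of observed-view relationship entries A_ij = 2 f_ij."""
    alleles = gene_drop_observed(obs, n_reps, seed)
    est, se = [], []
    for (i, j) in pairs:
        ai, aj = alleles[i], alleles[j]
        if i == j:
            # mean over independent double draws includes the same-slot pairs
            m = (ai[:, :, None] == ai[:, None, :]).mean(axis=(1, 2))
        else:
            m = (ai[:, :, None] == aj[:, None, :]).mean(axis=(1, 2))
        m = 2.0 * m  # A = 2 f
        est.append(m.mean())
        se.append(m.std(ddof=1) / np.sqrt(n_reps))
    return np.asarray(est), np.asarray(se)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_KIND_NAMES = {
    OBS_BASE_QUEEN: "queen",
    OBS_QUEEN: "queen",
    OBS_MATING_UNKNOWN: "sire-entity",
    OBS_MATING_STATION: "sire-entity",
}


def write_pedigree_csv(obs: ObservedPedigree, path) -> None:
    """Write the observed pedigree in the documented CSV dialect.

    Columns ``id, kind, dam_id, sire_ref, birth_year`` ("0" = base/unknown;
    ids are written 1-based so 0 stays a null marker) plus one extension
    column ``mate_ref`` recording the queen's own role in mating events:
    "unknown" or "station:<id>" for her own mating, "dpq:<id>" for the
    station she serves on as a DPQ, "0" otherwise.  The extension makes the
    BLUP relationship graph exactly reconstructible.
    """
    rows = []
    for i in range(obs.n):
        k = obs.kind[i]
        if k in (OBS_MATING_UNKNOWN, OBS_MATING_STATION):
            continue  # mating events are encoded on their queens
        m = obs.mating[i]
        if m != -1 and obs.kind[m] == OBS_MATING_UNKNOWN:
            mate_ref = "unknown"
        elif m != -1:
            mate_ref = f"station:{obs.sire_ref[m]}"
        elif i in obs.dpq_station:
            mate_ref = f"dpq:{obs.dpq_station[i]}"
        else:
            mate_ref = "0"
        sire = obs.sire_ref[i]
        if k == OBS_BASE_QUEEN:
            sire_ref = "0"
        elif sire == -1:
            sire_ref = "unknown"
        else:
            sire_ref = f"station:{sire}"
        rows.append(
            dict(
                id=i + 1,
                kind=_KIND_NAMES[k],
                dam_id=obs.dam[i] + 1 if obs.dam[i] != -1 else 0,
                sire_ref=sire_ref,
                birth_year=obs.birth_year[i],
                mate_ref=mate_ref,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pedigree_csv(path) -> ObservedPedigree:
    """Rebuild an :class:`ObservedPedigree` from the CSV dialect.

    Queens are re-added in id order; each queen's own mating event is rebuilt
    from ``mate_ref`` and station sister groups from the ``dpq:<id>`` tags,
    so the reconstructed graph has the same relationship matrix over queens
    as the one that was written (mating nodes may receive different internal
    ids).
    """
    df = pd.read_csv(path)
    obs = ObservedPedigree()
    id_map: dict[int, int] = {}
    station_dpqs: dict[int, list[int]] = {}
    station_rows: dict[int, tuple] = {}

    for _, row in df.sort_values("id").iterrows():
        year = int(row.birth_year)
        dam_raw = int(row.dam_id)
        if dam_raw == 0:
            i = obs.add_base_queen(year)
        else:
            i = obs.add_queen(id_map[dam_raw], year)
        id_map[int(row.id)] = i
        mref = str(row.mate_ref)
        if mref.startswith("dpq:"):
            station_dpqs.setdefault(int(mref.split(":")[1]), []).append(i)
        elif mref == "unknown":
            obs.add_unknown_mating(i)
        elif mref.startswith("station:"):
            sid = int(mref.split(":")[1])
            if sid not in station_rows:
                station_rows[sid] = obs.station_row(station_dpqs.get(sid, []))
            obs.add_station_mating(i, station_dpqs[sid], sid, _row=station_rows[sid])
    return obs
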