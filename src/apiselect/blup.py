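"""Mixed-model evaluation (BLUP) for the maternal + direct colony trait.

The model for one performance record of a tested queen ``Q`` mated in event
``M`` (her 12-drone group) is

    y = mu + u_m(Q) + u_d(W) + e,        e ~ N(0, sigma2_E),

where the worker group ``W`` is the exact average ``(Q + M) / 2`` of the
queen and her drone group, so the record resolves to

    y = mu + u_m(Q) + (u_d(Q) + u_d(M)) / 2 + e.

Random effects ``u = (u_m, u_d)`` are bivariate per pedigree entity with
``Var(u) = Sigma_A (x) A`` over the *observed* relationship matrix ``A``
(see :mod:`apiselect.pedigree`); variance components are taken as known.
The only fixed effect is the overall mean.  Unknowns are ordered
``[mu, u_m(0..n-1), u_d(0..n-1)]``.

The normal equations are solved with a Jacobi-preconditioned conjugate
gradient to a 1e-8 relative residual (deterministic; an optional warm start
speeds up the yearly re-evaluations), with a sparse direct solve as a
fallback when CG stalls.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .genetics import VarianceComponents
from .pedigree import build_a_inverse

__all__ = ["MixedModelEquations", "EbvTable", "assemble_mme", "solve_mme", "selection_criterion"]


@dataclasses.dataclass
class MixedModelEquations:
    """Assembled sparse normal equations ``coef @ x = rhs``."""

    coef: sp.csr_matrix
    rhs: np.ndarray
    n_entities: int

    def check_symmetry(self, tol: float = 1e-10) -> float:
        d = self.coef - self.coef.T
        return float(np.abs(d.data).max()) if d.nnz else 0.0


@dataclasses.dataclass
class EbvTable:
    """Per-entity maternal/direct EBVs from one evaluation."""

    ebv_m: np.ndarray
    ebv_d: np.ndarray
    mean: float
    year: int | None = None

    def worker_group_ebv(self, queen: int, mating: int) -> tuple[float, float]:
        """EBV of the worker group of a queen and her mating (absorbed entity)."""
        return (
            0.5 * (self.ebv_m[queen] + self.ebv_m[mating]),
            0.5 * (self.ebv_d[queen] + self.ebv_d[mating]),
        )

    def criterion(self, queens, matings) -> np.ndarray:
        """Selection criterion for queens: total EBV of their worker groups."""
        queens = np.asarray(queens, dtype=np.int64)
        matings = np.asarray(matings, dtype=np.int64)
        wm = 0.5 * (self.ebv_m[queens] + self.ebv_m[matings])
        wd = 0.5 * (self.ebv_d[queens] + self.ebv_d[matings])
        return wm + wd

    def to_frame(self, queens, matings) -> pd.DataFrame:
        crit = self.criterion(queens, matings)
        return pd.DataFrame(
            dict(
                id=np.asarray(queens),
                year=self.year,
                ebv_m=self.ebv_m[np.asarray(queens)],
                ebv_d=self.ebv_d[np.asarray(queens)],
                criterion=crit,
            )
        )


def assemble_mme(
    phenotypes,
    a_inverse,
    vc: VarianceComponents,
) -> MixedModelEquations:
    """Assemble the normal equations.

    Parameters
    ----------
    phenotypes : tuple of arrays ``(queen_ids, mating_ids, y)``
        One colony record per tested queen, referencing observed-pedigree
        entity ids.
    a_inverse : sparse matrix or :class:`~apiselect.pedigree.ObservedPedigree`
        Inverse relationship matrix over the ``n`` observed entities.
    vc : VarianceComponents
        Known (co)variances; ``Sigma_A`` must be positive definite.
    """
    ainv = a_inverse if sp.issparse(a_inverse) else build_a_inverse(a_inverse)
    n = ainv.shape[0]
    queen_ids, mating_ids, y = phenotypes
    queen_ids = np.asarray(queen_ids, dtype=np.int64)
    mating_ids = np.asarray(mating_ids, dtype=np.int64)
    y = np.asarray(y, dtype=float)
    if queen_ids.size and (queen_ids.max() >= n or mating_ids.max() >= n):
        raise ValueError("phenotype references an entity missing from the pedigree")

    nrec = y.size
    # design matrix W over [mu, u_m, u_d]
    rows = np.repeat(np.arange(nrec), 4)
    cols = np.empty(4 * nrec, dtype=np.int64)
    vals = np.empty(4 * nrec)
    cols[0::4] = 0
    vals[0::4] = 1.0
    cols[1::4] = 1 + queen_ids
    vals[1::4] = 1.0  # maternal effect of the queen
    cols[2::4] = 1 + n + queen_ids
    vals[2::4] = 0.5  # direct effect: worker group = (queen + mating)/2
    cols[3::4] = 1 + n + mating_ids
    vals[3::4] = 0.5
    w = sp.coo_matrix((vals, (rows, cols)), shape=(nrec, 1 + 2 * n)).tocsr()

    s = vc.sigma_A
    det = s[0, 0] * s[1, 1] - s[0, 1] ** 2
    if det <= 0:
        raise ValueError("BLUP requires a positive-definite Sigma_A")
    sinv = np.array([[s[1, 1], -s[0, 1]], [-s[0, 1], s[0, 0]]]) / det
    lam = vc.sigma2_E if vc.sigma2_E > 0 else 1.0
    g = sp.bmat(
        [
            [lam * sinv[0, 0] * ainv, lam * sinv[0, 1] * ainv],
            [lam * sinv[1, 0] * ainv, lam * sinv[1, 1] * ainv],
        ],
        format="csr",
    )
    coef = (w.T @ w + sp.block_diag([sp.csr_matrix((1, 1)), g], format="csr")).tocsr()
    rhs = w.T @ y
    return MixedModelEquations(coef=coef, rhs=rhs, n_entities=n)


def solve_mme(
    mme: MixedModelEquations,
    tolerance: float = 1e-8,
    x0: np.ndarray | None = None,
    year: int | None = None,
    maxiter: int = 20_000,
) -> EbvTable:
    """Solve the equations to the requested relative residual.

    With no phenotypes the solution is exactly zero.  CG starts at zero (or
    the supplied warm start) and is deterministic; if it fails to reach the
    tolerance a sparse LU factorization finishes the job.
    """
    n = mme.n_entities
    bnorm = np.linalg.norm(mme.rhs)
    if bnorm == 0:
        x = np.zeros(1 + 2 * n)
    else:
        # block-Jacobi preconditioner over the (m, d) pair of each entity;
        # the strong maternal-direct correlation makes the 2x2 coupling the
        # dominant off-diagonal structure
        diag = mme.coef.diagonal()
        d0 = diag[0] if diag[0] > 0 else 1.0
        dm = diag[1 : 1 + n].copy()
        dd = diag[1 + n :].copy()
        dx = mme.coef.diagonal(n)[1 : 1 + n].copy()
        det = dm * dd - dx * dx
        bad = det <= 1e-300
        if np.any(bad):
            dm[bad] = np.where(dm[bad] > 0, dm[bad], 1.0)
            dd[bad] = np.where(dd[bad] > 0, dd[bad], 1.0)
            dx[bad] = 0.0
            det[bad] = dm[bad] * dd[bad]

        def _pre(v):
            out = np.empty_like(v)
            out[0] = v[0] / d0
            vm = v[1 : 1 + n]
            vd = v[1 + n :]
            out[1 : 1 + n] = (dd * vm - dx * vd) / det
            out[1 + n :] = (dm * vd - dx * vm) / det
            return out

        pre = spla.LinearOperator(mme.coef.shape, matvec=_pre)
        x, info = spla.cg(
            mme.coef,
            mme.rhs,
            x0=x0,
            rtol=tolerance,
            atol=0.0,
            maxiter=maxiter,
            M=pre,
        )
        res = np.linalg.norm(mme.coef @ x - mme.rhs) / bnorm
        if info != 0 or res > tolerance * 10:
            try:
                x = spla.splu(mme.coef.tocsc()).solve(mme.rhs)
            except RuntimeError as exc:  # pragma: no cover - singular systems
                raise RuntimeError(
                    f"mixed-model solve failed (cg info={info}, residual={res:.2e})"
                ) from exc
            res = np.linalg.norm(mme.coef @ x - mme.rhs) / bnorm
            if res > tolerance * 10:
                raise RuntimeError(f"mixed-model solve did not converge (residual={res:.2e})")
    return EbvTable(
        ebv_m=x[1 : 1 + n], ebv_d=x[1 + n : 1 + 2 * n], mean=float(x[0]), year=year
    )


def selection_criterion(worker_ebv_m, worker_ebv_d) -> np.ndarray:
    """Sum of the worker group's maternal and direct EBVs (the selection index)."""
    return np.asarray(worker_ebv_m, dtype=float) + np.asarray(worker_ebv_d, dtype=float)
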