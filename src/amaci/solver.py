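"""Mixed-model-equation system container and preconditioned conjugate gradients.

The coefficient matrix of a single-step system is kept in operator form:
a sparse data part (W' R^-1 W), a sparse prior part (random-effect precisions
including G^-1 (x) A^-1), and an optional dense correction on the genotyped
block of the genetic effects (G^-1 (x) (G_w^-1 - A22^-1)).  The dense
correction is never expanded into the sparse matrix; it is applied as two
small matrix products per matvec, which is what makes the genomic systems
tractable at full population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class MMESystem:
    """Symmetric positive (semi)definite mixed model equations C x = rhs."""

    c_data: sp.csr_matrix
    c_prior: sp.csr_matrix
    rhs: np.ndarray
    # genetic-effect layout: trait-major block of n_traits x n_animals starting
    # at gen_offset; needed for the dense correction and the preconditioner
    gen_offset: int = 0
    n_animals: int = 0
    n_traits: int = 0
    ainv_diag: np.ndarray | None = None
    g_inv: np.ndarray | None = None
    # dense single-step correction on the genotyped animals
    g_rows: np.ndarray | None = None  # pedigree positions of genotyped animals
    delta_h: np.ndarray | None = None  # G_w^-1 - A22^-1

    @property
    def n(self) -> int:
        return self.rhs.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.c_data @ v + self.c_prior @ v
        if self.delta_h is not None and len(self.g_rows):
            n, t = self.n_animals, self.n_traits
            V = v[self.gen_offset : self.gen_offset + n * t].reshape(t, n)
            corr = self.g_inv @ V[:, self.g_rows] @ self.delta_h
            block = np.zeros((t, n))
            block[:, self.g_rows] = corr
            out[self.gen_offset : self.gen_offset + n * t] += block.ravel()
        return out

    def diagonal(self) -> np.ndarray:
        d = self.c_data.diagonal() + self.c_prior.diagonal()
        if self.delta_h is not None and len(self.g_rows):
            n, t = self.n_animals, self.n_traits
            add = np.zeros((t, n))
            add[:, self.g_rows] = np.outer(np.diag(self.g_inv), np.diag(self.delta_h))
            d[self.gen_offset : self.gen_offset + n * t] += add.ravel()
        return d

    def to_dense(self) -> np.ndarray:
        """Materialise C (small systems only: oracles and direct solves)."""
        C = (self.c_data + self.c_prior).toarray()
        if self.delta_h is not None and len(self.g_rows):
            n, t = self.n_animals, self.n_traits
            for a in range(t):
                for b in range(t):
                    ra = self.gen_offset + a * n + self.g_rows
                    rb = self.gen_offset + b * n + self.g_rows
                    C[np.ix_(ra, rb)] += self.g_inv[a, b] * self.delta_h
        return C

    # ------------------------------------------------------------------
    def _precond(self):
        """Block-Jacobi preconditioner: one n_traits x n_traits block per
        animal for the genetic effects, scalar Jacobi elsewhere."""
        d = self.c_data.diagonal() + self.c_prior.diagonal()
        n, t = self.n_animals, self.n_traits
        off = self.gen_offset
        if t == 0 or self.g_inv is None:
            safe = np.where(d > 0, d, 1.0)
            return lambda r: r / safe
        blocks = np.einsum("ij,k->kij", self.g_inv, self.ainv_diag).copy()
        if self.delta_h is not None and len(self.g_rows):
            dh = np.diag(self.delta_h)
            blocks[self.g_rows] += np.einsum("ij,k->kij", self.g_inv, dh)
        # data contributions enter the genetic diagonal only
        data_diag = self.c_data.diagonal()[off : off + n * t].reshape(t, n)
        ii = np.arange(t)
        blocks[:, ii, ii] += data_diag.T
        inv_blocks = np.linalg.inv(blocks)
        scalar = np.where(d > 0, d, 1.0)

        def apply(r: np.ndarray) -> np.ndarray:
            z = r / scalar
            R = r[off : off + n * t].reshape(t, n).T  # (n, t)
            Z = np.einsum("kij,kj->ki", inv_blocks, R)
            z[off : off + n * t] = Z.T.ravel()
            return z

        return apply


@dataclass
class SolveInfo:
    iterations: int
    criterion: float
    converged: bool
    relative_residual: float


def solve_pcg(
    system: MMESystem,
    tol: float = 1e-5,
    max_iter: int = 5000,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, SolveInfo]:
    """Preconditioned conjugate gradients on the mixed model equations.

    The convergence criterion is the square root of the relative difference
    between solutions of two consecutive iterations,
    sqrt(sum (x_k - x_{k-1})^2 / sum x_k^2), stopped when below ``tol``.
    """
    b = system.rhs
    precond = system._precond()
    x = np.zeros_like(b) if x0 is None else x0.astype(float).copy()
    r = b - system.matvec(x) if x0 is not None else b.copy()
    z = precond(r)
    p = z.copy()
    rz = float(r @ z)
    criterion = np.inf
    it = 0
    b_norm = float(np.linalg.norm(b)) or 1.0
    for it in range(1, max_iter + 1):
        q = system.matvec(p)
        pq = float(p @ q)
        if pq <= 0:  # numerical breakdown on a PSD system
            break
        alpha = rz / pq
        x += alpha * p
        x_norm = float(np.linalg.norm(x))
        criterion = abs(alpha) * float(np.linalg.norm(p)) / (x_norm or 1.0)
        if criterion < tol:
            break
        r -= alpha * q
        if float(np.linalg.norm(r)) == 0.0:  # exact solution reached
            criterion = 0.0
            break
        z = precond(r)
        rz_new = float(r @ z)
        if rz_new <= 0:
            criterion = 0.0 if rz_new == 0 else criterion
            break
        p = z + (rz_new / rz) * p
        rz = rz_new
    rel_res = float(np.linalg.norm(b - system.matvec(x))) / b_norm
    converged = criterion < tol
    if not converged:
        raise RuntimeError(
            f"PCG did not converge in {max_iter} iterations "
            f"(criterion {criterion:.3e})"
        )
    return x, SolveInfo(it, criterion, converged, rel_res)


def solve_direct(system: MMESystem) -> tuple[np.ndarray, SolveInfo]:
    """Dense factorisation of the MME; intended for small systems."""
    C = system.to_dense()
    x = np.linalg.solve(C, system.rhs)
    rel = float(
        np.linalg.norm(system.rhs - C @ x) / (np.linalg.norm(system.rhs) or 1.0)
    )
    return x, SolveInfo(iterations=0, criterion=0.0, converged=True, relative_residual=rel)
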