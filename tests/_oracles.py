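"""Independent reference implementations used only by the tests.

Everything here is deliberately written along a different computational route
from the package: the relationship matrix by the dense tabular recursion
(not Henderson's sparse inverse), H from its covariance-block formula (not
the sparse H-inverse correction), and the mixed model equations as dense
matrices with animal-major genetic ordering (the package is trait-major),
solved by LAPACK.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Requires a topologically sorted pedigree (parents before offspring);
    unknown parents are -1.
    """
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def dense_h(A: np.ndarray, g_idx: np.ndarray, g_w: np.ndarray) -> np.ndarray:
    """Combined pedigree-genomic relationship matrix from its covariance form.

    With blocks ordered (ungenotyped 1, genotyped 2):
    H11 = A11 + A12 A22^-1 (G_w - A22) A22^-1 A21, H12 = A12 A22^-1 G_w,
    H22 = G_w; assembled back into pedigree order.
    """
    n = A.shape[0]
    g_idx = np.asarray(g_idx)
    n_idx = np.setdiff1d(np.arange(n), g_idx)
    A11 = A[np.ix_(n_idx, n_idx)]
    A12 = A[np.ix_(n_idx, g_idx)]
    A22 = A[np.ix_(g_idx, g_idx)]
    A22inv = np.linalg.inv(A22)
    P = A12 @ A22inv
    H = np.zeros_like(A)
    H[np.ix_(n_idx, n_idx)] = A11 + P @ (g_w - A22) @ P.T
    H[np.ix_(n_idx, g_idx)] = P @ g_w
    H[np.ix_(g_idx, n_idx)] = (P @ g_w).T
    H[np.ix_(g_idx, g_idx)] = g_w
    return H


def j_vector(A: np.ndarray, g_idx: np.ndarray) -> np.ndarray:
    """Compatibility covariates from the dense relationship matrix:
    J = A[:, g] A_gg^-1 (-1), which is -1 at genotyped animals and the
    parent average at non-ancestors."""
    x = np.linalg.solve(A[np.ix_(g_idx, g_idx)], -np.ones(len(g_idx)))
    return A[:, g_idx] @ x


def oracle_solve(
    phenotypes: pd.DataFrame,
    ped_table: pd.DataFrame,
    vc,
    genotypes=None,
    fit_pe: bool = True,
    fit_herd: bool = True,
):
    """Dense GLS solve of the multi-country maternal-effects MME.

    Builds every matrix with explicit loops and animal-major genetic
    ordering, computes H from :func:`dense_h` when genotypes are given, and
    returns named solutions (fixed effects, direct/maternal EBV with the
    genomic-EBV correction applied, J coefficients).
    """
    countries = list(vc.countries)
    c = len(countries)
    animals = list(ped_table["animal"])
    pos = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    sire = np.array([pos.get(s, -1) for s in ped_table["sire"]])
    dam = np.array([pos.get(d, -1) for d in ped_table["dam"]])
    A = tabular_a(sire, dam)

    J = None
    g_idx = None
    if genotypes is not None and genotypes.n_animals > 0:
        g_idx = np.array([pos[a] for a in genotypes.animal_ids])
        dosage = genotypes.dosage.astype(float)
        p = dosage.mean(axis=0) / 2.0
        z = dosage - 2.0 * p
        g_star = z @ z.T / (2.0 * np.sum(p * (1.0 - p)))
        A22 = A[np.ix_(g_idx, g_idx)]
        w = vc.residual_polygenic_fraction
        g_w = (1.0 - w) * g_star + w * A22
        H = dense_h(A, g_idx, g_w)
        J = j_vector(A, g_idx)
        K = H
    else:
        K = A
    Kinv = np.linalg.inv(K)
    Ginv = np.linalg.inv(vc.g)

    # fixed-effect columns
    recs = phenotypes.reset_index(drop=True)
    n_rec = len(recs)
    fixed_names: list[str] = []
    fixed_cols: list[np.ndarray] = []
    present = [ctry for ctry in countries if (recs["country"] == ctry).any()]
    for ctry in present:
        fixed_names.append(f"mu_{ctry}")
        fixed_cols.append((recs["country"] == ctry).to_numpy(float))
    for ctry in present:
        in_c = recs["country"] == ctry
        for lev in sorted(set(recs.loc[in_c, "sex"]))[1:]:
            fixed_names.append(f"sex_{ctry}_{lev}")
            fixed_cols.append((in_c & (recs["sex"] == lev)).to_numpy(float))
    if J is not None:
        j_dir = np.array([J[pos[a]] for a in recs["animal"].astype(str)])
        j_mat = np.array(
            [
                J[dam[pos[a]]] if dam[pos[a]] >= 0 else 0.0
                for a in recs["animal"].astype(str)
            ]
        )
        fixed_names += ["j_direct", "j_maternal"]
        fixed_cols += [j_dir, j_mat]
    X = np.column_stack(fixed_cols)

    # herd and PE levels
    herd_levels, pe_levels = [], []
    if fit_herd and "herd" in recs.columns:
        herd_levels = sorted(
            {(ct, h) for ct, h in zip(recs["country"], recs["herd"].astype(str))}
        )
    for r in range(n_rec):
        a = pos[str(recs.loc[r, "animal"])]
        if fit_pe and dam[a] >= 0:
            key = (recs.loc[r, "country"], dam[a])
            if key not in pe_levels:
                pe_levels.append(key)
    pe_levels = sorted(pe_levels)

    n_fix, n_h, n_pe = X.shape[1], len(herd_levels), len(pe_levels)
    n_gen = n * 2 * c  # animal-major: u[k, t]
    N = n_fix + n_h + n_gen + n_pe
    W = np.zeros((n_rec, N))
    W[:, :n_fix] = X
    rinv = np.zeros(n_rec)
    for r in range(n_rec):
        ctry = recs.loc[r, "country"]
        ci = countries.index(ctry)
        a = pos[str(recs.loc[r, "animal"])]
        rinv[r] = 1.0 / vc.residual_variance[ci]
        if fit_herd and "herd" in recs.columns:
            W[r, n_fix + herd_levels.index((ctry, str(recs.loc[r, "herd"])))] = 1.0
        W[r, n_fix + n_h + a * 2 * c + ci] = 1.0
        if dam[a] >= 0:
            W[r, n_fix + n_h + dam[a] * 2 * c + c + ci] = 1.0
            if fit_pe:
                W[r, n_fix + n_h + n_gen + pe_levels.index((ctry, dam[a]))] = 1.0

    C = (W * rinv[:, None]).T @ W
    y = recs["y"].to_numpy(float)
    rhs = (W * rinv[:, None]).T @ y
    prior = np.zeros((N, N))
    for i, (ctry, _) in enumerate(herd_levels):
        prior[n_fix + i, n_fix + i] = 1.0 / vc.herd_variance[countries.index(ctry)]
    prior[n_fix + n_h : n_fix + n_h + n_gen,
          n_fix + n_h : n_fix + n_h + n_gen] = np.kron(Kinv, Ginv)
    for i, (ctry, _) in enumerate(pe_levels):
        k = n_fix + n_h + n_gen + i
        prior[k, k] = 1.0 / vc.pe_variance[countries.index(ctry)]
    sol = np.linalg.solve(C + prior, rhs)

    fixed = dict(zip(fixed_names, sol[:n_fix]))
    u = sol[n_fix + n_h : n_fix + n_h + n_gen].reshape(n, 2 * c)
    direct = u[:, :c].copy()
    maternal = u[:, c:].copy()
    if J is not None:
        direct += np.outer(J, np.ones(c)) * fixed["j_direct"]
        maternal += np.outer(J, np.ones(c)) * fixed["j_maternal"]
    return {
        "fixed": fixed,
        "direct": direct,
        "maternal": maternal,
        "animals": animals,
        "A": A,
    }
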