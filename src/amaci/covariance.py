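"""Across-country genetic covariance structure.

Each of the c countries is modelled as a correlated trait, twice over: once
for the direct genetic effect and once for the maternal genetic effect.  The
2c x 2c genetic covariance matrix is G = S Phi S, where S is the diagonal
matrix of national genetic standard deviations (kg) and Phi the across-country
genetic correlation matrix assembled from pairwise bivariate estimates.  An
assembled Phi is frequently not positive definite; ``bend`` repairs it by
eigenvalue replacement with rescaling back to a correlation matrix.

Trait ordering is fixed everywhere in the package as
``(direct: country 1..c, maternal: country 1..c)`` so that G partitions as
``[[G_dd, G_dm], [G_md, G_mm]]``; the Kronecker products G (x) A and
G (x) H in the evaluations follow the same ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def trait_labels(countries) -> list[str]:
    """Direct then maternal trait labels, e.g. ['AAA_d', 'BBB_d', 'AAA_m', ...]."""
    return [f"{c}_d" for c in countries] + [f"{c}_m" for c in countries]


def assemble_phi(countries, pairwise: dict) -> np.ndarray:
    """Build the 2c x 2c correlation matrix from pairwise estimates.

    ``pairwise`` maps (trait_i, trait_j) labels to a correlation; one entry is
    required per unordered off-diagonal pair.  Supplying both orientations
    with different values is an error, as is a missing pair or |r| > 1.
    """
    labels = trait_labels(countries)
    t = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    phi = np.eye(t)
    seen: dict[tuple[int, int], float] = {}
    for (a, b), r in pairwise.items():
        if a not in pos or b not in pos:
            raise KeyError(f"unknown trait label in pair ({a}, {b})")
        i, j = pos[a], pos[b]
        if i == j:
            if r != 1.0:
                raise ValueError(f"diagonal entry for {a} must be 1")
            continue
        if abs(r) > 1.0:
            raise ValueError(f"|r| > 1 for pair ({a}, {b}): {r}")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != r:
            raise ValueError(f"inconsistent duplicate entry for pair ({a}, {b})")
        seen[key] = r
        phi[i, j] = phi[j, i] = r
    missing = [
        (labels[i], labels[j])
        for i in range(t)
        for j in range(i + 1, t)
        if (i, j) not in seen
    ]
    if missing:
        raise ValueError(f"missing correlation for pairs: {missing[:5]} ...")
    return phi


def bend(
    phi: np.ndarray, eigen_floor: float = 1e-4, max_iter: int = 100
) -> np.ndarray:
    """Repair a non-positive-definite correlation matrix.

    Eigenvalues below ``eigen_floor`` are replaced by a strictly descending
    sequence bounded below by the floor (preserving the descending eigenvalue
    order); the matrix is reconstructed and rescaled back to unit diagonal.
    Rescaling can reintroduce tiny negative eigenvalues, so the procedure
    iterates until the minimum eigenvalue is at least the floor.  An input
    that is already positive definite with min eigenvalue >= floor is
    returned unchanged.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("phi must be square")
    if not np.allclose(phi, phi.T, atol=1e-12):
        raise ValueError("phi must be symmetric")
    if not np.allclose(np.diag(phi), 1.0, atol=1e-12):
        raise ValueError("phi must have unit diagonal")

    out = phi.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= eigen_floor:
            return out
        order = np.argsort(vals)[::-1]  # descending
        vals_d = vals[order]
        deficient = np.flatnonzero(vals_d < eigen_floor)
        n_def = len(deficient)
        # strictly descending replacements, all >= eigen_floor
        repl = eigen_floor * (1.0 + 0.01 * np.arange(n_def, 0, -1))
        vals_d[deficient] = repl
        fixed = (vecs[:, order] * vals_d) @ vecs[:, order].T
        d = np.sqrt(np.diag(fixed))
        out = fixed / np.outer(d, d)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
    vals = np.linalg.eigvalsh(out)
    if vals.min() < eigen_floor:  # pragma: no cover - defensive
        raise RuntimeError("bending did not converge in max_iter iterations")
    return out


def build_g(s: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Genetic covariance G = S Phi S with S = diag(s), s in kg."""
    s = np.asarray(s, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if s.ndim != 1 or phi.shape != (s.size, s.size):
        raise ValueError("dimension mismatch between S and phi")
    if np.any(s <= 0):
        raise ValueError("national genetic standard deviations must be positive")
    return phi * np.outer(s, s)


@dataclass
class VarianceComponents:
    """National variance components feeding the evaluations.

    All SDs in kg, variances in kg^2.  ``phi`` is bent on construction if
    needed so that G = S Phi S is positive definite.
    """

    countries: list[str]
    genetic_sd_direct: np.ndarray
    genetic_sd_maternal: np.ndarray
    phi: np.ndarray
    herd_variance: np.ndarray
    pe_variance: np.ndarray
    residual_variance: np.ndarray
    residual_polygenic_fraction: float = 0.05
    eigen_floor: float = 1e-4
    g: np.ndarray = field(init=False)

    def __post_init__(self):
        c = len(self.countries)
        self.genetic_sd_direct = np.asarray(self.genetic_sd_direct, float)
        self.genetic_sd_maternal = np.asarray(self.genetic_sd_maternal, float)
        self.herd_variance = np.asarray(self.herd_variance, float)
        self.pe_variance = np.asarray(self.pe_variance, float)
        self.residual_variance = np.asarray(self.residual_variance, float)
        for name in ("genetic_sd_direct", "genetic_sd_maternal",
                     "herd_variance", "pe_variance", "residual_variance"):
            arr = getattr(self, name)
            if arr.shape != (c,):
                raise ValueError(f"{name} must have one entry per country")
        if np.any(self.herd_variance < 0) or np.any(self.pe_variance < 0):
            raise ValueError("variances must be non-negative")
        if np.any(self.residual_variance < 0):
            # zero is allowed (noise-free simulation limit); the evaluation
            # models require strictly positive residuals and check themselves
            raise ValueError("residual variances must be non-negative")
        if not 0.0 <= self.residual_polygenic_fraction <= 1.0:
            raise ValueError("residual_polygenic_fraction must be in [0, 1]")
        self.phi = bend(np.asarray(self.phi, float), self.eigen_floor)
        self.g = build_g(self.s_diag, self.phi)
        np.linalg.cholesky(self.g)  # PD guarantee after bending

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def s_diag(self) -> np.ndarray:
        """The 2c national genetic SDs in trait order (direct, then maternal)."""
        return np.concatenate([self.genetic_sd_direct, self.genetic_sd_maternal])

    @property
    def trait_labels(self) -> list[str]:
        return trait_labels(self.countries)

    def for_country(self, country: str) -> "VarianceComponents":
        """Single-country components (2 x 2 genetic block), for national runs."""
        i = self.countries.index(country)
        c = self.n_countries
        idx = [i, c + i]
        return VarianceComponents(
            countries=[country],
            genetic_sd_direct=self.genetic_sd_direct[[i]],
            genetic_sd_maternal=self.genetic_sd_maternal[[i]],
            phi=self.phi[np.ix_(idx, idx)],
            herd_variance=self.herd_variance[[i]],
            pe_variance=self.pe_variance[[i]],
            residual_variance=self.residual_variance[[i]],
            residual_polygenic_fraction=self.residual_polygenic_fraction,
            eigen_floor=self.eigen_floor,
        )
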