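"""Genomic relationship matrices, PCA and pedigree-genomic diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def allele_frequencies(
    geno: GenotypeMatrix, allow_all_missing: bool = False
) -> np.ndarray:
    """Observed allele frequency per SNP: p_j = mean non-missing dosage / 2."""
    d = geno.dosage
    called = d != MISSING
    n = called.sum(axis=0)
    if not allow_all_missing and np.any(n == 0):
        raise ValueError("SNP with all calls missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, d.clip(min=0).sum(axis=0) / (2 * np.maximum(n, 1)), 0.0)
    return p


@dataclass
class GRM:
    """Genomic relationship matrix for the genotyped animals."""

    animal_ids: np.ndarray
    values: np.ndarray
    method: str
    allele_freqs: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.triu_indices(len(self.animal_ids))
        return pd.DataFrame(
            {
                "id1": self.animal_ids[i],
                "id2": self.animal_ids[j],
                "value": self.values[i, j],
            }
        )


def grm(
    dosage: np.ndarray,
    p: np.ndarray,
    animal_ids,
    method: str = "vanraden2",
) -> GRM:
    """Genomic relationship matrix from a complete dosage matrix.

    With Z = M - 2p (column-centred dosages):

    * ``vanraden1``: G = Z Z' / (2 sum_j p_j (1 - p_j))
    * ``vanraden2``: G = (1/m) sum_j z_j z_j' / (2 p_j (1 - p_j)),
      i.e. each SNP standardised to unit variance before averaging.

    Method 2 requires every SNP to be polymorphic (0 < p_j < 1).
    """
    dosage = np.asarray(dosage, dtype=float)
    p = np.asarray(p, dtype=float)
    z = dosage - 2.0 * p
    het = 2.0 * p * (1.0 - p)
    if method == "vanraden1":
        denom = het.sum()
        if denom <= 0:
            raise ValueError("all SNPs monomorphic")
        values = z @ z.T / denom
    elif method == "vanraden2":
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("monomorphic SNP not allowed under VanRaden method 2")
        zs = z / np.sqrt(het)
        values = zs @ zs.T / dosage.shape[1]
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    return GRM(
        animal_ids=np.asarray(animal_ids).astype(str),
        values=values,
        method=method,
        allele_freqs=p,
    )


def pca_grm(g: GRM | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the GRM with explained-variance fractions.

    Returns (components, eigenvalues, explained) where ``components`` is
    n x k.  Explained variance is lambda_i / sum of non-negative eigenvalues.
    Sign convention: the largest-magnitude loading of each component is
    positive, so the decomposition is deterministic.
    """
    values = g.values if isinstance(g, GRM) else np.asarray(g, dtype=float)
    n = values.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds GRM dimension {n}")
    vals, vecs = np.linalg.eigh(values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    top_vals, top_vecs = vals[:k], vecs[:, :k].copy()
    for j in range(k):
        lead = np.argmax(np.abs(top_vecs[:, j]))
        if top_vecs[lead, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    denom = np.clip(vals, 0.0, None).sum()
    explained = top_vals / denom if denom > 0 else np.zeros(k)
    return top_vecs, top_vals, explained


def ped_gen_consistency(
    g: GRM, a_values: np.ndarray, threshold: float = 0.4
) -> pd.DataFrame:
    """Pairs whose genomic and pedigree relationships disagree.

    The machine analogue of visually screening a genomic-vs-pedigree
    relationship plot: returns every (ordered once) pair with
    |g_ij - a_ij| > threshold, including the diagonal.
    """
    a_values = np.asarray(a_values, dtype=float)
    if a_values.shape != g.values.shape:
        raise ValueError("GRM and pedigree block dimensions differ")
    diff = g.values - a_values
    i, j = np.triu_indices(len(g.animal_ids))
    mask = np.abs(diff[i, j]) > threshold
    return pd.DataFrame(
        {
            "id1": g.animal_ids[i[mask]],
            "id2": g.animal_ids[j[mask]],
            "genomic": g.values[i[mask], j[mask]],
            "pedigree": a_values[i[mask], j[mask]],
        }
    )
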