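"""Phenotype outlier filtering and the genotype QC cascade.

The cascade mirrors routine practice for multi-panel SNP data entering a
single-step evaluation: merge panels on a selected SNP set, drop SNPs with an
excess of Mendelian conflicts, sever pedigree links contradicted by the
genotypes, then apply per-SNP call-rate / Hardy-Weinberg / minor-allele
frequency filters (in that order) and per-animal filters, and finally fill
any remaining missing calls with their expected dosage.  Filter order
matters and re-running the full cascade on its own output removes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree
from .relationships import allele_frequencies


@dataclass
class QCReport:
    """Audit trail of the cascade: what was removed and why."""

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_animals: list[tuple[str, str]] = field(default_factory=list)
    severed_links: list[tuple[str, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed_snps:
            out[f"snp:{reason}"] = out.get(f"snp:{reason}", 0) + 1
        for _, reason in self.removed_animals:
            out[f"animal:{reason}"] = out.get(f"animal:{reason}", 0) + 1
        out["severed_links"] = len(self.severed_links)
        return out

    def to_tsv(self, path) -> None:
        rows = (
            [("snp", i, r) for i, r in self.removed_snps]
            + [("animal", i, r) for i, r in self.removed_animals]
            + [("link", f"{o}|{p}", "parent_offspring_conflict")
               for o, p in self.severed_links]
        )
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def filter_phenotype_outliers(
    phenotypes: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records beyond k phenotypic SD of their population-sex mean.

    The mean and SD of each (country, sex) group are computed once, before
    any removal (a single pass, no re-iteration); a record is discarded iff
    |y - mean| > k * sd, strictly.  Groups with fewer than two records pass
    through untouched, as does a zero-SD group.
    """
    df = phenotypes.copy()
    if df.empty:
        return df, df.iloc[0:0]
    stats_ = df.groupby(["country", "sex"])["y"].agg(["mean", "std", "count"])
    merged = df.join(stats_, on=["country", "sex"])
    sd = merged["std"].fillna(0.0)
    out = (merged["count"] >= 2) & ((merged["y"] - merged["mean"]).abs() > k * sd)
    out = out.fillna(False).to_numpy(dtype=bool)
    return df.loc[~out], df.loc[out]


# ---------------------------------------------------------------------------
# panel merging
# ---------------------------------------------------------------------------

def merge_panels(panels: list[GenotypeMatrix], selected_snps) -> GenotypeMatrix:
    """Merge per-country panels onto a selected SNP set.

    Each panel keeps the intersection of its SNPs with ``selected_snps``;
    animals are the union across panels; positions not assayed by an animal's
    panel are missing.  Duplicated SNP positions within a panel are dropped
    with a warning; a duplicate animal across panels is an error.
    """
    selected = [str(s) for s in selected_snps]
    sel_pos = {s: j for j, s in enumerate(selected)}
    all_ids: list[str] = []
    rows: list[np.ndarray] = []
    prov: list[str] = []
    breed: list[float] = []
    for panel in panels:
        pos_counts = pd.Series(panel.snp_positions).value_counts()
        dup_pos = set(pos_counts.index[pos_counts > 1])
        if dup_pos:
            warnings.warn(
                f"dropping {sum(pos_counts[pos_counts > 1])} SNPs at duplicated "
                "positions within a panel"
            )
        keep = np.array(
            [
                (p not in dup_pos) and (s in sel_pos)
                for s, p in zip(panel.snp_ids, panel.snp_positions)
            ]
        )
        sub = panel.subset(snps=keep)
        cols = np.array([sel_pos[s] for s in sub.snp_ids], dtype=np.int64)
        block = np.full((sub.n_animals, len(selected)), MISSING, dtype=np.int8)
        block[:, cols] = sub.dosage
        for a in sub.animal_ids:
            if a in all_ids:
                raise ValueError(f"duplicate animal id across panels: {a}")
        all_ids.extend(sub.animal_ids)
        rows.append(block)
        prov.extend(sub.provenance_country)
        breed.extend(sub.breed_fraction)
    return GenotypeMatrix(
        animal_ids=np.array(all_ids),
        snp_ids=np.array(selected),
        dosage=np.vstack(rows) if rows else np.zeros((0, len(selected)), np.int8),
        provenance_country=np.array(prov),
        breed_fraction=np.array(breed),
    )


# ---------------------------------------------------------------------------
# Mendelian-conflict filters
# ---------------------------------------------------------------------------

def _genotyped_pairs(geno: GenotypeMatrix, ped: Pedigree):
    """(offspring_row, parent_row, offspring_id, parent_id) for genotyped pairs."""
    gpos = {a: i for i, a in enumerate(geno.animal_ids)}
    pairs = []
    tab = ped.table
    for _, rec in tab.iterrows():
        o = rec["animal"]
        if o not in gpos:
            continue
        for parent in (rec["sire"], rec["dam"]):
            if parent != UNKNOWN and parent in gpos:
                pairs.append((gpos[o], gpos[parent], o, parent))
    return pairs


def mendelian_snp_filter(
    geno: GenotypeMatrix, ped: Pedigree, threshold: float = 0.01
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs with an excess of parent-offspring conflicts.

    A conflict at a SNP is a pair of opposing homozygotes (0 vs 2).  A SNP is
    removed iff its conflict count strictly exceeds ``threshold`` times the
    number of pairs with both genotypes called at that SNP.
    """
    pairs = _genotyped_pairs(geno, ped)
    if not pairs:
        return geno, []
    o_idx = np.array([p[0] for p in pairs])
    p_idx = np.array([p[1] for p in pairs])
    go, gp = geno.dosage[o_idx], geno.dosage[p_idx]
    both = (go != MISSING) & (gp != MISSING)
    conflict = (((go == 0) & (gp == 2)) | ((go == 2) & (gp == 0))) & both
    n_conf = conflict.sum(axis=0)
    n_pairs = both.sum(axis=0)
    removed_mask = n_conf > threshold * n_pairs
    removed = list(geno.snp_ids[removed_mask])
    return geno.subset(snps=~removed_mask), removed


def parent_offspring_conflicts(
    geno: GenotypeMatrix, ped: Pedigree, threshold: float = 0.01
) -> tuple[list[tuple[str, str]], Pedigree]:
    """Sever pedigree links contradicted by the genotypes.

    A pair is flagged iff its count of opposing-homozygote SNPs strictly
    exceeds ``threshold`` times the SNPs called in both animals; flagged
    links are severed by setting the offspring's parent to missing.  Run
    after :func:`mendelian_snp_filter`.
    """
    pairs = _genotyped_pairs(geno, ped)
    severed: list[tuple[str, str]] = []
    if pairs:
        o_idx = np.array([p[0] for p in pairs])
        p_idx = np.array([p[1] for p in pairs])
        go, gp = geno.dosage[o_idx], geno.dosage[p_idx]
        both = (go != MISSING) & (gp != MISSING)
        conflict = (((go == 0) & (gp == 2)) | ((go == 2) & (gp == 0))) & both
        n_conf = conflict.sum(axis=1)
        n_shared = both.sum(axis=1)
        for (o_row, p_row, o, parent), c, s in zip(pairs, n_conf, n_shared):
            if c > threshold * s:
                severed.append((o, parent))
    if not severed:
        return severed, ped
    tab = ped.table.copy()
    for o, parent in severed:
        row = tab["animal"] == o
        tab.loc[row & (tab["sire"] == parent), "sire"] = UNKNOWN
        tab.loc[row & (tab["dam"] == parent), "dam"] = UNKNOWN
    return severed, Pedigree(tab)


# ---------------------------------------------------------------------------
# per-SNP and per-animal QC
# ---------------------------------------------------------------------------

def hwe_chi2_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """1-df Pearson chi-square p-values of genotype counts vs HWE expectation.

    Expected counts come from the observed allele frequency of the
    non-missing calls; no continuity correction.  A monomorphic SNP has a
    chi-square of 0 (p = 1) by convention.
    """
    d = geno.dosage
    called = d != MISSING
    n0 = ((d == 0) & called).sum(axis=0).astype(float)
    n1 = ((d == 1) & called).sum(axis=0).astype(float)
    n2 = ((d == 2) & called).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
    chi2 = np.zeros(geno.n_snps)
    for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (obs - exp) ** 2 / exp
        chi2 += np.where((exp > 0) & np.isfinite(term), term, 0.0)
    chi2 = np.where(n > 0, chi2, 0.0)
    return stats.chi2.sf(chi2, df=1)


def snp_qc(
    geno: GenotypeMatrix,
    call_rate: float = 0.95,
    hwe_p: float = 1e-15,
    maf: float = 0.01,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Per-SNP filters, applied in order: call rate, HWE, then MAF.

    Call rate >= 0.95 is inclusive; the HWE p-value must be strictly greater
    than 1e-15 and the minor allele frequency strictly greater than 0.01.
    Each filter is computed on the matrix surviving the previous one.
    """
    report = report if report is not None else QCReport()
    keep = geno.snp_call_rate() >= call_rate
    for s in geno.snp_ids[~keep]:
        report.removed_snps.append((s, "call_rate"))
    geno = geno.subset(snps=keep)

    keep = hwe_chi2_pvalues(geno) > hwe_p
    for s in geno.snp_ids[~keep]:
        report.removed_snps.append((s, "hwe"))
    geno = geno.subset(snps=keep)

    p = allele_frequencies(geno, allow_all_missing=True)
    maf_obs = np.minimum(p, 1.0 - p)
    keep = maf_obs > maf
    for s in geno.snp_ids[~keep]:
        report.removed_snps.append((s, "maf"))
    geno = geno.subset(snps=keep)
    return geno, report


def animal_qc(
    geno: GenotypeMatrix,
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    call_rate: float = 0.90,
    breed_min: float = 0.875,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Per-animal filters: call rate, breed composition, informativeness.

    Removes animals with call rate < 0.90 or pedigree-based breed fraction
    < 0.875, and animals lacking all three of phenotype, progeny and a known
    parent (their genotype would be disconnected from the evaluation).
    """
    report = report if report is not None else QCReport()
    keep = np.ones(geno.n_animals, dtype=bool)

    low_cr = geno.animal_call_rate() < call_rate
    for a in geno.animal_ids[low_cr & keep]:
        report.removed_animals.append((a, "call_rate"))
    keep &= ~low_cr

    low_breed = geno.breed_fraction < breed_min
    for a in geno.animal_ids[low_breed & keep]:
        report.removed_animals.append((a, "breed_fraction"))
    keep &= ~low_breed

    phen_ids = set(phenotypes["animal"].astype(str)) if len(phenotypes) else set()
    progeny = ped.progeny_counts()
    tab = ped.table.set_index("animal")
    for i, a in enumerate(geno.animal_ids):
        if not keep[i]:
            continue
        has_phen = a in phen_ids
        has_prog = a in progeny.index and progeny[a] > 0
        has_parent = False
        if a in tab.index:
            rec = tab.loc[a]
            has_parent = rec["sire"] != UNKNOWN or rec["dam"] != UNKNOWN
        if not (has_phen or has_prog or has_parent):
            report.removed_animals.append((a, "uninformative"))
            keep[i] = False
    return geno.subset(animals=keep), report


def fill_missing(geno: GenotypeMatrix, allele_freqs: np.ndarray) -> np.ndarray:
    """Replace missing calls with the expected dosage 2 p_j.

    Returns a float matrix (expected dosages are fractional).  This stands in
    for phased imputation, which is deliberately out of scope for synthetic
    panels without linkage structure.
    """
    d = geno.dosage.astype(float)
    missing = geno.dosage == MISSING
    d[missing] = np.broadcast_to(2.0 * allele_freqs, d.shape)[missing]
    return d


def run_cascade(
    geno: GenotypeMatrix,
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    mendel_threshold: float = 0.01,
) -> tuple[GenotypeMatrix, Pedigree, QCReport]:
    """Full genotype QC cascade in its canonical order."""
    report = QCReport()
    geno, removed = mendelian_snp_filter(geno, ped, mendel_threshold)
    report.removed_snps.extend((s, "mendelian") for s in removed)
    severed, ped = parent_offspring_conflicts(geno, ped, mendel_threshold)
    report.severed_links.extend(severed)
    geno, report = snp_qc(geno, report=report)
    geno, report = animal_qc(geno, ped, phenotypes, report=report)
    return geno, ped, report
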