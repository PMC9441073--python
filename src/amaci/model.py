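"""Multi-country maternal-effects evaluations, pedigree-based and single-step.

The pedigree model is the AMACI multi-trait animal model: each of the c
countries is a correlated trait, and every record in country i is

    y = X_i b_i + C_i r_i + Z_i u_i + W_i m_i + P_i p_i + e_i

with direct (u) and maternal (m) genetic effects sharing the covariance
G (x) A over the 2c trait vector (direct countries first, then maternal), a
random environmental (herd) effect, a maternal permanent-environment effect
carried by the dam, and a per-country residual.

The single-step extension replaces A by the combined pedigree-genomic matrix
H, where H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]] on the genotyped block
and G_w = (1 - w) G* + w A22 blends the observed-allele-frequency genomic
relationship matrix G* with the pedigree block (w is the residual polygenic
fraction, 5% by default).  Compatibility between the genomic and pedigree
bases is handled by two J covariates fitted as fixed effects — the animal's
own J on the direct effect and its dam's J on the maternal effect — and the
product of an animal's J and the estimated coefficient is added to its
genetic value to form its genomic EBV.

Classes follow the model/results convention: build an :class:`AmaciModel` or
:class:`SingleStepModel` from the data, call ``fit()``, and work with the
returned :class:`EvaluationResults`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .covariance import VarianceComponents
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .qc import fill_missing
from .relationships import allele_frequencies
from .solver import MMESystem, SolveInfo, solve_direct, solve_pcg

SCENARIOS = ("PBLUP_NAT", "ssSNPBLUP_NAT", "PBLUP_INT", "ssSNPBLUP_INT")


@dataclass
class ModelSpec:
    """Per-country model configuration.

    ``fit_herd`` and ``fit_maternal_pe`` may be a single bool or a
    country -> bool mapping (a country can drop the maternal PE term, as one
    national model does).  ``per_country_j`` expands the two shared J
    regressions into one pair per country; off by default.  ``fit_j`` can
    disable the compatibility regression entirely, appropriate when the
    genomic and pedigree bases are known to be compatible (e.g. genotypes
    centred with base-population frequencies).
    """

    scenario: str = "PBLUP_INT"
    fit_herd: bool | dict = True
    fit_maternal_pe: bool | dict = True
    per_country_j: bool = False
    fit_j: bool = True

    def herd_enabled(self, country: str) -> bool:
        if isinstance(self.fit_herd, dict):
            return bool(self.fit_herd.get(country, True))
        return bool(self.fit_herd)

    def pe_enabled(self, country: str) -> bool:
        if isinstance(self.fit_maternal_pe, dict):
            return bool(self.fit_maternal_pe.get(country, True))
        return bool(self.fit_maternal_pe)


# ---------------------------------------------------------------------------
# J covariates
# ---------------------------------------------------------------------------

def j_covariates(
    ped: Pedigree, genotyped_ids, a_cols: np.ndarray | None = None
) -> pd.Series:
    """Compatibility covariates for every pedigree animal.

    Three stages: J = -1 for genotyped animals; non-genotyped ancestors of
    genotyped animals get J_anc = A_anc,g (A_g,g)^-1 J_g; every remaining
    animal gets the average of its parents' J in topological order, an
    unknown parent contributing 0.  ``a_cols`` may pass precomputed dense A
    columns for the genotyped animals (pedigree order) to avoid refactoring.
    """
    genotyped_ids = [str(a) for a in genotyped_ids]
    if len(genotyped_ids) == 0:
        raise ValueError("genotyped set is empty")
    n = len(ped)
    g_idx = ped.index_of(genotyped_ids)
    J = np.zeros(n)
    J[g_idx] = -1.0
    anc = ped.ancestors_of(genotyped_ids) - set(genotyped_ids)
    if anc:
        anc_idx = ped.index_of(sorted(anc))
        if a_cols is None:
            a_cols = ped.a_columns(g_idx)
        a_gg = a_cols[g_idx]
        x = np.linalg.solve(a_gg, -np.ones(len(g_idx)))
        J[anc_idx] = a_cols[anc_idx] @ x
    done = np.zeros(n, dtype=bool)
    done[g_idx] = True
    if anc:
        done[anc_idx] = True
    sire, dam = ped.sire_idx, ped.dam_idx
    for k in np.flatnonzero(~done):  # topological order
        js = J[sire[k]] if sire[k] >= 0 else 0.0
        jd = J[dam[k]] if dam[k] >= 0 else 0.0
        J[k] = 0.5 * (js + jd)
    return pd.Series(J, index=ped.animals, name="J")


# ---------------------------------------------------------------------------
# single-step genetic structure (shared between whole and partial runs)
# ---------------------------------------------------------------------------

class SingleStepStructure:
    """Genomic pieces of the single-step system, computed once per scenario.

    Holds the genotyped animals' pedigree positions, the dense correction
    G_w^-1 - A22^-1, and the J covariates.  Whole and partial evaluations of
    one scenario share an instance, which also guarantees the same observed
    allele frequencies are used in both.
    """

    def __init__(
        self,
        ped: Pedigree,
        geno: GenotypeMatrix,
        w_poly: float = 0.05,
        allele_freqs: np.ndarray | None = None,
    ):
        if geno.n_animals == 0:
            raise ValueError("genotyped set is empty")
        missing = [a for a in geno.animal_ids if a not in ped]
        if missing:
            raise KeyError(f"genotyped animals absent from pedigree: {missing[:5]}")
        self.ped = ped
        self.geno = geno
        self.w_poly = float(w_poly)
        self.g_rows = ped.index_of(geno.animal_ids)
        p = allele_frequencies(geno) if allele_freqs is None else np.asarray(allele_freqs)
        self.allele_freqs = p
        dosage = fill_missing(geno, p)
        z = dosage - 2.0 * p
        het = float(np.sum(2.0 * p * (1.0 - p)))
        if het <= 0:
            raise ValueError("all SNPs monomorphic; genomic matrix undefined")
        self.g_star = z @ z.T / het
        a_cols = ped.a_columns(self.g_rows)
        self.a22 = a_cols[self.g_rows]
        g_w = (1.0 - self.w_poly) * self.g_star + self.w_poly * self.a22
        try:
            gw_inv = np.linalg.inv(g_w)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "G_w singular; increase the residual polygenic fraction"
            ) from exc
        self.delta_h = gw_inv - np.linalg.inv(self.a22)
        self.delta_h = 0.5 * (self.delta_h + self.delta_h.T)
        self.j = j_covariates(ped, geno.animal_ids, a_cols=a_cols)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResults:
    """Solutions of one evaluation.

    ``direct`` and ``maternal`` are (n_animals x c) arrays of EBV in kg, in
    pedigree order; for single-step fits the genomic-EBV correction
    (J times the estimated coefficient) has already been added.
    """

    scenario: str
    countries: list[str]
    animals: np.ndarray
    direct: np.ndarray
    maternal: np.ndarray
    fixed_effects: pd.Series
    j_coefficients: pd.Series | None
    herd_effects: pd.Series
    pe_effects: pd.Series
    info: SolveInfo
    vc: VarianceComponents
    base_rescaled: bool = False
    n_records: int = 0
    dropped_maternal_records: int = 0

    def _cidx(self, country: str) -> int:
        return self.countries.index(country)

    def ebv(self, country: str, effect: str = "direct") -> pd.Series:
        arr = self.direct if effect == "direct" else self.maternal
        return pd.Series(arr[:, self._cidx(country)], index=self.animals)

    def ebv_frame(self) -> pd.DataFrame:
        cols = {}
        for i, ctry in enumerate(self.countries):
            cols[f"{ctry}_d"] = self.direct[:, i]
            cols[f"{ctry}_m"] = self.maternal[:, i]
        return pd.DataFrame(cols, index=self.animals)

    def summary(self) -> str:
        lines = [
            f"Evaluation scenario: {self.scenario}",
            f"Countries: {', '.join(self.countries)}",
            f"Animals in pedigree: {len(self.animals)}; records: {self.n_records}",
            f"Solver: {self.info.iterations} iterations, "
            f"final criterion {self.info.criterion:.2e}, "
            f"relative residual {self.info.relative_residual:.2e}",
            f"Base-rescaled: {self.base_rescaled}",
        ]
        if self.j_coefficients is not None:
            jc = ", ".join(f"{k} = {v:.4f}" for k, v in self.j_coefficients.items())
            lines.append(f"J regression coefficients: {jc}")
        for i, ctry in enumerate(self.countries):
            lines.append(
                f"  {ctry}: direct EBV sd {np.std(self.direct[:, i]):.2f} kg, "
                f"maternal EBV sd {np.std(self.maternal[:, i]):.2f} kg"
            )
        return "\n".join(lines)


def rescale_to_base(
    result: EvaluationResults, phenotypes: pd.DataFrame, base_year: int = 2002
) -> EvaluationResults:
    """Express all EBV relative to a per-country base generation.

    The base group of a country is its national animals born in ``base_year``
    with a phenotype; their mean EBV is subtracted per country-trait and
    effect, so differences between animals are untouched and rescaling twice
    equals rescaling once.
    """
    out = copy.deepcopy(result)
    pos = {a: i for i, a in enumerate(result.animals)}
    for i, country in enumerate(result.countries):
        grp = phenotypes.loc[
            (phenotypes["country"] == country)
            & (pd.to_numeric(phenotypes["birth_year"]) == base_year),
            "animal",
        ].astype(str)
        idx = np.array([pos[a] for a in grp if a in pos], dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"empty base group (born {base_year}) for {country}")
        out.direct[:, i] -= out.direct[idx, i].mean()
        out.maternal[:, i] -= out.maternal[idx, i].mean()
    out.base_rescaled = True
    return out


def make_partial(dataset, cutoff_year: int = 2014):
    """Partial-information dataset: phenotypes of animals born from
    ``cutoff_year`` onwards are set to missing; pedigree and genotypes are
    untouched (downstream allele frequencies are those of the whole run)."""
    phen = dataset.phenotypes
    keep = pd.to_numeric(phen["birth_year"]) < cutoff_year
    return _dc_replace(dataset, phenotypes=phen.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class AmaciModel:
    """Multi-country pedigree BLUP with maternal effects.

    Parameters
    ----------
    phenotypes : DataFrame with columns animal, country, y, sex and
        optionally herd and birth_year.  Each record belongs to exactly one
        country-trait.
    pedigree : the (pruned) pedigree; genetic effects are fitted for every
        pedigree animal.
    vc : variance components whose countries cover the record countries.
    spec : per-country model switches.
    """

    has_genomics = False

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        vc: VarianceComponents,
        spec: ModelSpec | None = None,
    ):
        self.spec = spec or ModelSpec()
        self.phenotypes = phenotypes.reset_index(drop=True)
        self.ped = pedigree
        self.vc = vc
        unknown = set(self.phenotypes["country"]) - set(vc.countries)
        if unknown:
            raise ValueError(f"records from countries without components: {unknown}")
        if np.any(vc.residual_variance <= 0):
            raise ValueError("evaluation requires positive residual variances")
        self._system: MMESystem | None = None
        self._layout: dict | None = None

    # -- assembly ----------------------------------------------------------
    def _j_values(self):
        return None  # pedigree model fits no compatibility regression

    def build_system(self) -> MMESystem:
        if self._system is not None:
            return self._system
        ped, vc, spec = self.ped, self.vc, self.spec
        phen = self.phenotypes
        c = vc.n_countries
        n = len(ped)
        n_rec = len(phen)
        countries = vc.countries

        animal_idx = ped.index_of(phen["animal"])
        rec_country = phen["country"].astype(str).to_numpy()
        ci = np.array([countries.index(x) for x in rec_country])
        dam_idx = ped.dam_idx[animal_idx]
        y = phen["y"].to_numpy(dtype=float)
        rinv = 1.0 / vc.residual_variance[ci]

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        rr = np.arange(n_rec)

        # fixed effects -------------------------------------------------
        fixed_names: list[str] = []

        def add_fixed(name: str, mask: np.ndarray, values: np.ndarray | None = None):
            col = len(fixed_names)
            fixed_names.append(name)
            rows.append(rr[mask])
            cols.append(np.full(mask.sum(), col))
            vals.append(
                np.ones(mask.sum()) if values is None else values[mask]
            )

        present = [ctry for ctry in countries if (rec_country == ctry).any()]
        for ctry in present:
            add_fixed(f"mu_{ctry}", rec_country == ctry)
        sex = phen["sex"].astype(str).to_numpy() if "sex" in phen else None
        if sex is not None:
            for ctry in present:
                in_c = rec_country == ctry
                levels = sorted(set(sex[in_c]))
                for lev in levels[1:]:  # drop first level: reference
                    add_fixed(f"sex_{ctry}_{lev}", in_c & (sex == lev))
        jvals = self._j_values()
        if jvals is not None:
            j_anim = jvals[animal_idx]
            j_dam = np.where(dam_idx >= 0, jvals[np.maximum(dam_idx, 0)], 0.0)
            if spec.per_country_j:
                for ctry in present:
                    in_c = rec_country == ctry
                    add_fixed(f"j_direct_{ctry}", in_c, j_anim)
                    add_fixed(f"j_maternal_{ctry}", in_c, j_dam)
            else:
                all_r = np.ones(n_rec, dtype=bool)
                add_fixed("j_direct", all_r, j_anim)
                add_fixed("j_maternal", all_r, j_dam)
        n_fix = len(fixed_names)

        # herd (random environmental) -----------------------------------
        herd_levels: list[tuple[str, str]] = []
        herd_offset = n_fix
        if "herd" in phen.columns:
            herd_col = phen["herd"].astype(str).to_numpy()
            use = np.array(
                [
                    spec.herd_enabled(ctry) and h not in ("", "nan", "None")
                    for ctry, h in zip(rec_country, herd_col)
                ]
            )
            keys = pd.Series(
                [(ctry, h) for ctry, h in zip(rec_country, herd_col)]
            )
            levels = sorted(set(keys[use]))
            lev_pos = {k: i for i, k in enumerate(levels)}
            herd_levels = levels
            mask = use
            rows.append(rr[mask])
            cols.append(
                herd_offset
                + np.array([lev_pos[k] for k in keys[mask]], dtype=np.int64)
            )
            vals.append(np.ones(mask.sum()))
        n_herd = len(herd_levels)

        # genetic: trait-major 2c x n -----------------------------------
        gen_offset = herd_offset + n_herd
        rows.append(rr)
        cols.append(gen_offset + ci * n + animal_idx)
        vals.append(np.ones(n_rec))
        has_dam = dam_idx >= 0
        self._dropped_maternal = int((~has_dam).sum())
        rows.append(rr[has_dam])
        cols.append(gen_offset + (c + ci[has_dam]) * n + dam_idx[has_dam])
        vals.append(np.ones(has_dam.sum()))

        # maternal permanent environment --------------------------------
        pe_offset = gen_offset + 2 * c * n
        pe_use = has_dam & np.array([spec.pe_enabled(x) for x in rec_country])
        pe_keys = [
            (rec_country[r], int(dam_idx[r])) for r in np.flatnonzero(pe_use)
        ]
        pe_levels = sorted(set(pe_keys))
        pe_pos = {k: i for i, k in enumerate(pe_levels)}
        rows.append(rr[pe_use])
        cols.append(
            pe_offset + np.array([pe_pos[k] for k in pe_keys], dtype=np.int64)
        )
        vals.append(np.ones(pe_use.sum()))
        n_pe = len(pe_levels)

        n_unknowns = pe_offset + n_pe
        W = sp.csr_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_rec, n_unknowns),
        )
        Rinv = sp.diags(rinv)
        c_data = (W.T @ Rinv @ W).tocsr()
        rhs = W.T @ (rinv * y)

        # prior precisions ----------------------------------------------
        ainv = self.ped.a_inverse()
        g_inv = np.linalg.inv(vc.g)
        herd_var = np.array(
            [vc.herd_variance[countries.index(k[0])] for k in herd_levels]
        )
        pe_var = np.array(
            [vc.pe_variance[countries.index(k[0])] for k in pe_levels]
        )
        blocks = [
            sp.csr_matrix((n_fix, n_fix)),
            sp.diags(1.0 / herd_var) if n_herd else sp.csr_matrix((0, 0)),
            sp.kron(g_inv, ainv, format="csr"),
            sp.diags(1.0 / pe_var) if n_pe else sp.csr_matrix((0, 0)),
        ]
        c_prior = sp.block_diag(blocks, format="csr")

        system = MMESystem(
            c_data=c_data,
            c_prior=c_prior,
            rhs=rhs,
            gen_offset=gen_offset,
            n_animals=n,
            n_traits=2 * c,
            ainv_diag=ainv.diagonal(),
            g_inv=g_inv,
        )
        self._attach_genomics(system)
        self._system = system
        self._layout = {
            "fixed_names": fixed_names,
            "herd_levels": herd_levels,
            "pe_levels": pe_levels,
            "gen_offset": gen_offset,
            "pe_offset": pe_offset,
        }
        return system

    def _attach_genomics(self, system: MMESystem) -> None:
        pass

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        method: str = "pcg",
        tol: float = 1e-5,
        max_iter: int = 5000,
    ) -> EvaluationResults:
        system = self.build_system()
        if method == "pcg":
            x, info = solve_pcg(system, tol=tol, max_iter=max_iter)
        elif method == "direct":
            x, info = solve_direct(system)
        else:
            raise ValueError(f"unknown solve method {method!r}")
        return self._unpack(x, info)

    def _unpack(self, x: np.ndarray, info: SolveInfo) -> EvaluationResults:
        lay = self._layout
        vc = self.vc
        c, n = vc.n_countries, len(self.ped)
        fixed = pd.Series(x[: len(lay["fixed_names"])], index=lay["fixed_names"])
        herd = pd.Series(
            x[len(lay["fixed_names"]) : lay["gen_offset"]],
            index=[f"{k[0]}:{k[1]}" for k in lay["herd_levels"]],
        )
        a = x[lay["gen_offset"] : lay["gen_offset"] + 2 * c * n].reshape(2 * c, n).T
        direct = a[:, :c].copy()
        maternal = a[:, c:].copy()
        pe = pd.Series(
            x[lay["pe_offset"] :],
            index=[f"{k[0]}:{self.ped.animals[k[1]]}" for k in lay["pe_levels"]],
        )
        j_coef = None
        jvals = self._j_values()
        if jvals is not None:
            j_names = [nm for nm in lay["fixed_names"] if nm.startswith("j_")]
            j_coef = fixed[j_names]
            # genomic EBV: add J x coefficient to each genetic value
            for nm in j_names:
                beta = fixed[nm]
                if nm.startswith("j_direct"):
                    tgt, suffix = direct, nm[len("j_direct") :]
                else:
                    tgt, suffix = maternal, nm[len("j_maternal") :]
                cols = (
                    range(c)
                    if not suffix
                    else [vc.countries.index(suffix.lstrip("_"))]
                )
                for col in cols:
                    tgt[:, col] += jvals * beta
        return EvaluationResults(
            scenario=self.spec.scenario,
            countries=list(vc.countries),
            animals=self.ped.animals,
            direct=direct,
            maternal=maternal,
            fixed_effects=fixed,
            j_coefficients=j_coef,
            herd_effects=herd,
            pe_effects=pe,
            info=info,
            vc=vc,
            n_records=len(self.phenotypes),
            dropped_maternal_records=getattr(self, "_dropped_maternal", 0),
        )


class SingleStepModel(AmaciModel):
    """Single-step SNPBLUP: the AMACI model with genomic information.

    Either pass ``genotypes`` (the structure is computed here) or a
    precomputed :class:`SingleStepStructure`; whole and partial evaluations
    of one scenario should share the structure so the genomic matrices and
    observed allele frequencies are computed once.
    """

    has_genomics = True

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        vc: VarianceComponents,
        genotypes: GenotypeMatrix | None = None,
        structure: SingleStepStructure | None = None,
        spec: ModelSpec | None = None,
    ):
        super().__init__(phenotypes, pedigree, vc, spec)
        if structure is None:
            if genotypes is None:
                raise ValueError("either genotypes or structure is required")
            if genotypes.n_animals == 0:
                # degenerate reduction: no genomic information, H = A and no
                # compatibility regression -> plain pedigree BLUP
                self.structure = None
                return
            structure = SingleStepStructure(
                pedigree, genotypes, w_poly=vc.residual_polygenic_fraction
            )
        if structure.ped is not pedigree:
            raise ValueError("structure was built for a different pedigree")
        self.structure = structure

    def _j_values(self):
        if self.structure is None or not self.spec.fit_j:
            return None
        return self.structure.j.to_numpy()

    def _attach_genomics(self, system: MMESystem) -> None:
        if self.structure is None:
            return
        system.g_rows = self.structure.g_rows
        system.delta_h = self.structure.delta_h
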