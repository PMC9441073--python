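"""Synthetic multi-country weaning-weight data generator.

Emulates the statistical structure a multi-country maternal-effects
evaluation assumes: c country populations modelled as 2c correlated traits
(direct + maternal), common bulls linking countries through cross-country
matings, herd and maternal permanent-environment random effects, SNP-driven
true breeding values with a residual polygenic fraction, and optional
selective genotyping.  Genotypes are propagated by gene dropping, so the
generated data satisfy the generative assumptions of the single-step model
exactly and every downstream stage is testable without any real data.

Randomness is controlled by a single master seed; independent sub-streams
(pedigree structure, founder haplotypes and gene dropping, SNP effects,
polygenic values, environmental noise, genotyping) are spawned from it, so
datasets are byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import VarianceComponents
from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


def default_phi(
    c: int,
    r_direct: float = 0.80,
    r_maternal: float = 0.70,
    r_dm_within: float = -0.15,
    r_dm_across: float = -0.10,
) -> np.ndarray:
    """Structured across-country correlation matrix (direct, then maternal).

    Direct-direct correlations between countries default to 0.80 and
    maternal-maternal to 0.70 — strong but below 1, the device by which trait
    and model differences between countries are absorbed.  Direct-maternal
    correlations are mildly negative, as is typical for weaning weight.
    """
    phi = np.eye(2 * c)
    for i in range(c):
        for j in range(c):
            if i != j:
                phi[i, j] = r_direct
                phi[c + i, c + j] = r_maternal
                phi[i, c + j] = phi[c + j, i] = r_dm_across
        phi[i, c + i] = phi[c + i, i] = r_dm_within
    return phi


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a five-country weaning-weight population: national
    genetic SDs around 20 kg (direct) and 12 kg (maternal), phenotypic SD
    around 40 kg, five offspring generations on a four-year generation
    interval, and a minority of matings using a foreign sire.
    """

    n_countries: int = 5
    founders_per_country: int = 180
    n_generations: int = 5
    offspring_per_dam: int = 2
    cross_country_sire_rate: float = 0.08
    n_snps: int = 800
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    residual_polygenic_fraction: float = 0.05
    genetic_sd_direct: float | np.ndarray = 20.0
    genetic_sd_maternal: float | np.ndarray = 12.0
    phi: np.ndarray | None = None
    herd_variance: float | np.ndarray = 200.0
    pe_variance: float | np.ndarray = 100.0
    residual_variance: float | np.ndarray = 800.0
    genotyping_rate: float | np.ndarray = 0.65
    genotyping_strategy: str = "random"
    genotyping_from_year: int | None = 2006
    country_mean: float = 250.0
    sex_effect: float = 12.0
    dams_per_herd: int = 10
    base_birth_year: int = 1998
    generation_gap: int = 4
    seed: int = 0

    def __post_init__(self):
        c = self.n_countries
        if c < 1:
            raise ValueError("need at least one country")
        if c < 2 and self.cross_country_sire_rate > 0:
            raise ValueError(
                "cross_country_sire_rate must be 0 with a single country"
            )
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        for name in ("cross_country_sire_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if np.any(np.asarray(self.genotyping_rate) < 0) or np.any(
            np.asarray(self.genotyping_rate) > 1
        ):
            raise ValueError("genotyping_rate must be in [0, 1]")
        if self.genotyping_strategy not in ("random", "selective"):
            raise ValueError("genotyping_strategy must be random or selective")
        if not 0.0 <= self.residual_polygenic_fraction <= 1.0:
            raise ValueError("residual_polygenic_fraction must be in [0, 1]")

    @property
    def countries(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_countries)]

    def _per_country(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_countries, float(arr))
        if arr.shape != (self.n_countries,):
            raise ValueError("per-country value has wrong length")
        return arr

    def variance_components(self) -> VarianceComponents:
        phi = self.phi if self.phi is not None else default_phi(self.n_countries)
        return VarianceComponents(
            countries=self.countries,
            genetic_sd_direct=self._per_country(self.genetic_sd_direct),
            genetic_sd_maternal=self._per_country(self.genetic_sd_maternal),
            phi=phi,
            herd_variance=self._per_country(self.herd_variance),
            pe_variance=self._per_country(self.pe_variance),
            residual_variance=self._per_country(self.residual_variance),
            residual_polygenic_fraction=self.residual_polygenic_fraction,
        )


@dataclass
class SyntheticDataset:
    """Everything a study run needs, with the simulated truth attached."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_values: pd.DataFrame  # animals x 2c trait columns, kg
    snp_effects: np.ndarray  # n_snps x 2c, kg per allele copy
    variance_components: VarianceComponents
    config: SimulationConfig
    full_genotypes: GenotypeMatrix | None = None

    def true_direct(self, animals, country: str) -> np.ndarray:
        return self.true_values.loc[list(map(str, animals)), f"{country}_d"].to_numpy()

    def true_maternal(self, animals, country: str) -> np.ndarray:
        return self.true_values.loc[list(map(str, animals)), f"{country}_m"].to_numpy()


# ---------------------------------------------------------------------------

def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete multi-country dataset under the configured model.

    The steps are: breeding structure (random within-country mating with a
    configurable fraction of foreign sires; dams mated within country only),
    gene dropping of founder haplotypes, SNP effects drawn with across-trait
    covariance (1 - w_poly) G / (2 sum_j p_j (1 - p_j)), a pedigree polygenic
    component with Mendelian-sampling covariance
    0.5 w_poly G (1 - (F_s + F_d)/2), and phenotypes
    y = mu_i + sex + herd + u_direct + m_maternal(dam) + pe(dam) + e recorded
    in the animal's own country.
    """
    vc = config.variance_components()
    master = np.random.SeedSequence(config.seed)
    (ss_ped, ss_geno, ss_eff, ss_poly, ss_env, ss_assign) = master.spawn(6)

    ped_table, dam_of, sire_of, herd_of = _breeding_structure(
        config, np.random.default_rng(ss_ped)
    )
    ped = Pedigree(ped_table)
    n = len(ped)
    # simulation order == topological order of the constructed table
    idx = ped.index_of(ped_table["animal"])
    inv = np.empty(n, dtype=np.int64)
    inv[idx] = np.arange(n)

    haplo, founder_p = _gene_drop(config, ped, np.random.default_rng(ss_geno))
    dosage = haplo.sum(axis=2).astype(np.int8)

    c2 = 2 * config.n_countries
    rng_eff = np.random.default_rng(ss_eff)
    het = float(np.sum(2.0 * founder_p * (1.0 - founder_p)))
    w = config.residual_polygenic_fraction
    chol_g = np.linalg.cholesky(vc.g)
    snp_effects = (
        rng_eff.standard_normal((config.n_snps, c2))
        @ chol_g.T
        * np.sqrt((1.0 - w) / het)
    )
    genomic = (dosage - 2.0 * founder_p) @ snp_effects  # pedigree order

    poly = _polygenic(ped, vc.g, w, np.random.default_rng(ss_poly))
    true_vals = genomic + poly

    true_values = pd.DataFrame(true_vals, index=ped.animals, columns=vc.trait_labels)

    phenotypes = _phenotypes(
        config, vc, ped, true_values, dam_of, herd_of, np.random.default_rng(ss_env)
    )

    full_geno = GenotypeMatrix(
        animal_ids=ped.animals,
        snp_ids=np.array([f"snp{j + 1}" for j in range(config.n_snps)]),
        dosage=dosage,
        provenance_country=ped.table["country"].to_numpy(),
    )
    dataset = SyntheticDataset(
        pedigree=ped,
        genotypes=full_geno,  # replaced below by the genotyped subset
        phenotypes=phenotypes,
        true_values=true_values,
        snp_effects=snp_effects,
        variance_components=vc,
        config=config,
        full_genotypes=full_geno,
    )
    dataset.genotypes = assign_genotyping(
        dataset,
        strategy=config.genotyping_strategy,
        rates=config._per_country(config.genotyping_rate),
        seed=ss_assign,
        from_year=config.genotyping_from_year,
    )
    return dataset


def assign_genotyping(
    dataset: SyntheticDataset,
    strategy: str,
    rates,
    seed,
    from_year: int | None = None,
) -> GenotypeMatrix:
    """Select which animals are genotyped and return their genotype subset.

    Eligible animals are those born in ``from_year`` or later (all animals if
    None).  Per country, round(rate * eligible) animals are chosen: uniformly
    at random under ``random``, or the top-ranked animals by true direct
    genetic value in the animal's own country under ``selective``.
    """
    if strategy not in ("random", "selective"):
        raise ValueError("strategy must be random or selective")
    config = dataset.config
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 0:
        rates = np.full(config.n_countries, float(rates))
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("genotyping rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    tab = dataset.pedigree.table
    years = pd.to_numeric(tab["birth_year"], errors="coerce")
    eligible = (
        pd.Series(True, index=tab.index) if from_year is None else years >= from_year
    )
    chosen: list[str] = []
    for country, rate in zip(config.countries, rates):
        pool = tab.loc[eligible & (tab["country"] == country), "animal"].to_numpy()
        n_sel = int(round(rate * len(pool)))
        if n_sel == 0:
            continue
        if strategy == "random":
            chosen.extend(rng.choice(pool, size=n_sel, replace=False))
        else:
            tbv = dataset.true_values.loc[pool, f"{country}_d"].to_numpy()
            top = pool[np.argsort(tbv)[::-1][:n_sel]]
            chosen.extend(top)
    order = [a for a in dataset.pedigree.animals if a in set(chosen)]
    return dataset.full_genotypes.select_animals(order)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _breeding_structure(config: SimulationConfig, rng: np.random.Generator):
    countries = config.countries
    rows = []
    males: dict[str, list[str]] = {c: [] for c in countries}
    females: dict[str, list[str]] = {c: [] for c in countries}
    dam_of: dict[str, str] = {}
    sire_of: dict[str, str] = {}
    herd_of: dict[str, str] = {}
    counter = 0

    def new_id(country: str) -> str:
        nonlocal counter
        counter += 1
        return f"{country}A{counter:06d}"

    year0 = config.base_birth_year
    for ci, country in enumerate(countries):
        for _ in range(config.founders_per_country):
            a = new_id(country)
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append((a, UNKNOWN, UNKNOWN, sex, year0, country))
            (males if sex == "M" else females)[country].append(a)

    for g in range(1, config.n_generations + 1):
        year = year0 + g * config.generation_gap
        new_males: dict[str, list[str]] = {c: [] for c in countries}
        new_females: dict[str, list[str]] = {c: [] for c in countries}
        for ci, country in enumerate(countries):
            dams = females[country]
            n_herds = max(1, len(dams) // config.dams_per_herd)
            herd_assign = rng.integers(0, n_herds, size=len(dams))
            for di, dam in enumerate(dams):
                herd = f"{country}_Y{year}_H{herd_assign[di] + 1:03d}"
                foreign = (
                    config.n_countries > 1
                    and rng.random() < config.cross_country_sire_rate
                )
                if foreign:
                    others = [c for c in countries if c != country and males[c]]
                    sire_pool = males[rng.choice(others)] if others else males[country]
                else:
                    sire_pool = males[country]
                if not sire_pool:  # pragma: no cover - degenerate config
                    continue
                sire = sire_pool[rng.integers(0, len(sire_pool))]
                for _ in range(config.offspring_per_dam):
                    a = new_id(country)
                    sex = "M" if rng.random() < 0.5 else "F"
                    rows.append((a, sire, dam, sex, year, country))
                    dam_of[a] = dam
                    sire_of[a] = sire
                    herd_of[a] = herd
                    (new_males if sex == "M" else new_females)[country].append(a)
        males, females = new_males, new_females

    table = pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "birth_year", "country"]
    )
    return table, dam_of, sire_of, herd_of


def _gene_drop(config: SimulationConfig, ped: Pedigree, rng: np.random.Generator):
    """Founder haplotypes from per-SNP MAF, then Mendelian inheritance."""
    lo, hi = config.founder_maf_range
    m = config.n_snps
    p = rng.uniform(lo, hi, size=m)
    n = len(ped)
    haplo = np.zeros((n, m, 2), dtype=np.int8)
    sire, dam = ped.sire_idx, ped.dam_idx
    founders = np.flatnonzero((sire < 0) & (dam < 0))
    haplo[founders] = (
        rng.random((len(founders), m, 2)) < p[None, :, None]
    ).astype(np.int8)
    # pedigree order is topological: parents are always processed first
    nonf = np.flatnonzero((sire >= 0) | (dam >= 0))
    for k in nonf:
        for slot, parent in enumerate((sire[k], dam[k])):
            if parent < 0:  # pragma: no cover - not produced by the generator
                haplo[k, :, slot] = (rng.random(m) < p).astype(np.int8)
            else:
                pick = rng.integers(0, 2, size=m)
                haplo[k, :, slot] = haplo[parent, np.arange(m), pick]
    return haplo, p


def _polygenic(
    ped: Pedigree, g_mat: np.ndarray, w: float, rng: np.random.Generator
) -> np.ndarray:
    """Residual polygenic values propagated through the pedigree."""
    n = len(ped)
    c2 = g_mat.shape[0]
    if w == 0.0:
        return np.zeros((n, c2))
    chol = np.linalg.cholesky(g_mat)
    F = ped.inbreeding()
    sire, dam = ped.sire_idx, ped.dam_idx
    z = rng.standard_normal((n, c2)) @ chol.T  # N(0, G) draws, scaled below
    poly = np.zeros((n, c2))
    for k in range(n):
        s, d = sire[k], dam[k]
        if s < 0 and d < 0:
            poly[k] = np.sqrt(w) * z[k]
            continue
        mean = np.zeros(c2)
        ms_factor = 1.0
        if s >= 0:
            mean += 0.5 * poly[s]
            ms_factor -= 0.25 * (1.0 + F[s])
        if d >= 0:
            mean += 0.5 * poly[d]
            ms_factor -= 0.25 * (1.0 + F[d])
        poly[k] = mean + np.sqrt(w * ms_factor) * z[k]
    return poly


def _phenotypes(
    config: SimulationConfig,
    vc: VarianceComponents,
    ped: Pedigree,
    true_values: pd.DataFrame,
    dam_of: dict[str, str],
    herd_of: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    countries = config.countries
    herd_ids = sorted(set(herd_of.values()))
    country_of_herd = {h: h.split("_")[0] for h in herd_ids}
    herd_effect = {}
    for h in herd_ids:
        ci = countries.index(country_of_herd[h])
        herd_effect[h] = rng.normal(0.0, np.sqrt(vc.herd_variance[ci]))
    dams = sorted(set(dam_of.values()))
    pe_effect = {}
    for d in dams:
        ci = countries.index(ped.table.set_index("animal").loc[d, "country"])
        pe_effect[d] = rng.normal(0.0, np.sqrt(vc.pe_variance[ci]))

    tab = ped.table.set_index("animal")
    recs = []
    recorded = [a for a in ped.animals if a in dam_of]  # non-founders only
    for a in recorded:
        country = tab.loc[a, "country"]
        ci = countries.index(country)
        dam = dam_of[a]
        y = (
            config.country_mean
            + (config.sex_effect if tab.loc[a, "sex"] == "M" else 0.0)
            + herd_effect[herd_of[a]]
            + true_values.loc[a, f"{country}_d"]
            + true_values.loc[dam, f"{country}_m"]
            + pe_effect[dam]
            + rng.normal(0.0, np.sqrt(vc.residual_variance[ci]))
        )
        recs.append(
            (
                a,
                country,
                float(y),
                tab.loc[a, "sex"],
                herd_of[a],
                int(tab.loc[a, "birth_year"]),
                dam,
            )
        )
    return pd.DataFrame(
        recs, columns=["animal", "country", "y", "sex", "herd", "birth_year", "dam"]
    )
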