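"""Four-scenario study orchestration and reporting.

Runs the national/international x pedigree/single-step grid the evaluation
study is built around: for every scenario a whole and a partial evaluation
(phenotypes of animals born from the cutoff year onwards masked), EBV
rescaled to a per-country base generation, within-scenario LR estimates per
country, and between-scenario increases in population accuracy toward the
international single-step scenario computed from whole-evaluation EBV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AmaciModel,
    EvaluationResults,
    ModelSpec,
    SCENARIOS,
    SingleStepModel,
    SingleStepStructure,
    make_partial,
    rescale_to_base,
)
from .pedigree import prune_pedigree
from .simulate import SimulationConfig, SyntheticDataset, simulate_population
from .validation import (
    LREstimates,
    between_scenario_inc_acc,
    bootstrap_se,
    connectedness,
    focal_group,
    lr_estimates,
    pooled_bootstrap_se,
    pooled_lr_estimates,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Study definition: data source, scenarios and validation settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scenarios: tuple[str, ...] = SCENARIOS
    cutoff_year: int = 2014
    base_year: int = 2002
    solver_tol: float = 1e-5
    solver_max_iter: int = 5000
    n_bootstrap: int = 10_000
    compute_bootstrap_se: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")


def build_pseudo_national(dataset: SyntheticDataset, country: str) -> SyntheticDataset:
    """National view of the data for the pseudo-national scenarios.

    Phenotypes and genotypes are restricted to those submitted by the
    country; the pedigree is pruned to the national animals with data plus
    all their ancestors (foreign sires and deeper ancestors stay).  The
    within-country variance components are reused unchanged.
    """
    phen = dataset.phenotypes[dataset.phenotypes["country"] == country]
    if phen.empty:
        raise ValueError(f"country {country} has no phenotypes")
    geno = dataset.genotypes
    nat_mask = geno.provenance_country == country
    nat_geno = geno.subset(animals=nat_mask)
    keep = set(phen["animal"].astype(str)) | set(nat_geno.animal_ids)
    ped = prune_pedigree(dataset.pedigree, keep)
    return _dc_replace(
        dataset,
        pedigree=ped,
        phenotypes=phen.reset_index(drop=True),
        genotypes=nat_geno,
        full_genotypes=nat_geno,
    )


@dataclass
class ScenarioRun:
    """Whole + partial evaluations of one scenario (one country for the
    national scenarios, all countries for the international ones)."""

    scenario: str
    country: str | None
    whole: EvaluationResults | dict[str, EvaluationResults]
    partial: EvaluationResults | dict[str, EvaluationResults]

    def results_for(self, country: str) -> tuple[EvaluationResults, EvaluationResults]:
        if isinstance(self.whole, dict):
            return self.whole[country], self.partial[country]
        return self.whole, self.partial


@dataclass
class StudyResult:
    config: StudyConfig
    dataset: SyntheticDataset
    runs: dict[str, ScenarioRun]
    lr_table: pd.DataFrame
    between_table: pd.DataFrame
    skipped: list[str]
    focal: pd.DataFrame

    def write_reports(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.lr_table.to_csv(out / "lr_estimates.tsv", sep="\t", index=False)
        self.between_table.to_csv(
            out / "between_scenario_inc_acc.tsv", sep="\t", index=False
        )
        conn = connectedness(
            self.dataset.pedigree,
            self.dataset.phenotypes,
            self.dataset.genotypes.animal_ids,
        )
        conn.to_tsv(out / "connectedness_pairs.tsv", out / "connectedness_summary.tsv")


# ---------------------------------------------------------------------------

def _fit_scenario(
    scenario: str,
    dataset: SyntheticDataset,
    config: StudyConfig,
    spec: ModelSpec,
) -> tuple[EvaluationResults, EvaluationResults]:
    """Whole and partial evaluations sharing the genomic structure."""
    vc = dataset.variance_components
    if len(vc.countries) == 1:
        vc = vc  # already national components
    partial_ds = make_partial(dataset, config.cutoff_year)
    kwargs = dict(tol=config.solver_tol, max_iter=config.solver_max_iter)
    if scenario.startswith("ssSNPBLUP"):
        structure = SingleStepStructure(
            dataset.pedigree,
            dataset.genotypes,
            w_poly=vc.residual_polygenic_fraction,
        )
        whole = SingleStepModel(
            dataset.phenotypes, dataset.pedigree, vc, structure=structure, spec=spec
        ).fit(**kwargs)
        part = SingleStepModel(
            partial_ds.phenotypes, dataset.pedigree, vc, structure=structure, spec=spec
        ).fit(**kwargs)
    else:
        whole = AmaciModel(dataset.phenotypes, dataset.pedigree, vc, spec=spec).fit(
            **kwargs
        )
        part = AmaciModel(
            partial_ds.phenotypes, dataset.pedigree, vc, spec=spec
        ).fit(**kwargs)
    whole = rescale_to_base(whole, dataset.phenotypes, config.base_year)
    part = rescale_to_base(part, dataset.phenotypes, config.base_year)
    return whole, part


def run_study(config: StudyConfig, dataset: SyntheticDataset | None = None) -> StudyResult:
    """Run every configured scenario and assemble the validation report.

    Deterministic given the configuration seed; a dataset may be passed in
    (e.g. loaded from files), otherwise it is simulated from
    ``config.simulation`` with the study seed.
    """
    if dataset is None:
        sim = _dc_replace(config.simulation, seed=config.seed)
        dataset = simulate_population(sim)
    countries = dataset.variance_components.countries
    focal = focal_group(dataset, config.cutoff_year, require_genotype=True)
    runs: dict[str, ScenarioRun] = {}
    skipped: list[str] = []

    for scenario in dict.fromkeys(config.scenarios):
        spec = ModelSpec(scenario=scenario)
        if scenario.endswith("_INT"):
            whole, part = _fit_scenario(scenario, dataset, config, spec)
            runs[scenario] = ScenarioRun(scenario, None, whole, part)
        else:
            wholes: dict[str, EvaluationResults] = {}
            parts: dict[str, EvaluationResults] = {}
            for country in countries:
                nat = build_pseudo_national(dataset, country)
                if scenario.startswith("ssSNPBLUP") and nat.genotypes.n_animals == 0:
                    msg = (
                        f"{scenario} skipped for {country}: no genotypes "
                        "submitted by the country"
                    )
                    logger.info(msg)
                    skipped.append(msg)
                    continue
                nat_vc = dataset.variance_components.for_country(country)
                nat = _dc_replace(nat, variance_components=nat_vc)
                w, p = _fit_scenario(scenario, nat, config, spec)
                wholes[country] = w
                parts[country] = p
            runs[scenario] = ScenarioRun(scenario, None, wholes, parts)

    lr_table = _lr_table(config, dataset, runs, focal)
    between_table = _between_table(dataset, runs, focal)
    result = StudyResult(
        config=config,
        dataset=dataset,
        runs=runs,
        lr_table=lr_table,
        between_table=between_table,
        skipped=skipped,
        focal=focal,
    )
    if config.output_dir:
        result.write_reports(config.output_dir)
    return result


def _focal_vectors(
    run: ScenarioRun, focal: pd.DataFrame, country: str, effect: str
):
    try:
        whole, part = run.results_for(country)
    except KeyError:
        return None
    animals = focal.loc[focal["country"] == country, "animal"].astype(str)
    if animals.empty:
        return None
    u_w = whole.ebv(country, effect).loc[animals].to_numpy()
    u_p = part.ebv(country, effect).loc[animals].to_numpy()
    return animals, u_w, u_p


def _sigma(vc, country: str, effect: str) -> float:
    i = vc.countries.index(country)
    return float(
        vc.genetic_sd_direct[i] if effect == "direct" else vc.genetic_sd_maternal[i]
    )


def _lr_table(config, dataset, runs, focal) -> pd.DataFrame:
    vc = dataset.variance_components
    inb = pd.Series(dataset.pedigree.inbreeding(), index=dataset.pedigree.animals)
    rows = []
    boot_seed = np.random.SeedSequence([config.seed, 2024])
    for scenario, run in runs.items():
        for effect in ("direct", "maternal"):
            pooled_w, pooled_p, pooled_f = [], [], []
            for country in vc.countries:
                vecs = _focal_vectors(run, focal, country, effect)
                if vecs is None:
                    continue
                animals, u_w, u_p = vecs
                f_bar = float(inb.loc[animals].mean())
                sigma = _sigma(vc, country, effect)
                est = lr_estimates(u_w, u_p, sigma, f_bar)
                if config.compute_bootstrap_se:
                    est.se = bootstrap_se(
                        u_w, u_p, sigma, f_bar,
                        n_boot=config.n_bootstrap, seed=boot_seed.spawn(1)[0],
                    )
                rows.append(_lr_row(scenario, country, effect, est))
                pooled_w.append(u_w / sigma)
                pooled_p.append(u_p / sigma)
                pooled_f.append(inb.loc[animals].to_numpy())
            if len(pooled_w) > 1:
                f_bar = float(np.concatenate(pooled_f).mean())
                est = pooled_lr_estimates(pooled_w, pooled_p, f_bar=f_bar)
                if config.compute_bootstrap_se:
                    est.se = pooled_bootstrap_se(
                        pooled_w, pooled_p, f_bar,
                        n_boot=config.n_bootstrap, seed=boot_seed.spawn(1)[0],
                    )
                rows.append(_lr_row(scenario, "ALL", effect, est))
    return pd.DataFrame(rows)


def _lr_row(scenario, country, effect, est: LREstimates) -> dict:
    row = {
        "scenario": scenario,
        "country": country,
        "effect": effect,
        "n": est.n,
        "f_bar": est.f_bar,
        "delta_p": est.delta_p,
        "b_p": est.b_p,
        "acc_p": est.acc_p,
        "rho_pw": est.rho_pw,
        "inc_acc": est.inc_acc,
        "dispersion": est.dispersion_flag,
    }
    for key, se in est.se.items():
        row[f"se_{key}"] = se
    return row


def _between_table(dataset, runs, focal) -> pd.DataFrame:
    target = "ssSNPBLUP_INT"
    rows = []
    if target not in runs:
        return pd.DataFrame(rows)
    vc = dataset.variance_components
    tgt = runs[target]
    for scenario, run in runs.items():
        if scenario == target:
            continue
        for effect in ("direct", "maternal"):
            pooled_a, pooled_b = [], []
            for country in vc.countries:
                vecs = _focal_vectors(run, focal, country, effect)
                if vecs is None:
                    continue
                animals, u_w_a, _ = vecs
                u_w_b = tgt.results_for(country)[0].ebv(country, effect)
                u_w_b = u_w_b.loc[animals].to_numpy()
                inc, rho = between_scenario_inc_acc(u_w_a, u_w_b)
                rows.append(
                    {
                        "from_scenario": scenario,
                        "country": country,
                        "effect": effect,
                        "n": len(animals),
                        "rho_whole": rho,
                        "inc_acc": inc,
                    }
                )
                sigma = _sigma(vc, country, effect)
                pooled_a.append(u_w_a / sigma)
                pooled_b.append(u_w_b / sigma)
            if len(pooled_a) > 1:
                # within-country deviations, as for the pooled LR estimators
                inc, rho = between_scenario_inc_acc(
                    np.concatenate([v - v.mean() for v in pooled_a]),
                    np.concatenate([v - v.mean() for v in pooled_b]),
                )
                rows.append(
                    {
                        "from_scenario": scenario,
                        "country": "ALL",
                        "effect": effect,
                        "n": sum(map(len, pooled_a)),
                        "rho_whole": rho,
                        "inc_acc": inc,
                    }
                )
    return pd.DataFrame(rows)
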