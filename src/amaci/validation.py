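"""LR-method validation: bias, dispersion, accuracy, and connectedness.

The LR method compares the EBV of a focal group between a partial evaluation
(recent phenotypes masked) and a whole evaluation.  Its estimators:

* level bias  Delta_p = mean(u_p) - mean(u_w), reported in genetic standard
  deviations (GSD);
* dispersion  b_p = cov(u_w, u_p) / var(u_p), expectation 1; values beyond
  1.15 / below 0.85 are flagged as considerable under-/over-dispersion;
* accuracy    acc_p = sqrt(cov(u_w, u_p) / ((1 - F_bar) sigma_u^2));
* rho_pw, the Pearson correlation of u_p and u_w, whose expectation is the
  ratio of the two accuracies, so inc_acc = (1/rho - 1) * 100 is the relative
  increase in population accuracy from the partial to the whole evaluation
  (rho = 0.80 gives 25%).

Standard errors come from bootstrapping animals within the focal group.
Connectedness statistics (common bulls and common maternal grand-sires) and
genetic-trend / realized-Mendelian-sampling diagnostics live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

DISPERSION_BAND = (0.85, 1.15)  # acceptable b_p interval


# ---------------------------------------------------------------------------
# focal group
# ---------------------------------------------------------------------------

def focal_group(
    dataset,
    cutoff_year: int = 2014,
    require_genotype: bool = True,
    country: str | None = None,
) -> pd.DataFrame:
    """Validation cohort: phenotyped (and genotyped) animals born from
    ``cutoff_year`` onwards, grouped by the country of the phenotype.

    Returns a frame with columns animal, country.  Raises when a requested
    country has an empty group.
    """
    phen = dataset.phenotypes
    sel = phen.loc[pd.to_numeric(phen["birth_year"]) >= cutoff_year,
                   ["animal", "country"]].copy()
    if require_genotype:
        genotyped = set(dataset.genotypes.animal_ids)
        sel = sel[sel["animal"].astype(str).isin(genotyped)]
    if country is not None:
        sel = sel[sel["country"] == country]
        if sel.empty:
            raise ValueError(f"empty focal group for country {country}")
    return sel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LR estimators
# ---------------------------------------------------------------------------

@dataclass
class LREstimates:
    delta_p: float  # level bias, GSD units
    b_p: float  # dispersion slope
    acc_p: float  # accuracy of partial EBV (nan + flag when undefined)
    rho_pw: float  # accuracy ratio (Pearson correlation)
    inc_acc: float  # percent increase in population accuracy
    n: int
    f_bar: float
    sigma_u: float
    acc_defined: bool = True
    se: dict = field(default_factory=dict)

    @property
    def dispersion_flag(self) -> str:
        lo, hi = DISPERSION_BAND
        if self.b_p < lo:
            return "over-dispersion"
        if self.b_p > hi:
            return "under-dispersion"
        return "acceptable"

    def summary(self) -> str:
        def fmt(name, value):
            se = self.se.get(name)
            return f"{value:.3f} ({se:.3f})" if se is not None else f"{value:.3f}"

        return (
            f"LR estimates (n = {self.n}, F_bar = {self.f_bar:.4f}):\n"
            f"  level bias Delta_p [GSD]: {fmt('delta_p', self.delta_p)}\n"
            f"  dispersion b_p: {fmt('b_p', self.b_p)} [{self.dispersion_flag}]\n"
            f"  accuracy acc_p: {fmt('acc_p', self.acc_p)}\n"
            f"  rho_pw: {fmt('rho_pw', self.rho_pw)}; "
            f"inc_acc: {fmt('inc_acc', self.inc_acc)} %"
        )


def inc_acc_from_rho(rho: float) -> float:
    """Relative increase in population accuracy, percent: (1/rho - 1) * 100."""
    if rho <= 0:
        raise ValueError("inc_acc undefined for non-positive correlation")
    return (1.0 / rho - 1.0) * 100.0


def lr_estimates(
    u_whole: np.ndarray,
    u_partial: np.ndarray,
    sigma_u: float,
    f_bar: float = 0.0,
) -> LREstimates:
    """Within-scenario LR estimators for one focal group (same animals,
    same order, in both vectors).  Covariances use the n-1 denominator."""
    u_w = np.asarray(u_whole, dtype=float)
    u_p = np.asarray(u_partial, dtype=float)
    if u_w.shape != u_p.shape or u_w.ndim != 1:
        raise ValueError("whole and partial EBV vectors must align")
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive")
    if not 0.0 <= f_bar < 1.0:
        raise ValueError("mean inbreeding must be in [0, 1)")
    n = u_w.size
    var_p = float(np.var(u_p, ddof=1))
    if var_p == 0:
        raise ValueError("partial EBV have zero variance")
    cov = float(np.cov(u_w, u_p, ddof=1)[0, 1])
    delta = (u_p.mean() - u_w.mean()) / sigma_u
    b = cov / var_p
    acc_defined = cov >= 0
    acc = np.sqrt(cov / ((1.0 - f_bar) * sigma_u**2)) if acc_defined else np.nan
    var_w = float(np.var(u_w, ddof=1))
    rho = cov / np.sqrt(var_p * var_w) if var_w > 0 else np.nan
    inc = inc_acc_from_rho(rho) if rho > 0 else np.nan
    return LREstimates(
        delta_p=delta,
        b_p=b,
        acc_p=float(acc),
        rho_pw=float(rho),
        inc_acc=float(inc),
        n=n,
        f_bar=f_bar,
        sigma_u=sigma_u,
        acc_defined=acc_defined,
    )


def bootstrap_se(
    u_whole: np.ndarray,
    u_partial: np.ndarray,
    sigma_u: float,
    f_bar: float = 0.0,
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, float]:
    """Bootstrap standard errors of the LR estimators.

    Animals are resampled with replacement within the focal group; the SE of
    an estimator is the standard deviation of its value across the
    ``n_boot`` samples.  Fully vectorised and deterministic given the seed.
    """
    u_w = np.asarray(u_whole, dtype=float)
    u_p = np.asarray(u_partial, dtype=float)
    n = u_w.size
    if n < 2:
        raise ValueError("focal group too small to bootstrap")
    if n_boot < 2:
        raise ValueError("need at least two bootstrap samples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    w = u_w[idx]
    p = u_p[idx]
    mw, mp = w.mean(axis=1), p.mean(axis=1)
    # n-1 denominator to match the point estimators
    cov = ((w - mw[:, None]) * (p - mp[:, None])).sum(axis=1) / (n - 1)
    var_p = ((p - mp[:, None]) ** 2).sum(axis=1) / (n - 1)
    var_w = ((w - mw[:, None]) ** 2).sum(axis=1) / (n - 1)
    delta = (mp - mw) / sigma_u
    b = cov / var_p
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.sqrt(np.clip(cov, 0.0, None) / ((1.0 - f_bar) * sigma_u**2))
        rho = cov / np.sqrt(var_p * var_w)
        inc = np.where(rho > 0, (1.0 / rho - 1.0) * 100.0, np.nan)
    return {
        "delta_p": float(np.nanstd(delta, ddof=1)),
        "b_p": float(np.nanstd(b, ddof=1)),
        "acc_p": float(np.nanstd(acc, ddof=1)),
        "rho_pw": float(np.nanstd(rho, ddof=1)),
        "inc_acc": float(np.nanstd(inc, ddof=1)),
    }


def pooled_lr_estimates(
    u_whole_groups: list[np.ndarray],
    u_partial_groups: list[np.ndarray],
    f_bar: float = 0.0,
) -> LREstimates:
    """LR estimators for several focal groups pooled on a common scale.

    Inputs are per-group (per-country) EBV vectors already standardised by
    the national genetic SD.  Level bias is the size-weighted mean of the
    per-group level biases (equivalently the pooled mean difference).  The
    covariance-based estimators (b_p, acc_p, rho) are computed on deviations
    from each group's own focal mean, so between-country level differences
    (which are a property of the national bases, not of individual
    prediction) do not leak into the pooled covariance.
    """
    uw = [np.asarray(v, float) for v in u_whole_groups]
    up = [np.asarray(v, float) for v in u_partial_groups]
    if len(uw) != len(up) or any(a.shape != b.shape for a, b in zip(uw, up)):
        raise ValueError("group vectors must align")
    w_all = np.concatenate(uw)
    p_all = np.concatenate(up)
    n = w_all.size
    delta = p_all.mean() - w_all.mean()
    w_c = np.concatenate([v - v.mean() for v in uw])
    p_c = np.concatenate([v - v.mean() for v in up])
    var_p = float(p_c @ p_c) / (n - 1)
    var_w = float(w_c @ w_c) / (n - 1)
    cov = float(w_c @ p_c) / (n - 1)
    if var_p == 0:
        raise ValueError("partial EBV have zero variance")
    b = cov / var_p
    acc_defined = cov >= 0
    acc = np.sqrt(cov / (1.0 - f_bar)) if acc_defined else np.nan
    rho = cov / np.sqrt(var_p * var_w) if var_w > 0 else np.nan
    inc = inc_acc_from_rho(rho) if rho > 0 else np.nan
    return LREstimates(
        delta_p=float(delta),
        b_p=float(b),
        acc_p=float(acc),
        rho_pw=float(rho),
        inc_acc=float(inc),
        n=n,
        f_bar=f_bar,
        sigma_u=1.0,
        acc_defined=acc_defined,
    )


def pooled_bootstrap_se(
    u_whole_groups: list[np.ndarray],
    u_partial_groups: list[np.ndarray],
    f_bar: float = 0.0,
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, float]:
    """Bootstrap SEs for the pooled LR estimators.

    Animals are resampled with replacement within each group independently
    (matching per-country reporting); the pooled estimators of
    :func:`pooled_lr_estimates` are recomputed per sample via group sums.
    """
    rng = np.random.default_rng(seed)
    N = sum(len(v) for v in u_whole_groups)
    S_w = np.zeros(n_boot)
    S_p = np.zeros(n_boot)
    cov_acc = np.zeros(n_boot)
    varp_acc = np.zeros(n_boot)
    varw_acc = np.zeros(n_boot)
    for uw, up in zip(u_whole_groups, u_partial_groups):
        uw = np.asarray(uw, float)
        up = np.asarray(up, float)
        n_g = uw.size
        idx = rng.integers(0, n_g, size=(n_boot, n_g))
        w = uw[idx]
        p = up[idx]
        sw, sp_ = w.sum(axis=1), p.sum(axis=1)
        S_w += sw
        S_p += sp_
        cov_acc += (w * p).sum(axis=1) - sw * sp_ / n_g
        varp_acc += (p * p).sum(axis=1) - sp_**2 / n_g
        varw_acc += (w * w).sum(axis=1) - sw**2 / n_g
    delta = (S_p - S_w) / N
    cov = cov_acc / (N - 1)
    var_p = varp_acc / (N - 1)
    var_w = varw_acc / (N - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = cov / var_p
        acc = np.sqrt(np.clip(cov, 0.0, None) / (1.0 - f_bar))
        rho = cov / np.sqrt(var_p * var_w)
        inc = np.where(rho > 0, (1.0 / rho - 1.0) * 100.0, np.nan)
    return {
        "delta_p": float(np.nanstd(delta, ddof=1)),
        "b_p": float(np.nanstd(b, ddof=1)),
        "acc_p": float(np.nanstd(acc, ddof=1)),
        "rho_pw": float(np.nanstd(rho, ddof=1)),
        "inc_acc": float(np.nanstd(inc, ddof=1)),
    }


def between_scenario_inc_acc(
    u_whole_a: np.ndarray, u_whole_b: np.ndarray
) -> tuple[float, float]:
    """Increase in population accuracy moving from scenario A to scenario B.

    Computed from the whole-evaluation EBV of the shared focal group,
    treating A as the partial-information evaluation: rho = corr(A, B) and
    inc_acc = (1/rho - 1) * 100.  Returns (inc_acc, rho).
    """
    a = np.asarray(u_whole_a, dtype=float)
    b = np.asarray(u_whole_b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("scenario EBV vectors must align and be nonempty")
    rho = float(np.corrcoef(a, b)[0, 1])
    return inc_acc_from_rho(rho), rho


# ---------------------------------------------------------------------------
# connectedness
# ---------------------------------------------------------------------------

@dataclass
class ConnectednessReport:
    pair_counts: pd.DataFrame  # per country pair: CB/CMGS and genotyped counts
    country_summary: pd.DataFrame  # per country: sire/dam offspring statistics
    common_bulls: dict[tuple[str, str], set]
    common_mgs: dict[tuple[str, str], set]

    def to_tsv(self, path_pairs, path_summary) -> None:
        self.pair_counts.to_csv(path_pairs, sep="\t", index=False)
        self.country_summary.to_csv(path_summary, sep="\t", index=False)


def connectedness(
    ped: Pedigree, phenotypes: pd.DataFrame, genotyped_ids
) -> ConnectednessReport:
    """Common bulls, common maternal grand-sires and sire/dam summaries.

    A common bull (CB) of a country pair is a sire with recorded (phenotyped)
    offspring in both countries; a common maternal grand-sire (CMGS) is a
    sire of a dam with recorded grand-offspring in both.  Per country the
    report counts sires/dams with recorded offspring, their genotyping
    status, and the offspring-count strata (>= 20, >= 100, and >= 100 spread
    over at least 5 herds).
    """
    genotyped = {str(a) for a in genotyped_ids}
    tab = ped.table.set_index("animal")
    phen = phenotypes.copy()
    phen["animal"] = phen["animal"].astype(str)
    phen = phen[phen["animal"].isin(tab.index)]
    phen["sire"] = tab.loc[phen["animal"], "sire"].to_numpy()
    phen["dam"] = tab.loc[phen["animal"], "dam"].to_numpy()
    dam_known = phen["dam"] != UNKNOWN
    mgs = pd.Series(UNKNOWN, index=phen.index, dtype=object)
    mgs[dam_known] = tab.loc[phen.loc[dam_known, "dam"], "sire"].to_numpy()
    phen["mgs"] = mgs

    countries = sorted(set(phen["country"]))
    sire_countries = (
        phen[phen["sire"] != UNKNOWN].groupby("sire")["country"].agg(set)
    )
    mgs_countries = phen[phen["mgs"] != UNKNOWN].groupby("mgs")["country"].agg(set)

    rows = []
    cb_map: dict[tuple[str, str], set] = {}
    cmgs_map: dict[tuple[str, str], set] = {}
    for c1, c2 in combinations(countries, 2):
        cb = {s for s, cs in sire_countries.items() if c1 in cs and c2 in cs}
        cm = {s for s, cs in mgs_countries.items() if c1 in cs and c2 in cs}
        cb_map[(c1, c2)] = cb
        cmgs_map[(c1, c2)] = cm
        rows.append(
            {
                "country1": c1,
                "country2": c2,
                "cb": len(cb),
                "cb_genotyped": len(cb & genotyped),
                "cmgs": len(cm),
                "cmgs_genotyped": len(cm & genotyped),
            }
        )
    pair_counts = pd.DataFrame(
        rows,
        columns=["country1", "country2", "cb", "cb_genotyped", "cmgs",
                 "cmgs_genotyped"],
    )

    summaries = []
    for ctry in countries:
        nat = phen[phen["country"] == ctry]
        for role in ("sire", "dam"):
            parents = nat[nat[role] != UNKNOWN]
            offspring = parents.groupby(role)["animal"].count()
            herds = (
                parents.groupby(role)["herd"].nunique()
                if "herd" in parents.columns
                else pd.Series(1, index=offspring.index)
            )
            geno_mask = offspring.index.astype(str).isin(genotyped)
            summaries.append(
                {
                    "country": ctry,
                    "role": role,
                    "with_recorded_offspring": int(len(offspring)),
                    "genotyped": int(geno_mask.sum()),
                    "avg_recorded_offspring": float(offspring.mean())
                    if len(offspring)
                    else 0.0,
                    "ge20_offspring": int((offspring >= 20).sum()),
                    "ge100_offspring": int((offspring >= 100).sum()),
                    "ge100_offspring_5herds": int(
                        ((offspring >= 100) & (herds >= 5)).sum()
                    ),
                }
            )
    return ConnectednessReport(
        pair_counts=pair_counts,
        country_summary=pd.DataFrame(summaries),
        common_bulls=cb_map,
        common_mgs=cmgs_map,
    )


# ---------------------------------------------------------------------------
# trend diagnostics
# ---------------------------------------------------------------------------

def trends(
    result,
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    effect: str = "direct",
    min_offspring: int = 10,
    min_sires: int = 5,
) -> pd.DataFrame:
    """Per-country genetic trend of proven sires.

    For each country and sire birth year: the mean EBV of sires with at least
    ``min_offspring`` recorded offspring in that country; years with fewer
    than ``min_sires`` qualifying sires are omitted.
    """
    tab = ped.table.set_index("animal")
    phen = phenotypes.copy()
    phen["animal"] = phen["animal"].astype(str)
    phen["sire"] = tab.loc[phen["animal"], "sire"].to_numpy()
    rows = []
    for ctry, nat in phen.groupby("country"):
        counts = nat[nat["sire"] != UNKNOWN].groupby("sire")["animal"].count()
        qualifying = counts[counts >= min_offspring].index
        if len(qualifying) == 0:
            continue
        ebv = result.ebv(ctry, effect)
        years = pd.to_numeric(tab.loc[qualifying, "birth_year"], errors="coerce")
        df = pd.DataFrame(
            {"sire": qualifying, "year": years.to_numpy(),
             "ebv": ebv.loc[qualifying].to_numpy()}
        ).dropna()
        grp = df.groupby("year").agg(n=("sire", "count"), mean_ebv=("ebv", "mean"))
        grp = grp[grp["n"] >= min_sires]
        for year, rec in grp.iterrows():
            rows.append(
                {"country": ctry, "year": int(year), "n_sires": int(rec["n"]),
                 "mean_ebv": float(rec["mean_ebv"])}
            )
    return pd.DataFrame(rows, columns=["country", "year", "n_sires", "mean_ebv"])


def realized_mendelian_sampling(
    result, ped: Pedigree, country: str, effect: str = "direct"
) -> pd.Series:
    """RMS per animal: EBV minus half the EBV of each known parent, in GSD.

    With one unknown parent only the known parent's half is subtracted.
    Animals with no known parent get RMS equal to their own (scaled) EBV.
    """
    ci = result.countries.index(country)
    arr = result.direct if effect == "direct" else result.maternal
    ebv = arr[:, ci]
    sigma = (
        result.vc.genetic_sd_direct[ci]
        if effect == "direct"
        else result.vc.genetic_sd_maternal[ci]
    )
    rms = ebv.copy()
    s, d = ped.sire_idx, ped.dam_idx
    rms[s >= 0] -= 0.5 * ebv[s[s >= 0]]
    rms[d >= 0] -= 0.5 * ebv[d[d >= 0]]
    return pd.Series(rms / sigma, index=ped.animals)


def rms_trend(
    result,
    ped: Pedigree,
    genotyped_ids,
    country: str,
    effect: str = "direct",
) -> pd.DataFrame:
    """Per-birth-year mean RMS, split by genotyped status.

    Non-zero mean RMS of the genotyped group is the footprint of selective
    genotyping; under random genotyping its expectation is 0.
    """
    rms = realized_mendelian_sampling(result, ped, country, effect)
    genotyped = {str(a) for a in genotyped_ids}
    df = pd.DataFrame(
        {
            "animal": ped.animals,
            "year": pd.to_numeric(ped.table["birth_year"], errors="coerce"),
            "rms": rms.to_numpy(),
            "genotyped": [a in genotyped for a in ped.animals],
        }
    ).dropna(subset=["year"])
    out = (
        df.groupby(["year", "genotyped"])["rms"]
        .agg(["mean", "count", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_rms", "count": "n", "std": "sd"})
    )
    out["year"] = out["year"].astype(int)
    return out
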