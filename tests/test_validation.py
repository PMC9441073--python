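import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amaci import (
    EvaluationResults,
    Pedigree,
    SimulationConfig,
    between_scenario_inc_acc,
    bootstrap_se,
    connectedness,
    focal_group,
    inc_acc_from_rho,
    lr_estimates,
    realized_mendelian_sampling,
    rms_trend,
    simulate_population,
    trends,
)
from amaci.solver import SolveInfo
from conftest import ped_frame


class TestLREstimates:
    def test_identity_case(self):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 2.0, 500)
        sigma = float(np.std(u, ddof=1))
        est = lr_estimates(u, u, sigma_u=sigma, f_bar=0.0)
        assert est.delta_p == pytest.approx(0.0, abs=1e-12)
        assert est.b_p == pytest.approx(1.0)
        assert est.acc_p == pytest.approx(1.0)
        assert est.rho_pw == pytest.approx(1.0)
        assert est.inc_acc == pytest.approx(0.0, abs=1e-9)

    def test_partial_twice_whole_gives_half_slope(self):
        rng = np.random.default_rng(1)
        u_w = rng.normal(0, 1.0, 400)
        est = lr_estimates(u_w, 2.0 * u_w, sigma_u=1.0)
        assert est.b_p == pytest.approx(0.5)
        assert est.rho_pw == pytest.approx(1.0)

    def test_worked_example_rho_080_gives_25_percent(self):
        assert inc_acc_from_rho(0.80) == pytest.approx(25.0)

    def test_dispersion_flags(self):
        rng = np.random.default_rng(2)
        u_w = rng.normal(0, 1.0, 2000)
        over = lr_estimates(u_w, u_w / 0.7, sigma_u=1.0)  # b ~ 0.7
        assert over.dispersion_flag == "over-dispersion"
        under = lr_estimates(u_w, u_w / 1.3, sigma_u=1.0)  # b ~ 1.3
        assert under.dispersion_flag == "under-dispersion"

    def test_negative_covariance_flags_accuracy_undefined(self):
        rng = np.random.default_rng(3)
        u_w = rng.normal(size=300)
        u_p = -u_w + rng.normal(size=300) * 0.1
        est = lr_estimates(u_w, u_p, sigma_u=1.0)
        assert not est.acc_defined
        assert np.isnan(est.acc_p)
        assert np.isfinite(est.b_p)  # other estimators are not poisoned

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lr_estimates(np.ones(3), np.ones(4), 1.0)
        with pytest.raises(ValueError):
            lr_estimates(np.arange(3.0), np.arange(3.0), sigma_u=-1.0)
        with pytest.raises(ValueError, match="zero variance"):
            lr_estimates(np.arange(3.0), np.ones(3), sigma_u=1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.2, 5.0))
    def test_shift_invariance_of_slope_and_rho(self, seed, scale):
        """Base rescaling is shift-only, so b_p and rho are unaffected by
        adding constants to either EBV vector."""
        rng = np.random.default_rng(seed)
        u_w = rng.normal(0, scale, 100)
        u_p = 0.8 * u_w + rng.normal(0, 0.3 * scale, 100)
        a = lr_estimates(u_w, u_p, sigma_u=scale)
        b = lr_estimates(u_w + 3.7, u_p - 1.2, sigma_u=scale)
        assert a.b_p == pytest.approx(b.b_p)
        assert a.rho_pw == pytest.approx(b.rho_pw)
        assert a.acc_p == pytest.approx(b.acc_p)


class TestBootstrap:
    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        u_w = rng.normal(size=200)
        u_p = 0.9 * u_w + rng.normal(size=200) * 0.3
        se1 = bootstrap_se(u_w, u_p, 1.0, n_boot=500, seed=11)
        se2 = bootstrap_se(u_w, u_p, 1.0, n_boot=500, seed=11)
        assert se1 == se2

    def test_near_constant_difference_gives_tiny_delta_se(self):
        rng = np.random.default_rng(5)
        u_w = rng.normal(size=300)
        u_p = u_w + 1e-9 * rng.normal(size=300)
        se = bootstrap_se(u_w, u_p, 1.0, n_boot=500, seed=0)
        assert se["delta_p"] < 1e-9

    def test_slope_se_matches_regression_theory(self):
        """SE(b) from 10,000 bootstrap samples on a 500-animal group vs the
        closed-form OLS slope standard error."""
        rng = np.random.default_rng(6)
        n = 500
        u_p = rng.normal(0, 1.0, n)
        u_w = 1.0 * u_p + rng.normal(0, 0.8, n)
        se = bootstrap_se(u_w, u_p, 1.0, n_boot=10_000, seed=1)
        slope = np.cov(u_w, u_p)[0, 1] / np.var(u_p, ddof=1)
        resid = u_w - u_w.mean() - slope * (u_p - u_p.mean())
        analytic = np.sqrt(
            (resid @ resid / (n - 2)) / ((n - 1) * np.var(u_p, ddof=1))
        )
        assert abs(se["b_p"] - analytic) / analytic < 0.10

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se(np.array([1.0]), np.array([1.0]), 1.0)


class TestBetweenScenario:
    def test_identical_scenarios_zero_gain(self):
        u = np.random.default_rng(7).normal(size=100)
        inc, rho = between_scenario_inc_acc(u, u)
        assert inc == pytest.approx(0.0, abs=1e-9)
        assert rho == pytest.approx(1.0)

    def test_half_correlation_doubles_accuracy(self):
        rng = np.random.default_rng(8)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=n)
        inc, rho = between_scenario_inc_acc(a, b)
        assert rho == pytest.approx(0.5, abs=0.01)
        assert inc == pytest.approx(100.0, rel=0.05)

    def test_inc_acc_strictly_decreasing_in_rho(self):
        rhos = np.linspace(0.1, 1.0, 10)
        incs = [inc_acc_from_rho(r) for r in rhos]
        assert all(x > y for x, y in zip(incs, incs[1:]))


@pytest.fixture(scope="module")
def dataset():
    return simulate_population(
        SimulationConfig(
            n_countries=2,
            founders_per_country=40,
            n_generations=3,
            n_snps=30,
            genotyping_rate=0.5,
            seed=17,
        )
    )


class TestFocalGroup:

    def test_membership_rules(self, dataset):
        cutoff = 2006
        grp = focal_group(dataset, cutoff_year=cutoff)
        genotyped = set(dataset.genotypes.animal_ids)
        phen = dataset.phenotypes.set_index("animal")
        assert len(grp) > 0
        for a in grp["animal"]:
            assert a in genotyped
            assert phen.loc[a, "birth_year"] >= cutoff
        # animals born just before the cutoff are excluded
        early = phen[phen["birth_year"] < cutoff].index
        assert not set(grp["animal"]) & set(early)

    def test_without_genotype_requirement(self, dataset):
        grp = focal_group(dataset, cutoff_year=2006, require_genotype=False)
        phen = dataset.phenotypes
        expected = (phen["birth_year"] >= 2006).sum()
        assert len(grp) == expected

    def test_empty_country_group_raises(self, dataset):
        with pytest.raises(ValueError, match="C1"):
            focal_group(dataset, cutoff_year=3000, country="C1")


def toy_results(ped, countries, direct, maternal):
    cfg = SimulationConfig(
        n_countries=len(countries),
        cross_country_sire_rate=0.0 if len(countries) == 1 else 0.08,
    )
    vc = cfg.variance_components()
    return EvaluationResults(
        scenario="PBLUP_INT",
        countries=list(countries),
        animals=ped.animals,
        direct=np.asarray(direct, float),
        maternal=np.asarray(maternal, float),
        fixed_effects=pd.Series(dtype=float),
        j_coefficients=None,
        herd_effects=pd.Series(dtype=float),
        pe_effects=pd.Series(dtype=float),
        info=SolveInfo(0, 0.0, True, 0.0),
        vc=vc,
    )


class TestConnectedness:
    def pedigree(self):
        rows = [
            ("SIRE1", "0", "0", "M", 1995, "C1"),
            ("SIRE2", "0", "0", "M", 1995, "C1"),
            ("MGS1", "0", "0", "M", 1990, "C2"),
            ("DAM1", "MGS1", "0", "F", 1996, "C1"),
            ("DAM2", "MGS1", "0", "F", 1996, "C2"),
            ("O1", "SIRE1", "DAM1", "M", 2000, "C1"),
            ("O2", "SIRE1", "DAM2", "F", 2000, "C2"),
            ("O3", "SIRE2", "DAM1", "M", 2001, "C1"),
        ]
        return Pedigree(ped_frame(rows))

    def phenotypes(self):
        return pd.DataFrame(
            {
                "animal": ["O1", "O2", "O3"],
                "country": ["C1", "C2", "C1"],
                "y": [1.0, 2.0, 3.0],
                "sex": ["M", "F", "M"],
                "herd": ["h1", "h2", "h1"],
            }
        )

    def test_common_bulls_and_mgs(self):
        rep = connectedness(self.pedigree(), self.phenotypes(), ["SIRE1"])
        row = rep.pair_counts.iloc[0]
        # SIRE1 has phenotyped offspring in C1 and C2; SIRE2 only in C1
        assert rep.common_bulls[("C1", "C2")] == {"SIRE1"}
        assert row["cb"] == 1 and row["cb_genotyped"] == 1
        # MGS1 is the dam-sire of phenotyped offspring in both countries
        assert rep.common_mgs[("C1", "C2")] == {"MGS1"}
        assert row["cmgs"] == 1 and row["cmgs_genotyped"] == 0

    def test_single_country_sire_is_not_cb(self):
        rep = connectedness(self.pedigree(), self.phenotypes(), [])
        assert "SIRE2" not in rep.common_bulls[("C1", "C2")]

    def test_country_summary_counts(self):
        rep = connectedness(self.pedigree(), self.phenotypes(), [])
        c1_sires = rep.country_summary.query(
            "country == 'C1' and role == 'sire'"
        ).iloc[0]
        assert c1_sires["with_recorded_offspring"] == 2
        assert c1_sires["avg_recorded_offspring"] == pytest.approx(1.0)

    def test_matches_brute_force_on_nested_maternal_lines(self):
        rng = np.random.default_rng(23)
        ds = simulate_population(
            SimulationConfig(
                n_countries=3,
                founders_per_country=25,
                n_generations=3,
                n_snps=10,
                cross_country_sire_rate=0.4,
                seed=23,
            )
        )
        rep = connectedness(ds.pedigree, ds.phenotypes, [])
        tab = ds.pedigree.table.set_index("animal")
        phen = ds.phenotypes
        # brute force CMGS for one pair
        brute = set()
        for _, rec in phen.iterrows():
            dam = tab.loc[rec["animal"], "dam"]
            if dam == "0":
                continue
            mgs = tab.loc[dam, "sire"]
            if mgs != "0":
                brute.add((mgs, rec["country"]))
        for (c1, c2), found in rep.common_mgs.items():
            expected = {
                m for m, _ in brute
                if (m, c1) in brute and (m, c2) in brute
            }
            assert found == expected


class TestTrends:
    def test_no_qualifying_sire_gives_empty(self):
        ped = Pedigree(
            ped_frame(
                [
                    ("S", "0", "0", "M", 1995, "C1"),
                    ("O", "S", "0", "M", 2000, "C1"),
                ]
            )
        )
        phen = pd.DataFrame(
            {"animal": ["O"], "country": ["C1"], "y": [1.0], "sex": ["M"],
             "herd": ["h"]}
        )
        res = toy_results(ped, ["C1"], np.zeros((2, 1)), np.zeros((2, 1)))
        assert trends(res, ped, phen).empty

    def test_qualifying_sires_match_hand_means(self):
        rows = [(f"S{i}", "0", "0", "M", 1995 + (i % 2), "C1") for i in range(6)]
        phen_rows = []
        for i in range(6):
            for k in range(10):
                rows.append((f"O{i}_{k}", f"S{i}", "0", "M", 2000, "C1"))
                phen_rows.append((f"O{i}_{k}", "C1", 1.0, "M", "h"))
        ped = Pedigree(ped_frame(rows))
        phen = pd.DataFrame(
            phen_rows, columns=["animal", "country", "y", "sex", "herd"]
        )
        direct = np.zeros((len(ped), 1))
        for i in range(6):
            direct[list(ped.animals).index(f"S{i}"), 0] = float(i)
        res = toy_results(ped, ["C1"], direct, np.zeros_like(direct))
        out = trends(res, ped, phen, min_offspring=10, min_sires=3)
        by_year = {r["year"]: r["mean_ebv"] for _, r in out.iterrows()}
        assert by_year[1995] == pytest.approx(np.mean([0, 2, 4]))
        assert by_year[1996] == pytest.approx(np.mean([1, 3, 5]))

    def test_identical_results_zero_difference(self):
        ped = Pedigree(ped_frame([("S", "0", "0", "M", 1995, "C1")]))
        res = toy_results(ped, ["C1"], [[1.0]], [[0.0]])
        a = trends(res, ped, pd.DataFrame(columns=["animal", "country", "y"]))
        assert a.empty


class TestRMS:
    def test_parent_average_gives_zero(self, full_sib_pedigree):
        ped = full_sib_pedigree
        direct = np.array([[2.0], [4.0], [3.0], [3.0], [3.0]])
        res = toy_results(ped, ["C1"], direct, np.zeros_like(direct))
        rms = realized_mendelian_sampling(res, ped, "C1")
        assert rms["C"] == pytest.approx(0.0)  # (2+4)/2 = 3
        assert rms["E"] == pytest.approx(0.0)

    def test_shift_invariance_with_both_parents_known(self, full_sib_pedigree):
        ped = full_sib_pedigree
        rng = np.random.default_rng(0)
        direct = rng.normal(size=(5, 1))
        res1 = toy_results(ped, ["C1"], direct, np.zeros_like(direct))
        res2 = toy_results(ped, ["C1"], direct + 7.0, np.zeros_like(direct))
        r1 = realized_mendelian_sampling(res1, ped, "C1")
        r2 = realized_mendelian_sampling(res2, ped, "C1")
        for a in ("C", "D", "E"):  # both parents known
            assert r1[a] == pytest.approx(r2[a])

    def test_trend_groups_by_year_and_genotype_status(self, full_sib_pedigree):
        ped = full_sib_pedigree
        direct = np.arange(5.0).reshape(-1, 1)
        res = toy_results(ped, ["C1"], direct, np.zeros_like(direct))
        out = rms_trend(res, ped, ["C", "E"], "C1")
        assert set(out.columns) >= {"year", "genotyped", "mean_rms", "n"}
        assert out.loc[out["genotyped"], "n"].sum() == 2
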