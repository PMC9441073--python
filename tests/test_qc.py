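import numpy as np
import pandas as pd
import pytest

from amaci import GenotypeMatrix, Pedigree
from amaci.qc import (
    animal_qc,
    fill_missing,
    filter_phenotype_outliers,
    hwe_chi2_pvalues,
    mendelian_snp_filter,
    merge_panels,
    parent_offspring_conflicts,
    run_cascade,
    snp_qc,
)
from amaci.genotypes import MISSING
from conftest import ped_frame


def make_geno(dosage, animal_prefix="A", **kwargs):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        animal_ids=[f"{animal_prefix}{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        dosage=dosage,
        **kwargs,
    )


def phen_frame(values, country="C1", sex="F"):
    return pd.DataFrame(
        {
            "animal": [f"A{i}" for i in range(len(values))],
            "country": country,
            "sex": sex,
            "y": values,
        }
    )


class TestPhenotypeOutliers:
    def test_zero_sd_group_kept(self):
        kept, dropped = filter_phenotype_outliers(phen_frame([10.0] * 5))
        assert len(kept) == 5 and dropped.empty

    def test_gross_outlier_removed_by_single_pass(self):
        rng = np.random.default_rng(1)
        values = list(rng.normal(0, 1, 100)) + [10.0]
        df = phen_frame(values)
        mean, sd = df["y"].mean(), df["y"].std()
        assert abs(10.0 - mean) > 3 * sd  # the oracle: direct computation
        kept, dropped = filter_phenotype_outliers(df)
        assert list(dropped["y"]) == [10.0]
        assert len(kept) == 100

    def test_infinite_k_keeps_everything(self):
        df = phen_frame([1.0, 2.0, 3.0, 400.0])
        kept, dropped = filter_phenotype_outliers(df, k=np.inf)
        assert len(kept) == 4 and dropped.empty

    def test_groups_are_population_by_sex(self):
        df = pd.concat(
            [
                phen_frame([0.0] * 20 + [30.0], sex="F"),
                phen_frame([30.0] * 21, sex="M"),
            ]
        )
        kept, dropped = filter_phenotype_outliers(df)
        # 30 is an outlier among females but the norm among males
        assert list(dropped["sex"]) == ["F"]

    def test_tiny_group_passes_through(self):
        kept, dropped = filter_phenotype_outliers(phen_frame([5.0]))
        assert len(kept) == 1 and dropped.empty


class TestMergePanels:
    def test_identical_panel_unchanged(self):
        panel = make_geno([[0, 1], [2, 1]])
        merged = merge_panels([panel], ["s0", "s1"])
        np.testing.assert_array_equal(merged.dosage, panel.dosage)

    def test_two_panels_union_with_missing(self):
        selected = [f"s{j}" for j in range(5)]
        p1 = GenotypeMatrix(["A0"], ["s0", "s1", "s2"],
                            np.array([[0, 1, 2]], dtype=np.int8),
                            snp_positions=[0, 1, 2])
        p2 = GenotypeMatrix(["B0"], ["s2", "s3", "s4"],
                            np.array([[1, 1, 0]], dtype=np.int8),
                            snp_positions=[2, 3, 4])
        merged = merge_panels([p1, p2], selected)
        assert merged.n_snps == 5 and merged.n_animals == 2
        # oracle: set intersection decides which cells are called
        assert list(merged.dosage[0]) == [0, 1, 2, MISSING, MISSING]
        assert list(merged.dosage[1]) == [MISSING, MISSING, 1, 1, 0]

    def test_zero_overlap_panel_gives_all_missing_rows(self):
        p = GenotypeMatrix(["A0"], ["weird"], np.array([[2]], dtype=np.int8),
                           snp_positions=[99])
        merged = merge_panels([p], ["s0", "s1"])
        assert (merged.dosage == MISSING).all()

    def test_duplicate_animal_across_panels_rejected(self):
        p1 = make_geno([[0]])
        p2 = make_geno([[1]])
        with pytest.raises(ValueError, match="duplicate animal"):
            merge_panels([p1, p2], ["s0"])

    def test_duplicated_position_dropped_with_warning(self):
        p = GenotypeMatrix(["A0"], ["s0", "s1"], np.array([[0, 2]], dtype=np.int8),
                           snp_positions=[7, 7])
        with pytest.warns(UserWarning, match="duplicated"):
            merged = merge_panels([p], ["s0", "s1"])
        assert (merged.dosage == MISSING).all()


def pair_pedigree(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows.append((f"P{i}", "0", "0", "M", 2000, "C1"))
        rows.append((f"A{i}", f"P{i}", "0", "F", 2005, "C1"))
    return Pedigree(ped_frame(rows))


class TestMendelianFilters:
    def _geno_with_conflicts(self, n_pairs, conflicts_snp0):
        """Parent-offspring pairs; snp0 has the given number of opposing
        homozygote pairs, snp1 none."""
        ids, rows = [], []
        for i in range(n_pairs):
            conflict = i < conflicts_snp0
            ids += [f"P{i}", f"A{i}"]
            rows += [[0, 1], [2 if conflict else 0, 1]]
        return GenotypeMatrix(ids, ["s0", "s1"], np.array(rows, dtype=np.int8))

    def test_clean_snp_kept(self):
        ped = pair_pedigree(10)
        geno = self._geno_with_conflicts(10, 0)
        _, removed = mendelian_snp_filter(geno, ped)
        assert removed == []

    def test_two_percent_conflicts_removed_one_percent_kept(self):
        ped = pair_pedigree(100)
        _, removed = mendelian_snp_filter(self._geno_with_conflicts(100, 2), ped)
        assert removed == ["s0"]
        _, removed = mendelian_snp_filter(self._geno_with_conflicts(100, 1), ped)
        assert removed == []  # 0.01 is not strictly greater than 0.01

    def test_pair_conflict_severs_link_strictly_above_threshold(self):
        m = 1000
        rows = []
        ped = pair_pedigree(2)
        # pair 0: 15 opposing homozygotes; pair 1: 10 (exactly 1%)
        for i, n_conf in enumerate((15, 10)):
            parent = np.zeros(m, dtype=np.int8)
            child = np.zeros(m, dtype=np.int8)
            child[:n_conf] = 2
            rows += [parent, child]
        geno = GenotypeMatrix(
            ["P0", "A0", "P1", "A1"],
            [f"s{j}" for j in range(m)],
            np.array(rows),
        )
        severed, new_ped = parent_offspring_conflicts(geno, ped)
        assert severed == [("A0", "P0")]
        tab = new_ped.table.set_index("animal")
        assert tab.loc["A0", "sire"] == "0" and tab.loc["A1", "sire"] == "P1"

    def test_identical_genotypes_no_conflict(self):
        ped = pair_pedigree(1)
        geno = GenotypeMatrix(
            ["P0", "A0"], ["s0", "s1"], np.array([[0, 2], [0, 2]], dtype=np.int8)
        )
        severed, _ = parent_offspring_conflicts(geno, ped)
        assert severed == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pairs, m = 25, 120
        ped = pair_pedigree(n_pairs)
        ids, rows = [], []
        for i in range(n_pairs):
            ids += [f"P{i}", f"A{i}"]
            rows += [rng.choice([0, 1, 2, MISSING], size=m, p=[0.3, 0.3, 0.3, 0.1]),
                     rng.choice([0, 1, 2, MISSING], size=m, p=[0.3, 0.3, 0.3, 0.1])]
        geno = GenotypeMatrix(ids, [f"s{j}" for j in range(m)],
                              np.array(rows, dtype=np.int8))
        # exhaustive pair x SNP enumeration
        conf = np.zeros(m, int)
        both = np.zeros(m, int)
        for i in range(n_pairs):
            gp, go = geno.dosage[2 * i], geno.dosage[2 * i + 1]
            for j in range(m):
                if gp[j] != MISSING and go[j] != MISSING:
                    both[j] += 1
                    if {gp[j], go[j]} == {0, 2}:
                        conf[j] += 1
        expected = [f"s{j}" for j in range(m) if conf[j] > 0.01 * both[j]]
        _, removed = mendelian_snp_filter(geno, ped)
        assert removed == expected


class TestSnpQC:
    def test_hwe_perfect_fit_kept(self):
        counts = [0] * 25 + [1] * 50 + [2] * 25
        geno = make_geno(np.array(counts, dtype=np.int8).reshape(-1, 1))
        assert hwe_chi2_pvalues(geno)[0] == pytest.approx(1.0)
        out, report = snp_qc(geno)
        assert out.n_snps == 1

    def test_low_maf_removed(self):
        col = np.zeros((100, 1), dtype=np.int8)
        col[0, 0] = 1  # MAF 0.005
        out, report = snp_qc(make_geno(col))
        assert out.n_snps == 0
        assert report.removed_snps[0][1] == "maf"

    def test_call_rate_boundary_inclusive(self):
        base = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (25, 1))
        g94 = base.copy()
        g94[:6, 0] = MISSING  # 94/100 called
        g95 = base.copy()
        g95[:5, 0] = MISSING  # 95/100 called
        assert snp_qc(make_geno(g94))[0].n_snps == 0
        assert snp_qc(make_geno(g95))[0].n_snps == 1

    def test_extreme_hwe_departure_removed(self):
        # 60 of each homozygote, no heterozygotes: chi2 = n, p << 1e-15
        col = np.array([0] * 60 + [2] * 60, dtype=np.int8).reshape(-1, 1)
        out, report = snp_qc(make_geno(col))
        assert ("s0", "hwe") in report.removed_snps


class TestAnimalQC:
    def _setup(self):
        ped = Pedigree(
            ped_frame(
                [
                    ("A0", "0", "0", "M", 2000, "C1"),
                    ("A1", "A0", "0", "F", 2005, "C1"),
                    ("A2", "0", "0", "M", 2005, "C1"),
                ]
            )
        )
        phen = pd.DataFrame({"animal": ["A1"], "country": ["C1"], "y": [1.0],
                             "sex": ["F"]})
        return ped, phen

    def test_informative_animals_kept(self):
        ped, phen = self._setup()
        geno = make_geno([[0, 1], [2, 1], [1, 1]])
        out, report = animal_qc(geno, ped, phen)
        # A0 has progeny, A1 has a phenotype and a known parent, A2 has none
        assert list(out.animal_ids) == ["A0", "A1"]
        assert ("A2", "uninformative") in report.removed_animals

    def test_call_rate_and_breed_filters(self):
        ped, phen = self._setup()
        dosage = np.array(
            [[0] + [MISSING] * 9, [1] * 10, [2] * 10], dtype=np.int8
        )
        geno = GenotypeMatrix(
            ["A0", "A1", "A2"],
            [f"s{j}" for j in range(10)],
            dosage,
            breed_fraction=[1.0, 0.5, 1.0],
        )
        out, report = animal_qc(geno, ped, phen)
        reasons = dict(report.removed_animals)
        assert reasons["A0"] == "call_rate" and reasons["A1"] == "breed_fraction"


class TestFillMissing:
    def test_no_missing_unchanged(self):
        geno = make_geno([[0, 2], [1, 1]])
        filled = fill_missing(geno, np.array([0.25, 0.75]))
        np.testing.assert_array_equal(filled, geno.dosage)

    def test_missing_replaced_by_expected_dosage(self):
        geno = make_geno([[MISSING, 2]])
        filled = fill_missing(geno, np.array([0.5, 0.75]))
        assert filled[0, 0] == pytest.approx(1.0)

    def test_column_mean_preserved_in_expectation(self):
        rng = np.random.default_rng(0)
        full = rng.binomial(2, 0.4, size=(4000, 3)).astype(np.int8)
        p = full.mean(axis=0) / 2
        masked = full.copy()
        mask = rng.random(full.shape) < 0.3
        masked[mask] = MISSING
        filled = fill_missing(make_geno(masked), p)
        np.testing.assert_allclose(
            filled.mean(axis=0), full.mean(axis=0), atol=0.03
        )


class TestCascade:
    def test_rerun_is_fixed_point(self):
        rng = np.random.default_rng(4)
        n_pairs = 20
        ped = pair_pedigree(n_pairs)
        dosage = rng.choice(
            [0, 1, 2, MISSING], p=[0.3, 0.35, 0.3, 0.05], size=(2 * n_pairs, 60)
        ).astype(np.int8)
        ids = [a for i in range(n_pairs) for a in (f"P{i}", f"A{i}")]
        geno = GenotypeMatrix(ids, [f"s{j}" for j in range(60)], dosage)
        phen = pd.DataFrame(
            {"animal": ids, "country": "C1", "sex": "F", "y": 1.0}
        )
        g1, p1, r1 = run_cascade(geno, ped, phen)
        g2, p2, r2 = run_cascade(g1, p1, phen)
        assert g2.n_snps == g1.n_snps and g2.n_animals == g1.n_animals
        assert r2.counts().get("severed_links", 0) == 0
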