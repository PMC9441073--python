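import numpy as np
import pandas as pd
import pytest

from amaci import Pedigree, SimulationConfig, simulate_population


def ped_frame(rows):
    """rows of (animal, sire, dam, sex, birth_year, country)."""
    return pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "birth_year", "country"]
    )


@pytest.fixture
def trio():
    """Sire, dam and one offspring."""
    return ped_frame(
        [
            ("S1", "0", "0", "M", 2000, "C1"),
            ("D1", "0", "0", "F", 2001, "C1"),
            ("O1", "S1", "D1", "M", 2004, "C1"),
        ]
    )


@pytest.fixture
def full_sib_pedigree():
    """Founders, two full sibs, and their (inbred) offspring."""
    return Pedigree(
        ped_frame(
            [
                ("A", "0", "0", "M", 1990, "C1"),
                ("B", "0", "0", "F", 1990, "C1"),
                ("C", "A", "B", "M", 1995, "C1"),
                ("D", "A", "B", "F", 1995, "C1"),
                ("E", "C", "D", "M", 2000, "C1"),
            ]
        )
    )


def random_pedigree(n, seed, n_founders=None, year0=2000):
    """Random acyclic pedigree for property tests and oracle checks."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 5)
    rows = []
    males, females = [], []
    for i in range(n):
        a = f"X{i:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        if i < n_founders:
            s = d = "0"
            year = year0
        else:
            s = males[rng.integers(len(males))] if males else "0"
            d = females[rng.integers(len(females))] if females else "0"
            year = year0 + 1 + i // 10
        rows.append((a, s, d, sex, year, "C1"))
        (males if sex == "M" else females).append(a)
    return Pedigree(ped_frame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """Two-country synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_countries=2,
        founders_per_country=40,
        n_generations=3,
        n_snps=200,
        seed=42,
    )
    return simulate_population(cfg)
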