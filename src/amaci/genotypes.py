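"""SNP genotype container shared by QC, relationship and evaluation code."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # sentinel inside the int8 dosage matrix; "NA" on disk


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix coded 0/1/2 with -1 for missing calls.

    ``provenance_country`` records which country submitted each genotype and
    ``breed_fraction`` the pedigree-based breed composition (synthetic data
    sets it to 1).  ``snp_positions`` is a dummy map for synthetic panels.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray  # int8, shape (n_animals, n_snps)
    provenance_country: np.ndarray | None = None
    breed_fraction: np.ndarray | None = None
    snp_positions: np.ndarray | None = None

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object).astype(str)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object).astype(str)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing (-1)")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp ids in genotype matrix")
        if self.provenance_country is None:
            self.provenance_country = np.array(["NA"] * len(self.animal_ids))
        else:
            self.provenance_country = np.asarray(self.provenance_country).astype(str)
        if self.breed_fraction is None:
            self.breed_fraction = np.ones(len(self.animal_ids))
        else:
            self.breed_fraction = np.asarray(self.breed_fraction, dtype=float)
        if self.snp_positions is None:
            self.snp_positions = np.arange(len(self.snp_ids), dtype=np.int64)
        else:
            self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def animal_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_animals)
        return self.called.mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        if self.n_animals == 0:
            return np.ones(self.n_snps)
        return self.called.mean(axis=0)

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer positions."""
        a = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        s = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if a.dtype == bool:
            a = np.flatnonzero(a)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[a],
            snp_ids=self.snp_ids[s],
            dosage=self.dosage[np.ix_(a, s)],
            provenance_country=self.provenance_country[a],
            breed_fraction=self.breed_fraction[a],
            snp_positions=self.snp_positions[s],
        )

    def select_animals(self, ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[str(x)] for x in ids], dtype=np.int64)
        return self.subset(animals=idx)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, index=self.animal_ids, columns=self.snp_ids)
        return df.replace(MISSING, np.nan)
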