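"""Readers and writers for the plain-text study formats.

Pedigree and phenotypes travel as CSV, genotypes as a PLINK-RAW-like text
matrix (animal id column followed by one column per SNP, missing = "NA"),
variance components as YAML, and correlation/covariance matrices as square
CSV with trait labels.  Every writer round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariance import VarianceComponents
from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree


# -- pedigree ---------------------------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype={c: str for c in ("animal", "sire", "dam")})
    return Pedigree(df)


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "dam": str})
    return df


# -- genotypes --------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path) -> None:
    values = geno.dosage.astype(object)
    values[geno.dosage == MISSING] = "NA"
    df = pd.DataFrame(values, index=geno.animal_ids, columns=geno.snp_ids)
    df.insert(0, "country", geno.provenance_country)
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col="animal_id", dtype=str, keep_default_na=False
    )
    country = df.pop("country").to_numpy()
    dosage = df.replace("NA", str(MISSING)).astype(np.int8)
    return GenotypeMatrix(
        animal_ids=df.index.to_numpy(),
        snp_ids=df.columns.to_numpy(),
        dosage=dosage.to_numpy(),
        provenance_country=country,
    )


# -- variance components ----------------------------------------------------

def write_variance_components(vc: VarianceComponents, path) -> None:
    payload = {
        "countries": list(vc.countries),
        "genetic_sd_direct": vc.genetic_sd_direct.tolist(),
        "genetic_sd_maternal": vc.genetic_sd_maternal.tolist(),
        "phi": vc.phi.tolist(),
        "herd_variance": vc.herd_variance.tolist(),
        "pe_variance": vc.pe_variance.tolist(),
        "residual_variance": vc.residual_variance.tolist(),
        "residual_polygenic_fraction": float(vc.residual_polygenic_fraction),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_variance_components(path) -> VarianceComponents:
    payload = yaml.safe_load(Path(path).read_text())
    return VarianceComponents(
        countries=payload["countries"],
        genetic_sd_direct=np.array(payload["genetic_sd_direct"]),
        genetic_sd_maternal=np.array(payload["genetic_sd_maternal"]),
        phi=np.array(payload["phi"]),
        herd_variance=np.array(payload["herd_variance"]),
        pe_variance=np.array(payload["pe_variance"]),
        residual_variance=np.array(payload["residual_variance"]),
        residual_polygenic_fraction=payload["residual_polygenic_fraction"],
    )


# -- square matrices --------------------------------------------------------

def write_square_matrix(matrix: np.ndarray, labels, path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)


def read_square_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


# -- results ----------------------------------------------------------------

def write_solutions(result, path) -> None:
    """EBV as TSV: animal, country, effect, ebv."""
    rows = []
    for i, country in enumerate(result.countries):
        for effect, arr in (("direct", result.direct), ("maternal", result.maternal)):
            rows.append(
                pd.DataFrame(
                    {
                        "animal": result.animals,
                        "country": country,
                        "effect": effect,
                        "ebv": arr[:, i],
                        "rescaled": result.base_rescaled,
                    }
                )
            )
    pd.concat(rows).to_csv(path, sep="\t", index=False)
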