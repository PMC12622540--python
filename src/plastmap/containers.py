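"""Core in-memory containers shared across the pipeline.

Tabular data (phenotypes, environments, association results) travel as
pandas DataFrames with documented column contracts; the genotype matrix,
which bundles a dense dosage array with SNP metadata, gets its own class.

Column contracts
----------------
Phenotype table (long format)
    ``accession``, ``environment``, ``trait``, ``value`` — at most one row
    per (accession, environment, trait).
Environment table
    ``environment``, ``site``, ``year``, ``tmin``, ``tmean``, ``tmax`` —
    temperatures in degrees Celsius over the grain-filling window, with
    tmin <= tmean <= tmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PERCENT_TRAITS",
    "validate_phenotypes",
    "validate_environments",
]

#: Trait ids measured on a 0-100 % scale (chalkiness rate/area/degree and
#: their white-belly / white-core / floury-endosperm components).
PERCENT_TRAITS = frozenset(
    {
        "GCR", "GCA", "GCD",
        "WBR", "WBA", "WBD",
        "WCR", "WCA", "WCD",
        "FER", "FEA", "FED",
    }
)


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs as minor-allele dosage counts.

    Attributes
    ----------
    accession_ids : list of str
        Ordered accession labels (rows of ``dosages``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos`` (1-based
        bp), ``ref``, ``alt``; positions strictly increasing within a
        chromosome.
    dosages : numpy.ndarray, shape (n_accessions, n_snps)
        Minor-allele counts in {0, 1, 2}; missing calls are NaN.
    """

    accession_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP (folded to <= 0.5)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean."""
        out = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = np.take(col_mean, idx[1])
        return out

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        order = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in order]
        if missing:
            raise KeyError(f"accessions not in genotype matrix: {missing[:5]}")
        rows = [order[a] for a in ids]
        return GenotypeMatrix(
            accession_ids=list(ids),
            snps=self.snps.copy(),
            dosages=self.dosages[rows, :],
        )


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype contract; return bound violations.

    Raises on missing columns or duplicated (accession, environment, trait)
    keys; returns a DataFrame of rows where a percent-scale trait falls
    outside [0, 100] (empty when clean).
    """
    required = ["accession", "environment", "trait", "value"]
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {missing}")
    dup = pheno.duplicated(subset=["accession", "environment", "trait"])
    if dup.any():
        keys = pheno.loc[dup, ["accession", "environment", "trait"]]
        raise ValueError(
            f"duplicate phenotype records for keys:\n{keys.head().to_string(index=False)}"
        )
    pct = pheno["trait"].isin(PERCENT_TRAITS)
    bad = pheno[pct & ((pheno["value"] < 0) | (pheno["value"] > 100))]
    return bad


def validate_environments(env: pd.DataFrame) -> None:
    required = ["environment", "tmin", "tmean", "tmax"]
    missing = [c for c in required if c not in env.columns]
    if missing:
        raise ValueError(f"environment table missing column(s): {missing}")
    bad = env[(env["tmin"] > env["tmean"]) | (env["tmean"] > env["tmax"])]
    if len(bad):
        raise ValueError(
            f"temperature ordering tmin <= tmean <= tmax violated:\n"
            f"{bad.to_string(index=False)}"
        )
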