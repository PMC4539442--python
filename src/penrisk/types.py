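"""Core containers shared across the pipeline.

Genotypes are held as minor-allele dosage codes {0, 1, 2} with ``numpy.nan``
standing in for missing calls, alongside per-SNP metadata.  Phenotypes,
environmental covariates and (for synthetic data) latent liabilities live in
a pandas DataFrame keyed by sample id and row-aligned with the genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan


def _is_missing(d: np.ndarray) -> np.ndarray:
    return np.isnan(d)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosages with SNP/sample metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``dosages``.
    snp_meta
        DataFrame with columns ``id, chrom, pos, allele1, allele2`` (allele1
        is the minor / counted allele), one row per column of ``dosages``.
    dosages
        Float array of shape (n_samples, n_snps) with entries in
        {0, 1, 2, nan}; fractional dosages are allowed after imputation.
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.snp_meta) != p:
            raise ValueError(f"{len(self.snp_meta)} SNP records for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if self.snp_meta["id"].duplicated().any():
            raise ValueError("SNP ids are not unique")
        ok = _is_missing(self.dosages) | np.isfinite(self.dosages)
        if not ok.all():
            raise ValueError("dosages contain non-finite, non-missing values")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return _is_missing(self.dosages)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over nonmissing calls.

        The stored coding counts the minor allele, but after subsetting the
        sample the empirical frequency can exceed 0.5; the folded frequency
        min(f, 1-f) is returned.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def subset(
        self,
        samples: Sequence[int] | None = None,
        snps: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset; returns a copy."""
        rows = np.arange(self.n_samples) if samples is None else np.asarray(samples, dtype=int)
        cols = np.arange(self.n_snps) if snps is None else np.asarray(snps, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            snp_meta=self.snp_meta.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), self.snp_meta.copy(), self.dosages.copy()
        )


@dataclass
class PhenotypeTable:
    """Binary outcome plus covariates, row-aligned with a GenotypeMatrix.

    ``table`` must contain columns ``sample_id`` and ``y`` (0/1); covariate
    columns are named in ``covariates``.  Synthetic data additionally carries
    a latent ``liability`` column.
    """

    table: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("sample_id", "y"):
            if col not in self.table.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        y = self.table["y"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise ValueError("y must be coded 0/1")
        missing = [c for c in self.covariates if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate columns absent from table: {missing}")

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((len(self.table), 0))
        return self.table[self.covariates].to_numpy(dtype=float)

    @property
    def liability(self) -> np.ndarray | None:
        if "liability" in self.table.columns:
            return self.table["liability"].to_numpy(dtype=float)
        return None

    def subset(self, rows: Sequence[int]) -> "PhenotypeTable":
        return PhenotypeTable(
            self.table.iloc[list(rows)].reset_index(drop=True),
            list(self.covariates),
        )


@dataclass
class QCReport:
    """Record of what a QC pass removed and why."""

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    n_snps_before: int = 0
    n_snps_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", i, r) for i, r in self.removed_snps]
        rows += [("sample", i, r) for i, r in self.removed_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])
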