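"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Long-format phenotype columns, one row per tree observation.
PHENOTYPE_COLUMNS = ["genotype", "location", "year", "row", "col", "trait", "value"]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a set of genotypes.

    Parameters
    ----------
    dosages
        ``(n, m)`` integer array with allele counts in ``{0, 1, 2}``.
    samples
        ``n`` unique genotype identifiers, row-aligned with ``dosages``.
    marker_map
        Data frame with columns ``marker``, ``chrom``, ``pos`` (bp, 1-based),
        sorted by chromosome then position, row-aligned with the columns of
        ``dosages``.
    groups
        Optional germplasm-group label per sample (e.g. ``accession`` /
        ``progeny`` / ``ancestor``).
    haplotypes
        Optional ``(n, 2, m)`` phased haplotype array kept by the simulator so
        that gametes can be sampled from these individuals.
    """

    dosages: np.ndarray
    samples: list[str]
    marker_map: pd.DataFrame
    groups: pd.Series | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x markers) array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.marker_map) != m:
            raise ValueError(f"{len(self.marker_map)} map rows for {m} markers")
        missing = {"marker", "chrom", "pos"} - set(self.marker_map.columns)
        if missing:
            raise ValueError(f"marker_map lacks columns: {sorted(missing)}")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted allele per marker."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.index_of(sample_ids)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            samples=[self.samples[i] for i in idx],
            marker_map=self.marker_map.reset_index(drop=True),
            groups=None if self.groups is None else self.groups.iloc[idx].reset_index(drop=True),
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )

    def subset_markers(self, marker_idx) -> "GenotypeMatrix":
        marker_idx = np.asarray(marker_idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, marker_idx],
            samples=list(self.samples),
            marker_map=self.marker_map.iloc[marker_idx].reset_index(drop=True),
            groups=self.groups,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, marker_idx],
        )

    def standardized(self, drop_monomorphic: bool = True):
        """Column-standardized marker matrix M (mean 0, SD 1).

        Returns ``(M, kept_idx)`` where ``kept_idx`` indexes the polymorphic
        markers retained.
        """
        X = self.dosages.astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0 if drop_monomorphic else np.ones(X.shape[1], bool)
        if not drop_monomorphic and np.any(sd == 0):
            raise ValueError("monomorphic markers present; cannot standardize")
        M = (X[:, keep] - mu[keep]) / sd[keep]
        return M, np.flatnonzero(keep)


@dataclass
class PedigreeTable:
    """Pedigree records with generation labels.

    ``table`` has columns ``id``, ``parent1``, ``parent2``, ``generation``.
    Founders carry empty-string parents.  ``generation`` counts backwards from
    the progeny group: progeny are generation 0, their parents generation 1,
    and so on up to the deepest recorded ancestors.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = {"id", "parent1", "parent2", "generation"} - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree lacks columns: {sorted(missing)}")

    def generation_of(self, ind_id: str) -> int:
        row = self.table.loc[self.table["id"] == ind_id]
        if row.empty:
            raise KeyError(f"{ind_id!r} not in pedigree")
        return int(row["generation"].iloc[0])

    def ids_in_generation(self, generation: int) -> list[str]:
        return self.table.loc[self.table["generation"] == generation, "id"].tolist()


def validate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with canonical dtypes."""
    missing = set(PHENOTYPE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    out = records.copy()
    out["value"] = pd.to_numeric(out["value"])
    out["year"] = out["year"].astype(int)
    return out


def environment_key(location: str, year: int | str) -> str:
    """Canonical 'LOCATION.YEAR' environment label."""
    return f"{location}.{year}"


def add_environment_column(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["environment"] = [
        environment_key(l, y) for l, y in zip(out["location"], out["year"])
    ]
    return out
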