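"""Phenotypic variance decomposition and trait clustering.

For every trait, a mixed model on the spatially adjusted tree values
partitions the phenotypic variance into the fixed effect of environments,
the random effects of each significantly associated SNP (a 3-level factor of
dosage classes), the remaining random genotype effects, genotype-by-
environment interactions and the residual.  The proportion attached to the
fixed environment effect is the variance of the fitted values with all
random effects set to zero; random-effect proportions are the REML variance
components relative to the total response variance, the residual being
reported as the remainder.  SNP and genotype proportions sum to the
genotypic variance.

Traits are then clustered on their centered and scaled variance profiles by
Ward's method, the dendrogram being cut at the largest gap between
successive merge heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from orchardgx.lmm import RandomTerm, fit_lmm


@dataclass
class VarianceProfile:
    """Per-trait variance proportions (SNPs sorted descending)."""

    trait: str
    snp_proportions: list[float]
    snp_names: list[str]
    genotype: float
    environment: float
    gxe: float
    residual: float

    def genotypic_variance(self) -> float:
        return float(sum(self.snp_proportions) + self.genotype)

    def total(self) -> float:
        return float(sum(self.snp_proportions) + self.genotype + self.environment
                     + self.gxe + self.residual)

    def as_row(self, max_snps: int | None = None) -> dict:
        row = {"trait": self.trait, "G": self.genotype, "E": self.environment,
               "GxE": self.gxe, "residual": self.residual}
        n = len(self.snp_proportions) if max_snps is None else max_snps
        for i in range(n):
            row[f"SNP{i+1}"] = self.snp_proportions[i] if i < len(self.snp_proportions) else 0.0
        return row


def decompose_variance(
    records: pd.DataFrame,
    snp_dosages: dict[str, pd.Series] | None = None,
    value_column: str = "adjusted",
) -> VarianceProfile:
    """Decompose the variance of one trait's adjusted tree values.

    ``records`` needs columns ``genotype``, ``environment`` and the value
    column.  ``snp_dosages`` maps marker names to per-genotype dosage classes
    of the significantly associated SNPs (omitted when the trait has no
    associations); constant SNPs are dropped with a warning.
    """
    df = records.reset_index(drop=True)
    y = df[value_column].to_numpy(float)
    var_y = float(np.var(y))
    trait = str(df["trait"].iloc[0]) if "trait" in df.columns else "trait"

    env_d = pd.get_dummies(df["environment"], drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), env_d])

    terms = []
    snp_names = []
    for name, dos in (snp_dosages or {}).items():
        levels = dos.reindex(df["genotype"]).to_numpy()
        if pd.isna(levels).any():
            raise KeyError(f"SNP {name!r}: dosage missing for some genotypes")
        if len(np.unique(levels)) < 2:
            warnings.warn(f"SNP {name!r} constant in the data; term dropped", stacklevel=2)
            continue
        terms.append(RandomTerm([f"c{v:g}" for v in levels], name=f"snp:{name}"))
        snp_names.append(name)
    terms.append(RandomTerm(df["genotype"], name="genotype"))
    ge = df["genotype"].astype(str) + ":" + df["environment"].astype(str)
    terms.append(RandomTerm(ge, name="gxe"))

    fit = fit_lmm(y, X, terms, max_iter=200, tol=1e-9)
    env_prop = float(np.var(fit.fitted_fixed)) / var_y

    # SNP share = variance across trees of the term's predicted values: the
    # 3-level factor is unbalanced, so the raw (level-unweighted) REML
    # component would overstate the explained share
    snp_props = []
    for nm in snp_names:
        blups = fit.blups[f"snp:{nm}"]
        levels = pd.Series([f"c{v:g}" for v in (snp_dosages or {})[nm].reindex(df["genotype"])])
        fitted_term = blups.reindex(levels).to_numpy()
        snp_props.append(float(np.var(fitted_term)) / var_y)
    order = np.argsort(snp_props)[::-1]
    snp_props = [snp_props[i] for i in order]
    snp_names = [snp_names[i] for i in order]
    g_prop = fit.variance_components["genotype"] / var_y
    ge_prop = fit.variance_components["gxe"] / var_y
    residual = max(0.0, 1.0 - env_prop - sum(snp_props) - g_prop - ge_prop)
    return VarianceProfile(trait, snp_props, snp_names, float(g_prop), env_prop,
                           float(ge_prop), float(residual))


def profiles_table(profiles: list[VarianceProfile]) -> pd.DataFrame:
    """Tidy trait x component table (SNP columns padded with zeros)."""
    max_snps = max((len(p.snp_proportions) for p in profiles), default=0)
    rows = [p.as_row(max_snps) for p in profiles]
    return pd.DataFrame(rows).set_index("trait").fillna(0.0)


def cluster_traits(table: pd.DataFrame) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of traits on centered/scaled variance profiles.

    Returns (labels, linkage).  The number of clusters comes from cutting
    the dendrogram where the gap between successive merge heights is
    largest.  Requires at least 3 traits; constant columns are dropped with
    a warning before scaling.
    """
    if table.shape[0] < 3:
        raise ValueError("clustering requires at least 3 traits")
    sd = table.std(ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"constant columns dropped before scaling: {list(table.columns[~keep])}",
                      stacklevel=2)
    Z = (table.loc[:, keep] - table.loc[:, keep].mean()) / sd[keep]
    link = hierarchy.linkage(Z.to_numpy(), method="ward")
    heights = link[:, 2]
    # cut at the largest gap between successive merge heights
    gaps = np.diff(np.concatenate([[0.0], heights]))
    cut_at = int(np.argmax(gaps))
    n_clusters = len(heights) - cut_at + 1
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=table.index, name="cluster"), link
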