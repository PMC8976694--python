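"""Phenotype stage: spatial adjustment, heritability, clonal values, correlations.

Tree-level field records are first adjusted for smooth spatial heterogeneity
within each environment (location-year).  A low-rank tensor-product penalized
spline surface over the row/column grid is fitted as a random effect (the
REML fit of :mod:`orchardgx.lmm` chooses the smoothing), jointly with random
genotype effects; the adjusted value of a tree is its observation minus the
estimated surface.

From the adjusted values the stage computes environment-specific and
across-environment clonal-mean heritability

    H2 = sigma_g^2 / sigma_p^2

with sigma_p^2 = sigma_g^2 + sigma_eps^2 / n_r (single environment) or
sigma_p^2 = sigma_g^2 + sigma_ge^2/n_e + sigma_eps^2/(n_e n_r) (several
environments, environment fixed, genotype and GxE random), filters out
location-year-trait combinations with H2 below 0.1, and extracts clonal
values (genotype BLUPs) at across-location, location-specific and global
scope.  Strongly skewed traits are natural-log transformed before the BLUP
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from orchardgx.data import add_environment_column, environment_key
from orchardgx.lmm import LMMFit, RandomTerm, fit_lmm

HERITABILITY_THRESHOLD = 0.1


@dataclass
class AdjustedValues:
    """Spatially adjusted phenotypes for one environment and trait."""

    environment: str
    trait: str
    tree_values: pd.DataFrame  # input records + 'adjusted' and 'surface' columns
    genotype_values: pd.Series  # genotype-level adjusted value (mean of trees)
    spatial_fitted: bool = True


@dataclass
class HeritabilityEstimate:
    H2: float
    sigma_g2: float
    sigma_e2: float
    sigma_ge2: float
    n_r: float
    n_e: int
    scope: str  # 'environment-specific' | 'across-environment'
    flagged: bool = False


@dataclass
class ClonalValues:
    trait: str
    scope: str  # 'across-location' | 'location-specific' | 'global'
    values: pd.Series  # indexed by genotype
    transform: str = "none"
    location: str | None = None
    #: global values mix two fixed-effect structures and are not strictly
    #: comparable between across-location and single-location traits.
    mixed_scopes: bool = False


def _bspline_basis(x: np.ndarray, n_segments: int = 6, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.ones((len(x), 1))
    inner = np.linspace(lo, hi, n_segments + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    return BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()


def _second_diff_penalty(q: int) -> np.ndarray:
    if q < 3:
        return np.zeros((q, q))
    D = np.diff(np.eye(q), n=2, axis=0)
    return D.T @ D


def _tensor_spline_design(rows: np.ndarray, cols: np.ndarray, n_segments: int = 6):
    """Mixed-model representation of a 2-D P-spline surface.

    Returns ``(X_spat, Z_spat)``: the penalty null-space columns (linear
    row/column trends, excluding the constant) enter as fixed effects, the
    penalized range as iid random effects whose REML variance acts as the
    smoothing parameter.
    """
    Br = _bspline_basis(rows, n_segments)
    Bc = _bspline_basis(cols, n_segments)
    B = np.einsum("ij,ik->ijk", Br, Bc).reshape(len(rows), -1)
    qr, qc = Br.shape[1], Bc.shape[1]
    P = np.kron(_second_diff_penalty(qr), np.eye(qc)) + np.kron(np.eye(qr), _second_diff_penalty(qc))
    w, U = np.linalg.eigh(P)
    null = w < 1e-8 * max(w.max(), 1.0)
    X_all = B @ U[:, null]  # constant + linear trends
    # drop the constant direction (absorbed by the model intercept) and
    # orthonormalize what remains
    Xc = X_all - X_all.mean(axis=0)
    Uu, s, _ = np.linalg.svd(Xc, full_matrices=False)
    X_spat = Uu[:, s > 1e-8 * max(s.max(), 1.0)]
    Z_spat = B @ (U[:, ~null] / np.sqrt(w[~null]))
    return X_spat, Z_spat


def adjust_spatial(records: pd.DataFrame, environment: str | None = None,
                   n_segments: int = 6) -> AdjustedValues:
    """Adjust one environment's tree records for spatial heterogeneity.

    ``records`` must hold a single trait and a single (location, year); rows
    and columns are grid coordinates.  Records without coordinates trigger a
    fall-back with no spatial term (a logged warning), i.e. adjusted = raw.
    """
    recs = records.reset_index(drop=True)
    traits = recs["trait"].unique()
    if len(traits) != 1:
        raise ValueError("adjust_spatial expects a single trait")
    env_keys = {environment_key(l, y) for l, y in zip(recs["location"], recs["year"])}
    if len(env_keys) != 1:
        raise ValueError("adjust_spatial expects a single environment")
    env = environment or env_keys.pop()
    y = recs["value"].to_numpy(float)
    genotype = recs["genotype"]

    have_coords = not (recs["row"].isna().any() or recs["col"].isna().any())
    enough = (
        len(recs) >= 20
        and recs["row"].nunique() >= 3
        and recs["col"].nunique() >= 3
    )
    if not have_coords:
        warnings.warn(
            f"{env}: missing row/column coordinates; design-effects-only adjustment",
            stacklevel=2,
        )
        surface = np.zeros(len(recs))
    elif not enough:
        # too small a grid to support a surface; adjustment is the identity
        surface = np.zeros(len(recs))
    else:
        rows = recs["row"].to_numpy(float)
        cols = recs["col"].to_numpy(float)
        X_spat, Z_spat = _tensor_spline_design(rows, cols, n_segments)
        # the penalty null space (linear trends) is shrunk too, so a flat
        # field yields an (almost) identity adjustment; the surface does not
        # need fully converged variance components, so the EM budget is capped
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = fit_lmm(
                y,
                None,
                [
                    RandomTerm(genotype, name="genotype"),
                    RandomTerm(X_spat, name="trend"),
                    RandomTerm(Z_spat, name="spline"),
                ],
                max_iter=150,
                tol=1e-8,
            )
        surface = (
            X_spat @ fit.blups["trend"].to_numpy()
            + Z_spat @ fit.blups["spline"].to_numpy()
        )
        surface = surface - surface.mean()

    out = recs.copy()
    out["surface"] = surface
    out["adjusted"] = y - surface
    geno_vals = out.groupby("genotype")["adjusted"].mean()
    return AdjustedValues(env, str(traits[0]), out, geno_vals, spatial_fitted=have_coords)


def env_clonal_heritability(adjusted: AdjustedValues) -> HeritabilityEstimate:
    """Environment-specific clonal-mean heritability from a random-genotype model."""
    df = adjusted.tree_values
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    y = df["adjusted"].to_numpy(float)
    fit = fit_lmm(y, None, [RandomTerm(df["genotype"], name="genotype")])
    n_r = float(df.groupby("genotype").size().mean())
    sg, se = fit.variance_components["genotype"], fit.residual_variance
    flagged = False
    if (df.groupby("genotype").size() == 1).all():
        flagged = True
    sp = sg + se / n_r
    H2 = 0.0 if sp == 0 else sg / sp
    return HeritabilityEstimate(H2, sg, se, 0.0, n_r, 1, "environment-specific", flagged)


def across_env_heritability(adjusted_list: list[AdjustedValues]) -> HeritabilityEstimate:
    """Across-environment clonal-mean heritability.

    Environments enter as fixed effects, genotype and genotype-by-environment
    as random effects; the phenotypic variance uses the number of
    environments and the mean replication within environment.
    """
    if len(adjusted_list) < 2:
        raise ValueError("across-environment heritability needs >= 2 environments; "
                         "use env_clonal_heritability for a single one")
    frames = []
    for adj in adjusted_list:
        f = adj.tree_values[["genotype", "adjusted"]].copy()
        f["environment"] = adj.environment
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    env_d = pd.get_dummies(df["environment"], drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), env_d])
    ge = df["genotype"].astype(str) + ":" + df["environment"]
    fit = fit_lmm(
        df["adjusted"].to_numpy(float),
        X,
        [RandomTerm(df["genotype"], name="genotype"), RandomTerm(ge, name="gxe")],
    )
    n_e = df["environment"].nunique()
    n_r = float(df.groupby(["genotype", "environment"]).size().mean())
    sg = fit.variance_components["genotype"]
    sge = fit.variance_components["gxe"]
    se = fit.residual_variance
    sp = sg + sge / n_e + se / (n_e * n_r)
    H2 = 0.0 if sp == 0 else sg / sp
    return HeritabilityEstimate(H2, sg, se, sge, n_r, n_e, "across-environment")


def heritability_from_components(sigma_g2: float, sigma_e2: float, n_r: float,
                                 sigma_ge2: float = 0.0, n_e: int = 1) -> float:
    """Clonal-mean H2 from given variance components (the Eq-form arithmetic)."""
    sp = sigma_g2 + sigma_ge2 / n_e + sigma_e2 / (n_e * n_r)
    return 0.0 if sp == 0 else sigma_g2 / sp


def filter_low_heritability(
    estimates: dict[tuple, float], threshold: float = HERITABILITY_THRESHOLD
) -> set:
    """Keep (location, year, trait) combinations with H2 >= threshold.

    'Below threshold' is strict, so a combination exactly at the threshold is
    retained.
    """
    return {key for key, h2 in estimates.items() if h2 >= threshold}


def compute_clonal_values(
    adjusted_list: list[AdjustedValues],
    scope: str = "across-location",
    log_transform: bool = False,
) -> ClonalValues:
    """Genotype BLUPs (clonal values) from spatially adjusted tree values.

    across-location: location, year and their interaction fixed, genotype
    random.  location-specific: single location, year fixed, genotype random.
    ``log_transform`` applies the natural log first (values must be > 0).
    """
    if not adjusted_list:
        raise ValueError("no adjusted values supplied")
    frames = []
    for adj in adjusted_list:
        f = adj.tree_values[["genotype", "adjusted"]].copy()
        loc, yr = adj.environment.rsplit(".", 1)
        f["location"] = loc
        f["year"] = yr
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    trait = adjusted_list[0].trait

    y = df["adjusted"].to_numpy(float)
    if log_transform:
        if (y <= 0).any():
            raise ValueError(f"trait {trait!r}: non-positive values cannot be log-transformed")
        y = np.log(y)

    if scope == "across-location":
        fx = pd.get_dummies(df["location"].astype(str) + ":" + df["year"].astype(str), drop_first=True)
        X = np.column_stack([np.ones(len(df)), fx.to_numpy(float)])
    elif scope == "location-specific":
        if df["location"].nunique() != 1:
            raise ValueError("location-specific clonal values require a single location")
        fx = pd.get_dummies(df["year"], drop_first=True)
        X = np.column_stack([np.ones(len(df)), fx.to_numpy(float)])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    fit = fit_lmm(y, X, [RandomTerm(df["genotype"], name="genotype")])
    vals = fit.blups["genotype"]
    return ClonalValues(trait, scope, vals, "log" if log_transform else "none",
                        location=df["location"].iloc[0] if scope == "location-specific" else None)


def global_clonal_values(per_trait: dict[str, ClonalValues]) -> dict[str, ClonalValues]:
    """Assemble global clonal values: across-location where available,
    location-specific for traits measured at a single location only."""
    out = {}
    for trait, cv in per_trait.items():
        out[trait] = ClonalValues(
            trait, "global", cv.values, cv.transform,
            mixed_scopes=(cv.scope == "location-specific"),
        )
    return out


def trait_correlations(clonal: dict[str, ClonalValues]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait clonal values."""
    table = pd.DataFrame({t: cv.values for t, cv in clonal.items()})
    degenerate = table.std(skipna=True) == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance traits dropped from correlations: {list(table.columns[degenerate])}",
            stacklevel=2,
        )
    return table.corr(method="pearson", min_periods=2)


def environment_correlations(adjusted_list: list[AdjustedValues]) -> pd.DataFrame:
    """Pearson correlations between environments on genotype adjusted values."""
    table = pd.DataFrame({adj.environment: adj.genotype_values for adj in adjusted_list})
    return table.corr(method="pearson", min_periods=2)


def pca_scores(clonal: dict[str, ClonalValues], n_components: int = 2):
    """PCA of the genotype x trait global clonal-value table.

    The table is centered and scaled per trait; missing entries are replaced
    by the trait mean (i.e. zero after centering).  Returns (scores,
    loadings, explained_variance_ratio).
    """
    from sklearn.decomposition import PCA

    table = pd.DataFrame({t: cv.values for t, cv in clonal.items()})
    Z = (table - table.mean()) / table.std(ddof=0)
    Z = Z.fillna(0.0)
    pca = PCA(n_components=min(n_components, Z.shape[1]))
    scores = pca.fit_transform(Z.to_numpy())
    return (
        pd.DataFrame(scores, index=table.index,
                     columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        pd.DataFrame(pca.components_.T, index=table.columns,
                     columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        pca.explained_variance_ratio_,
    )
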