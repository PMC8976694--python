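"""Synthetic genotypes, pedigrees and multi-environment trial phenotypes.

The generator emulates a clonally replicated perennial-crop reference
population: a diverse accession group plus biparental progeny families with a
recorded ancestor chain, LD-structured biallelic SNP genotypes, and
multi-location multi-year trials in which every genotype is replicated as
grafted trees on a spatial grid.  All variance components are planted with
known ground truth so that recovery can be asserted exactly.

Phenotype model per tree::

    y = mu + env_effect + genetic_value + gxe_deviation + spatial(row, col) + residual

with ``genetic_value = QTL part + polygenic tail`` shared across environments
and every component scaled so its realized variance over trees matches the
requested fraction of a unit total phenotypic variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from orchardgx.data import GenotypeMatrix, PedigreeTable, environment_key


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class TraitSpec:
    """Variance architecture of one simulated trait.

    Fractions refer to the total phenotypic variance of single trees and must
    sum to one (the spatial field is added on top, scaled by
    ``SimConfig.spatial_field_sd``, and is regarded as nuisance to be removed
    by the adjustment stage rather than a phenotypic variance component).
    """

    name: str
    n_qtl: int = 0
    qtl_variance_fraction: float = 0.0
    polygenic_variance_fraction: float = 0.3
    env_variance_fraction: float = 0.3
    gxe_variance_fraction: float = 0.1
    residual_variance_fraction: float = 0.3
    skewed: bool = False
    #: compound-symmetry correlation of the G×E deviations across
    #: environments; > 0 makes environments genetically more alike so that
    #: reference-environment records are informative (CV2-style designs).
    gxe_env_correlation: float = 0.0
    mean: float = 10.0

    def __post_init__(self) -> None:
        fracs = self.variance_fractions()
        if any(f < 0 for f in fracs.values()):
            raise ConfigurationError("variance fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"variance fractions of trait {self.name!r} sum to "
                f"{sum(fracs.values()):.4f}, expected 1"
            )
        if self.n_qtl == 0 and self.qtl_variance_fraction > 0:
            raise ConfigurationError("qtl_variance_fraction > 0 requires n_qtl > 0")
        if not 0 <= self.gxe_env_correlation < 1:
            raise ConfigurationError("gxe_env_correlation must be in [0, 1)")

    def variance_fractions(self) -> dict[str, float]:
        return {
            "qtl": self.qtl_variance_fraction,
            "polygenic": self.polygenic_variance_fraction,
            "environment": self.env_variance_fraction,
            "gxe": self.gxe_variance_fraction,
            "residual": self.residual_variance_fraction,
        }


@dataclass
class SimConfig:
    """Dimensions and rates of the simulated population and trial network."""

    n_accessions: int = 200
    n_crosses: int = 10
    progeny_per_cross: int = 10
    n_ancestor_generations: int = 5
    m_markers: int = 2000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 30_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    recomb_rate_per_bp: float = 1e-8
    trait_specs: list[TraitSpec] = field(default_factory=list)
    environments: list[tuple[str, int]] = field(
        default_factory=lambda: [("CHE", 2018), ("CHE", 2019), ("FRA", 2018), ("FRA", 2019)]
    )
    replicates_per_env: int = 2
    spatial_field_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in (
            "n_accessions",
            "n_crosses",
            "progeny_per_cross",
            "n_ancestor_generations",
            "m_markers",
            "n_chromosomes",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.replicates_per_env < 1:
            raise ConfigurationError("replicates_per_env must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if not self.environments:
            raise ConfigurationError("at least one environment required")


@dataclass
class GroundTruth:
    """Planted truth of one simulated trait, aligned with its records."""

    trait: str
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    #: (n_genotypes, n_environments) total genetic value per environment
    #: (shared genetic value + G×E deviation), on the latent (pre-exp) scale.
    genetic_values: np.ndarray
    genotype_ids: list[str]
    environment_ids: list[str]
    variance_components: dict[str, float]
    #: per-record planted components, row-aligned with the PhenotypeRecords.
    tree_components: pd.DataFrame
    log_scale: bool = False

    def shared_genetic_values(self) -> np.ndarray:
        """Across-environment (main-effect) genetic value per genotype."""
        return self.genetic_values.mean(axis=1)


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.m_markers // config.n_chromosomes)
    per_chrom[: config.m_markers % config.n_chromosomes] += 1
    rows = []
    for c, m_c in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, config.chromosome_length_bp + 1), size=m_c, replace=False))
        for p in pos:
            rows.append((f"chr{c}_{p}", c, int(p)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"])


def simulate_founder_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate LD-structured founder (accession) genotypes.

    Haplotype alleles come from a latent AR(1) Gaussian process along each
    chromosome (autocorrelation ``ld_rho`` between adjacent markers),
    thresholded at the quantile of a per-marker allele frequency drawn
    uniformly from ``maf_range``.  Adjacent-marker LD therefore decays
    geometrically with marker distance.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mmap = _marker_map(config, rng)
    n = config.n_accessions
    n_hap = 2 * n
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.m_markers)
    thresholds = stats.norm.ppf(freqs)
    haplo = np.empty((n_hap, config.m_markers), dtype=np.int8)
    for c in mmap["chrom"].unique():
        idx = np.flatnonzero(mmap["chrom"].to_numpy() == c)
        m_c = len(idx)
        e = rng.standard_normal((n_hap, m_c))
        if config.ld_rho > 0:
            x = e * math.sqrt(1.0 - config.ld_rho**2)
            x[:, 0] = e[:, 0]
            z = signal.lfilter([1.0], [1.0, -config.ld_rho], x, axis=1)
        else:
            z = e
        haplo[:, idx] = (z < thresholds[idx]).astype(np.int8)
    haplotypes = haplo.reshape(n, 2, config.m_markers)
    dosages = haplotypes.sum(axis=1, dtype=np.int8)
    samples = [f"ACC{i:04d}" for i in range(n)]
    groups = pd.Series(["accession"] * n)
    return GenotypeMatrix(dosages, samples, mmap, groups=groups, haplotypes=haplotypes)


def _meiosis(parent_haps: np.ndarray, mmap: pd.DataFrame, config: SimConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete from a (2, m) phased parent, Haldane model (no interference)."""
    gamete = np.empty(parent_haps.shape[1], dtype=np.int8)
    chrom = mmap["chrom"].to_numpy()
    pos = mmap["pos"].to_numpy()
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        length_morgans = config.chromosome_length_bp * config.recomb_rate_per_bp
        n_xo = rng.poisson(length_morgans)
        phase = rng.integers(0, 2)
        if n_xo > 0:
            xo_pos = np.sort(rng.uniform(0, config.chromosome_length_bp, size=n_xo))
            # phase flips at every crossover left of a marker
            flips = np.searchsorted(xo_pos, pos[idx])
            strand = (phase + flips) % 2
        else:
            strand = np.full(len(idx), phase)
        gamete[idx] = parent_haps[strand, idx]
    return gamete


def simulate_pedigree_genotypes(
    founders: GenotypeMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Breed an ancestor chain and progeny families from the founders.

    A linear chain of crosses spans ``n_ancestor_generations``: the deepest
    generation consists of founder accessions, every later generation is bred
    from the one before it, and the final progeny group of
    ``n_crosses x progeny_per_cross`` genotypes descends from generation-1
    parents.  Returns the genotypes of all bred individuals (ancestors and
    progeny) and the pedigree of everyone involved, progeny labelled
    generation 0.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if founders.haplotypes is None:
        raise ValueError("founders must carry phased haplotypes")
    depth = config.n_ancestor_generations
    chain_size = max(2 * config.n_crosses, 4)
    mmap = founders.marker_map

    ped_rows: list[tuple[str, str, str, int]] = []
    hap_store: dict[str, np.ndarray] = {}

    founder_idx = rng.choice(founders.n_samples, size=min(chain_size, founders.n_samples), replace=False)
    current = [founders.samples[i] for i in founder_idx]
    for s, i in zip(current, founder_idx):
        hap_store[s] = founders.haplotypes[i]
        ped_rows.append((s, "", "", depth))

    new_ids: list[str] = []
    for g in range(depth - 1, 0, -1):
        nxt = []
        for j in range(chain_size):
            p1, p2 = rng.choice(current, size=2, replace=False)
            child = f"ANC{g}_{j:03d}"
            hap_store[child] = np.stack(
                [_meiosis(hap_store[p1], mmap, config, rng), _meiosis(hap_store[p2], mmap, config, rng)]
            )
            ped_rows.append((child, p1, p2, g))
            nxt.append(child)
            new_ids.append(child)
        current = nxt

    parents_pool = current
    for k in range(config.n_crosses):
        p1, p2 = rng.choice(parents_pool, size=2, replace=False)
        for j in range(config.progeny_per_cross):
            child = f"PRO{k:02d}_{j:03d}"
            hap_store[child] = np.stack(
                [_meiosis(hap_store[p1], mmap, config, rng), _meiosis(hap_store[p2], mmap, config, rng)]
            )
            ped_rows.append((child, p1, p2, 0))
            new_ids.append(child)

    haplotypes = np.stack([hap_store[s] for s in new_ids])
    dosages = haplotypes.sum(axis=1, dtype=np.int8)
    groups = pd.Series(["progeny" if s.startswith("PRO") else "ancestor" for s in new_ids])
    bred = GenotypeMatrix(dosages, new_ids, mmap.reset_index(drop=True), groups=groups, haplotypes=haplotypes)
    ped = PedigreeTable(pd.DataFrame(ped_rows, columns=["id", "parent1", "parent2", "generation"]))
    return bred, ped


def combine_genotypes(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two genotype matrices sharing a marker map."""
    if not a.marker_map["marker"].equals(b.marker_map["marker"]):
        raise ValueError("marker maps differ")
    groups = pd.concat(
        [
            a.groups if a.groups is not None else pd.Series(["?"] * a.n_samples),
            b.groups if b.groups is not None else pd.Series(["?"] * b.n_samples),
        ],
        ignore_index=True,
    )
    haps = None
    if a.haplotypes is not None and b.haplotypes is not None:
        haps = np.concatenate([a.haplotypes, b.haplotypes])
    return GenotypeMatrix(
        np.concatenate([a.dosages, b.dosages]),
        list(a.samples) + list(b.samples),
        a.marker_map.reset_index(drop=True),
        groups=groups,
        haplotypes=haps,
    )


def simulate_population(config: SimConfig) -> dict:
    """Founders + bred individuals in one call.

    Returns a dict with ``founders``, ``bred``, ``pedigree`` and ``study``,
    the latter being the accession + progeny study population that enters the
    trial stages (intermediate ancestors are genotyped but not planted).
    """
    rng = np.random.default_rng(config.seed)
    founders = simulate_founder_genotypes(config, rng)
    bred, ped = simulate_pedigree_genotypes(founders, config, rng)
    progeny_ids = [s for s in bred.samples if s.startswith("PRO")]
    study = combine_genotypes(founders, bred.subset_samples(progeny_ids))
    return {"founders": founders, "bred": bred, "pedigree": ped, "study": study}


def _scale_to_sd(x: np.ndarray, target_sd: float) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0 or target_sd == 0:
        return np.zeros_like(x) if target_sd == 0 else x
    return x * (target_sd / sd)


def _spatial_surface(rows: np.ndarray, cols: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth field: 2-4 Gaussian bumps plus linear row/column gradients."""
    if sd == 0:
        return np.zeros(len(rows), dtype=float)
    r01 = rows / max(rows.max(), 1)
    c01 = cols / max(cols.max(), 1)
    surf = rng.normal(0, 0.5) * r01 + rng.normal(0, 0.5) * c01
    for _ in range(rng.integers(2, 5)):
        cr, cc = rng.uniform(0, 1, size=2)
        width = rng.uniform(0.15, 0.4)
        amp = rng.normal(0, 1)
        surf = surf + amp * np.exp(-((r01 - cr) ** 2 + (c01 - cc) ** 2) / (2 * width**2))
    surf = surf - surf.mean()
    return _scale_to_sd(surf, sd)


def simulate_multienv_trial(
    genotypes: GenotypeMatrix,
    spec: TraitSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate tree-level phenotype records for one trait.

    Every genotype is planted ``replicates_per_env`` times per environment on
    a near-square row/column grid.  Component draws are rescaled so that each
    realized variance over trees equals its requested fraction of a unit
    total phenotypic variance exactly; realized fractions are reported in the
    returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed + 7) if rng is None else rng
    n = genotypes.n_samples
    envs = [environment_key(loc, yr) for loc, yr in config.environments]
    r = len(envs)
    reps = config.replicates_per_env

    X = genotypes.dosages.astype(float)
    maf = genotypes.maf()

    # QTL part: equal variance share per QTL so per-locus R^2 is controllable.
    if spec.n_qtl > 0:
        eligible = np.flatnonzero(maf >= 0.1)
        if len(eligible) < spec.n_qtl:
            eligible = np.argsort(maf)[::-1][: spec.n_qtl]
        # spread QTL out so that planted loci are in weak mutual LD
        min_gap = max(1, genotypes.n_markers // (4 * spec.n_qtl))
        chosen: list[int] = []
        for k in rng.permutation(eligible):
            if all(abs(int(k) - c) >= min_gap for c in chosen):
                chosen.append(int(k))
            if len(chosen) == spec.n_qtl:
                break
        while len(chosen) < spec.n_qtl:  # fallback if spacing infeasible
            k = int(rng.choice(eligible))
            if k not in chosen:
                chosen.append(k)
        qtl_idx = np.sort(np.array(chosen))
        per_qtl_sd = math.sqrt(spec.qtl_variance_fraction / spec.n_qtl)
        signs = rng.choice([-1.0, 1.0], size=spec.n_qtl)
        qtl_effects = np.zeros(spec.n_qtl)
        g_qtl = np.zeros(n)
        for j, k in enumerate(qtl_idx):
            z = X[:, k] - X[:, k].mean()
            sd = z.std()
            beta = 0.0 if sd == 0 else signs[j] * per_qtl_sd / sd
            qtl_effects[j] = beta
            g_qtl += beta * z
        # rescale the summed QTL part to its exact fraction (residual LD
        # between planted loci would otherwise inflate it)
        scale = per_qtl_sd * math.sqrt(spec.n_qtl) / max(g_qtl.std(), 1e-12)
        g_qtl *= scale
        qtl_effects *= scale
    else:
        qtl_idx = np.array([], dtype=int)
        qtl_effects = np.array([])
        g_qtl = np.zeros(n)

    # Polygenic tail over all non-QTL markers.
    if spec.polygenic_variance_fraction > 0:
        poly_mask = np.ones(genotypes.n_markers, bool)
        poly_mask[qtl_idx] = False
        poly_mask &= X.std(axis=0) > 0
        b = rng.standard_normal(int(poly_mask.sum()))
        g_poly = (X[:, poly_mask] - X[:, poly_mask].mean(axis=0)) @ b
        g_poly = g_poly - g_poly.mean()
        if spec.n_qtl > 0 and g_qtl.std() > 0:
            # orthogonalize against the QTL part so fractions are additive
            g_poly -= g_qtl * (g_poly @ g_qtl) / (g_qtl @ g_qtl)
        g_poly = _scale_to_sd(g_poly, math.sqrt(spec.polygenic_variance_fraction))
    else:
        g_poly = np.zeros(n)
    g = g_qtl + g_poly

    # Environment main effects (variance over trees = env fraction; balanced
    # design, so the variance over environments equals it too).
    if spec.env_variance_fraction > 0 and r > 1:
        env_eff = rng.standard_normal(r)
        env_eff = _scale_to_sd(env_eff - env_eff.mean(), math.sqrt(spec.env_variance_fraction))
    else:
        env_eff = np.zeros(r)

    # G×E deviations: environment-specific polygenic effects (marker effects
    # that change across environments), with compound-symmetry correlation
    # rho between the per-environment marker-effect vectors.
    if spec.gxe_variance_fraction > 0 and r > 1:
        rho = spec.gxe_env_correlation
        Xc = X - X.mean(axis=0)
        c0 = rng.standard_normal(genotypes.n_markers)
        cols = []
        for _ in range(r):
            ce = math.sqrt(rho) * c0 + math.sqrt(1 - rho) * rng.standard_normal(genotypes.n_markers)
            ue = Xc @ ce
            ue = ue - ue.mean()
            if g.std() > 0:  # keep deviations orthogonal to the main genetic value
                ue -= g * (ue @ g) / (g @ g)
            cols.append(ue)
        gxe = np.column_stack(cols)
        gxe = _scale_to_sd(gxe, math.sqrt(spec.gxe_variance_fraction))
    else:
        gxe = np.zeros((n, r))

    mu = math.log(spec.mean) if spec.skewed else spec.mean

    records = []
    comp_rows = []
    n_plots = n * reps
    ncol = int(math.ceil(math.sqrt(n_plots)))
    for e_i, (loc, yr) in enumerate(config.environments):
        order = rng.permutation(np.repeat(np.arange(n), reps))
        plot_rows = np.arange(n_plots) // ncol
        plot_cols = np.arange(n_plots) % ncol
        surf = _spatial_surface(plot_rows, plot_cols, config.spatial_field_sd, rng)
        resid = rng.standard_normal(n_plots)
        resid = _scale_to_sd(resid - resid.mean(), math.sqrt(spec.residual_variance_fraction))
        for t in range(n_plots):
            i = order[t]
            latent = mu + env_eff[e_i] + g[i] + gxe[i, e_i] + surf[t] + resid[t]
            value = math.exp(latent) if spec.skewed else latent
            records.append(
                (genotypes.samples[i], loc, yr, int(plot_rows[t]), int(plot_cols[t]), spec.name, value)
            )
            comp_rows.append((envs[e_i], env_eff[e_i], g[i], gxe[i, e_i], surf[t], resid[t]))

    records_df = pd.DataFrame(
        records, columns=["genotype", "location", "year", "row", "col", "trait", "value"]
    )
    comps = pd.DataFrame(
        comp_rows, columns=["environment", "env_effect", "genetic", "gxe", "spatial", "residual"]
    )
    total_var = float(
        np.var(comps[["env_effect", "genetic", "gxe", "residual"]].sum(axis=1))
    )
    realized = {
        "qtl": float(np.var(g_qtl)),
        "polygenic": float(np.var(g_poly)),
        "environment": float(np.var(comps["env_effect"])),
        "gxe": float(np.var(comps["gxe"])),
        "residual": float(np.var(comps["residual"])),
        "total": total_var,
    }
    truth = GroundTruth(
        trait=spec.name,
        qtl_indices=qtl_idx,
        qtl_effects=qtl_effects,
        genetic_values=g[:, None] + gxe,
        genotype_ids=list(genotypes.samples),
        environment_ids=envs,
        variance_components=realized,
        tree_components=comps,
        log_scale=spec.skewed,
    )
    return records_df, truth
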