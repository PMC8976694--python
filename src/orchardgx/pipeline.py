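"""End-to-end orchestration: adjust -> heritability filter -> clonal values ->
GWAS -> genomic prediction -> variance decomposition.

The pipeline mirrors the stage order of a full multi-environment trial
analysis.  Every stage writes its table under the output directory and the
run closes with a machine-readable manifest (configuration, seed, stage
outputs, package version), so a rerun with the same configuration and seed
reproduces the same files.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import orchardgx
from orchardgx import io as oio
from orchardgx.data import GenotypeMatrix, PedigreeTable, add_environment_column
from orchardgx.evaluation import cross_validate_main, make_cv_plan
from orchardgx.gp import GibbsConfig, build_kernels, fit_bayescpi, fit_gblup, genomic_heritability
from orchardgx.gwas import associations_to_frame, blink_scan
from orchardgx.pheno import (
    AdjustedValues,
    HERITABILITY_THRESHOLD,
    adjust_spatial,
    across_env_heritability,
    compute_clonal_values,
    env_clonal_heritability,
    filter_low_heritability,
    global_clonal_values,
)
from orchardgx.vardecomp import decompose_variance, profiles_table


@dataclass
class PipelineConfig:
    """Paths, trait list and stage settings of one pipeline run."""

    genotype_dosages: str
    genotype_map: str
    phenotypes: str
    out_dir: str
    pedigree: str | None = None
    catalog: str | None = None
    log_traits: list[str] = field(default_factory=list)
    heritability_threshold: float = HERITABILITY_THRESHOLD
    gwas_n_pcs: int = 2
    gwas_maf_min: float = 0.05
    gwas_alpha: float = 0.05
    prediction_models: list[str] = field(default_factory=lambda: ["gblup"])
    gibbs_iterations: int = 12000
    gibbs_thinning: int = 5
    gibbs_burn_in: int = 2000
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        for attr in ("genotype_dosages", "genotype_map", "phenotypes"):
            p = getattr(cfg, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        return cfg


def load_inputs(config: PipelineConfig):
    genotypes = oio.read_dosage_tsv(config.genotype_dosages, config.genotype_map)
    phenotypes = oio.read_phenotypes(config.phenotypes, known_genotypes=genotypes.samples)
    pedigree = oio.read_pedigree(config.pedigree) if config.pedigree else None
    catalog = oio.read_catalog(config.catalog) if config.catalog else None
    overlap = set(phenotypes["genotype"]) & set(genotypes.samples)
    if not overlap:
        raise ValueError("no genotype ids shared between genotype and phenotype inputs")
    return genotypes, phenotypes, pedigree, catalog


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "orchardgx",
        "version": orchardgx.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
    }
    stage = "load"
    try:
        genotypes, phenotypes, pedigree, catalog = load_inputs(config)
        phenotypes = add_environment_column(phenotypes)
        traits = sorted(phenotypes["trait"].unique())

        # 1. spatial adjustment per trait x environment
        stage = "adjust"
        adjusted: dict[str, dict[str, AdjustedValues]] = {}
        rows = []
        for trait in traits:
            adjusted[trait] = {}
            sub_t = phenotypes[phenotypes["trait"] == trait]
            if trait in config.log_traits:
                # strongly skewed traits are treated as multiplicative: the
                # spatial model and all later stages act on the log scale
                if (sub_t["value"] <= 0).any():
                    raise ValueError(f"trait {trait!r}: non-positive values cannot be log-transformed")
                sub_t = sub_t.assign(value=np.log(sub_t["value"]))
            for env, sub in sub_t.groupby("environment"):
                adj = adjust_spatial(sub.drop(columns="environment"))
                adjusted[trait][env] = adj
                rows.append(adj.tree_values.assign(environment=env))
        adj_table = pd.concat(rows, ignore_index=True)
        adj_table.to_csv(out / "adjusted_phenotypes.csv", index=False)
        manifest["stages"]["adjust"] = {"rows": len(adj_table)}

        # 2. environment-specific heritability and filtering
        stage = "heritability"
        h2_rows = []
        est = {}
        for trait in traits:
            for env, adj in adjusted[trait].items():
                h = env_clonal_heritability(adj)
                loc, yr = env.rsplit(".", 1)
                est[(loc, yr, trait)] = h.H2
                h2_rows.append({"trait": trait, "environment": env, "H2": h.H2,
                                "sigma_g2": h.sigma_g2, "sigma_e2": h.sigma_e2,
                                "n_r": h.n_r, "scope": h.scope})
        retained = filter_low_heritability(est, config.heritability_threshold)
        for trait in traits:
            adjusted[trait] = {
                env: adj for env, adj in adjusted[trait].items()
                if (env.rsplit(".", 1)[0], env.rsplit(".", 1)[1], trait) in retained
            }
        # across-environment heritability on the retained environments
        for trait in traits:
            adjs = list(adjusted[trait].values())
            if len(adjs) >= 2:
                h = across_env_heritability(adjs)
                h2_rows.append({"trait": trait, "environment": "across", "H2": h.H2,
                                "sigma_g2": h.sigma_g2, "sigma_e2": h.sigma_e2,
                                "n_r": h.n_r, "scope": h.scope})
        pd.DataFrame(h2_rows).to_csv(out / "heritability.csv", index=False)
        manifest["stages"]["heritability"] = {
            "n_combinations": len(est), "n_retained": len(retained),
        }

        # 3. clonal values (across-location; location-specific for
        #    single-location traits), assembled into global clonal values
        stage = "clonal"
        per_trait = {}
        for trait in traits:
            adjs = list(adjusted[trait].values())
            if not adjs:
                warnings.warn(f"trait {trait!r}: no environments retained", stacklevel=2)
                continue
            locations = {a.environment.rsplit(".", 1)[0] for a in adjs}
            scope = "across-location" if len(locations) > 1 else "location-specific"
            cv = compute_clonal_values(adjs, scope)  # log already applied upstream
            if trait in config.log_traits:
                cv.transform = "log"
            per_trait[trait] = cv
        clonal = global_clonal_values(per_trait)
        clonal_table = pd.DataFrame({t: cv.values for t, cv in clonal.items()})
        clonal_table.to_csv(out / "clonal_values.csv")
        manifest["stages"]["clonal"] = {"traits": list(clonal)}

        # 4. GWAS on global clonal values
        stage = "gwas"
        all_assocs = []
        assoc_by_trait = {}
        for trait, cv in clonal.items():
            scan = blink_scan(
                genotypes, cv.values, trait=trait, scope="global",
                n_pcs=config.gwas_n_pcs, maf_min=config.gwas_maf_min,
                alpha=config.gwas_alpha,
            )
            assoc_by_trait[trait] = scan.associations
            all_assocs.extend(scan.associations)
        assoc_frame = associations_to_frame(all_assocs)
        assoc_frame.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["stages"]["gwas"] = {"n_associations": len(all_assocs)}

        # 5. genomic prediction with cross-validation + genomic heritability
        stage = "predict"
        kb = build_kernels(genotypes)
        Mc = genotypes.dosages.astype(float)
        Mc = Mc - Mc.mean(axis=0)
        gc = GibbsConfig(config.gibbs_iterations, config.gibbs_thinning,
                         config.gibbs_burn_in, config.seed)
        ability_rows = []
        h2_genomic = {}
        for trait, cv in clonal.items():
            y = cv.values.reindex(kb.samples)
            plan = make_cv_plan(list(y.dropna().index), k=config.cv_folds,
                                repeats=config.cv_repeats, scenario="main",
                                seed=config.seed)
            for model in config.prediction_models:
                fit_predict = _main_model(model, kb, Mc, gc)
                ability_rows.append(
                    cross_validate_main(y.dropna(), fit_predict, plan, trait, model)
                )
            bfit = fit_bayescpi(y.to_numpy(), Mc, gc)
            h2_genomic[trait] = genomic_heritability(bfit)
        abilities = pd.concat(ability_rows, ignore_index=True)
        abilities.to_csv(out / "predictive_ability.csv", index=False)
        oio.write_json(h2_genomic, out / "genomic_heritability.json")
        manifest["stages"]["predict"] = {
            "models": config.prediction_models,
            "n_ability_records": len(abilities),
        }

        # 6. variance decomposition per trait + trait clustering
        stage = "decompose"
        profiles = []
        for trait in traits:
            adjs = adjusted.get(trait, {})
            if not adjs:
                continue
            frames = [a.tree_values.assign(environment=a.environment) for a in adjs.values()]
            recs = pd.concat(frames, ignore_index=True)
            snp_dos = {}
            midx = {m: i for i, m in enumerate(genotypes.marker_map["marker"])}
            for a in assoc_by_trait.get(trait, []):
                snp_dos[a.marker] = pd.Series(
                    genotypes.dosages[:, midx[a.marker]], index=genotypes.samples
                )
            profiles.append(decompose_variance(recs, snp_dos or None))
        prof_table = profiles_table(profiles)
        prof_table.to_csv(out / "variance_profiles.csv")
        if len(prof_table) >= 3:
            from orchardgx.vardecomp import cluster_traits

            labels, _ = cluster_traits(prof_table)
            labels.to_csv(out / "trait_clusters.csv")
        manifest["stages"]["decompose"] = {"n_traits": len(profiles)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        oio.write_json(manifest, out / "manifest.json")
        raise

    manifest["runtime_s"] = round(time.time() - t0, 1)
    manifest["hash"] = _manifest_hash(out)
    oio.write_json(manifest, out / "manifest.json")
    return manifest


def _main_model(model: str, kb, Mc, gc: GibbsConfig):
    """fit_predict closure for the main-effect CV engine."""
    import pandas as pd

    samples = kb.samples

    if model == "gblup":
        def fp(masked_y: pd.Series) -> pd.Series:
            y = masked_y.reindex(samples)
            fit = fit_gblup(y, kb.G, gc)
            return pd.Series(fit.u.to_numpy(), index=samples)
        return fp
    if model == "bayescpi":
        def fp(masked_y: pd.Series) -> pd.Series:
            y = masked_y.reindex(samples)
            fit = fit_bayescpi(y.to_numpy(), Mc, gc)
            return pd.Series(fit.u.to_numpy(), index=samples)
        return fp
    if model == "rkhs":
        from orchardgx.gp import fit_rkhs_multikernel

        def fp(masked_y: pd.Series) -> pd.Series:
            y = masked_y.reindex(samples)
            fit = fit_rkhs_multikernel(y.to_numpy(), list(kb.kernels.values()), gc)
            return pd.Series(fit.u.to_numpy(), index=samples)
        return fp
    if model == "rf":
        from orchardgx.gp import fit_rf

        def fp(masked_y: pd.Series) -> pd.Series:
            y = masked_y.reindex(samples)
            rf = fit_rf(y.to_numpy(), kb.M, seed=gc.seed)
            return pd.Series(rf.predict(kb.M), index=samples)
        return fp
    raise ValueError(f"unknown prediction model {model!r}")


def _manifest_hash(out_dir: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(out_dir.glob("*.csv")) + sorted(out_dir.glob("*.tsv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]
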