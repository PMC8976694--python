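"""Cross-validation engine and predictive-ability bookkeeping.

Five-fold cross-validation masks the phenotypes of 20% of the genotypes per
fold.  Scenarios:

* ``main`` — masks global clonal values (single-response models);
* ``CV1``  — masks a genotype's records in every environment (completely
  untested material);
* ``CV2``  — masks them in every environment except designated reference
  environments (material phenotyped at the breeding site only).

Predictive ability is the Pearson correlation between the observed values of
the masked genotypes and their predictions, per environment for the
multi-environment scenarios.  Repeating the 5-fold split five times yields
25 estimates per trait and model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_PAIRS = 3


@dataclass
class CVPlan:
    """Fold assignments per repeat for a set of genotypes."""

    genotypes: list[str]
    k_folds: int
    repeats: int
    scenario: str  # 'main' | 'CV1' | 'CV2'
    assignments: np.ndarray  # (repeats, n) fold index per genotype
    reference_environments: list[str] = field(default_factory=list)
    seed: int = 0

    def masked_genotypes(self, repeat: int, fold: int) -> list[str]:
        mask = self.assignments[repeat] == fold
        return [g for g, m in zip(self.genotypes, mask) if m]

    def iter_folds(self):
        for rep in range(self.repeats):
            for fold in range(self.k_folds):
                yield rep, fold, self.masked_genotypes(rep, fold)


def make_cv_plan(
    genotypes,
    k: int = 5,
    repeats: int = 5,
    scenario: str = "main",
    reference_envs=None,
    seed: int = 0,
) -> CVPlan:
    """Random k-fold partitions of the genotypes, reshuffled per repeat."""
    genotypes = list(genotypes)
    n = len(genotypes)
    if k > n:
        raise ValueError("more folds than genotypes")
    if scenario not in {"main", "CV1", "CV2"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    reference_envs = list(reference_envs or [])
    if scenario == "CV2" and not reference_envs:
        raise ValueError("CV2 requires reference environments")
    if scenario != "CV2" and reference_envs:
        raise ValueError("reference environments only apply to CV2")
    master = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    base = np.arange(n) % k  # sizes differ by at most 1
    for rep in range(repeats):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = base
        assignments[rep] = folds
    return CVPlan(genotypes, k, repeats, scenario, assignments, reference_envs, seed)


def apply_mask_series(y: pd.Series, masked: list[str]) -> pd.Series:
    """Main-effect masking: NaN out the clonal values of masked genotypes."""
    out = y.copy().astype(float)
    out.loc[out.index.intersection(masked)] = np.nan
    return out


def apply_mask_env(Y: pd.DataFrame, masked: list[str], plan: CVPlan) -> pd.DataFrame:
    """CV1/CV2 masking of a genotype x environment table."""
    out = Y.copy().astype(float)
    rows = out.index.intersection(masked)
    if plan.scenario == "CV1":
        out.loc[rows, :] = np.nan
    elif plan.scenario == "CV2":
        cols = [c for c in out.columns if c not in plan.reference_environments]
        out.loc[rows, cols] = np.nan
    else:
        raise ValueError("environment masking requires scenario CV1 or CV2")
    return out


def predictive_ability(
    observed: pd.Series | pd.DataFrame,
    predicted: pd.Series | pd.DataFrame,
    trait: str = "trait",
    model: str = "model",
    scenario: str = "main",
    fold: int = 0,
    repeat: int = 0,
) -> pd.DataFrame:
    """Pearson correlation of observed vs predicted for masked genotypes.

    Series inputs yield one 'global' record; DataFrame inputs (genotype x
    environment) yield one record per environment.  Groups with fewer than
    three pairs or constant predictions are reported as missing with a
    warning.
    """

    def one(obs: pd.Series, pred: pd.Series, env: str):
        common = obs.index.intersection(pred.index)
        o = obs.loc[common].astype(float)
        p = pred.loc[common].astype(float)
        ok = np.isfinite(o) & np.isfinite(p)
        o, p = o[ok], p[ok]
        if len(o) < MIN_PAIRS or np.std(p) == 0 or np.std(o) == 0:
            warnings.warn(f"{env}: predictive ability undefined (n={len(o)})", stacklevel=3)
            r = np.nan
        else:
            r = float(np.corrcoef(o, p)[0, 1])
        return {
            "trait": trait, "model": model, "scenario": scenario, "fold": fold,
            "repeat": repeat, "environment": env, "r": r, "n_pairs": int(len(o)),
        }

    if isinstance(observed, pd.Series):
        if not isinstance(predicted, pd.Series):
            raise TypeError("observed and predicted must both be Series or both DataFrames")
        return pd.DataFrame([one(observed, predicted, "global")])
    records = []
    for env in observed.columns:
        if env not in predicted.columns:
            raise KeyError(f"environment {env!r} missing from predictions")
        records.append(one(observed[env], predicted[env], env))
    return pd.DataFrame(records)


def aggregate_abilities(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean predictive ability per trait/model/scenario and per model/scenario.

    Missing correlations are excluded; counts of contributing estimates are
    reported alongside the means.
    """
    ok = records.dropna(subset=["r"])
    per_trait = (
        ok.groupby(["trait", "model", "scenario"])["r"]
        .agg(r_mean="mean", n="count")
        .reset_index()
    )
    per_model = (
        ok.groupby(["model", "scenario"])["r"].agg(r_mean="mean", n="count").reset_index()
    )
    return per_trait, per_model


def cross_validate_main(
    y: pd.Series,
    fit_predict,
    plan: CVPlan,
    trait: str = "trait",
    model: str = "model",
) -> pd.DataFrame:
    """Run main-effect CV: ``fit_predict(masked_y) -> pd.Series`` of GEBVs."""
    records = []
    for rep, fold, masked in plan.iter_folds():
        masked_y = apply_mask_series(y, masked)
        pred = fit_predict(masked_y)
        obs = y.loc[y.index.intersection(masked)]
        records.append(
            predictive_ability(obs, pred, trait, model, plan.scenario, fold, rep)
        )
    return pd.concat(records, ignore_index=True)


def cross_validate_multienv(
    Y: pd.DataFrame,
    fit_predict,
    plan: CVPlan,
    trait: str = "trait",
    model: str = "model",
) -> pd.DataFrame:
    """Run CV1/CV2: ``fit_predict(masked_Y) -> DataFrame`` of per-environment
    genetic predictions; ability is scored per predicted environment on the
    masked genotypes only."""
    records = []
    for rep, fold, masked in plan.iter_folds():
        masked_Y = apply_mask_env(Y, masked, plan)
        pred = fit_predict(masked_Y)
        rows = Y.index.intersection(masked)
        score_envs = [c for c in Y.columns if c not in plan.reference_environments]
        records.append(
            predictive_ability(
                Y.loc[rows, score_envs], pred.loc[rows, score_envs],
                trait, model, plan.scenario, fold, rep,
            )
        )
    return pd.concat(records, ignore_index=True)
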