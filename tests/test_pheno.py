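"""Phenotype stage: spatial adjustment, heritability arithmetic, clonal values."""

import numpy as np
import pandas as pd
import pytest

from orchardgx.data import add_environment_column
from orchardgx.pheno import (
    across_env_heritability,
    adjust_spatial,
    compute_clonal_values,
    env_clonal_heritability,
    environment_correlations,
    filter_low_heritability,
    global_clonal_values,
    heritability_from_components,
    pca_scores,
    trait_correlations,
)
from orchardgx.syndata import SimConfig, TraitSpec, simulate_founder_genotypes, simulate_multienv_trial


@pytest.fixture(scope="module")
def flat_field_env(small_pop):
    cfg, pop = small_pop
    spec = TraitSpec("t", polygenic_variance_fraction=0.4, env_variance_fraction=0.2,
                     gxe_variance_fraction=0.1, residual_variance_fraction=0.3)
    rec, truth = simulate_multienv_trial(pop["study"], spec, cfg)  # spatial_field_sd=0
    rec = add_environment_column(rec)
    return rec, truth


@pytest.fixture(scope="module")
def bumpy_field_env():
    cfg = SimConfig(n_accessions=400, m_markers=300, environments=[("CHE", 2018)],
                    replicates_per_env=2, spatial_field_sd=0.8, seed=33)
    g = simulate_founder_genotypes(cfg)
    spec = TraitSpec("t", polygenic_variance_fraction=0.4, env_variance_fraction=0.0,
                     gxe_variance_fraction=0.0, residual_variance_fraction=0.6)
    rec, truth = simulate_multienv_trial(g, spec, cfg)
    return add_environment_column(rec), truth


def test_zero_field_adjustment_is_nearly_identity(flat_field_env):
    rec, _ = flat_field_env
    sub = rec[rec.environment == "CHE.2018"].drop(columns="environment")
    adj = adjust_spatial(sub)
    dev = (adj.tree_values["adjusted"] - adj.tree_values["value"]).abs().max()
    assert dev < 0.05 * sub["value"].std()
    assert len(adj.tree_values) == len(sub)


def test_planted_surface_recovered(bumpy_field_env):
    rec, truth = bumpy_field_env
    sub = rec[rec.environment == "CHE.2018"].drop(columns="environment")
    adj = adjust_spatial(sub)
    true_surf = truth.tree_components["spatial"].to_numpy()
    r = np.corrcoef(adj.tree_values["surface"], true_surf)[0, 1]
    assert r > 0.9
    assert len(adj.tree_values) == len(sub)


def test_single_tree_flat_field_genotype_equals_tree_value():
    rec = pd.DataFrame({
        "genotype": ["g1", "g2", "g3"], "location": "X", "year": 1,
        "row": [0, 0, 0], "col": [0, 1, 2], "trait": "t", "value": [1.0, 2.0, 3.0],
    })
    adj = adjust_spatial(rec)
    got = adj.genotype_values.sort_index().to_numpy()
    tree = adj.tree_values.set_index("genotype")["adjusted"].sort_index().to_numpy()
    np.testing.assert_allclose(got, tree)


def test_missing_coordinates_fall_back_with_warning():
    rec = pd.DataFrame({
        "genotype": list("abcabc"), "location": "X", "year": 1,
        "row": [np.nan] * 6, "col": [np.nan] * 6, "trait": "t",
        "value": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
    })
    with pytest.warns(UserWarning, match="coordinates"):
        adj = adjust_spatial(rec)
    np.testing.assert_allclose(adj.tree_values["adjusted"], rec["value"])
    assert not adj.spatial_fitted


@pytest.mark.parametrize(
    "sg, se, nr, want",
    [(3.0, 2.0, 2.0, 0.75), (0.0, 2.0, 2.0, 0.0), (7.0, 2.0, 2.0, 0.875)],
)
def test_single_environment_heritability_arithmetic(sg, se, nr, want):
    assert heritability_from_components(sg, se, nr) == pytest.approx(want)


def test_across_environment_heritability_arithmetic():
    # sigma_p^2 = 3 + 2/2 + 2/(2*2) = 4.5 -> H2 = 3/4.5
    assert heritability_from_components(3.0, 2.0, 2.0, sigma_ge2=2.0, n_e=2) == pytest.approx(
        2.0 / 3.0, abs=1e-4
    )


def test_across_formula_reduces_to_single_env_formula():
    a = heritability_from_components(3.0, 2.0, 2.0, sigma_ge2=0.0, n_e=1)
    b = heritability_from_components(3.0, 2.0, 2.0)
    assert a == b


def test_env_heritability_chains_from_reml_oracle():
    # the balanced 2x2 oracle: sig_g=7, sig_e=2, n_r=2 -> H2 = 7/8
    rec = pd.DataFrame({
        "genotype": ["A", "A", "B", "B"], "location": "X", "year": 1,
        "row": [0, 0, 1, 1], "col": [0, 1, 0, 1], "trait": "t",
        "value": [1.0, 3.0, 5.0, 7.0],
    })
    adj = adjust_spatial(rec)
    adj.tree_values["adjusted"] = rec["value"]  # isolate the heritability model
    h = env_clonal_heritability(adj)
    assert h.H2 == pytest.approx(0.875, abs=1e-4)


def test_low_heritability_filter_boundary():
    est = {("L", "2018", "a"): 0.1, ("L", "2018", "b"): 0.09, ("L", "2019", "a"): 0.5}
    kept = filter_low_heritability(est)
    assert ("L", "2018", "a") in kept  # boundary kept: 'below 0.1' is strict
    assert ("L", "2018", "b") not in kept
    assert filter_low_heritability({}) == set()


def test_simulated_across_env_heritability_matches_analytic(flat_field_env):
    rec, _ = flat_field_env
    adjs = []
    for env in sorted(rec["environment"].unique()):
        sub = rec[rec.environment == env].drop(columns="environment")
        adj = adjust_spatial(sub)
        adjs.append(adj)
    h = across_env_heritability(adjs)
    # sg=0.4, sge=0.1, se=0.3, ne=4, nr=2 -> H2 = 0.4/(0.4+0.025+0.0375)
    want = 0.4 / (0.4 + 0.1 / 4 + 0.3 / 8)
    assert h.H2 == pytest.approx(want, abs=0.1)
    assert 0.0 <= h.H2 <= 1.0


def test_across_env_heritability_refuses_single_environment(flat_field_env):
    rec, _ = flat_field_env
    sub = rec[rec.environment == "CHE.2018"].drop(columns="environment")
    with pytest.raises(ValueError):
        across_env_heritability([adjust_spatial(sub)])


def test_clonal_value_balanced_shrinkage_oracle():
    # genotype means 2 and 6, grand mean 4; shrink factor 7/8 -> -1.75, +1.75
    rec = pd.DataFrame({
        "genotype": ["A", "A", "B", "B"], "location": "X", "year": 1,
        "row": [0, 0, 1, 1], "col": [0, 1, 0, 1], "trait": "t",
        "value": [1.0, 3.0, 5.0, 7.0],
    })
    adj = adjust_spatial(rec)
    adj.tree_values["adjusted"] = rec["value"]
    cv = compute_clonal_values([adj], scope="location-specific")
    np.testing.assert_allclose(cv.values.sort_index().to_numpy(), [-1.75, 1.75], atol=1e-4)


def test_identical_observations_give_zero_clonal_values():
    rec = pd.DataFrame({
        "genotype": list("ab") * 3, "location": "X", "year": 1,
        "row": list(range(6)), "col": [0] * 6, "trait": "t", "value": [4.0] * 6,
    })
    adj = adjust_spatial(rec)
    cv = compute_clonal_values([adj], scope="location-specific")
    assert np.allclose(cv.values, 0.0)


def test_log_transform_rejects_non_positive_values():
    rec = pd.DataFrame({
        "genotype": list("aabb"), "location": "X", "year": 1,
        "row": [0, 0, 1, 1], "col": [0, 1, 0, 1], "trait": "t",
        "value": [1.0, -3.0, 5.0, 7.0],
    })
    adj = adjust_spatial(rec)
    with pytest.raises(ValueError, match="log"):
        compute_clonal_values([adj], scope="location-specific", log_transform=True)


def test_clonal_values_have_mean_near_zero(flat_field_env):
    rec, _ = flat_field_env
    adjs = [
        adjust_spatial(rec[rec.environment == e].drop(columns="environment"))
        for e in sorted(rec["environment"].unique())
    ]
    cv = compute_clonal_values(adjs, scope="across-location")
    assert abs(cv.values.mean()) < 1e-6 * rec["value"].std()


def test_trait_correlation_identities():
    vals = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
    from orchardgx.pheno import ClonalValues

    clonal = {
        "a": ClonalValues("a", "global", vals),
        "b": ClonalValues("b", "global", -vals),
    }
    corr = trait_correlations(clonal)
    assert corr.loc["a", "a"] == pytest.approx(1.0)
    assert corr.loc["a", "b"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T)


def test_shared_qtl_traits_strongly_correlated(small_pop):
    cfg, pop = small_pop
    spec = TraitSpec("t", n_qtl=3, qtl_variance_fraction=0.5,
                     polygenic_variance_fraction=0.3, env_variance_fraction=0.0,
                     gxe_variance_fraction=0.0, residual_variance_fraction=0.2)
    rng = np.random.default_rng(77)
    rec1, truth = simulate_multienv_trial(pop["study"], spec, cfg, rng=np.random.default_rng(55))
    g = truth.shared_genetic_values()
    # second trait shares all genetic effects, different residual draw
    noise_sd = np.sqrt(0.05)  # clonal values are well de-noised by replication
    y1 = pd.Series(g + rng.normal(0, noise_sd, len(g)), index=truth.genotype_ids)
    y2 = pd.Series(g + rng.normal(0, noise_sd, len(g)), index=truth.genotype_ids)
    assert np.corrcoef(y1, y2)[0, 1] > 0.9


def test_environment_correlations_and_pca(flat_field_env):
    rec, _ = flat_field_env
    adjs = [
        adjust_spatial(rec[rec.environment == e].drop(columns="environment"))
        for e in sorted(rec["environment"].unique())
    ]
    corr = environment_correlations(adjs)
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)

    from orchardgx.pheno import ClonalValues

    cv = compute_clonal_values(adjs, scope="across-location")
    vals = cv.values
    clonal = {
        "a": ClonalValues("a", "global", vals),
        "b": ClonalValues("b", "global", vals * 2 + 1),
        "c": ClonalValues("c", "global", pd.Series(
            np.random.default_rng(1).standard_normal(len(vals)), index=vals.index)),
    }
    scores, loadings, evr = pca_scores(clonal)
    assert scores.shape == (len(vals), 2)
    assert evr[0] >= evr[1]


def test_global_clonal_values_flag_mixed_scope():
    from orchardgx.pheno import ClonalValues

    vals = pd.Series([1.0, -1.0], index=["a", "b"])
    out = global_clonal_values({
        "multi": ClonalValues("multi", "across-location", vals),
        "single": ClonalValues("single", "location-specific", vals, location="X"),
    })
    assert not out["multi"].mixed_scopes
    assert out["single"].mixed_scopes
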