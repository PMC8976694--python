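"""GWAS scan, segment assignment, co-localization, catalogs, allele dynamics, LD."""

import numpy as np
import pandas as pd
import pytest

from orchardgx.data import GenotypeMatrix
from orchardgx.gwas import (
    Association,
    LociCatalog,
    allele_frequency_dynamics,
    assign_segment,
    blink_scan,
    bonferroni_threshold,
    catalog_overlap,
    colocalize_associations,
    ld_window,
    marker_r2,
)
from orchardgx.syndata import SimConfig, TraitSpec, simulate_multienv_trial, simulate_population


@pytest.fixture(scope="module")
def qtl_scan(founders_500):
    cfg, g = founders_500
    spec = TraitSpec("t", n_qtl=5, qtl_variance_fraction=0.4,
                     polygenic_variance_fraction=0.0, env_variance_fraction=0.0,
                     gxe_variance_fraction=0.0, residual_variance_fraction=0.6,
                     mean=0.0)
    rec, truth = simulate_multienv_trial(
        g, spec, SimConfig(n_accessions=cfg.n_accessions, m_markers=cfg.m_markers,
                           environments=[("X", 1)], seed=cfg.seed)
    )
    y = rec.groupby("genotype")["value"].mean()
    return g, y, truth, blink_scan(g, y, trait="t")


def test_bonferroni_threshold_exceeds_printed_bound():
    # full-panel marker count: -log10(0.05/303148) = 6.78 >= the 6.74 bound
    assert bonferroni_threshold(0.05, 303_148) >= 6.74
    assert bonferroni_threshold(0.05, 303_148) == pytest.approx(6.7827, abs=1e-3)


def test_marker_r2_perfect_and_null():
    dosage = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1], float)
    assert marker_r2(dosage, 2.0 * dosage + 1.0) == pytest.approx(1.0)
    assert marker_r2(dosage + 1.0, 2.0 * dosage) == pytest.approx(1.0)  # 1,2,3 coding
    rng = np.random.default_rng(0)
    r2s = [marker_r2(rng.integers(0, 3, 1000).astype(float), rng.standard_normal(1000))
           for _ in range(50)]
    assert np.mean(r2s) < 0.01


def test_marker_r2_orthogonal_response_is_zero():
    snp = np.array([0.0, 1.0, 2.0, 1.0])
    y = np.array([1.0, 0.0, 1.0, 0.0])  # slope of y on snp is 0
    assert marker_r2(snp, y) == pytest.approx(0.0, abs=1e-12)


def test_marker_r2_rejects_constant_marker():
    with pytest.raises(ValueError):
        marker_r2(np.ones(10), np.arange(10.0))


@pytest.mark.parametrize(
    "pos, want",
    [(5_000_000, "top"), (10_000_000, "top"), (15_000_000, "center"),
     (20_000_000, "center"), (25_000_000, "bottom"), (30_000_000, "bottom")],
)
def test_segment_thirds(pos, want):
    assert assign_segment(pos, 30_000_000) == want


def test_segment_partition_is_exhaustive():
    L = 29_999_999
    for pos in np.linspace(1, L, 57).astype(int):
        assert assign_segment(int(pos), L) in {"top", "center", "bottom"}
    with pytest.raises(ValueError):
        assign_segment(L + 1, L)


def _assoc(chrom, pos, trait="t"):
    return Association(f"m{chrom}_{pos}", chrom, pos, 1e-9, 9.0, 0.1, trait, segment="top")


def test_colocalization_window_rules():
    # observed pair 94,203 bp apart joins one cluster; exactly 100 kb splits
    near = [_assoc(3, 30_587_378), _assoc(3, 30_681_581, trait="u")]
    clusters = colocalize_associations(near)
    assert len(clusters) == 1 and clusters[0]["cross_trait"]

    apart = [_assoc(1, 1_000_000), _assoc(1, 1_100_000)]
    assert len(colocalize_associations(apart)) == 2  # strict '<'

    cross = [_assoc(1, 500), _assoc(2, 600)]
    assert len(colocalize_associations(cross)) == 2


def test_catalog_overlap_counting():
    former = LociCatalog(pd.DataFrame(
        [("A", 1, "top", 100, "ref1")],
        columns=["trait_group", "chromosome", "segment", "n_markers", "source"],
    ))
    present = {("A", 1, "top"), ("B", 2, "center")}
    rep = catalog_overlap(present, former)
    assert rep["n_shared"] == 1 and rep["overlap_pct"] == pytest.approx(50.0)
    assert catalog_overlap({("C", 3, "bottom")}, former)["overlap_pct"] == 0.0
    assert catalog_overlap({("A", 1, "top")}, former)["overlap_pct"] == 100.0


def test_catalog_rejects_unknown_segment():
    with pytest.raises(ValueError):
        LociCatalog(pd.DataFrame(
            [("A", 1, "middle", 1, "x")],
            columns=["trait_group", "chromosome", "segment", "n_markers", "source"],
        ))


def test_planted_qtl_recovered_without_false_clusters(qtl_scan):
    g, y, truth, scan = qtl_scan
    midx = {m: i for i, m in enumerate(g.marker_map["marker"])}
    detected = sum(
        1 for q in truth.qtl_indices
        if any(abs(midx[a.marker] - q) <= 50 for a in scan.associations)
    )
    assert detected >= 4
    false = [a for a in scan.associations
             if min(abs(midx[a.marker] - q) for q in truth.qtl_indices) > 50]
    n_false_clusters = len(colocalize_associations(false)) if false else 0
    assert n_false_clusters <= 1


def test_pseudo_qtns_pairwise_ld_below_cutoff(qtl_scan):
    g, y, truth, scan = qtl_scan
    midx = {m: i for i, m in enumerate(g.marker_map["marker"])}
    d = g.dosages.astype(float)
    qs = [midx[m] for m in scan.pseudo_qtns]
    for i, a in enumerate(qs):
        for b in qs[i + 1:]:
            r2 = np.corrcoef(d[:, a], d[:, b])[0, 1] ** 2
            assert r2 < 0.7


def test_null_phenotype_rarely_significant(founders_500):
    cfg, g = founders_500
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(1000 + seed)
        y = pd.Series(rng.standard_normal(g.n_samples), index=g.samples)
        hits += len(blink_scan(g, y, trait="null").associations) > 0
    assert hits <= 1  # family-wise error held on at least 4 of 5 seeds


def test_lower_alpha_never_adds_associations(qtl_scan):
    g, y, truth, scan = qtl_scan
    strict = blink_scan(g, y, trait="t", alpha=0.005)
    assert {a.marker for a in strict.associations} <= {a.marker for a in scan.associations}


def test_scan_invariant_to_row_permutation(founders_500):
    cfg, g = founders_500
    sub = g.subset_samples(g.samples[:200]).subset_markers(np.arange(500))
    rng = np.random.default_rng(3)
    qtl = sub.dosages[:, 250].astype(float)
    y = pd.Series(qtl * 0.8 + rng.standard_normal(200) * 0.6, index=sub.samples)
    res1 = blink_scan(sub, y, trait="t")
    perm = list(rng.permutation(sub.samples))
    sub2 = sub.subset_samples(perm)
    res2 = blink_scan(sub2, y.loc[perm], trait="t")
    assert {a.marker for a in res1.associations} == {a.marker for a in res2.associations}


def test_allele_frequency_dynamics(small_pop):
    cfg, pop = small_pop
    bred, ped = pop["bred"], pop["pedigree"]
    from orchardgx.syndata import combine_genotypes

    allg = combine_genotypes(pop["founders"], bred)
    # pick a marker segregating in the progeny
    prog_idx = [i for i, s in enumerate(allg.samples) if s.startswith("PRO")]
    freqs = allg.dosages[prog_idx].mean(axis=0) / 2
    k = int(np.argmax((freqs > 0.2) & (freqs < 0.8)))
    marker = allg.marker_map["marker"].iloc[k]
    a = Association(marker, 1, 100, 1e-9, 9.0, 0.2, "t", effect_sign=1.0)
    out = allele_frequency_dynamics(allg, ped, [a], seed=5)
    assert set(out["generation"]) == set(range(cfg.n_ancestor_generations + 1))
    assert ((out["frequency"] >= 0) & (out["frequency"] <= 1)).all()
    prog_row = out[out["generation"] == 0].iloc[0]
    assert "resampled_mean" in prog_row
    # exhaustive resample equals the group frequency exactly
    n_prog = int(prog_row["n"])
    out2 = allele_frequency_dynamics(allg, ped, [a], resample_size=n_prog, seed=5)
    row2 = out2[out2["generation"] == 0].iloc[0]
    assert row2["resampled_mean"] == pytest.approx(row2["frequency"], abs=1e-12)


def test_allele_frequency_fixed_and_absent_extremes():
    mmap = pd.DataFrame({"marker": ["m1"], "chrom": [1], "pos": [100]})
    dosages = np.array([[2], [2], [2], [0], [0]], dtype=np.int8)
    g = GenotypeMatrix(dosages, ["p1", "p2", "p3", "a1", "a2"], mmap)
    ped = pd.DataFrame({
        "id": ["p1", "p2", "p3", "a1", "a2"],
        "parent1": ["a1", "a1", "a2", "", ""],
        "parent2": ["a2", "a2", "a1", "", ""],
        "generation": [0, 0, 0, 1, 1],
    })
    from orchardgx.data import PedigreeTable

    out = allele_frequency_dynamics(g, PedigreeTable(ped), [
        Association("m1", 1, 100, 1e-9, 9.0, 0.2, "t", effect_sign=1.0)
    ], resample_size=3, seed=0)
    prog = out[out["generation"] == 0].iloc[0]
    anc = out[out["generation"] == 1].iloc[0]
    assert prog["frequency"] == 1.0 and prog["fixed"]
    assert anc["frequency"] == 0.0


def test_ld_window_identity_duplicate_and_truncation(founders_500):
    cfg, g = founders_500
    sub = g.subset_samples(g.samples[:300])
    focal = sub.marker_map["marker"].iloc[10]
    prof = ld_window(sub, focal, window=100)
    assert prof.loc[prof["marker"] == focal, "r2"].iloc[0] == pytest.approx(1.0)
    # truncated at the chromosome start: fewer than window markers
    assert len(prof) <= 101
    # a far, unlinked marker has near-zero r2 on average
    chrom1 = sub.marker_map[sub.marker_map["chrom"] == 1]
    focal2 = chrom1["marker"].iloc[0]
    prof2 = ld_window(sub, focal2, window=3000)
    far = prof2.iloc[-50:]["r2"].dropna()
    assert far.mean() < 0.25
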