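"""Multi-locus GWAS and locus cataloguing.

The scan follows the iterative multi-locus scheme popularized for large
diversity panels: single-marker fixed-effect tests with principal-component
covariates, selection of pseudo-QTNs (markers carried as covariates to absorb
detected signal) by p-value ranking with a pairwise-LD filter, choice of the
number of retained pseudo-QTNs by BIC over nested sets, iterated until the
selected set stabilizes.  Significance is Bonferroni-corrected over the
markers actually tested.

Downstream utilities assign associations to chromosome thirds, co-localize
them within a base-pair window, count overlap with a catalog of previously
published loci, trace allele-frequency dynamics through ancestor generations,
and profile local LD around major associations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from orchardgx.data import GenotypeMatrix, PedigreeTable

LD_CUTOFF_R2 = 0.7
MAX_SCAN_ITER = 10


@dataclass
class Association:
    """One significant marker-trait association."""

    marker: str
    chrom: int
    pos: int
    p_value: float
    minus_log10_p: float
    r2: float
    trait: str
    scope: str = "across-location"
    segment: str = ""
    effect_sign: float = 1.0

    def key(self, trait_group: str | None = None) -> tuple:
        return (trait_group or self.trait, self.chrom, self.segment)


@dataclass
class ScanResult:
    """Full scan output: associations plus diagnostics."""

    associations: list[Association]
    p_values: pd.Series  # per tested marker
    pseudo_qtns: list[str]
    n_tested: int
    alpha: float
    threshold_minus_log10: float
    n_iterations: int


def bonferroni_threshold(alpha: float = 0.05, m: int = 303_148) -> float:
    """-log10 of the Bonferroni-corrected per-marker significance level."""
    return -math.log10(alpha / m)


def marker_r2(snp: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of y regressed on a single marker.

    Marker values may be coded 0,1,2 or 1,2,3; the affine shift leaves R^2
    unchanged.
    """
    snp = np.asarray(snp, float)
    y = np.asarray(y, float)
    if len(snp) < 3:
        raise ValueError("need at least 3 genotypes")
    if np.std(snp) == 0:
        raise ValueError("constant marker: R^2 undefined")
    r = np.corrcoef(snp, y)[0, 1]
    return float(r * r)


def _residualize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of A after OLS on covariates C."""
    coef, *_ = np.linalg.lstsq(C, A, rcond=None)
    return A - C @ coef


def _pvalues_given_covariates(Xm: np.ndarray, y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-marker p-values of the marker coefficient given covariates C."""
    n = len(y)
    ry = _residualize(y[:, None], C).ravel()
    RX = _residualize(Xm, C)
    sx = np.linalg.norm(RX, axis=0)
    sy = np.linalg.norm(ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (RX.T @ ry) / (sx * sy)
    df = n - C.shape[1] - 1
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t2 = r * r * df / (1 - r * r)
    p = stats.f.sf(t2, 1, df)
    p[sx < 1e-10] = 1.0
    return p


def _ld_r2(Xm: np.ndarray, a: int, b: int) -> float:
    xa, xb = Xm[:, a], Xm[:, b]
    if xa.std() == 0 or xb.std() == 0:
        return 0.0
    return float(np.corrcoef(xa, xb)[0, 1] ** 2)


def blink_scan(
    genotypes: GenotypeMatrix,
    y: pd.Series,
    trait: str = "trait",
    scope: str = "across-location",
    n_pcs: int = 2,
    maf_min: float = 0.05,
    alpha: float = 0.05,
    ld_cutoff: float = LD_CUTOFF_R2,
    max_iter: int = MAX_SCAN_ITER,
    candidate_p: float = 1e-4,
) -> ScanResult:
    """Iterative multi-locus association scan.

    ``y`` is indexed by genotype id (clonal values); only genotypes present
    in both inputs are used.  Markers below the MAF threshold are excluded
    and the Bonferroni correction uses the number of markers actually tested.
    """
    common = [s for s in genotypes.samples if s in y.index]
    sub = genotypes.subset_samples(common)
    yv = y.loc[common].to_numpy(float)
    n = len(common)

    maf = sub.maf()
    keep = np.flatnonzero(maf >= maf_min)
    Xm = sub.dosages[:, keep].astype(float)
    markers = sub.marker_map.iloc[keep].reset_index(drop=True)
    m_tested = len(keep)
    if m_tested == 0:
        raise ValueError("no markers pass the MAF threshold")

    # principal components of the standardized marker matrix
    M, _ = sub.standardized()
    if n <= n_pcs + 2:
        raise np.linalg.LinAlgError("fewer genotypes than covariates")
    if n_pcs > 0:
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        pcs = U[:, :n_pcs] * s[:n_pcs]
    else:
        pcs = np.empty((n, 0))
    base_C = np.column_stack([np.ones(n), pcs])

    max_qtns = max(1, min(50, n // 10))
    pseudo: list[int] = []
    p_final = np.ones(m_tested)
    it = 0
    for it in range(1, max_iter + 1):
        # step 1: tests with current pseudo-QTNs as covariates
        if pseudo:
            C = np.column_stack([base_C, Xm[:, pseudo]])
        else:
            C = base_C
        p = _pvalues_given_covariates(Xm, yv, C)
        # markers in LD with a pseudo-QTN: retest excluding those covariates
        if pseudo:
            sd = Xm.std(axis=0)
            Zn = (Xm - Xm.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            ld = (Zn[:, pseudo].T @ Zn / n) ** 2  # (n_pseudo, m)
            ld[:, sd == 0] = 0.0
            conflicted = np.flatnonzero((ld >= ld_cutoff).any(axis=0))
            for j in conflicted:
                kept = [q for qi, q in enumerate(pseudo) if ld[qi, j] < ld_cutoff and q != j]
                Cj = np.column_stack([base_C, Xm[:, kept]]) if kept else base_C
                p[j] = _pvalues_given_covariates(Xm[:, [j]], yv, Cj)[0]
        p_final = p

        # step 2: candidate pseudo-QTNs, p-ranked and LD-pruned
        order = np.argsort(p)
        candidates: list[int] = []
        for j in order:
            if p[j] >= candidate_p:  # only clearly promising markers become covariates
                break
            if all(_ld_r2(Xm, j, c) < ld_cutoff for c in candidates):
                candidates.append(int(j))
            if len(candidates) >= max_qtns:
                break

        # step 3: BIC over nested candidate sets
        best_k, best_bic = 0, np.inf
        for k in range(0, len(candidates) + 1):
            Ck = np.column_stack([base_C, Xm[:, candidates[:k]]]) if k else base_C
            resid = _residualize(yv[:, None], Ck).ravel()
            rss = float(resid @ resid)
            bic = n * math.log(max(rss, 1e-300) / n) + (Ck.shape[1] + 1) * math.log(n)
            if bic < best_bic - 1e-9:
                best_bic, best_k = bic, k
        new_pseudo = candidates[:best_k]
        if set(new_pseudo) == set(pseudo):
            pseudo = new_pseudo
            break
        pseudo = new_pseudo

    thresh_p = alpha / m_tested
    chrom_len = markers.groupby("chrom")["pos"].max().to_dict()
    assocs = []
    for j in np.flatnonzero(p_final < thresh_p):
        snp = Xm[:, j]
        slope = np.polyfit(snp, yv, 1)[0] if snp.std() > 0 else 0.0
        mk = markers.iloc[j]
        assocs.append(
            Association(
                marker=str(mk["marker"]),
                chrom=int(mk["chrom"]),
                pos=int(mk["pos"]),
                p_value=float(p_final[j]),
                minus_log10_p=float(-np.log10(max(p_final[j], 1e-300))),
                r2=marker_r2(snp, yv) if snp.std() > 0 else 0.0,
                trait=trait,
                scope=scope,
                segment=assign_segment(int(mk["pos"]), int(chrom_len[mk["chrom"]])),
                effect_sign=float(np.sign(slope)) or 1.0,
            )
        )
    assocs.sort(key=lambda a: a.p_value)
    return ScanResult(
        associations=assocs,
        p_values=pd.Series(p_final, index=markers["marker"]),
        pseudo_qtns=[str(markers["marker"].iloc[q]) for q in pseudo],
        n_tested=m_tested,
        alpha=alpha,
        threshold_minus_log10=bonferroni_threshold(alpha, m_tested),
        n_iterations=it,
    )


def assign_segment(position: int, chromosome_length: int) -> str:
    """Assign a position to the top/center/bottom third of its chromosome.

    Boundaries are left-closed: a position exactly at L/3 belongs to the
    lower (earlier) segment.
    """
    if not 0 < position <= chromosome_length:
        raise ValueError(f"position {position} outside (0, {chromosome_length}]")
    third = chromosome_length / 3.0
    if position <= third:
        return "top"
    if position <= 2 * third:
        return "center"
    return "bottom"


def colocalize_associations(assocs: list[Association], window: int = 100_000) -> list[dict]:
    """Single-linkage clusters of associations with pairwise gaps < window bp.

    Returns one dict per cluster with the member associations, the span, and
    whether the cluster joins several traits.
    """
    clusters: list[dict] = []
    by_chrom: dict[int, list[Association]] = {}
    for a in assocs:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: a.pos)
        current = [members[0]]
        for a in members[1:]:
            if a.pos - current[-1].pos < window:
                current.append(a)
            else:
                clusters.append(_cluster_record(chrom, current))
                current = [a]
        clusters.append(_cluster_record(chrom, current))
    return clusters


def _cluster_record(chrom: int, members: list[Association]) -> dict:
    traits = sorted({a.trait for a in members})
    return {
        "chrom": chrom,
        "start": min(a.pos for a in members),
        "end": max(a.pos for a in members),
        "members": members,
        "traits": traits,
        "cross_trait": len(traits) > 1,
    }


@dataclass
class LociCatalog:
    """Published loci as unique (trait_group, chromosome, segment) entries."""

    entries: pd.DataFrame  # trait_group, chromosome, segment, n_markers, source

    def __post_init__(self) -> None:
        bad = set(self.entries["segment"]) - {"top", "center", "bottom"}
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")

    def combinations(self) -> set[tuple]:
        return {
            (r.trait_group, int(r.chromosome), r.segment)
            for r in self.entries.itertuples()
        }


def catalog_overlap(present: set[tuple], former: LociCatalog | set[tuple]) -> dict:
    """Overlap between present and previously published locus combinations."""
    former_set = former.combinations() if isinstance(former, LociCatalog) else set(former)
    for combos in (present, former_set):
        for c in combos:
            if c[2] not in {"top", "center", "bottom"}:
                raise ValueError(f"unknown segment label in {c}")
    shared = present & former_set
    return {
        "n_present": len(present),
        "n_former": len(former_set),
        "n_shared": len(shared),
        "n_present_only": len(present - former_set),
        "n_former_only": len(former_set - present),
        "overlap_pct": 100.0 * len(shared) / len(present) if present else float("nan"),
    }


def allele_frequency_dynamics(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable,
    assocs: list[Association],
    n_resample: int = 10,
    resample_size: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency of the phenotype-increasing allele across generations.

    For every association, the counted allele is the one whose extra copy
    increases the trait (``effect_sign``).  Frequencies are reported for each
    ancestor generation and for the progeny group (generation 0), together
    with the mean and standard error over repeated resamples of
    ``resample_size`` progeny genotypes.
    """
    rng = np.random.default_rng(seed)
    marker_idx = {m: i for i, m in enumerate(genotypes.marker_map["marker"])}
    sample_idx = {s: i for i, s in enumerate(genotypes.samples)}
    rows = []
    for a in assocs:
        if a.marker not in marker_idx:
            raise KeyError(f"association marker {a.marker!r} missing from genotypes")
        col = genotypes.dosages[:, marker_idx[a.marker]].astype(float)
        if a.effect_sign < 0:
            col = 2.0 - col  # count the decreasing-coded complement
        for gen in sorted(pedigree.table["generation"].unique(), reverse=True):
            ids = [i for i in pedigree.ids_in_generation(int(gen)) if i in sample_idx]
            if not ids:
                continue
            dos = col[[sample_idx[i] for i in ids]]
            freq = float(dos.mean() / 2.0)
            row = {
                "marker": a.marker,
                "trait": a.trait,
                "generation": int(gen),
                "n": len(ids),
                "frequency": freq,
                "fixed": bool(freq in (0.0, 1.0)),
            }
            if gen == 0:  # progeny group: add resampled mean +/- SE
                size = min(resample_size, len(ids))
                means = []
                for _ in range(n_resample):
                    pick = rng.choice(len(ids), size=size, replace=False)
                    means.append(float(dos[pick].mean() / 2.0))
                row["resampled_mean"] = float(np.mean(means))
                row["resampled_se"] = float(np.std(means, ddof=1) / math.sqrt(n_resample)) if n_resample > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def ld_window(genotypes: GenotypeMatrix, focal_marker: str, window: int = 3000) -> pd.DataFrame:
    """Squared Pearson correlation of the focal marker with markers around it.

    The window counts markers (not base pairs), centered on the focal marker
    and truncated at the chromosome ends.  Monomorphic markers yield missing
    r^2.
    """
    mmap = genotypes.marker_map
    hits = np.flatnonzero(mmap["marker"].to_numpy() == focal_marker)
    if len(hits) == 0:
        raise KeyError(f"marker {focal_marker!r} not found")
    f = int(hits[0])
    chrom = mmap["chrom"].iloc[f]
    on_chrom = np.flatnonzero(mmap["chrom"].to_numpy() == chrom)
    pos_in_chrom = int(np.flatnonzero(on_chrom == f)[0])
    half = window // 2
    lo = max(0, pos_in_chrom - half)
    hi = min(len(on_chrom), pos_in_chrom + half + 1)
    idx = on_chrom[lo:hi]
    focal = genotypes.dosages[:, f].astype(float)
    out = []
    for j in idx:
        x = genotypes.dosages[:, j].astype(float)
        if x.std() == 0 or focal.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(focal, x)[0, 1] ** 2)
        out.append((mmap["marker"].iloc[j], int(mmap["chrom"].iloc[j]), int(mmap["pos"].iloc[j]), r2))
    return pd.DataFrame(out, columns=["marker", "chrom", "pos", "r2"])


def associations_to_frame(assocs: list[Association]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": a.trait,
                "scope": a.scope,
                "chrom": a.chrom,
                "pos": a.pos,
                "p": a.p_value,
                "minus_log10_p": a.minus_log10_p,
                "r2": a.r2,
                "segment": a.segment,
                "marker": a.marker,
            }
            for a in assocs
        ]
    )
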