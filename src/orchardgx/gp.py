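"""Main-effect genomic prediction: G-BLUP, BayesCpi, multi-kernel RKHS,
random-forest regression, and a bivariate unstructured multivariate model.

All Bayesian models share the random-effects form

    y = 1 mu + u + eps

fitted by Gibbs sampling (defaults: 12 000 iterations, thinning 5, burn-in
2000).  Genetic effects are sampled in the eigenbasis of their covariance
kernel, and phenotypes of masked genotypes are handled by data augmentation,
which keeps every full conditional diagonal.  Variance hyperpriors are
scaled-inverse-chi^2 with 5 degrees of freedom, scale set so the prior mode
splits the response variance 50/50 between signal and noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orchardgx.data import GenotypeMatrix

DEFAULT_BANDWIDTHS = (0.1, 0.5, 2.5)
PRIOR_DF = 5.0


@dataclass
class GibbsConfig:
    """Chain settings of every Gibbs-sampled model."""

    iterations: int = 12000
    thinning: int = 5
    burn_in: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class KernelBundle:
    """Standardized markers and the kernels derived from them."""

    M: np.ndarray  # (n, m) column mean 0 / SD 1
    G: np.ndarray  # M M' / m
    D: np.ndarray  # average squared Euclidean distances
    kernels: dict[float, np.ndarray]  # bandwidth -> exp(-h D)
    samples: list[str]
    n_dropped_monomorphic: int = 0


@dataclass
class FitResult:
    """Posterior summaries of one Gibbs-sampled model."""

    u: pd.Series  # posterior-mean genetic values (per genotype)
    variance_samples: dict[str, np.ndarray]
    model: str
    extras: dict = field(default_factory=dict)

    def variance_means(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.variance_samples.items()}

    def to_dict(self) -> dict:
        return {"model": self.model, "variances": self.variance_means()}


def build_kernels(genotypes: GenotypeMatrix, bandwidths=DEFAULT_BANDWIDTHS) -> KernelBundle:
    """Standardize dosages and build G, D and the Gaussian kernels.

    Monomorphic markers are removed (with a logged count) before
    standardization.  ``G = M M'/m``; ``D`` holds average squared Euclidean
    distances between standardized genotype vectors; ``K_h = exp(-h D)``.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 genotypes")
    n_before = genotypes.n_markers
    M, kept = genotypes.standardized()
    dropped = n_before - len(kept)
    if dropped:
        warnings.warn(f"{dropped} monomorphic markers dropped before kernel construction",
                      stacklevel=2)
    m = M.shape[1]
    G = M @ M.T / m
    d = np.diag(G)
    D = d[:, None] + d[None, :] - 2 * G
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    kernels = {float(h): np.exp(-h * D) for h in bandwidths}
    return KernelBundle(M, G, D, kernels, list(genotypes.samples), dropped)


def _prior_scale(var_y: float, df: float = PRIOR_DF) -> float:
    # scaled-inv-chi^2 mode = df*S/(df+2); aim the mode at var_y/2
    return 0.5 * var_y * (df + 2.0) / df


def _sample_sinvchi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _eig_kernel(K: np.ndarray):
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    keep = w > 1e-8 * max(w.max(), 1.0)
    return w[keep], V[:, keep]


def _prepare_response(y) -> tuple[np.ndarray, np.ndarray, pd.Index | None]:
    if isinstance(y, pd.Series):
        idx = y.index
        yv = y.to_numpy(float)
    else:
        idx = None
        yv = np.asarray(y, float)
    miss = ~np.isfinite(yv)
    if miss.all():
        raise ValueError("response has no observed values")
    return yv, miss, idx


def fit_gblup(y, G: np.ndarray, config: GibbsConfig | None = None) -> FitResult:
    """G-BLUP via Gibbs sampling: u ~ N(0, G sigma_u^2).

    ``y`` may contain NaN for genotypes to be predicted (masked in CV);
    their phenotypes are imputed by data augmentation each iteration.
    """
    config = config or GibbsConfig()
    yv, miss, idx = _prepare_response(y)
    n = len(yv)
    if G.shape != (n, n):
        raise ValueError("G dimension does not match y")
    w, V = _eig_kernel(G)
    rng = np.random.default_rng(config.seed)

    var_y = float(np.nanvar(yv))
    S0 = _prior_scale(var_y)
    sig_u = sig_e = var_y / 2
    mu = float(np.nanmean(yv))
    y_aug = np.where(miss, mu, yv)
    alpha = np.zeros(len(w))
    u = np.zeros(n)

    keep_u = np.zeros(n)
    su_s, se_s = [], []
    kept = 0
    for it in range(config.iterations):
        if miss.any():
            y_aug[miss] = mu + u[miss] + rng.standard_normal(miss.sum()) * np.sqrt(sig_e)
        mu = float(np.mean(y_aug - u)) + rng.standard_normal() * np.sqrt(sig_e / n)
        e = V.T @ (y_aug - mu)
        prec = 1.0 / sig_e + 1.0 / (w * sig_u)
        mean = (e / sig_e) / prec
        alpha = mean + rng.standard_normal(len(w)) / np.sqrt(prec)
        u = V @ alpha
        ssu = float(np.sum(alpha**2 / w))
        sig_u = _sample_sinvchi2(rng, PRIOR_DF + len(w), (PRIOR_DF * S0 + ssu) / (PRIOR_DF + len(w)))
        resid = y_aug - mu - u
        sig_e = _sample_sinvchi2(rng, PRIOR_DF + n, (PRIOR_DF * S0 + float(resid @ resid)) / (PRIOR_DF + n))
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_u += u
            su_s.append(sig_u)
            se_s.append(sig_e)
            kept += 1
    u_mean = keep_u / kept
    return FitResult(
        u=pd.Series(u_mean, index=idx),
        variance_samples={"sigma_u2": np.array(su_s), "sigma_e2": np.array(se_s)},
        model="gblup",
    )


def closed_form_blup(y: np.ndarray, G: np.ndarray, sigma_u2: float, sigma_e2: float) -> np.ndarray:
    """Oracle BLUP at fixed variance components:
    u* = sigma_u^2 G (sigma_u^2 G + sigma_e^2 I)^(-1) (y - ybar)."""
    n = len(y)
    yc = y - y.mean()
    return sigma_u2 * G @ np.linalg.solve(sigma_u2 * G + sigma_e2 * np.eye(n), yc)


def fit_rkhs_multikernel(y, kernels: list[np.ndarray], config: GibbsConfig | None = None) -> FitResult:
    """Multi-kernel RKHS regression: u = sum_l u_l, u_l ~ N(0, K_l sigma_ul^2)."""
    config = config or GibbsConfig()
    yv, miss, idx = _prepare_response(y)
    n = len(yv)
    L = len(kernels)
    if L == 0:
        raise ValueError("at least one kernel required")
    eigs = []
    for K in kernels:
        if K.shape != (n, n):
            raise ValueError("kernel dimension does not match y")
        eigs.append(_eig_kernel(K))
    rng = np.random.default_rng(config.seed)

    var_y = float(np.nanvar(yv))
    S0 = _prior_scale(var_y)
    sig = np.full(L, var_y / (2 * L))
    sig_e = var_y / 2
    mu = float(np.nanmean(yv))
    y_aug = np.where(miss, mu, yv)
    us = [np.zeros(n) for _ in range(L)]

    keep_u = np.zeros(n)
    keep_ul = [np.zeros(n) for _ in range(L)]
    s_samples = [[] for _ in range(L)]
    se_s = []
    kept = 0
    for it in range(config.iterations):
        u_tot = np.sum(us, axis=0)
        if miss.any():
            y_aug[miss] = mu + u_tot[miss] + rng.standard_normal(miss.sum()) * np.sqrt(sig_e)
        mu = float(np.mean(y_aug - u_tot)) + rng.standard_normal() * np.sqrt(sig_e / n)
        for l in range(L):
            w, V = eigs[l]
            others = np.sum([us[j] for j in range(L) if j != l], axis=0) if L > 1 else 0.0
            e = V.T @ (y_aug - mu - others)
            prec = 1.0 / sig_e + 1.0 / (w * sig[l])
            mean = (e / sig_e) / prec
            alpha = mean + rng.standard_normal(len(w)) / np.sqrt(prec)
            us[l] = V @ alpha
            ssu = float(np.sum(alpha**2 / w))
            sig[l] = _sample_sinvchi2(
                rng, PRIOR_DF + len(w), (PRIOR_DF * S0 / L + ssu) / (PRIOR_DF + len(w))
            )
        u_tot = np.sum(us, axis=0)
        resid = y_aug - mu - u_tot
        sig_e = _sample_sinvchi2(rng, PRIOR_DF + n, (PRIOR_DF * S0 + float(resid @ resid)) / (PRIOR_DF + n))
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_u += u_tot
            for l in range(L):
                keep_ul[l] += us[l]
            for l in range(L):
                s_samples[l].append(sig[l])
            se_s.append(sig_e)
            kept += 1
    out = {f"sigma_u2_k{l+1}": np.array(s_samples[l]) for l in range(L)}
    out["sigma_e2"] = np.array(se_s)
    return FitResult(
        u=pd.Series(keep_u / kept, index=idx),
        variance_samples=out,
        model="rkhs",
        extras={"u_per_kernel": [ul / kept for ul in keep_ul]},
    )


def fit_bayescpi(y, M_centered: np.ndarray, config: GibbsConfig | None = None) -> FitResult:
    """BayesCpi whole-genome regression.

    Marker effects share a common variance and a point mass at zero with
    prior inclusion probability 1 - pi; pi carries a uniform [0, 1] prior and
    is sampled from its Beta full conditional.  ``M_centered`` holds centered
    allele counts (one column per marker).
    """
    from orchardgx._bayescpi import bayescpi_chain

    config = config or GibbsConfig()
    yv, miss, idx = _prepare_response(y)
    n = len(yv)
    if M_centered.ndim != 2 or M_centered.shape[0] != n:
        raise ValueError("marker matrix does not match y")
    m = M_centered.shape[1]
    if m == 0:
        raise ValueError("no markers supplied")
    if float(np.nanvar(yv)) < 1e-12 * max(1.0, float(np.nanmean(yv)) ** 2):
        # constant response: no signal, no noise — the degenerate fit
        zeros = config.n_kept
        return FitResult(
            u=pd.Series(np.zeros(n), index=idx),
            variance_samples={"sigma_a2": np.zeros(zeros), "sigma_e2": np.zeros(zeros),
                              "pi": np.ones(zeros), "h2": np.zeros(zeros)},
            model="bayescpi",
            extras={"marker_effects": np.zeros(m), "inclusion_freq": np.zeros(m)},
        )
    Mt = np.ascontiguousarray(M_centered.T, dtype=np.float64)
    zz = np.sum(Mt * Mt, axis=1)
    var_y = float(np.nanvar(yv))
    S0e = _prior_scale(var_y)
    # prior scale for the marker-effect variance: half the response variance
    # spread over the markers expected to be in the model a priori (pi = 0.5)
    mean_zz = float(np.mean(zz[zz > 0])) / n if np.any(zz > 0) else 1.0
    S0a = _prior_scale(var_y) / max(0.5 * m * mean_zz, 1e-8)
    y_in = np.where(miss, 0.0, yv)
    seed = int(np.random.default_rng(config.seed).integers(0, 2**31 - 1))
    u_mean, a_mean, incl_freq, h2_s, pi_s, sa_s, se_s = bayescpi_chain(
        Mt, zz, y_in, miss, config.iterations, config.burn_in, config.thinning,
        PRIOR_DF, S0a, S0e, seed,
    )
    return FitResult(
        u=pd.Series(u_mean, index=idx),
        variance_samples={"sigma_a2": sa_s, "sigma_e2": se_s, "pi": pi_s, "h2": h2_s},
        model="bayescpi",
        extras={"marker_effects": a_mean, "inclusion_freq": incl_freq},
    )


def genomic_heritability(fit: FitResult) -> float:
    """Mean over retained iterations of Vg/(Vg+Ve) from the marker effects."""
    if "h2" not in fit.variance_samples or len(fit.variance_samples["h2"]) == 0:
        raise RuntimeError("fit carries no retained heritability samples")
    return float(np.mean(fit.variance_samples["h2"]))


def fit_rf(y, M: np.ndarray, n_trees: int = 500, mtry: int | None = None,
           seed: int = 0):
    """Random-forest regression on the marker matrix.

    ``mtry`` defaults to floor(m/3) candidate markers per split, clamped to 1
    (with a warning) for tiny marker sets.  Returns the fitted sklearn model;
    predictions for masked genotypes come from :func:`predict_rf`.
    """
    from sklearn.ensemble import RandomForestRegressor

    yv, miss, _ = _prepare_response(y)
    m = M.shape[1]
    if mtry is None:
        mtry = m // 3
    if mtry < 1:
        warnings.warn("fewer than 3 markers: mtry clamped to 1", stacklevel=2)
        mtry = 1
    rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1)
    rf.fit(M[~miss], yv[~miss])
    return rf


def gebv_correlations(gebvs: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlations of genomic breeding values between traits."""
    return gebvs.corr()


def select_trait_pairs(gebvs: pd.DataFrame, threshold: float = 0.3) -> list[tuple[str, str]]:
    """Trait pairs whose GEBV correlation exceeds the threshold."""
    corr = gebvs.corr()
    pairs = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                pairs.append((a, b))
    return pairs


def _sample_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    from scipy.stats import invwishart

    return invwishart.rvs(df=df, scale=scale, random_state=rng)


def fit_mtm_un(Y: pd.DataFrame, G: np.ndarray, config: GibbsConfig | None = None) -> FitResult:
    """Bivariate genomic model with unstructured covariances.

    ``Y`` is an (n genotypes x 2 traits) frame, NaN marking masked cells.
    Random effects u ~ N(0, U (x) G) and residuals eps ~ N(0, R (x) I), both
    2x2 covariances sampled from inverse-Wishart full conditionals
    (weakly informative prior: df = t + 2, identity scale).
    """
    config = config or GibbsConfig()
    if Y.shape[1] != 2:
        raise ValueError("fit_mtm_un takes exactly two traits")
    idx = Y.index
    t = 2
    Yv = Y.to_numpy(float)
    n = Yv.shape[0]
    if G.shape != (n, n):
        raise ValueError("G dimension does not match Y")
    miss = ~np.isfinite(Yv)
    if miss.all(axis=0).any():
        raise ValueError("a trait with no observations cannot be fitted")
    w, V = _eig_kernel(G)
    k = len(w)
    rng = np.random.default_rng(config.seed)

    col_var = np.nanvar(Yv, axis=0)
    col_var[col_var == 0] = 1.0
    mu = np.nanmean(Yv, axis=0)
    Y_aug = np.where(miss, mu, Yv)
    U = np.diag(col_var / 2)
    R = np.diag(col_var / 2)
    prior_df = t + 2.0
    prior_scale = np.eye(t)
    alpha = np.zeros((k, t))

    keep_u = np.zeros((n, t))
    U_s, R_s = [], []
    kept = 0
    # group rows by missingness pattern for batched augmentation
    patterns: dict[tuple, np.ndarray] = {}
    for pat in {tuple(row) for row in miss}:
        patterns[pat] = np.flatnonzero((miss == np.array(pat)).all(axis=1))

    for it in range(config.iterations):
        u = V @ alpha  # (n, t)
        # augmentation: conditional normal of missing traits given observed
        for pat, rows in patterns.items():
            mis = np.array(pat)
            if not mis.any():
                continue
            obs = ~mis
            mean = mu + u[rows]
            if obs.any():
                Roo = R[np.ix_(obs, obs)]
                Rmo = R[np.ix_(mis, obs)]
                gain = Rmo @ np.linalg.inv(Roo)
                cond_mean = mean[:, mis] + (Yv[np.ix_(rows, obs)] - mean[:, obs]) @ gain.T
                cond_cov = R[np.ix_(mis, mis)] - gain @ Rmo.T
            else:
                cond_mean = mean[:, mis]
                cond_cov = R[np.ix_(mis, mis)]
            Lc = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(int(mis.sum())))
            draw = cond_mean + rng.standard_normal(cond_mean.shape) @ Lc.T
            Y_aug[np.ix_(rows, mis)] = draw
        # intercepts
        Rinv = np.linalg.inv(R)
        resid_mean = (Y_aug - u).mean(axis=0)
        Lmu = np.linalg.cholesky(R / n)
        mu = resid_mean + Lmu @ rng.standard_normal(t)
        # genetic effects in the eigenbasis: per component i,
        # alpha_i ~ N(0, w_i U), likelihood precision R^-1
        E = V.T @ (Y_aug - mu)  # (k, t)
        Uinv = np.linalg.inv(U)
        # vectorized 2x2 conditional: prec_i = Rinv + Uinv / w_i
        pa = Rinv[0, 0] + Uinv[0, 0] / w
        pb = Rinv[0, 1] + Uinv[0, 1] / w
        pc = Rinv[1, 1] + Uinv[1, 1] / w
        det = pa * pc - pb * pb
        c00, c01, c11 = pc / det, -pb / det, pa / det
        RE = E @ Rinv.T
        m0 = c00 * RE[:, 0] + c01 * RE[:, 1]
        m1 = c01 * RE[:, 0] + c11 * RE[:, 1]
        l11 = np.sqrt(c00)
        l21 = c01 / l11
        l22 = np.sqrt(np.maximum(c11 - l21 * l21, 1e-300))
        z = rng.standard_normal((k, 2))
        alpha[:, 0] = m0 + l11 * z[:, 0]
        alpha[:, 1] = m1 + l21 * z[:, 0] + l22 * z[:, 1]
        u = V @ alpha
        # covariance updates
        Su = (alpha.T * (1.0 / w)) @ alpha
        U = _sample_invwishart(rng, prior_df + k, prior_scale + Su)
        resid = Y_aug - mu - u
        Sr = resid.T @ resid
        R = _sample_invwishart(rng, prior_df + n, prior_scale + Sr)
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_u += u
            U_s.append(U.copy())
            R_s.append(R.copy())
            kept += 1
    u_mean = keep_u / kept
    U_mean = np.mean(U_s, axis=0)
    corr_g = U_mean[0, 1] / np.sqrt(U_mean[0, 0] * U_mean[1, 1])
    return FitResult(
        u=pd.Series(u_mean[:, 0], index=idx),
        variance_samples={"U": np.array(U_s), "R": np.array(R_s)},
        model="mtm_un",
        extras={
            "u_matrix": pd.DataFrame(u_mean, index=idx, columns=list(Y.columns)),
            "genetic_correlation": float(corr_g),
            "U_mean": U_mean,
            "R_mean": np.mean(R_s, axis=0),
        },
    )
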