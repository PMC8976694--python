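"""Multi-environment genomic prediction.

Three models act on the genotype x environment table of adjusted phenotypes
(environments = location-year combinations retained by the heritability
filter), stacked as a length n*r response with one intercept per environment:

* across-environment G-BLUP (``gblup_e``): one genetic effect shared by all
  environments, u ~ N(0, (J (x) G) sigma_u^2) with J the all-ones r x r
  matrix — i.e. marker effects constant across environments;
* marker-by-environment interaction G-BLUP (``gblup_e_gxe``): the shared
  effect plus environment-specific deviations with block-diagonal
  covariance diag(sigma_u1^2 G, ..., sigma_ur^2 G);
* factor-analytic multivariate model (``mtm_fa``): u ~ N(0, C (x) G) with
  C = B B' + Psi, loadings B carrying a Gaussian prior of variance 100 and
  diagonal Psi; residuals are unstructured across environments.

Samplers work in the eigenbasis of G and never materialize n*r x n*r
matrices; missing genotype-environment cells are handled by data
augmentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from orchardgx.gp import (
    PRIOR_DF,
    FitResult,
    GibbsConfig,
    _eig_kernel,
    _prior_scale,
    _sample_sinvchi2,
)

LOADING_PRIOR_VARIANCE = 100.0


def _prepare_env_matrix(Y: pd.DataFrame):
    Yv = Y.to_numpy(float)
    miss = ~np.isfinite(Yv)
    empty = miss.all(axis=0)
    if empty.any():
        import warnings

        warnings.warn(f"environments with no data dropped: {list(Y.columns[empty])}",
                      stacklevel=3)
        Y = Y.loc[:, ~empty]
        Yv = Y.to_numpy(float)
        miss = ~np.isfinite(Yv)
    if miss.all(axis=1).any() and miss.all():
        raise ValueError("no observed cells")
    return Y, Yv, miss


def build_g0(G: np.ndarray, r: int) -> np.ndarray:
    """Across-environment covariance J (x) G (for inspection/tests only)."""
    return np.kron(np.ones((r, r)), G)


def build_g1(G: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Block-diagonal interaction covariance diag(sigma_j^2 G)."""
    r = len(sigmas)
    out = np.zeros((r * G.shape[0], r * G.shape[0]))
    n = G.shape[0]
    for j, s in enumerate(sigmas):
        out[j * n:(j + 1) * n, j * n:(j + 1) * n] = s * G
    return out


def fit_gblup_e(Y: pd.DataFrame, G: np.ndarray, config: GibbsConfig | None = None) -> FitResult:
    """Across-environment G-BLUP: genetic effects constant over environments."""
    config = config or GibbsConfig()
    Y, Yv, miss = _prepare_env_matrix(Y)
    n, r = Yv.shape
    if G.shape != (n, n):
        raise ValueError("G dimension does not match Y")
    w, V = _eig_kernel(G)
    rng = np.random.default_rng(config.seed)

    var_y = float(np.nanvar(Yv))
    S0 = _prior_scale(var_y)
    sig_u = sig_e = var_y / 2
    mu = np.nanmean(Yv, axis=0)
    mu = np.where(np.isfinite(mu), mu, np.nanmean(Yv))
    Y_aug = np.where(miss, mu, Yv)
    g = np.zeros(n)

    keep_g = np.zeros(n)
    su_s, se_s = [], []
    kept = 0
    for it in range(config.iterations):
        if miss.any():
            mean_mis = (mu[None, :] + g[:, None])[miss]
            Y_aug[miss] = mean_mis + rng.standard_normal(miss.sum()) * np.sqrt(sig_e)
        mu = (Y_aug - g[:, None]).mean(axis=0) + rng.standard_normal(r) * np.sqrt(sig_e / n)
        s = (Y_aug - mu).sum(axis=1)  # per-genotype residual sum over envs
        e = V.T @ s
        prec = r / sig_e + 1.0 / (w * sig_u)
        mean = (e / sig_e) / prec
        alpha = mean + rng.standard_normal(len(w)) / np.sqrt(prec)
        g = V @ alpha
        ssu = float(np.sum(alpha**2 / w))
        sig_u = _sample_sinvchi2(rng, PRIOR_DF + len(w), (PRIOR_DF * S0 + ssu) / (PRIOR_DF + len(w)))
        resid = Y_aug - mu - g[:, None]
        sse = float(np.sum(resid**2))
        sig_e = _sample_sinvchi2(rng, PRIOR_DF + n * r, (PRIOR_DF * S0 + sse) / (PRIOR_DF + n * r))
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_g += g
            su_s.append(sig_u)
            se_s.append(sig_e)
            kept += 1
    g_mean = keep_g / kept
    env_pred = pd.DataFrame(np.tile(g_mean[:, None], (1, r)), index=Y.index, columns=Y.columns)
    return FitResult(
        u=pd.Series(g_mean, index=Y.index),
        variance_samples={"sigma_u2": np.array(su_s), "sigma_e2": np.array(se_s)},
        model="gblup_e",
        extras={"env_genetic": env_pred},
    )


def fit_gblup_e_gxe(Y: pd.DataFrame, G: np.ndarray, config: GibbsConfig | None = None) -> FitResult:
    """Interaction G-BLUP: shared genetic effect plus environment deviations."""
    config = config or GibbsConfig()
    Y, Yv, miss = _prepare_env_matrix(Y)
    n, r = Yv.shape
    if r < 2:
        raise ValueError("interaction model requires at least 2 environments")
    if G.shape != (n, n):
        raise ValueError("G dimension does not match Y")
    w, V = _eig_kernel(G)
    k = len(w)
    rng = np.random.default_rng(config.seed)

    var_y = float(np.nanvar(Yv))
    S0 = _prior_scale(var_y)
    sig_u0 = var_y / 2
    sig_uj = np.full(r, var_y / 4)
    sig_e = var_y / 2
    mu = np.nanmean(Yv, axis=0)
    mu = np.where(np.isfinite(mu), mu, np.nanmean(Yv))
    Y_aug = np.where(miss, mu, Yv)
    g = np.zeros(n)
    d = np.zeros((n, r))

    keep_g = np.zeros(n)
    keep_env = np.zeros((n, r))
    su0_s, se_s = [], []
    suj_s = []
    kept = 0
    for it in range(config.iterations):
        pred = mu[None, :] + g[:, None] + d
        if miss.any():
            Y_aug[miss] = pred[miss] + rng.standard_normal(miss.sum()) * np.sqrt(sig_e)
        mu = (Y_aug - g[:, None] - d).mean(axis=0) + rng.standard_normal(r) * np.sqrt(sig_e / n)
        # shared component
        s = (Y_aug - mu - d).sum(axis=1)
        e = V.T @ s
        prec = r / sig_e + 1.0 / (w * sig_u0)
        alpha0 = (e / sig_e) / prec + rng.standard_normal(k) / np.sqrt(prec)
        g = V @ alpha0
        ss0 = float(np.sum(alpha0**2 / w))
        sig_u0 = _sample_sinvchi2(rng, PRIOR_DF + k, (PRIOR_DF * S0 / 2 + ss0) / (PRIOR_DF + k))
        # environment-specific deviations
        base = Y_aug - mu - g[:, None]
        E = V.T @ base  # (k, r)
        prec_j = 1.0 / sig_e + 1.0 / (w[:, None] * sig_uj[None, :])
        mean_j = (E / sig_e) / prec_j
        alpha1 = mean_j + rng.standard_normal((k, r)) / np.sqrt(prec_j)
        d = V @ alpha1
        ssj = (alpha1**2 / w[:, None]).sum(axis=0)
        for j in range(r):
            sig_uj[j] = _sample_sinvchi2(
                rng, PRIOR_DF + k, (PRIOR_DF * S0 / (2 * r) + ssj[j]) / (PRIOR_DF + k)
            )
        resid = Y_aug - mu - g[:, None] - d
        sse = float(np.sum(resid**2))
        sig_e = _sample_sinvchi2(rng, PRIOR_DF + n * r, (PRIOR_DF * S0 + sse) / (PRIOR_DF + n * r))
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_g += g
            keep_env += g[:, None] + d
            su0_s.append(sig_u0)
            suj_s.append(sig_uj.copy())
            se_s.append(sig_e)
            kept += 1
    env_pred = pd.DataFrame(keep_env / kept, index=Y.index, columns=Y.columns)
    return FitResult(
        u=pd.Series(keep_g / kept, index=Y.index),
        variance_samples={
            "sigma_u0_2": np.array(su0_s),
            "sigma_uj_2": np.array(suj_s),
            "sigma_e2": np.array(se_s),
        },
        model="gblup_e_gxe",
        extras={"env_genetic": env_pred},
    )


def fit_mtm_fa(
    Y: pd.DataFrame,
    G: np.ndarray,
    n_factors: int = 1,
    config: GibbsConfig | None = None,
    loading_prior_variance: float = LOADING_PRIOR_VARIANCE,
) -> FitResult:
    """Factor-analytic multivariate model across environments.

    u ~ N(0, C (x) G) with C = B B' + Psi; residuals unstructured across
    environments.  Requires at least three environments (with fewer, the
    factor structure is not identifiable and the model refuses, matching the
    eligibility rule of the surrounding pipeline).  The sign of the first
    loading is fixed positive for identifiability.
    """
    config = config or GibbsConfig()
    Y, Yv, miss = _prepare_env_matrix(Y)
    n, r = Yv.shape
    if r < 3:
        raise ValueError("factor-analytic model requires at least 3 environments")
    if G.shape != (n, n):
        raise ValueError("G dimension does not match Y")
    w, V = _eig_kernel(G)
    k = len(w)
    rng = np.random.default_rng(config.seed)

    var_y = float(np.nanvar(Yv))
    S0 = _prior_scale(var_y)
    mu = np.nanmean(Yv, axis=0)
    mu = np.where(np.isfinite(mu), mu, np.nanmean(Yv))
    Y_aug = np.where(miss, mu, Yv)
    B = np.full((r, n_factors), np.sqrt(var_y / 4))
    Psi = np.full(r, var_y / 4)
    R = np.eye(r) * var_y / 2
    prior_df = r + 2.0
    prior_scale = np.eye(r)
    alpha = np.zeros((k, r))  # genetic effects in the eigenbasis of G

    patterns: dict[tuple, np.ndarray] = {}
    for pat in {tuple(row) for row in miss}:
        patterns[pat] = np.flatnonzero((miss == np.array(pat)).all(axis=1))

    keep_env = np.zeros((n, r))
    B_s, Psi_s, R_s, C_s = [], [], [], []
    kept = 0
    for it in range(config.iterations):
        u = V @ alpha
        # augmentation with unstructured residual covariance
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
            Lc = np.linalg.cholesky(cond_cov + 1e-10 * np.eye(int(mis.sum())))
            Y_aug[np.ix_(rows, mis)] = cond_mean + rng.standard_normal(cond_mean.shape) @ Lc.T
        Rinv = np.linalg.inv(R)
        mu = (Y_aug - u).mean(axis=0) + np.linalg.cholesky(R / n) @ rng.standard_normal(r)
        # genetic effects: alpha_i ~ N(0, w_i C), C = BB' + diag(Psi)
        C = B @ B.T + np.diag(Psi)
        E = V.T @ (Y_aug - mu)  # (k, r)
        Cinv = np.linalg.inv(C + 1e-10 * np.eye(r))
        prec = Rinv[None, :, :] + Cinv[None, :, :] / w[:, None, None]
        cov = np.linalg.inv(prec)
        mean = np.einsum("kij,kj->ki", cov, E @ Rinv.T)
        Lc = np.linalg.cholesky(cov)
        alpha = mean + np.einsum("kij,kj->ki", Lc, rng.standard_normal((k, r)))
        # factor decomposition of the sampled genetic effects:
        # alpha_i = B f_i + d_i with f_i ~ N(0, w_i I), d_i ~ N(0, w_i Psi)
        PsiInv = np.diag(1.0 / Psi)
        Fprec = B.T @ PsiInv @ B + np.eye(n_factors)
        Fcov = np.linalg.inv(Fprec)
        Lf = np.linalg.cholesky(Fcov)
        FM = alpha @ (PsiInv @ B @ Fcov.T)  # (k, n_factors): mean/sqrt(w) scale handled below
        # conditional of f_i: N(Fcov B' PsiInv alpha_i, w_i Fcov)
        F = FM + (rng.standard_normal((k, n_factors)) @ Lf.T) * np.sqrt(w)[:, None]
        # loadings: per environment, regression of alpha[:, e] on F weighted by 1/w
        for e_i in range(r):
            xw = F / w[:, None]
            prec_b = F.T @ xw / Psi[e_i] + np.eye(n_factors) / loading_prior_variance
            cov_b = np.linalg.inv(prec_b)
            mean_b = cov_b @ (xw.T @ alpha[:, e_i]) / Psi[e_i]
            B[e_i] = mean_b + np.linalg.cholesky(cov_b) @ rng.standard_normal(n_factors)
        if B[0, 0] < 0:
            B[:, 0] *= -1.0
            F[:, 0] *= -1.0
        # environment-specific variances Psi
        Dres = alpha - F @ B.T
        ssd = (Dres**2 / w[:, None]).sum(axis=0)
        for e_i in range(r):
            Psi[e_i] = _sample_sinvchi2(
                rng, PRIOR_DF + k, (PRIOR_DF * S0 / 4 + ssd[e_i]) / (PRIOR_DF + k)
            )
        u = V @ alpha
        resid = Y_aug - mu - u
        R = invwishart.rvs(df=prior_df + n, scale=prior_scale + resid.T @ resid, random_state=rng)
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            keep_env += u
            B_s.append(B.copy())
            Psi_s.append(Psi.copy())
            R_s.append(R.copy())
            C_s.append(B @ B.T + np.diag(Psi))
            kept += 1
    env_pred = pd.DataFrame(keep_env / kept, index=Y.index, columns=Y.columns)
    C_mean = np.mean(C_s, axis=0)
    return FitResult(
        u=pd.Series(env_pred.mean(axis=1), index=Y.index),
        variance_samples={
            "B": np.array(B_s),
            "Psi": np.array(Psi_s),
            "R": np.array(R_s),
        },
        model="mtm_fa",
        extras={
            "env_genetic": env_pred,
            "C_mean": C_mean,
            "B_mean": np.mean(B_s, axis=0),
            "Psi_mean": np.mean(Psi_s, axis=0),
            "environments": list(Y.columns),
        },
    )
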