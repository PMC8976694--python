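"""Linear mixed-model engine: REML variance components and BLUPs.

Fits the general model

    y = X beta + sum_j Z_j b_j + eps,    b_j ~ N(0, sigma_j^2 K_j),
    eps ~ N(0, sigma_eps^2 I)

via EM-REML on Henderson's mixed-model equations, with Aitken acceleration.
Kernel-structured random effects (K_j not the identity) are rotated to
independent effects through the eigendecomposition of K_j, so the working
model always has iid random effects per term.

On balanced designs the REML estimates coincide with the classical ANOVA
method-of-moments estimates (clamped at zero); this is exploited in the test
oracles rather than in the algorithm itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

_EIG_TOL = 1e-8


class RankError(np.linalg.LinAlgError):
    """Fixed-effect design is rank deficient."""


@dataclass
class RandomTerm:
    """One random effect term.

    ``Z`` may be an ``(N, q)`` design matrix or a length-N sequence of factor
    levels (converted to an indicator design).  ``K`` is an optional ``(q, q)``
    covariance/relationship structure among the ``q`` effects; ``None`` means
    identity.  ``levels`` names the effects (derived automatically for factor
    input).
    """

    Z: np.ndarray | list | pd.Series
    K: np.ndarray | None = None
    name: str = "random"
    levels: list | None = None

    def materialize(self, n_obs: int) -> tuple[np.ndarray, list]:
        Z = self.Z
        if isinstance(Z, (list, pd.Series)) or (isinstance(Z, np.ndarray) and Z.ndim == 1):
            codes, levels = pd.factorize(pd.Series(np.asarray(Z)), sort=True)
            Zm = np.zeros((len(codes), len(levels)))
            Zm[np.arange(len(codes)), codes] = 1.0
            return Zm, list(levels)
        Zm = np.asarray(Z, dtype=float)
        if Zm.shape[0] != n_obs:
            raise ValueError(f"random term {self.name!r}: {Zm.shape[0]} rows for {n_obs} observations")
        levels = self.levels if self.levels is not None else list(range(Zm.shape[1]))
        return Zm, levels


@dataclass
class LMMFit:
    """REML fit: variance components, BLUPs, fixed effects, convergence info."""

    variance_components: dict[str, float]
    residual_variance: float
    blups: dict[str, pd.Series]
    beta: np.ndarray
    fitted_fixed: np.ndarray
    fitted: np.ndarray
    n_iter: int
    converged: bool
    loglik: float

    def to_dict(self) -> dict:
        return {
            "variance_components": self.variance_components,
            "residual_variance": self.residual_variance,
            "beta": self.beta.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik": self.loglik,
        }


def _check_psd(K: np.ndarray, name: str) -> None:
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError(f"covariance of term {name!r} is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError(f"covariance of term {name!r} is not positive semi-definite")


def _rotate_kernel(Z: np.ndarray, K: np.ndarray, name: str):
    """Return (Z*, back) with Z* = Z E L^(1/2) so effects become iid;
    back maps iid BLUPs to the original effect scale."""
    _check_psd(K, name)
    w, E = np.linalg.eigh(K)
    keep = w > _EIG_TOL * w.max()
    w, E = w[keep], E[:, keep]
    T = E * np.sqrt(w)
    return Z @ T, T


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray | None,
    random_terms: list[RandomTerm],
    max_iter: int = 500,
    tol: float = 1e-10,
) -> LMMFit:
    """Fit the mixed model by EM-REML.

    Parameters
    ----------
    y
        Response vector, length N.
    X
        Fixed-effect design; ``None`` means intercept only.  Must have full
        column rank.
    random_terms
        At least one :class:`RandomTerm`.
    """
    y = np.asarray(y, dtype=float).ravel()
    N = len(y)
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != N:
        raise ValueError("X row count does not match y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("fixed-effect design is rank deficient")
    if N <= X.shape[1]:
        raise RankError("more fixed-effect columns than observations")
    if not random_terms:
        raise ValueError("at least one random term is required")

    names, Zs, backs, levels_per_term = [], [], [], []
    for j, term in enumerate(random_terms):
        Z, levels = term.materialize(N)
        back = None
        if term.K is not None:
            Z, back = _rotate_kernel(Z, np.asarray(term.K, float), term.name)
        names.append(term.name if term.name != "random" else f"random{j}")
        Zs.append(Z)
        backs.append(back)
        levels_per_term.append(levels)

    var_y = float(np.var(y))
    if var_y < 1e-14 * max(1.0, float(np.mean(y)) ** 2) or var_y == 0.0:
        # degenerate constant response: everything zero
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        blups = {
            nm: pd.Series(np.zeros(len(lv)), index=lv)
            for nm, lv in zip(names, levels_per_term)
        }
        return LMMFit({nm: 0.0 for nm in names}, 0.0, blups, beta, X @ beta, X @ beta, 0, True, 0.0)

    p = X.shape[1]
    qs = [Z.shape[1] for Z in Zs]
    q_tot = sum(qs)
    W = np.concatenate([X] + Zs, axis=1)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    k = len(Zs)
    sig = np.full(k, var_y / (2 * k))
    sig_e = var_y / 2
    floor = 1e-10 * var_y

    blocks = []
    start = p
    for q in qs:
        blocks.append(slice(start, start + q))
        start += q

    def reml_step(sig, sig_e):
        A = WtW.copy()
        for j, sl in enumerate(blocks):
            lam = sig_e / max(sig[j], floor)
            A[sl, sl] += np.eye(qs[j]) * lam
        cho = linalg.cho_factor(A, lower=True)
        theta = linalg.cho_solve(cho, Wty)
        Ainv = linalg.cho_solve(cho, np.eye(A.shape[0]))
        logdetA = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sse = yty - float(theta @ Wty)
        new_e = max(sse / (N - p), floor)
        new_sig = np.empty(k)
        for j, sl in enumerate(blocks):
            b = theta[sl]
            tr = np.trace(Ainv[sl, sl])
            new_sig[j] = max((float(b @ b) + sig_e * tr) / qs[j], floor)
        # REML log-likelihood at the *current* parameters
        ll = -0.5 * (
            (N - p - q_tot) * np.log(sig_e)
            + sum(qs[j] * np.log(max(sig[j], floor)) for j in range(k))
            + logdetA
            + max(sse, 0.0) / sig_e
        )
        return new_sig, new_e, theta, ll

    prev = None
    ll_prev = -np.inf
    theta = None
    converged = False
    it = 0
    history: list[np.ndarray] = []
    while it < max_iter:
        it += 1
        new_sig, new_e, theta, ll = reml_step(sig, sig_e)
        params = np.concatenate([new_sig, [new_e]])
        history.append(params)
        # Aitken acceleration on the parameter sequence every 4 EM sweeps
        if len(history) >= 3 and it % 4 == 0:
            p2, p1, p0 = history[-1], history[-2], history[-3]
            d1, d0 = p2 - p1, p1 - p0
            denom = d0 - d1
            ok = np.abs(denom) > 1e-14
            acc = p2.copy()
            acc[ok] = p0[ok] + d0[ok] * d0[ok] / denom[ok]
            if np.all(acc > 0):
                trial_sig, trial_e = acc[:-1], acc[-1]
                _, _, _, ll_trial = reml_step(trial_sig, trial_e)
                if ll_trial >= ll:
                    params = acc
        sig, sig_e = params[:-1], params[-1]
        if prev is not None:
            rel_ll = abs(ll - ll_prev) / (abs(ll_prev) + 1.0)
            # components collapsing to the zero boundary are treated as
            # converged; their relative change never settles
            active = params > 1e-5 * var_y
            rel_par = 0.0
            if active.any():
                rel_par = np.max(
                    np.abs(params[active] - prev[active]) / (np.abs(prev[active]) + var_y * 1e-8)
                )
            if rel_ll < tol and rel_par < 1e-7:
                converged = True
                break
        prev, ll_prev = params, ll
    _, _, theta, ll = reml_step(sig, sig_e)
    if not converged and it >= max_iter:
        warnings.warn("EM-REML reached max_iter without meeting tolerance", stacklevel=2)

    # clamp tiny components to exactly zero for reporting
    sig_rep = np.where(sig < 1e-5 * var_y, 0.0, sig)
    sig_e_rep = 0.0 if sig_e < 1e-9 * var_y else sig_e

    beta = theta[:p]
    blups = {}
    fitted = X @ beta
    for j, sl in enumerate(blocks):
        b = theta[sl]
        fitted = fitted + Zs[j] @ b
        if backs[j] is not None:
            b = backs[j] @ b
        blups[names[j]] = pd.Series(b, index=levels_per_term[j])
    return LMMFit(
        variance_components={nm: float(s) for nm, s in zip(names, sig_rep)},
        residual_variance=float(sig_e_rep),
        blups=blups,
        beta=beta,
        fitted_fixed=X @ beta,
        fitted=fitted,
        n_iter=it,
        converged=converged or it < max_iter,
        loglik=float(ll),
    )
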