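"""Numba inner chain for the BayesCpi whole-genome regression sampler."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def bayescpi_chain(
    Mt,  # (m, n) centered dosage rows, C-contiguous
    zz,  # (m,) column sums of squares
    y,  # (n,) response with NaN-masked entries already encoded via miss
    miss,  # (n,) bool missing mask
    iterations,
    burn_in,
    thinning,
    nu0,
    S0a,
    S0e,
    seed,
):
    np.random.seed(seed)
    m, n = Mt.shape
    y_aug = y.copy()
    obs = ~miss
    n_obs = int(obs.sum())
    mu = 0.0
    s = 0.0
    for i in range(n):
        if obs[i]:
            s += y_aug[i]
    mu = s / n_obs
    for i in range(n):
        if miss[i]:
            y_aug[i] = mu
    a = np.zeros(m)
    delta = np.zeros(m, dtype=np.bool_)
    pi = 0.5
    sig_a = S0a
    sig_e = S0e
    e = y_aug - mu  # residual y - mu - sum z a

    n_kept = (iterations - burn_in) // thinning
    u_sum = np.zeros(n)
    a_sum = np.zeros(m)
    freq = np.zeros(m)
    h2_samples = np.zeros(n_kept)
    pi_samples = np.zeros(n_kept)
    sig_a_samples = np.zeros(n_kept)
    sig_e_samples = np.zeros(n_kept)
    kept = 0

    for it in range(iterations):
        # data augmentation for masked genotypes
        for i in range(n):
            if miss[i]:
                u_i = y_aug[i] - mu - e[i]
                y_new = mu + u_i + np.random.normal() * np.sqrt(sig_e)
                diff = y_new - y_aug[i]
                y_aug[i] = y_new
                e[i] += diff

        # intercept
        s = 0.0
        for i in range(n):
            s += e[i]
        mu_new = mu + s / n + np.random.normal() * np.sqrt(sig_e / n)
        shift = mu_new - mu
        mu = mu_new
        for i in range(n):
            e[i] -= shift

        # marker sweep
        n_in = 0
        ssa = 0.0
        log_pi = np.log(pi)
        log_1mpi = np.log(1.0 - pi)
        for k in range(m):
            zk = Mt[k]
            rhs = 0.0
            for i in range(n):
                rhs += zk[i] * e[i]
            if delta[k]:
                rhs += zz[k] * a[k]
            v0 = zz[k] * sig_e
            v1 = v0 + zz[k] * zz[k] * sig_a
            if v0 <= 0.0:
                continue
            logL1 = -0.5 * (np.log(v1) + rhs * rhs / v1)
            logL0 = -0.5 * (np.log(v0) + rhs * rhs / v0)
            logodds = logL1 - logL0 + log_1mpi - log_pi
            if logodds > 35.0:
                p1 = 1.0
            elif logodds < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-logodds))
            include = np.random.random() < p1
            a_old = a[k] if delta[k] else 0.0
            if include:
                Ck = zz[k] + sig_e / sig_a
                mean = rhs / Ck
                a_new = mean + np.random.normal() * np.sqrt(sig_e / Ck)
            else:
                a_new = 0.0
            diffa = a_new - a_old
            if diffa != 0.0:
                for i in range(n):
                    e[i] -= zk[i] * diffa
            a[k] = a_new
            delta[k] = include
            if include:
                n_in += 1
                ssa += a_new * a_new

        # pi ~ Beta(m - n_in + 1, n_in + 1) under a uniform prior
        g1 = np.random.gamma(m - n_in + 1.0, 1.0)
        g2 = np.random.gamma(n_in + 1.0, 1.0)
        pi = g1 / (g1 + g2)
        pi = min(max(pi, 1e-6), 1.0 - 1e-6)

        # common marker-effect variance, scaled-inverse-chi^2
        dfa = nu0 + n_in
        sig_a = (nu0 * S0a + ssa) / np.random.chisquare(dfa)

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        dfe = nu0 + n
        sig_e = (nu0 * S0e + sse) / np.random.chisquare(dfe)

        if it >= burn_in and (it - burn_in) % thinning == 0:
            vg_mean = 0.0
            for i in range(n):
                vg_mean += y_aug[i] - mu - e[i]
            vg_mean /= n
            vg = 0.0
            for i in range(n):
                d = (y_aug[i] - mu - e[i]) - vg_mean
                vg += d * d
            vg /= n
            h2_samples[kept] = vg / (vg + sig_e)
            pi_samples[kept] = pi
            sig_a_samples[kept] = sig_a
            sig_e_samples[kept] = sig_e
            for i in range(n):
                u_sum[i] += y_aug[i] - mu - e[i]
            for k in range(m):
                a_sum[k] += a[k]
                if delta[k]:
                    freq[k] += 1.0
            kept += 1

    return (
        u_sum / kept,
        a_sum / kept,
        freq / kept,
        h2_samples,
        pi_samples,
        sig_a_samples,
        sig_e_samples,
    )
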