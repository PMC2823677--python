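"""Independent brute-force oracles used by the tests.

Everything here is built from the sequential Polya-urn / conjugate-predictive
view of the collapsed model -- a different route than the package's
Gamma-function formulas -- so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def icm_joint_prob(z, links, M, C, alpha, beta):
    """Exact collapsed joint p({L}, {z}) by sequential predictive products.

    Links are processed in order; each contributes a Chinese-restaurant
    factor for its component and two sequential Polya-urn factors for its
    endpoints.  Exchangeability makes the order irrelevant.
    """
    n = [0] * C
    q = [[0] * M for _ in range(C)]
    p = 1.0
    for t, (zl, (i, j)) in enumerate(zip(z, links)):
        p *= (n[zl] + alpha) / (t + C * alpha)
        p *= (q[zl][i] + beta) / (2 * n[zl] + M * beta)
        q[zl][i] += 1
        p *= (q[zl][j] + beta) / (2 * n[zl] + 1 + M * beta)
        q[zl][j] += 1
        n[zl] += 1
    return p


def icm_enumerate(links, M, C, alpha, beta):
    """All assignments with exact probabilities, plus per-link marginals."""
    N = len(links)
    table = {}
    total = 0.0
    for z in itertools.product(range(C), repeat=N):
        p = icm_joint_prob(z, links, M, C, alpha, beta)
        table[z] = p
        total += p
    marginals = np.zeros((N, C))
    for z, p in table.items():
        for l, zl in enumerate(z):
            marginals[l, zl] += p
    return {z: p / total for z, p in table.items()}, marginals / total


def gaussian_predictive_logpdf(x, m, datasum, sumsq, mu0, s0, s2):
    """log p(x | m previous values) under the conjugate normal-mean model.

    One-dimensional; ``datasum``/``sumsq`` summarize the previous values.
    ``sumsq`` is unused (the predictive needs only the mean) but kept to
    mirror the sufficient statistics tests track.
    """
    S = 1.0 / (1.0 / s0 + m / s2)
    A = S * (mu0 / s0 + datasum / s2)
    var = S + s2
    return -0.5 * math.log(2 * math.pi * var) - (x - A) ** 2 / (2 * var)


def icmg2_joint_prob(z_links, z_nodes, links, x, M, C, alpha, beta, mu0, s0, s2):
    """Exact collapsed joint of the link+expression model, sequentially.

    Links first, then node data, matching the pooled-count conventions:
    a single urn over components for all N + M items, one shared node urn
    per component (two draws per link, one per node datum), and the
    conjugate Gaussian predictive chain for the profiles.  ``x`` is
    ``(M, D)``.
    """
    x = np.asarray(x, dtype=float)
    D = x.shape[1]
    pool = [0] * C  # n_z + m_z so far
    tot = [0] * C  # 2 n_z + m_z so far (node draws)
    q = [[0] * M for _ in range(C)]
    mcnt = [0] * C
    datasum = np.zeros((C, D))
    logp = 0.0
    t = 0
    for zl, (i, j) in zip(z_links, links):
        logp += math.log((pool[zl] + alpha) / (t + C * alpha))
        logp += math.log((q[zl][i] + beta) / (tot[zl] + M * beta))
        q[zl][i] += 1
        tot[zl] += 1
        logp += math.log((q[zl][j] + beta) / (tot[zl] + M * beta))
        q[zl][j] += 1
        tot[zl] += 1
        pool[zl] += 1
        t += 1
    for node, zn in enumerate(z_nodes):
        logp += math.log((pool[zn] + alpha) / (t + C * alpha))
        logp += math.log((q[zn][node] + beta) / (tot[zn] + M * beta))
        q[zn][node] += 1
        tot[zn] += 1
        for d in range(D):
            logp += gaussian_predictive_logpdf(
                x[node, d], mcnt[zn], datasum[zn, d], None, mu0, s0, s2
            )
            datasum[zn, d] += x[node, d]
        mcnt[zn] += 1
        pool[zn] += 1
        t += 1
    return logp


def icmg2_enumerate(links, x, M, C, alpha, beta, mu0, s0, s2):
    """Exact posterior over all (link, node) assignments and their marginals."""
    N = len(links)
    logps = {}
    for zall in itertools.product(range(C), repeat=N + M):
        zl, zn = zall[:N], zall[N:]
        logps[zall] = icmg2_joint_prob(
            zl, zn, links, x, M, C, alpha, beta, mu0, s0, s2
        )
    mx = max(logps.values())
    weights = {z: math.exp(lp - mx) for z, lp in logps.items()}
    total = sum(weights.values())
    post = {z: w / total for z, w in weights.items()}
    marg = np.zeros((N + M, C))
    for z, p in post.items():
        for idx, c in enumerate(z):
            marg[idx, c] += p
    return post, marg
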