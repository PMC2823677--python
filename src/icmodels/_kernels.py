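"""Numba-compiled inner loops of the collapsed Gibbs samplers.

Randomness enters only through pre-drawn uniform variates (one per item per
sweep), so chains are reproducible from a NumPy generator held in Python.
The link kernel serves both the plain model and the joint link+expression
model: the latter pools node-datum counts ``m_z`` into the component prior
and into the node-multinomial denominators, and a plain-model call simply
passes ``m = 0``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_links(z, li, lj, n, m, q, alpha, beta, u):
    """One Gibbs sweep over all links, in index order, in place.

    For held-out link ``l`` with endpoints ``(i, j)`` the conditional over
    components is proportional to::

        (n'_z + m_z + alpha) * (q'_{z,i} + beta) * (q'_{z,j} + beta + [i==j])
        / ((2 n'_z + m_z + M beta) * (2 n'_z + m_z + M beta + 1))

    where primes denote counts excluding the held-out link.  ``u`` holds one
    uniform variate per link for inverse-CDF sampling.
    """
    N = li.shape[0]
    C = n.shape[0]
    M = q.shape[1]
    p = np.empty(C, dtype=np.float64)
    for l in range(N):
        zl = z[l]
        i = li[l]
        j = lj[l]
        n[zl] -= 1
        q[zl, i] -= 1
        q[zl, j] -= 1
        total = 0.0
        for c in range(C):
            denom = 2.0 * n[c] + m[c] + M * beta
            w = (n[c] + m[c] + alpha) * (q[c, i] + beta)
            if i == j:
                w *= q[c, j] + beta + 1.0
            else:
                w *= q[c, j] + beta
            w /= denom * (denom + 1.0)
            p[c] = w
            total += w
        r = u[l] * total
        acc = 0.0
        znew = C - 1
        for c in range(C):
            acc += p[c]
            if r < acc:
                znew = c
                break
        z[l] = znew
        n[znew] += 1
        q[znew, i] += 1
        q[znew, j] += 1


@njit(cache=True)
def sweep_nodes(zn, x, n, m, q, datasum, alpha, beta, mu0, s0, s2, u):
    """One Gibbs sweep over all node expression profiles, in place.

    Component means are marginalized: with spherical prior ``N(mu0, s0 I)``
    and noise ``N(., s2 I)`` the held-out predictive for profile ``x_i`` in
    component ``z`` is Gaussian with per-dimension variance ``S' + s2``,
    ``S' = 1 / (1/s0 + m'_z/s2)`` and mean ``A' = S' (mu0/s0 + datasum'_z/s2)``.
    The count factor pools link and node-datum draws from the shared theta::

        (n_z + m'_z + alpha) * (q'_{z,i} + beta) / (2 n_z + m'_z + M beta)
    """
    M = zn.shape[0]
    C = n.shape[0]
    D = x.shape[1]
    logw = np.empty(C, dtype=np.float64)
    for i in range(M):
        zi = zn[i]
        m[zi] -= 1
        q[zi, i] -= 1
        for d in range(D):
            datasum[zi, d] -= x[i, d]
        best = -1e308
        for c in range(C):
            S = 1.0 / (1.0 / s0 + m[c] / s2)
            var = S + s2
            ll = 0.0
            for d in range(D):
                A = S * (mu0[d] / s0 + datasum[c, d] / s2)
                diff = x[i, d] - A
                ll += -0.5 * np.log(2.0 * np.pi * var) - diff * diff / (2.0 * var)
            w = (
                np.log(n[c] + m[c] + alpha)
                + np.log(q[c, i] + beta)
                - np.log(2.0 * n[c] + m[c] + M * beta)
            )
            logw[c] = w + ll
            if logw[c] > best:
                best = logw[c]
        total = 0.0
        for c in range(C):
            logw[c] = np.exp(logw[c] - best)
            total += logw[c]
        r = u[i] * total
        acc = 0.0
        znew = C - 1
        for c in range(C):
            acc += logw[c]
            if r < acc:
                znew = c
                break
        zn[i] = znew
        m[znew] += 1
        q[znew, i] += 1
        for d in range(D):
            datasum[znew, d] += x[i, d]
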