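"""Joint link + expression model (ICMg2) with marginalized component means.

The same latent components that emit links also emit one expression
profile per node: a node datum's component is drawn from the shared
``theta``, the node identity from ``phi_z``, and the profile
``x_i ~ N(mu_z, sigma^2 I)`` around a component mean with conjugate prior
``mu_z ~ N(mu_0, sigma_0^2 I)``.  The means are integrated out, so the
sampler tracks, besides the link tables ``n``/``q``, per-component node
datum counts ``m_z`` and per-component data sums.

Pooling conventions (links and node data share both ``theta`` and the
``phi_z`` node draws):

* component prior counts are ``n_z + m_z``;
* the ``q`` table accumulates two endpoint draws per link plus one node
  draw per datum, normalized by ``2 n_z + m_z + M beta``.

The model is deliberately not constrained to place each node's single
datum in a component its links use; the datum's component is free.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from icmodels._kernels import sweep_links, sweep_nodes
from icmodels.core import (
    DEFAULT_BURN_IN,
    DEFAULT_INTERVAL,
    DEFAULT_N_SAMPLES,
    Hyperparameters,
    ModelState,
    _counts_from_assignments,
    _membership_rows,
    joint_log_prob,
    link_conditional,
)
from icmodels.exceptions import DataError, StateError
from icmodels.network import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionHyperparameters:
    """Gaussian hyperparameters for the expression arm.

    ``mu0`` is the prior mean of a component mean (scalar, broadcast across
    conditions), ``sigma0_sq`` the prior variance (``V0 = sigma0^2 I``) and
    ``sigma_sq`` the shared observation noise variance (``V = sigma^2 I``).
    The defaults (0, 1, 0.1) describe small variations around a zero base
    level, as appropriate for log-ratio expression data.
    """

    mu0: float = 0.0
    sigma0_sq: float = 1.0
    sigma_sq: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0 or self.sigma_sq <= 0:
            raise DataError("sigma0_sq and sigma_sq must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x conditions expression values with a missing-value mask."""

    genes: list[str]
    values: np.ndarray  # (M, D)
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(
            len(self.genes), -1
        )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise DataError("missing_mask shape must match values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionState:
    """Node-datum assignments and sufficient statistics of the expression arm."""

    z_nodes: np.ndarray  # (M,) component per node datum
    m: np.ndarray  # (C,) node data per component
    datasum: np.ndarray  # (C, D) per-component sums of assigned profiles

    def copy(self) -> "ExpressionState":
        return ExpressionState(self.z_nodes.copy(), self.m.copy(), self.datasum.copy())

    def check(self, values: np.ndarray) -> None:
        if self.m.sum() != len(self.z_nodes):
            raise StateError("inconsistent counts: sum(m) != M")
        recomputed = np.zeros_like(self.datasum)
        np.add.at(recomputed, self.z_nodes, values)
        if not np.allclose(recomputed, self.datasum, atol=1e-9):
            raise StateError("datasum drifted from assignments")


def posterior_mean_cov(
    m_z: float, datasum_z: np.ndarray, ehyper: ExpressionHyperparameters
) -> tuple[np.ndarray, float]:
    """Conjugate posterior of a component mean given its assigned profiles.

    With spherical covariances the update is scalar per dimension::

        S = 1 / (1/sigma0^2 + m_z/sigma^2)
        A = S (mu0/sigma0^2 + datasum_z/sigma^2)

    Returns the posterior mean vector ``A`` and the per-dimension posterior
    variance ``S``.  ``m_z = 0`` recovers the prior exactly.
    """
    if m_z < 0:
        raise StateError("inconsistent counts")
    S = 1.0 / (1.0 / ehyper.sigma0_sq + m_z / ehyper.sigma_sq)
    A = S * (
        ehyper.mu0 / ehyper.sigma0_sq
        + np.asarray(datasum_z, dtype=np.float64) / ehyper.sigma_sq
    )
    return A, S


def link_conditional_g2(
    link_state: ModelState,
    expr_state: ExpressionState,
    network: InteractionNetwork,
    link_index: int,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
) -> np.ndarray:
    """Conditional for a held-out link in the joint model.

    Identical to the plain-model conditional except that node-datum counts
    pool into the shared component prior, ``n'_z + m_z + alpha``, and into
    the node-draw totals, ``2 n'_z + m_z + M beta``.  No Gaussian factor
    appears (the held-out item is a link).  With no expression data
    assigned (``m = 0``) this reduces exactly to the plain conditional.
    """
    return link_conditional(link_state, network, hyper, link_index, m=expr_state.m)


def node_conditional(
    link_state: ModelState,
    expr_state: ExpressionState,
    x_i: np.ndarray,
    node: int,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
) -> np.ndarray:
    """Conditional for a held-out node datum (identity + profile).

    Proportional to::

        (n_z + m'_z + alpha) (q'_{z,node} + beta) / (2 n_z + m'_z + M beta)
          * N(x_i | A'_z, (S'_z + sigma^2) I)

    where ``A'``, ``S'`` are the conjugate posterior of the component mean
    computed without the held-out datum.  Evaluated in log space with
    max-subtraction before normalizing.
    """
    C = hyper.C
    M = link_state.q.shape[1]
    zi = expr_state.z_nodes[node]
    m_held = expr_state.m.astype(np.float64).copy()
    q_node = link_state.q[:, node].astype(np.float64).copy()
    datasum = expr_state.datasum.copy()
    m_held[zi] -= 1
    q_node[zi] -= 1
    datasum[zi] -= x_i
    if m_held[zi] < 0 or q_node[zi] < 0:
        raise StateError("inconsistent counts")
    logw = np.empty(C)
    for c in range(C):
        A, S = posterior_mean_cov(m_held[c], datasum[c], ehyper)
        var = S + ehyper.sigma_sq
        ll = np.sum(-0.5 * np.log(2 * np.pi * var) - (x_i - A) ** 2 / (2 * var))
        logw[c] = (
            np.log(link_state.n[c] + m_held[c] + hyper.alpha)
            + np.log(q_node[c] + hyper.beta)
            - np.log(2.0 * link_state.n[c] + m_held[c] + M * hyper.beta)
            + ll
        )
    w = np.exp(logw - logw.max())
    return w / w.sum()


def init_assignments_g2(
    network: InteractionNetwork,
    expression: ExpressionMatrix,
    hyper: Hyperparameters,
    seed: int | np.random.Generator,
) -> tuple[ModelState, ExpressionState]:
    """Uniform random initialization of both link and node-datum assignments."""
    if expression.genes != network.nodes:
        raise DataError("expression genes must align with network nodes")
    if np.any(expression.missing_mask):
        raise DataError("expression matrix contains missing values; impute first")
    rng = np.random.default_rng(seed)
    z = rng.integers(0, hyper.C, size=network.n_links, dtype=np.int64)
    n, q = _counts_from_assignments(z, network.links, hyper.C, network.n_nodes)
    zn = rng.integers(0, hyper.C, size=network.n_nodes, dtype=np.int64)
    m = np.bincount(zn, minlength=hyper.C).astype(np.int64)
    np.add.at(q, (zn, np.arange(network.n_nodes)), 1)
    datasum = np.zeros((hyper.C, expression.n_conditions))
    np.add.at(datasum, zn, expression.values)
    return ModelState(z_links=z, n=n, q=q, rng=rng), ExpressionState(zn, m, datasum)


def gibbs_sweep_g2(
    link_state: ModelState,
    expr_state: ExpressionState,
    network: InteractionNetwork,
    expression: ExpressionMatrix,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
) -> None:
    """One full sweep: all links in index order, then all node data."""
    rng = link_state.rng
    u_links = rng.random(network.n_links)
    sweep_links(
        link_state.z_links,
        network.links[:, 0].copy(),
        network.links[:, 1].copy(),
        link_state.n,
        expr_state.m,
        link_state.q,
        float(hyper.alpha),
        float(hyper.beta),
        u_links,
    )
    u_nodes = rng.random(network.n_nodes)
    mu0_vec = np.full(expression.n_conditions, float(ehyper.mu0))
    sweep_nodes(
        expr_state.z_nodes,
        expression.values,
        link_state.n,
        expr_state.m,
        link_state.q,
        expr_state.datasum,
        float(hyper.alpha),
        float(hyper.beta),
        mu0_vec,
        float(ehyper.sigma0_sq),
        float(ehyper.sigma_sq),
        u_nodes,
    )


def joint_log_prob_g2(
    link_state: ModelState,
    expr_state: ExpressionState,
    network: InteractionNetwork,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
    values: np.ndarray,
) -> float:
    """Collapsed joint log-probability of links, node data and assignments.

    The component prior is a single Dirichlet-multinomial over the pooled
    ``N + M`` items; the node multinomials see ``2 n_z + m_z`` draws; the
    Gaussian arm contributes, per component and condition, the marginal
    likelihood of its assigned values under the conjugate mean prior.
    """
    a, b = hyper.alpha, hyper.beta
    C, M, N = hyper.C, network.n_nodes, network.n_links
    s0, s2 = ehyper.sigma0_sq, ehyper.sigma_sq
    n, m, q = link_state.n, expr_state.m, link_state.q
    totals = 2.0 * n + m
    lp = gammaln(C * a) - gammaln(N + M + C * a)
    lp += np.sum(gammaln(n + m + a)) - C * gammaln(a)
    lp += C * gammaln(M * b) - np.sum(gammaln(totals + M * b))
    lp += float(np.sum(gammaln(q + b))) - C * M * gammaln(b)
    # Gaussian marginal per component: integrate the component mean
    sumsq = np.zeros_like(expr_state.datasum)
    np.add.at(sumsq, expr_state.z_nodes, values**2)
    for c in range(C):
        mc = m[c]
        S = 1.0 / (1.0 / s0 + mc / s2)
        A = S * (ehyper.mu0 / s0 + expr_state.datasum[c] / s2)
        lp += np.sum(
            -0.5 * mc * np.log(2 * np.pi * s2)
            + 0.5 * np.log(S / s0)
            - sumsq[c] / (2 * s2)
            - ehyper.mu0**2 / (2 * s0)
            + A**2 / (2 * S)
        )
    return float(lp)


def run_chain_g2(
    network: InteractionNetwork,
    expression: ExpressionMatrix,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
    burn_in: int = DEFAULT_BURN_IN,
    n_samples: int = DEFAULT_N_SAMPLES,
    interval: int = DEFAULT_INTERVAL,
    seed: int | np.random.Generator = 0,
    log_every: int = 1000,
) -> list[tuple[ModelState, ExpressionState]]:
    """Collapsed Gibbs chain for the joint model; spaced (link, expr) samples."""
    if burn_in < 0 or n_samples < 1 or interval < 1:
        raise DataError("invalid chain schedule")
    link_state, expr_state = init_assignments_g2(network, expression, hyper, seed)
    samples: list[tuple[ModelState, ExpressionState]] = []
    total = burn_in + n_samples * interval
    for sweep in range(1, total + 1):
        gibbs_sweep_g2(link_state, expr_state, network, expression, hyper, ehyper)
        if sweep % log_every == 0 or sweep == total:
            logger.info(
                "sweep %d/%d log p = %.3f",
                sweep,
                total,
                joint_log_prob_g2(
                    link_state, expr_state, network, hyper, ehyper, expression.values
                ),
            )
        if sweep > burn_in and (sweep - burn_in) % interval == 0:
            samples.append((link_state.copy(), expr_state.copy()))
    return samples


def run_chain_g2_best(
    network: InteractionNetwork,
    expression: ExpressionMatrix,
    hyper: Hyperparameters,
    ehyper: ExpressionHyperparameters,
    burn_in: int = DEFAULT_BURN_IN,
    n_samples: int = DEFAULT_N_SAMPLES,
    interval: int = DEFAULT_INTERVAL,
    seed: int = 0,
    n_init: int = 5,
) -> list[tuple[ModelState, ExpressionState]]:
    """Best of ``n_init`` joint-model chains by mean collapsed joint log-prob.

    Same multi-restart convergence protocol as
    :func:`icmodels.core.run_chain_best`; see there for rationale.
    """
    ss = np.random.SeedSequence(seed)
    best: list[tuple[ModelState, ExpressionState]] | None = None
    best_lp = -np.inf
    for child in ss.spawn(n_init):
        samples = run_chain_g2(
            network, expression, hyper, ehyper,
            burn_in, n_samples, interval, np.random.default_rng(child),
        )
        lp = float(
            np.mean([
                joint_log_prob_g2(ls, es, network, hyper, ehyper, expression.values)
                for ls, es in samples
            ])
        )
        logger.info("restart chain mean log p = %.3f", lp)
        if lp > best_lp:
            best, best_lp = samples, lp
    assert best is not None
    return best


def node_memberships_g2(
    samples: list[tuple[ModelState, ExpressionState]], hyper: Hyperparameters
) -> np.ndarray:
    """p(z | i) for the joint model, averaged over samples.

    Same Bayes-rule estimate as the plain model with the pooled counts:
    ``p(i|z) = (q_zi + beta) / (2 n_z + m_z + M beta)`` and
    ``p(z) = (n_z + m_z + alpha) / (N + M + C alpha)``.
    """
    if not samples:
        raise DataError("empty sample list")
    link0, _ = samples[0]
    M = link0.q.shape[1]
    N = len(link0.z_links)
    out = np.zeros((M, hyper.C))
    for link_state, expr_state in samples:
        out += _membership_rows(
            link_state.n + expr_state.m.astype(float),
            link_state.q,
            N + M,
            hyper,
            2.0 * link_state.n + expr_state.m,
        )
    out /= len(samples)
    return out
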