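"""Planted overlapping-module benchmark networks and model-generated expression.

The network generator plants ``n_modules`` modules of ``nodes_per_module``
base nodes each.  Links appear independently with probability ``p_intra``
within a module and ``p_inter`` between modules.  Overlap is created by
arranging the modules in a ring and, for each adjacent pair, promoting
``n_shared_per_pair`` nodes of one module to members of both: every pair
involving a shared node and the neighbour module's base nodes is wired
with ``p_intra`` instead of ``p_inter``.  With the defaults this yields 10
modules of 10--12 member nodes and roughly 600 links.  Ground truth gives
shared nodes probability 0.5 in each of their two modules and all other
nodes probability 1 in theirs.

The expression generator follows the joint model's own generative process:
component means are drawn ``N(mu0, sigma0^2 I)``, each node picks a
component from its ground-truth membership row, and its profile is drawn
``N(mu_z, sigma^2 I)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from icmodels.exceptions import DataError
from icmodels.icmg2 import ExpressionHyperparameters, ExpressionMatrix
from icmodels.network import InteractionNetwork


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted overlapping-module network."""

    n_modules: int = 10
    nodes_per_module: int = 10
    p_intra: float = 0.9
    p_inter: float = 0.01
    n_shared_per_pair: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_inter <= self.p_intra <= 1):
            raise DataError("require 0 <= p_inter <= p_intra <= 1")
        if self.n_shared_per_pair >= self.nodes_per_module:
            raise DataError("n_shared_per_pair must be < nodes_per_module")
        if self.n_modules < 1 or self.nodes_per_module < 1:
            raise DataError("module counts must be positive")


def link_probability_matrix(design: PlantedDesign) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair link probabilities and ground-truth memberships for a design.

    Returns ``(P, truth)`` where ``P[i, j]`` is the independent link
    probability of the unordered pair (upper triangle is authoritative) and
    ``truth`` is the ``(M, C)`` ground-truth membership matrix.  Splitting
    this from the sampling step lets tests check link-count expectations in
    closed form.
    """
    K, n = design.n_modules, design.nodes_per_module
    M = K * n
    base = np.repeat(np.arange(K), n)
    truth = np.zeros((M, K))
    truth[np.arange(M), base] = 1.0
    # ring sharing: first n_shared nodes of module k also join module k+1
    second = np.full(M, -1)
    if design.n_shared_per_pair > 0 and K > 1:
        for k in range(K):
            neighbour = (k + 1) % K
            shared = np.arange(k * n, k * n + design.n_shared_per_pair)
            second[shared] = neighbour
            truth[shared, k] = 0.5
            truth[shared, neighbour] = 0.5
    P = np.full((M, M), design.p_inter)
    same = base[:, None] == base[None, :]
    P[same] = design.p_intra
    # shared node vs. its second module's base nodes
    for i in np.where(second >= 0)[0]:
        members = np.where(base == second[i])[0]
        P[i, members] = design.p_intra
        P[members, i] = design.p_intra
    np.fill_diagonal(P, 0.0)
    return P, truth


def generate_overlapping_network(
    design: PlantedDesign,
) -> tuple[InteractionNetwork, np.ndarray]:
    """Sample one planted network; returns it with its ground-truth memberships."""
    P, truth = link_probability_matrix(design)
    M = P.shape[0]
    rng = np.random.default_rng(design.seed)
    iu, ju = np.triu_indices(M, k=1)
    drawn = rng.random(iu.shape[0]) < P[iu, ju]
    links = np.stack([iu[drawn], ju[drawn]], axis=1)
    nodes = [f"g{idx:03d}" for idx in range(M)]
    network = InteractionNetwork(
        nodes=nodes,
        links=links,
        link_source=np.full(len(links), "ppi", dtype=object),
    )
    return network, truth


def generate_expression(
    memberships: np.ndarray,
    ehyper: ExpressionHyperparameters,
    n_conditions: int = 20,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Draw expression data from the joint model's generative process.

    Returns ``(expression, means, z)``: the sampled profiles, the drawn
    component means (``C x D``) and each node's drawn component -- the
    latter two for parameter-recovery tests.
    """
    memberships = np.asarray(memberships, dtype=float)
    if memberships.ndim != 2 or np.any(memberships < 0):
        raise DataError("invalid membership matrix")
    rng = np.random.default_rng(seed)
    M, C = memberships.shape
    means = ehyper.mu0 + np.sqrt(ehyper.sigma0_sq) * rng.standard_normal(
        (C, n_conditions)
    )
    z = np.array([rng.choice(C, p=row / row.sum()) for row in memberships])
    values = means[z] + np.sqrt(ehyper.sigma_sq) * rng.standard_normal(
        (M, n_conditions)
    )
    genes = node_names or [f"g{idx:03d}" for idx in range(M)]
    expr = ExpressionMatrix(
        genes=genes, values=values, missing_mask=np.zeros((M, n_conditions), bool)
    )
    return expr, means, z


def write_dataset(
    out_dir,
    network: InteractionNetwork,
    truth: np.ndarray,
    expression: ExpressionMatrix | None = None,
) -> None:
    """Write edge-list, ground-truth membership (and expression) TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "network.tsv", "w") as fh:
        for i, j in network.links:
            fh.write(f"{network.nodes[i]}\t{network.nodes[j]}\n")
    with open(out / "truth.tsv", "w") as fh:
        C = truth.shape[1]
        fh.write("gene\t" + "\t".join(f"module{c}" for c in range(C)) + "\n")
        for name, row in zip(network.nodes, truth):
            fh.write(name + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")
    if expression is not None:
        from icmodels.preprocessing import write_expression

        write_expression(expression, out / "expression.tsv")
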