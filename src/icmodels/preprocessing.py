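"""Data ingestion, imputation, dataset intersection and correlation links.

File dialects
-------------
* edge list: two tab-separated identifier columns per line, ``#`` comments
  allowed; duplicate lines for the same unordered pair collapse to one
  link; node order is first appearance.
* expression: TSV with a header row of condition names, first column gene
  identifier; ``NA`` or an empty field marks a missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from icmodels.exceptions import DataError
from icmodels.icmg2 import ExpressionMatrix
from icmodels.network import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class RawDatasetPair:
    """A network and an expression matrix over (possibly differing) genes."""

    network: InteractionNetwork
    expression: ExpressionMatrix


def read_edge_list(path) -> InteractionNetwork:
    """Read a two-column TSV edge list into an interaction network.

    ``(A, B)`` and ``(B, A)`` are the same link; repeated occurrences in the
    file collapse to a single link (input files are treated as simple
    graphs -- multigraph pooling happens downstream in :func:`pool_links`).
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    nodes: list[str] = []
    known: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise DataError(f"malformed edge list line {lineno}: {line!r}")
            a, b = parts
            for x in (a, b):
                if x not in known:
                    known.add(x)
                    nodes.append(x)
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                edges.append((a, b))
    if not nodes:
        raise DataError("empty network")
    return InteractionNetwork.from_edges(edges, nodes=nodes)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x conditions TSV (header row, gene ids in column one)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError("empty expression matrix")
    return ExpressionMatrix(genes=[str(g) for g in df.index], values=df.to_numpy())


def write_expression(expression: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(
        expression.values,
        index=expression.genes,
        columns=[f"cond{j}" for j in range(expression.n_conditions)],
    )
    df.mask(expression.missing_mask).to_csv(path, sep="\t", na_rep="NA")


def knn_impute(expression: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells by averaging the k nearest genes' values.

    For a gene with a missing value in condition ``d``, candidate neighbour
    genes are those observed in ``d``; they are ranked by Euclidean
    distance computed over the conditions both genes have observed
    (normalized per shared condition, so genes with different amounts of
    missingness are comparable), and the missing cell becomes the
    unweighted mean of the ``k`` nearest candidates' values in ``d``.
    Observed cells are never touched.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    values = expression.values.copy()
    mask = expression.missing_mask.copy()
    M = expression.n_genes
    all_missing = mask.all(axis=1)
    if all_missing.any():
        gene = expression.genes[int(np.where(all_missing)[0][0])]
        raise DataError(f"gene {gene!r} has no observed values")
    obs = ~mask
    filled = np.where(mask, 0.0, values)
    for g in np.where(mask.any(axis=1))[0]:
        # mean squared difference over mutually observed conditions
        shared = obs & obs[g]  # (M, D)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, filled - filled[g], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(n_shared > 0, (diff**2).sum(axis=1), np.inf)
                           / np.maximum(n_shared, 1))
        dist[g] = np.inf
        for d in np.where(mask[g])[0]:
            cand = np.where(obs[:, d] & np.isfinite(dist))[0]
            if cand.size == 0:
                raise DataError(
                    f"no neighbour with observed condition {d} for gene "
                    f"{expression.genes[g]!r}"
                )
            order = cand[np.argsort(dist[cand], kind="stable")]
            nearest = order[: min(k, order.size)]
            values[g, d] = values[nearest, d].mean()
    return ExpressionMatrix(
        genes=list(expression.genes),
        values=values,
        missing_mask=np.zeros_like(mask),
    )


def correlation_links(
    expression: ExpressionMatrix, cutoff: float = 0.85
) -> InteractionNetwork:
    """Link every gene pair whose Pearson correlation strictly exceeds ``cutoff``.

    Strongly negative correlations are ignored.  Pairs involving a
    zero-variance gene are skipped with a warning (their correlation is
    undefined).  Links are tagged ``source="expression"``.
    """
    if np.any(expression.missing_mask):
        raise DataError("impute missing values before computing correlations")
    values = expression.values
    std = values.std(axis=1)
    degenerate = np.where(std == 0)[0]
    for g in degenerate:
        logger.warning(
            "gene %r has zero variance; its correlations are undefined and skipped",
            expression.genes[g],
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    edges = []
    M = expression.n_genes
    for i in range(M):
        for j in range(i + 1, M):
            if std[i] == 0 or std[j] == 0:
                continue
            if corr[i, j] > cutoff:
                edges.append((expression.genes[i], expression.genes[j]))
    return InteractionNetwork.from_edges(
        edges,
        sources=["expression"] * len(edges),
        nodes=list(expression.genes),
    )


def pool_links(
    ppi: InteractionNetwork, expr_links: InteractionNetwork
) -> InteractionNetwork:
    """Multiset union of physical and expression links over a shared node set.

    A pair present in both sources contributes one link per source --
    the pooled link count is always the simple sum, and the duplicated
    pair carries double weight in the sampler.  Provenance tags are kept.
    """
    if set(expr_links.nodes) - set(ppi.nodes):
        raise DataError("expression-link nodes must be a subset of PPI nodes")
    index = ppi.node_index
    remapped = np.array(
        [[index[expr_links.nodes[i]], index[expr_links.nodes[j]]]
         for i, j in expr_links.links],
        dtype=np.int64,
    ).reshape(-1, 2)
    links = np.vstack([ppi.links, remapped])
    sources = np.concatenate([ppi.link_source, expr_links.link_source])
    return InteractionNetwork(nodes=list(ppi.nodes), links=links, link_source=sources)


def intersect_datasets(pair: RawDatasetPair) -> RawDatasetPair:
    """Restrict to genes having both an expression row and >= 1 link.

    Link removal can strand further genes, so the link condition is applied
    iteratively within the kept set until a fixed point.
    """
    expr_genes = set(pair.expression.genes)
    keep = [g for g in pair.network.nodes if g in expr_genes]
    while True:
        if not keep:
            raise DataError("empty intersection of network and expression genes")
        net = pair.network.subnetwork(keep)
        degree = np.zeros(net.n_nodes, dtype=int)
        for i, j in net.links:
            degree[i] += 1
            degree[j] += 1
        still = [g for g, d in zip(net.nodes, degree) if d > 0]
        if len(still) == len(keep):
            break
        keep = still
    order = {g: k for k, g in enumerate(pair.expression.genes)}
    rows = [order[g] for g in net.nodes]
    expr = ExpressionMatrix(
        genes=list(net.nodes),
        values=pair.expression.values[rows],
        missing_mask=pair.expression.missing_mask[rows],
    )
    return RawDatasetPair(network=net, expression=expr)
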