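"""Validation statistics: perplexity, GO classes, enrichment, complex coverage
and membership distances against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from icmodels.exceptions import DataError

#: Default enrichment p-value grid, 1e-1 down to 1e-10.
DEFAULT_P_GRID = tuple(10.0**-k for k in range(1, 11))


# ---------------------------------------------------------------------------
# confusion matrix + perplexity


def confusion_from_clusters(
    clusters: dict[str, int], classes: dict[str, int | str]
) -> np.ndarray:
    """Frequency table with model clusters as rows and known classes as columns.

    Only genes present in both maps are counted.
    """
    genes = [g for g in clusters if g in classes]
    if not genes:
        raise DataError("no genes shared between clusters and classes")
    df = pd.DataFrame(
        {"m": [clusters[g] for g in genes], "c": [classes[g] for g in genes]}
    )
    return pd.crosstab(df["m"], df["c"]).to_numpy()


def perplexity(confusion: np.ndarray) -> float:
    """exp of the mean negative log p(class | cluster) over all samples.

    ``p(c|m)`` are the empirical row-normalized frequencies of the
    confusion matrix; every sample sits in its own cell so its conditional
    probability is strictly positive.  Bounded by 1 (class-pure clusters)
    and the number of classes (rows uniform over all classes).
    """
    confusion = np.asarray(confusion, dtype=float)
    if np.any(confusion < 0):
        raise DataError("negative confusion counts")
    N = confusion.sum()
    if N == 0:
        raise DataError("empty confusion matrix")
    row_totals = confusion.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = confusion / row_totals
        cell_ll = np.where(confusion > 0, confusion * np.log(p), 0.0)
    return float(np.exp(-cell_ll.sum() / N))


# ---------------------------------------------------------------------------
# GO standard classes


@dataclass
class AnnotationSet:
    """Gene-term annotations plus the term DAG.

    ``gene_terms`` maps gene -> set of annotated terms (assumed already
    propagated up the hierarchy, i.e. the transitive is-a/part-of closure);
    ``dag_edges`` are (parent, child) term pairs.
    """

    gene_terms: dict[str, set[str]]
    dag_edges: list[tuple[str, str]]
    _graph: nx.DiGraph = field(default=None, repr=False)  # type: ignore[assignment]

    def graph(self) -> nx.DiGraph:
        if self._graph is None:
            g = nx.DiGraph()
            g.add_edges_from(self.dag_edges)
            if not nx.is_directed_acyclic_graph(g):
                raise DataError("annotation term graph is not acyclic")
            self._graph = g
        return self._graph

    def term_genes(self, universe: set[str]) -> dict[str, set[str]]:
        """Genes of the universe annotated to each term."""
        out: dict[str, set[str]] = {t: set() for t in self.graph().nodes}
        for gene, terms in self.gene_terms.items():
            if gene in universe:
                for t in terms:
                    out.setdefault(t, set()).add(gene)
        return out

    @classmethod
    def from_tables(cls, annotation_df: pd.DataFrame, dag_df: pd.DataFrame):
        """Build from two-column (gene, term) and (parent, child) tables."""
        gene_terms: dict[str, set[str]] = {}
        for gene, term in annotation_df.itertuples(index=False):
            gene_terms.setdefault(str(gene), set()).add(str(term))
        edges = [(str(p), str(c)) for p, c in dag_df.itertuples(index=False)]
        return cls(gene_terms=gene_terms, dag_edges=edges)


def derive_standard_classes(
    annotations: AnnotationSet,
    gene_universe: set[str],
    cutoff: int,
    max_size: int = 300,
) -> dict[str, set[str]]:
    """Derive fixed evaluation classes from the term DAG by size cutoff.

    Starting from the root(s) and descending parent to child, annotation
    counts (restricted to ``gene_universe``) shrink; when a child's count
    falls below ``cutoff`` the traversal stops there and the parent is
    emitted as a class.  A term at or above the cutoff whose children are
    all below it (or that has no children) is therefore its branch's
    frontier and emits itself.  Classes covering more than ``max_size``
    universe genes are omitted; duplicates collapse.  Children are visited
    in lexicographic order, making the traversal deterministic.

    Returns ``{class term: genes of the universe annotated to it}``.
    """
    g = annotations.graph()
    counts = {t: len(genes) for t, genes in annotations.term_genes(gene_universe).items()}
    roots = sorted(t for t in g.nodes if g.in_degree(t) == 0)
    emitted: set[str] = set()
    visited: set[str] = set()
    stack = [r for r in reversed(roots) if counts.get(r, 0) >= cutoff]
    while stack:
        term = stack.pop()
        if term in visited:
            continue
        visited.add(term)
        children = sorted(g.successors(term))
        frontier = True
        for child in reversed(children):
            if counts.get(child, 0) >= cutoff:
                frontier = False
                stack.append(child)
            else:
                # descent dips below the cutoff here: the parent is a class
                emitted.add(term)
        if frontier:
            emitted.add(term)
    term_genes = annotations.term_genes(gene_universe)
    return {
        t: term_genes[t]
        for t in sorted(emitted)
        if counts.get(t, 0) <= max_size
    }


def crisp_class_map(classes: dict[str, set[str]]) -> dict[str, str]:
    """Assign each gene its (lexicographically first) smallest class.

    Utility for perplexity evaluation, which needs one class per gene.
    """
    out: dict[str, str] = {}
    for term in sorted(classes, key=lambda t: (len(classes[t]), t)):
        for gene in classes[term]:
            out.setdefault(gene, term)
    return out


# ---------------------------------------------------------------------------
# enrichment


def enrichment_counts(
    clusters: dict[str, int],
    classes: dict[str, set[str]],
    p_grid: tuple[float, ...] = DEFAULT_P_GRID,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Modules and classes enriched at each p-value cutoff.

    For every (module, class) pair a one-sided hypergeometric upper-tail
    p-value (Fisher exact) is computed over the clustered-gene universe.
    For each cutoff in ``p_grid`` the returned frame counts modules with at
    least one class enriched (p <= cutoff) and classes enriched in at
    least one module.  No multiple-testing correction by default -- the
    cutoff sweep plays that role; ``bh_correct`` applies Benjamini-Hochberg
    across all pairs first.
    """
    if not clusters:
        raise DataError("empty clustering")
    universe = set(clusters)
    G = len(universe)
    module_genes: dict[int, set[str]] = {}
    for gene, mod in clusters.items():
        module_genes.setdefault(mod, set()).add(gene)
    pvals = []
    pairs = []
    for mod, mgenes in module_genes.items():
        for term, tgenes in classes.items():
            tg = tgenes & universe
            k = len(mgenes & tg)
            p = float(hypergeom.sf(k - 1, G, len(tg), len(mgenes))) if k else 1.0
            pvals.append(p)
            pairs.append((mod, term))
    pvals_arr = np.array(pvals)
    if bh_correct and len(pvals_arr):
        from statsmodels.stats.multitest import multipletests

        pvals_arr = multipletests(pvals_arr, method="fdr_bh")[1]
    rows = []
    for cutoff in p_grid:
        hit = pvals_arr <= cutoff
        mods = {pairs[i][0] for i in np.where(hit)[0]}
        terms = {pairs[i][1] for i in np.where(hit)[0]}
        rows.append(
            {"cutoff": cutoff, "enriched_modules": len(mods), "enriched_classes": len(terms)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein complexes


def complex_coverage(
    clusters: dict[str, int],
    catalog: dict[str, set[str]],
    min_size: int = 2,
    bins: np.ndarray | None = None,
) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """Per-complex best-module coverage and its histogram.

    A complex is first restricted to proteins present in the clustered
    universe and kept if at least ``min_size`` remain.  Its coverage is the
    largest fraction of those proteins captured by any single module.
    Returns ``(coverages, histogram, bin_edges)``; default bins are ten
    equal-width bins over (0, 1].
    """
    universe = set(clusters)
    module_genes: dict[int, set[str]] = {}
    for gene, mod in clusters.items():
        module_genes.setdefault(mod, set()).add(gene)
    coverages = {}
    for cid, members in catalog.items():
        present = members & universe
        if len(present) < min_size:
            continue
        best = max(len(present & m) for m in module_genes.values())
        coverages[cid] = best / len(present)
    cov = pd.Series(coverages, dtype=float).sort_index()
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    hist, edges = np.histogram(cov.to_numpy(), bins=bins)
    return cov, hist, edges


# ---------------------------------------------------------------------------
# membership distances against planted truth


def align_components(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute estimated components to best match truth components.

    Maximum-agreement matching: the score of pairing estimated component k
    with truth component c is the dot product of their membership columns
    over nodes; the Hungarian algorithm finds the best one-to-one matching.
    Returns the column-permuted estimate.  Needed because Euclidean
    membership distance is not invariant to component relabeling.
    """
    estimated = np.asarray(estimated, float)
    truth = np.asarray(truth, float)
    if estimated.shape != truth.shape:
        raise DataError("estimate and truth must have identical shapes")
    score = estimated.T @ truth  # (C, C)
    row, col = linear_sum_assignment(-score)
    perm = np.empty(truth.shape[1], dtype=int)
    perm[col] = row
    return estimated[:, perm]


def membership_distance(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-node Euclidean distance to ground-truth membership rows.

    Estimated components are first aligned to truth components
    (:func:`align_components`); the statistic is the mean over nodes of
    ``||estimated_row - truth_row||_2``.
    """
    aligned = align_components(estimated, truth)
    per_node = np.linalg.norm(aligned - truth, axis=1)
    return float(per_node.mean())


def binarize_memberships(memberships: np.ndarray) -> np.ndarray:
    """Replace each row by the indicator of its most probable component.

    Ties break to the lowest component index; rows still sum to 1.
    """
    memberships = np.asarray(memberships, float)
    out = np.zeros_like(memberships)
    out[np.arange(memberships.shape[0]), memberships.argmax(axis=1)] = 1.0
    return out


def recovery_fraction(
    clusters: np.ndarray,
    truth: np.ndarray,
    nodes: np.ndarray | None = None,
) -> float:
    """Fraction of nodes whose crisp cluster matches a planted module.

    Cluster labels are aligned to truth components by maximum-agreement
    matching on the crisp indicator matrix; a node counts as recovered if
    its aligned cluster has positive ground-truth membership (so a node
    shared between two modules is recovered by either).  ``nodes``
    restricts the evaluation, e.g. to non-shared nodes.
    """
    clusters = np.asarray(clusters)
    C = truth.shape[1]
    if clusters.max() >= C:
        raise DataError("cluster label exceeds number of truth components")
    indicator = np.zeros((len(clusters), C))
    indicator[np.arange(len(clusters)), clusters] = 1.0
    aligned = align_components(indicator, truth)
    hit = (aligned * (truth > 0)).sum(axis=1) > 0
    if nodes is not None:
        hit = hit[np.asarray(nodes)]
    return float(hit.mean())
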