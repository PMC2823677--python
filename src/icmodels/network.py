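"""Undirected interaction networks stored as node-indexed link lists.

The model operates on a *multigraph*: the same unordered node pair may
occur several times (e.g. once as a physical interaction and once as an
expression-correlation link), and each occurrence is a separate datum for
the sampler.  Links are canonicalized to ``i <= j``; ``(i, j)`` and
``(j, i)`` denote the same link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from icmodels.exceptions import DataError

#: Allowed provenance tags for links.
LINK_SOURCES = ("ppi", "expression")


@dataclass
class InteractionNetwork:
    """An undirected multigraph of interaction links.

    Parameters
    ----------
    nodes
        Ordered unique node identifiers; index into this list is the node
        index used everywhere else.
    links
        ``(N, 2)`` integer array of node-index pairs, canonicalized so that
        ``links[l, 0] <= links[l, 1]``.  Self-links are permitted.
    link_source
        Length-``N`` provenance tag per link (``"ppi"`` or ``"expression"``);
        informational only -- the model treats all links identically.
    """

    nodes: list[str]
    links: np.ndarray
    link_source: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise DataError("empty network")
        if len(set(self.nodes)) != len(self.nodes):
            raise DataError("node identifiers must be unique")
        self.links = np.asarray(self.links, dtype=np.int64).reshape(-1, 2)
        # canonical storage i <= j
        self.links = np.sort(self.links, axis=1)
        if self.links.size and (
            self.links.min() < 0 or self.links.max() >= len(self.nodes)
        ):
            raise DataError("link endpoint index out of range")
        if self.link_source is None:
            self.link_source = np.full(len(self.links), "ppi", dtype=object)
        else:
            self.link_source = np.asarray(self.link_source, dtype=object)
            if len(self.link_source) != len(self.links):
                raise DataError("link_source length must match number of links")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def node_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.nodes)}

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        sources: list[str] | None = None,
        nodes: list[str] | None = None,
    ) -> "InteractionNetwork":
        """Build a network from identifier pairs.

        Node order is first appearance in ``edges`` unless an explicit
        ``nodes`` list is given (which may include isolated nodes).
        """
        if nodes is None:
            nodes = []
            seen: dict[str, int] = {}
            for a, b in edges:
                for x in (a, b):
                    if x not in seen:
                        seen[x] = len(nodes)
                        nodes.append(x)
        index = {name: i for i, name in enumerate(nodes)}
        try:
            links = np.array(
                [[index[a], index[b]] for a, b in edges], dtype=np.int64
            ).reshape(-1, 2)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataError(f"edge references unknown node {exc}") from exc
        src = None if sources is None else np.asarray(sources, dtype=object)
        return cls(nodes=list(nodes), links=links, link_source=src)

    def subnetwork(self, keep: list[str]) -> "InteractionNetwork":
        """Restrict to ``keep`` nodes, dropping links with a removed endpoint."""
        keep_set = set(keep)
        new_nodes = [n for n in self.nodes if n in keep_set]
        if not new_nodes:
            raise DataError("empty network")
        remap = {self.node_index[n]: k for k, n in enumerate(new_nodes)}
        rows, srcs = [], []
        for (i, j), s in zip(self.links, self.link_source):
            if i in remap and j in remap:
                rows.append([remap[i], remap[j]])
                srcs.append(s)
        return InteractionNetwork(
            nodes=new_nodes,
            links=np.array(rows, dtype=np.int64).reshape(-1, 2),
            link_source=np.asarray(srcs, dtype=object),
        )
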