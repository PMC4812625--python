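"""Network clustering with a pluggable strategy.

The default strategy is the map-equation (InfoMap) community detection
method, which determines the number of clusters itself, produces disjoint
clusters, and is run for a configurable number of optimization trials
(default 1000).  Any strategy registered in :data:`STRATEGIES` can stand in
for it; connected components double as a deterministic fallback and as a
test oracle.  Degree-0 nodes always end up in their own size-1 clusters.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import igraph

from .network import SimilarityNetwork

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 1000


@dataclass(frozen=True)
class Clustering:
    """Disjoint partition of network nodes into labeled clusters.

    Labels are contiguous integers starting at 1, assigned in order of
    first appearance along the node order.
    """

    assignment: dict[str, int]
    method: str
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out


def _relabel(nodes: tuple[str, ...], raw: list[int]) -> dict[str, int]:
    mapping: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for node, label in zip(nodes, raw):
        if label not in mapping:
            mapping[label] = len(mapping) + 1
        assignment[node] = mapping[label]
    return assignment


def _igraph_of(net: SimilarityNetwork) -> igraph.Graph:
    index = {v: k for k, v in enumerate(net.nodes)}
    g = igraph.Graph(n=len(net.nodes))
    g.add_edges([(index[a], index[b]) for a, b in net.edges])
    return g


def _infomap(net: SimilarityNetwork, iterations: int, seed: int) -> list[int]:
    g = _igraph_of(net)
    igraph.set_random_number_generator(random.Random(seed))
    try:
        membership = g.community_infomap(trials=iterations).membership
    finally:
        igraph.set_random_number_generator(random)
    return membership


def _components(net: SimilarityNetwork, iterations: int, seed: int) -> list[int]:
    return _igraph_of(net).connected_components().membership


StrategyFn = Callable[[SimilarityNetwork, int, int], list[int]]

STRATEGIES: dict[str, StrategyFn] = {
    "infomap": _infomap,
    "components": _components,
}


def cluster(
    net: SimilarityNetwork,
    method: str = "infomap",
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> Clustering:
    """Partition the network; deterministic given (net, method, iterations, seed)."""
    if method not in STRATEGIES:
        raise ValueError(f"unknown clustering method {method!r}; registered: {sorted(STRATEGIES)}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    raw = STRATEGIES[method](net, iterations, seed)
    return Clustering(assignment=_relabel(net.nodes, raw), method=method, seed=seed)


def connected_components(net: SimilarityNetwork) -> Clustering:
    """Connected components as a clustering; singletons are size-1 components."""
    raw = _components(net, 1, 0)
    return Clustering(assignment=_relabel(net.nodes, raw), method="components", seed=None)


def write_clustering(clustering: Clustering, path: str | Path, header: tuple[str, ...] = ()) -> None:
    """TSV ``molecule_id<TAB>cluster_label``."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for node, label in clustering.assignment.items():
            fh.write(f"{node}\t{label}\n")


def read_clustering(path: str | Path, method: str = "file") -> Clustering:
    """Read an assignment TSV, validating the partition property."""
    assignment: dict[str, int] = {}
    order: list[str] = []
    raw: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            node, label = line.split("\t")
            if node in assignment:
                raise ValueError(f"{path}: molecule {node!r} assigned twice")
            assignment[node] = int(label)
            order.append(node)
            raw.append(int(label))
    return Clustering(assignment=_relabel(tuple(order), raw), method=method, seed=None)
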