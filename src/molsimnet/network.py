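"""Threshold networks, clustering coefficients and the ACC(t) scan.

Applying a threshold t to a similarity matrix keeps an edge for every pair
with s_ij >= t; molecules whose similarities all fall below t remain as
degree-0 singleton nodes.  The clustering coefficient CC(i) of a node is
the fraction of realized edges among its neighbors (0 by definition for
degree <= 1); the average clustering coefficient ACC is the mean CC over
nodes of positive degree, 0 for an edgeless network.

Scanning a threshold grid produces ACC(t) and the edge count EN(t).  The
recommended clustering threshold t_alpha is the maximum of the ACC(t) peak
that spans the widest threshold range -- explicitly not the trivial
maximum at t = 0, where the network is complete and ACC = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from .similarity import SparseSimilarityMatrix


class NoPeakError(RuntimeError):
    """Raised when the ACC(t) curve has no interior maximum."""


@dataclass
class SimilarityNetwork:
    """Unweighted undirected graph derived from a similarity matrix at t.

    All molecules of the generating matrix are nodes regardless of t; edges
    are unordered id pairs (stored with the first id earlier in node order).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    threshold: float
    _adj: dict[str, set[str]] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {v: set() for v in self.nodes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    def singletons(self) -> list[str]:
        return [v for v in self.nodes if not self.adjacency[v]]


def apply_threshold(matrix: SparseSimilarityMatrix, t: float) -> SimilarityNetwork:
    """Binarize the matrix at t (inclusive >=) into a similarity network."""
    if t < matrix.t_store:
        raise ValueError(
            f"threshold below storage floor: {t} < {matrix.t_store}; "
            "pairs under the floor are unknowable"
        )
    edges = frozenset(pair for pair, s in matrix.entries.items() if s >= t)
    return SimilarityNetwork(nodes=matrix.ids, edges=edges, threshold=t)


def edge_count(net: SimilarityNetwork) -> int:
    return len(net.edges)


def clustering_coefficient(net: SimilarityNetwork, node: str) -> float:
    """Fraction of realized edges among the neighbors of ``node``.

    0 by definition for degree 0 or 1.
    """
    adj = net.adjacency
    if node not in adj:
        raise KeyError(f"unknown node {node!r}")
    return _node_cc(adj, node)


def _node_cc(adj: dict[str, set[str]], node: str) -> float:
    neighbors = adj[node]
    deg = len(neighbors)
    if deg < 2:
        return 0.0
    # each edge among neighbors is seen from both endpoints
    links2 = sum(len(adj[v] & neighbors) for v in neighbors)
    return links2 / (deg * (deg - 1))


def average_clustering_coefficient(net: SimilarityNetwork) -> float:
    """Mean CC over nodes of degree > 0; 0 when every node is a singleton."""
    return _acc_from_adj(net.adjacency)


def _acc_from_adj(adj: dict[str, set[str]]) -> float:
    connected = [v for v, nb in adj.items() if nb]
    if not connected:
        return 0.0
    return sum(_node_cc(adj, v) for v in connected) / len(connected)


@dataclass
class ThresholdScan:
    """ACC, edge count and singleton count over a strictly increasing grid."""

    grid: list[float]
    acc: list[float]
    en: list[int]
    singletons: list[int]


@dataclass(frozen=True)
class PeakResult:
    """The selected threshold t_alpha and its enclosing peak interval."""

    t_alpha: float
    peak_lo: float
    peak_hi: float
    acc_at_alpha: float


def threshold_grid(t_min: float, t_max: float, step: float) -> list[float]:
    """Grid t_min, t_min+step, ... generated by integer index to avoid drift.

    ``t_max`` is appended when not hit exactly.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if not 0.0 <= t_min <= t_max <= 1.0:
        raise ValueError(f"need 0 <= t_min <= t_max <= 1, got [{t_min}, {t_max}]")
    lo, hi, st = Fraction(str(t_min)), Fraction(str(t_max)), Fraction(str(step))
    grid: list[Fraction] = []
    k = 0
    while lo + k * st <= hi:
        grid.append(lo + k * st)
        k += 1
    if not grid or grid[-1] != hi:
        grid.append(hi)
    return [float(t) for t in grid]


def scan(
    matrix: SparseSimilarityMatrix,
    t_min: float = 0.0,
    t_max: float = 1.0,
    step: float = 0.01,
) -> ThresholdScan:
    """Compute ACC(t), EN(t) and the singleton count over a threshold grid.

    Edges are sorted by similarity once and each network is the suffix of
    pairs with s_ij >= t; by edge nesting this equals rebuilding the network
    from scratch at every t, and EN(t) is non-increasing along the grid.
    """
    if t_min < matrix.t_store:
        raise ValueError(
            f"t_min below storage floor: {t_min} < {matrix.t_store}"
        )
    grid = threshold_grid(t_min, t_max, step)
    ordered = sorted(matrix.entries.items(), key=lambda kv: kv[1])
    adj: dict[str, set[str]] = {v: set() for v in matrix.ids}
    for (a, b), s in ordered:
        if s >= t_min:
            adj[a].add(b)
            adj[b].add(a)
    n_edges = sum(1 for _, s in ordered if s >= t_min)
    ptr = 0
    n = len(ordered)
    accs: list[float] = []
    ens: list[int] = []
    sing: list[int] = []
    for t in grid:
        while ptr < n and ordered[ptr][1] < t:
            (a, b), s = ordered[ptr]
            if s >= t_min:  # edges below t_min were never added
                adj[a].discard(b)
                adj[b].discard(a)
                n_edges -= 1
            ptr += 1
        accs.append(_acc_from_adj(adj))
        ens.append(n_edges)
        sing.append(sum(1 for nb in adj.values() if not nb))
    return ThresholdScan(grid=grid, acc=accs, en=ens, singletons=sing)


def find_t_alpha(scan_result: ThresholdScan, epsilon: float = 0.01) -> PeakResult:
    """Select t_alpha at the widest peak of the ACC(t) curve.

    Procedure: (a) discard the leading plateau where ACC sticks at its
    initial value (this removes the trivial complete-network maximum);
    (b) locate local maxima on the remainder, flat runs counting once;
    (c) drop maxima whose topographic prominence is below ``epsilon`` --
    they are bumps riding on an enclosing peak; (d) bound each surviving
    peak by the minima separating it from its neighbors (or the region
    boundary) and measure its threshold span; (e) return the argmax of ACC
    inside the widest peak, preferring the smallest t on ties.
    """
    acc = list(scan_result.acc)
    ts = scan_result.grid
    if len(acc) < 3:
        raise ValueError("scan needs at least 3 grid points")
    start = next((i for i, a in enumerate(acc) if a != acc[0]), None)
    if start is None:
        raise NoPeakError("ACC is constant over the whole grid; no peak found")
    # edge sets are nested as t rises, so a triangle-free network stays
    # triangle-free: once ACC reaches 0 it is 0 for every larger t.  The
    # trailing zero run (singleton-dominated networks) is truncated to its
    # first point, mirroring the leading-plateau discard, so that no peak
    # inflates its span across structureless thresholds.
    end = len(acc) - 1
    while end > start and acc[end] == 0.0 and acc[end - 1] == 0.0:
        end -= 1
    sub = acc[start : end + 1]

    # compress into runs of equal value: (value, first_idx, last_idx)
    runs: list[tuple[float, int, int]] = []
    for i, a in enumerate(sub):
        if runs and runs[-1][0] == a:
            runs[-1] = (a, runs[-1][1], i)
        else:
            runs.append((a, i, i))

    # local maxima over the runs; the discarded plateau acts as the virtual
    # left neighbor of the first run, so a pure decline yields no maximum
    maxima: list[int] = []
    for r, (value, _, _) in enumerate(runs):
        left = acc[start - 1] if r == 0 else runs[r - 1][0]
        higher_left = value > left
        higher_right = r == len(runs) - 1 or value > runs[r + 1][0]
        if higher_left and higher_right:
            maxima.append(r)
    if not maxima:
        raise NoPeakError("no interior ACC maximum; ACC has no peak")

    def run_argmin(r_lo: int, r_hi: int) -> tuple[float, int]:
        """(min value, grid index of its first occurrence) between two runs."""
        best = min(runs[r][0] for r in range(r_lo, r_hi + 1))
        for r in range(r_lo, r_hi + 1):
            if runs[r][0] == best:
                return best, runs[r][1]
        raise AssertionError("unreachable")

    seps = [
        run_argmin(maxima[k] + 1, maxima[k + 1] - 1) for k in range(len(maxima) - 1)
    ]

    # merge maxima of insufficient prominence into their enclosing peak:
    # prominence is measured against the higher adjacent separating minimum
    while len(maxima) > 1:
        proms = []
        for k, r in enumerate(maxima):
            adjacent = []
            if k > 0:
                adjacent.append(seps[k - 1][0])
            if k < len(maxima) - 1:
                adjacent.append(seps[k][0])
            proms.append(runs[r][0] - max(adjacent))
        weakest = min(range(len(maxima)), key=lambda k: (proms[k], runs[maxima[k]][0], -k))
        if proms[weakest] >= epsilon:
            break
        if weakest == 0:
            del seps[0]
        elif weakest == len(maxima) - 1:
            del seps[-1]
        else:  # remove the higher separating minimum toward the absorbed side
            del seps[weakest - 1 if seps[weakest - 1][0] >= seps[weakest][0] else weakest]
        del maxima[weakest]

    # peak intervals between separating minima (or the region boundary)
    bounds = []
    for k in range(len(maxima)):
        lo = 0 if k == 0 else seps[k - 1][1]
        hi = len(sub) - 1 if k == len(maxima) - 1 else seps[k][1]
        bounds.append((lo, hi))
    spans = [ts[start + hi] - ts[start + lo] for lo, hi in bounds]
    best = max(range(len(bounds)), key=lambda k: spans[k])
    lo, hi = bounds[best]
    window = sub[lo : hi + 1]
    inner = window.index(max(window))  # first occurrence = smallest t
    idx = start + lo + inner
    return PeakResult(
        t_alpha=ts[idx],
        peak_lo=ts[start + lo],
        peak_hi=ts[start + hi],
        acc_at_alpha=float(acc[idx]),
    )


def write_network(
    net: SimilarityNetwork, edge_path: str | Path, node_path: str | Path
) -> None:
    """Edge-list plus node-list files; the node list preserves singletons."""
    with open(edge_path, "w") as fh:
        fh.write(f"# t={net.threshold}\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
    with open(node_path, "w") as fh:
        for v in net.nodes:
            fh.write(f"{v}\n")


def write_scan(scan_result: ThresholdScan, path: str | Path, header: Iterable[str] = ()) -> None:
    """TSV ``t<TAB>ACC<TAB>EN<TAB>singletons``."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("t\tACC\tEN\tsingletons\n")
        for t, a, e, s in zip(
            scan_result.grid, scan_result.acc, scan_result.en, scan_result.singletons
        ):
            fh.write(f"{t:.6g}\t{a:.12g}\t{e}\t{s}\n")
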