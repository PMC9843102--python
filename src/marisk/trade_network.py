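"""Directed trade network construction and weighted PageRank centrality.

Each country links to the partners whose LSBCI ties into its top-k
eligible values (default k = 3); exact ties at the k-th value are all
included, so out-degree can exceed k.  An optional maximum-days cutoff
(default use case: the ~14-day window *An. stephensi* eggs survive
desiccation) restricts the *eligible* partner set before top-k
selection, so a country may link to its 4th-best partner when its top
three are beyond the cutoff.  Zero-LSBCI pairs are never eligible: an
edge of weight zero carries no flow.

PageRank is computed by power iteration on the weighted transition
matrix — from node v, an edge (v -> u) is followed with probability
weight(v -> u) / sum of v's out-weights; dangling nodes redistribute
uniformly over all nodes; damping d teleports with probability 1 - d.
The result is a probability distribution over countries: the long-run
chance that a randomly drifting vessel is found at a given port.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .data_io import SymmetricMatrix

__all__ = [
    "TradeNetwork",
    "CentralityResult",
    "build_network",
    "pagerank",
    "top_partners",
    "rank_centrality",
]


@dataclass
class TradeNetwork:
    """Directed weighted graph over country codes.

    ``edges`` maps (origin, partner) -> LSBCI weight in (0, 1].
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    k: int
    max_days: float | None = None
    sources: frozenset[str] = frozenset()
    pagerank_scores: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self):
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"self-loop edge on {u}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def out_edges(self, node: str) -> list[tuple[str, float]]:
        return [(v, w) for (u, v), w in self.edges.items() if u == node]

    def in_degree(self, node: str) -> int:
        return sum(1 for (_, v) in self.edges if v == node)

    def __contains__(self, node: str) -> bool:
        return node in self.nodes


@dataclass(frozen=True)
class CentralityResult:
    """PageRank vector with the parameters it was computed under."""

    scores: dict[str, float]
    damping: float
    iterations: int
    converged: bool


def build_network(
    conn: SymmetricMatrix,
    k: int = 3,
    max_days: float | None = None,
    times: SymmetricMatrix | None = None,
    sources: Iterable[str] = (),
) -> TradeNetwork:
    """Build the directed top-k trade network from pairwise LSBCI.

    Parameters
    ----------
    conn
        Symmetric LSBCI matrix; zero or absent pairs are ineligible.
    k
        Each node links to all partners tying into its k largest
        eligible LSBCI values.
    max_days, times
        When ``max_days`` is set, partners farther than ``max_days``
        (or missing from ``times``) are removed from the eligible set
        *before* top-k selection; ``times`` is then required.
    sources
        Country codes flagged as established source populations.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if max_days is not None:
        if max_days <= 0:
            raise ValueError(f"max_days must be > 0, got {max_days}")
        if times is None:
            raise ValueError("max_days set but no transit-time table supplied")
    nodes = tuple(conn.countries())
    if not nodes:
        raise ValueError("empty connectivity matrix")
    sources = frozenset(sources)
    edges: dict[tuple[str, str], float] = {}
    for u in nodes:
        eligible: list[tuple[str, float]] = []
        for v in nodes:
            if v == u:
                continue
            w = conn.get(u, v)
            if w is None or w <= 0:
                continue
            if max_days is not None:
                d = times.get(u, v)
                if d is None or d > max_days:
                    continue
            eligible.append((v, w))
        if not eligible:
            continue
        weights = sorted((w for _, w in eligible), reverse=True)
        kth = weights[min(k, len(weights)) - 1]
        for v, w in eligible:
            if w >= kth:
                edges[(u, v)] = w
    return TradeNetwork(nodes=nodes, edges=edges, k=k, max_days=max_days, sources=sources)


def pagerank(
    net: TradeNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityResult:
    """Weighted directed PageRank by power iteration.

    Iterates ``pr = (1 - d)/n + d * (P^T pr + dangling mass / n)`` until
    the L1 change drops below ``tol``.  The returned scores sum to 1 and
    every score is at least ``(1 - d)/n``.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0,1), got {damping}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    nodes = net.nodes
    n = net.n
    if n == 0:
        raise ValueError("empty network")
    idx = {c: i for i, c in enumerate(nodes)}
    # Row-normalized transition matrix (dense: country networks are small).
    P = np.zeros((n, n))
    for (u, v), w in net.edges.items():
        P[idx[u], idx[v]] = w
    out = P.sum(axis=1)
    dangling = out == 0
    P[~dangling] /= out[~dangling, None]

    pr = np.full(n, 1.0 / n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dangling_mass = pr[dangling].sum()
        new = (1.0 - damping) / n + damping * (P.T @ pr + dangling_mass / n)
        if np.abs(new - pr).sum() < tol:
            pr = new
            converged = True
            break
        pr = new
    pr = pr / pr.sum()  # remove residual drift; the contract is a distribution
    return CentralityResult(
        scores={c: float(pr[idx[c]]) for c in nodes},
        damping=damping,
        iterations=iterations,
        converged=converged,
    )


def top_partners(net: TradeNetwork, country: str) -> list[tuple[str, float]]:
    """A country's out-neighbors by descending edge weight.

    This is the actionable surveillance list: if the vector is detected
    in ``country``, these are its strongest onward maritime links.
    """
    if country not in net:
        raise KeyError(f"unknown country: {country}")
    return sorted(net.out_edges(country), key=lambda t: (-t[1], t[0]))


def rank_centrality(result: CentralityResult) -> list[tuple[str, float, int]]:
    """Order countries by PageRank descending (alphabetical on exact ties)."""
    ordered = sorted(result.scores.items(), key=lambda t: (-t[1], t[0]))
    return [(c, v, i + 1) for i, (c, v) in enumerate(ordered)]
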