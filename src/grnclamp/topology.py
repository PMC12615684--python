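"""Signed directed GRN topologies: parsing, validation, interaction matrix,
and group betweenness centrality.

A topology is a signed directed graph over gene names.  The on-disk format is
the ``.topo`` dialect used throughout the RACIPE ecosystem: an optional header
``Source Target Type`` followed by whitespace-separated rows, with Type 1 for
activation and 2 for inhibition.  Node indices are assigned by first
appearance in the file and define the coordinate system for every interaction
matrix, spin state and expression vector downstream.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Topology",
    "NodeAnnotation",
    "TopoParseError",
    "read_topo",
    "write_topo",
    "read_annotation",
    "write_annotation",
    "interaction_matrix",
    "group_betweenness",
]


class TopoParseError(ValueError):
    """Raised when a ``.topo`` or annotation file cannot be parsed."""


@dataclass(frozen=True)
class Topology:
    """A signed directed gene regulatory network.

    Parameters
    ----------
    nodes
        Unique gene names in a stable order; position defines the integer
        index used by all matrices and state vectors.
    edges
        ``(source, target, sign)`` triples with sign +1 (activation) or
        -1 (inhibition).  At most one edge per ordered (source, target) pair.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        known = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign in self.edges:
            if src not in known or tgt not in known:
                raise ValueError(f"edge endpoint not a declared node: {src}->{tgt}")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +/-1, got {sign!r}")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge ({src}, {tgt})")
            seen.add((src, tgt))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        try:
            return self.nodes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge structure as (source_idx, target_idx, sign) integer arrays."""
        idx = {g: i for i, g in enumerate(self.nodes)}
        src = np.array([idx[s] for s, _, _ in self.edges], dtype=np.int64)
        tgt = np.array([idx[t] for _, t, _ in self.edges], dtype=np.int64)
        sgn = np.array([w for _, _, w in self.edges], dtype=np.int64)
        return src, tgt, sgn


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-gene phenotype scores: +1 epithelial, -1 mesenchymal, 0 unscored."""

    score: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, s in self.score.items():
            if s not in (-1, 0, 1):
                raise ValueError(f"score for {gene!r} must be in {{-1,0,1}}, got {s}")

    def vector(self, topology: Topology) -> np.ndarray:
        """Score vector aligned with ``topology.nodes`` (missing genes -> 0)."""
        unknown = set(self.score) - set(topology.nodes)
        if unknown:
            raise KeyError(f"annotation genes not in topology: {sorted(unknown)}")
        return np.array([self.score.get(g, 0) for g in topology.nodes], dtype=np.int64)

    def max_score(self) -> int:
        """Maximum attainable epithelial score (sum of |score|)."""
        return int(sum(abs(s) for s in self.score.values()))


def read_topo(path: str | Path) -> Topology:
    """Read a ``.topo`` file (``Source Target Type``; Type 1=act, 2=inh)."""
    path = Path(path)
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str, int]] = []
    seen_edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and [f.lower() for f in fields] == ["source", "target", "type"]:
                continue
            if len(fields) != 3:
                raise TopoParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}: {line!r}"
                )
            src, tgt, typ = fields
            if typ not in ("1", "2"):
                raise TopoParseError(
                    f"{path}:{lineno}: Type must be 1 (activation) or 2 (inhibition), got {typ!r}"
                )
            if (src, tgt) in seen_edges:
                raise TopoParseError(f"{path}:{lineno}: duplicate edge ({src}, {tgt})")
            seen_edges.add((src, tgt))
            for g in (src, tgt):
                if g not in seen_nodes:
                    seen_nodes.add(g)
                    nodes.append(g)
            edges.append((src, tgt, 1 if typ == "1" else -1))
    return Topology(nodes=tuple(nodes), edges=tuple(edges))


def write_topo(topology: Topology, path: str | Path) -> None:
    """Write a topology back to ``.topo`` format (with header)."""
    with open(path, "w") as fh:
        fh.write("Source Target Type\n")
        for src, tgt, sign in topology.edges:
            fh.write(f"{src} {tgt} {1 if sign == 1 else 2}\n")


def read_annotation(path: str | Path) -> NodeAnnotation:
    """Read a two-column ``gene score`` table with scores in {-1, 0, 1}."""
    path = Path(path)
    score: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[-1].lower() in ("score", "escore"):
                continue
            if len(fields) != 2:
                raise TopoParseError(f"{path}:{lineno}: expected 2 fields: {line!r}")
            gene, val = fields
            try:
                score[gene] = int(val)
            except ValueError:
                raise TopoParseError(f"{path}:{lineno}: bad score {val!r}") from None
    return NodeAnnotation(score=score)


def write_annotation(annotation: NodeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Gene Score\n")
        for gene, s in annotation.score.items():
            fh.write(f"{gene} {s}\n")


def interaction_matrix(topology: Topology) -> np.ndarray:
    """Interaction matrix J with J[i, j] = sign of the edge j -> i.

    Row i collects the incoming influences on node i, so the local field on a
    spin state ``s`` is ``J @ s``.
    """
    n = topology.n_nodes
    J = np.zeros((n, n), dtype=np.int64)
    src, tgt, sgn = topology.edge_arrays()
    J[tgt, src] = sgn
    return J


def _bfs_counts(adj: Sequence[Sequence[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path distances and path counts from ``source`` (unweighted)."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    q: deque[int] = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def group_betweenness(topology: Topology, group: Iterable[str],
                      include_endpoints: bool = False) -> float:
    """Group betweenness centrality of a set of nodes.

    The graph is treated as directed and unweighted with edge signs ignored.
    For every ordered pair (s, t) of distinct nodes outside the group, the
    fraction of shortest s->t paths passing through at least one group member
    is accumulated; group members are excluded as endpoints and no
    normalization is applied, so the score is a (possibly fractional) path
    count.

    With ``include_endpoints=True``, pairs with an endpoint inside the group
    also count (contributing 1 per reachable pair, since the endpoint itself
    lies on every path); under that variant the score is monotone in the
    group.

    Raises
    ------
    ValueError
        If the group is empty.
    KeyError
        If a group gene is not in the topology.
    """
    group = list(group)
    if not group:
        raise ValueError("group must be nonempty")
    gidx = {topology.index(g) for g in group}
    n = topology.n_nodes
    adj: list[list[int]] = [[] for _ in range(n)]
    src, tgt, _ = topology.edge_arrays()
    for s, t in zip(src, tgt):
        adj[s].append(int(t))
    # Adjacency with the group removed: shortest paths surviving there at the
    # original length are exactly the group-avoiding shortest paths.
    adj_wo: list[list[int]] = [
        [] if v in gidx else [w for w in adj[v] if w not in gidx] for v in range(n)
    ]
    outside = [v for v in range(n) if v not in gidx]
    sources = range(n) if include_endpoints else outside
    total = 0.0
    for s in sources:
        dist, sigma = _bfs_counts(adj, s, n)
        if s in gidx:  # only possible with include_endpoints
            total += sum(1.0 for t in range(n) if t != s and dist[t] >= 0)
            continue
        dist_wo, sigma_wo = _bfs_counts(adj_wo, s, n)
        targets = range(n) if include_endpoints else outside
        for t in targets:
            if t == s or dist[t] < 0:
                continue
            if t in gidx:
                total += 1.0
                continue
            avoid = sigma_wo[t] if dist_wo[t] == dist[t] else 0.0
            total += (sigma[t] - avoid) / sigma[t]
    return total
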