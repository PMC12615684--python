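"""Synthetic topologies and annotations for building and testing without
any external network files.

The toggle switch — two mutually inhibiting, self-activating genes — is the
canonical bistable motif and stands in for the E/M dichotomy: gene A plays
the epithelial marker, gene B the mesenchymal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topology import NodeAnnotation, Topology

__all__ = ["FixtureSpec", "make_toggle_switch", "make_random_grn",
           "make_annotation"]


@dataclass(frozen=True)
class FixtureSpec:
    """Size, sign balance and seed of a random signed GRN."""

    n_nodes: int
    n_edges: int
    activation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.activation_fraction <= 1:
            raise ValueError("activation_fraction must be in [0, 1]")
        if self.n_edges < 0 or self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"n_edges must be in [0, {self.n_nodes * (self.n_nodes - 1)}]")


def make_toggle_switch() -> tuple[Topology, NodeAnnotation]:
    """Mutually inhibiting pair with self-activation, annotated A=+1, B=-1."""
    topo = Topology(
        nodes=("A", "B"),
        edges=(("A", "B", -1), ("B", "A", -1), ("A", "A", 1), ("B", "B", 1)),
    )
    return topo, NodeAnnotation(score={"A": 1, "B": -1})


def make_random_grn(spec: FixtureSpec) -> Topology:
    """Uniformly sampled distinct directed edges between distinct nodes;
    each edge activates with probability ``activation_fraction``.
    Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nodes = tuple(f"G{i}" for i in range(spec.n_nodes))
    possible = [(i, j) for i in range(spec.n_nodes) for j in range(spec.n_nodes)
                if i != j]
    chosen = rng.choice(len(possible), size=spec.n_edges, replace=False)
    edges = []
    for c in chosen:
        i, j = possible[int(c)]
        sign = 1 if rng.random() < spec.activation_fraction else -1
        edges.append((nodes[i], nodes[j], sign))
    return Topology(nodes=nodes, edges=tuple(edges))


def make_annotation(topology: Topology, e_genes: Sequence[str],
                    m_genes: Sequence[str]) -> NodeAnnotation:
    """Annotation with +1 for ``e_genes``, -1 for ``m_genes``, 0 otherwise."""
    e_set, m_set = set(e_genes), set(m_genes)
    overlap = e_set & m_set
    if overlap:
        raise ValueError(f"genes in both lists: {sorted(overlap)}")
    unknown = (e_set | m_set) - set(topology.nodes)
    if unknown:
        raise ValueError(f"unknown genes: {sorted(unknown)}")
    score = {g: (1 if g in e_set else -1 if g in m_set else 0)
             for g in topology.nodes}
    return NodeAnnotation(score=score)
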