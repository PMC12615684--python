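"""Aggregation of screen outputs: efficacy matrices, rank correlations,
PCA projections and E/M-group trajectory summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .topology import NodeAnnotation, Topology

__all__ = [
    "signal_key",
    "efficacy_matrix",
    "matrix_to_table",
    "rank_correlation",
    "PCAProjection",
    "pca_projection",
    "trajectory_summary",
]


def signal_key(genes: Sequence[str]) -> tuple[str, ...]:
    """Canonical (sorted) key for a 1- or 2-gene signal."""
    return tuple(sorted(genes))


def efficacy_matrix(table: Mapping[tuple[str, ...], float],
                    topology: Topology) -> pd.DataFrame:
    """Reshape a complete per-signal efficacy table into an N x N matrix.

    Off-diagonal entry (i, j) is the pair efficacy; the diagonal carries the
    singleton efficacies.  The matrix is symmetric by construction.

    Raises a completeness error listing any missing signals.
    """
    genes = topology.nodes
    missing = []
    for i, g in enumerate(genes):
        if signal_key((g,)) not in table:
            missing.append((g,))
        for h in genes[i + 1:]:
            if signal_key((g, h)) not in table:
                missing.append((g, h))
    if missing:
        raise ValueError(f"efficacy table incomplete; missing signals: {missing}")
    n = len(genes)
    M = np.zeros((n, n))
    for i, g in enumerate(genes):
        M[i, i] = table[signal_key((g,))]
        for j in range(i + 1, n):
            v = table[signal_key((g, genes[j]))]
            M[i, j] = M[j, i] = v
    return pd.DataFrame(M, index=genes, columns=genes)


def matrix_to_table(matrix: pd.DataFrame) -> dict[tuple[str, ...], float]:
    """Inverse of :func:`efficacy_matrix` (lossless round trip)."""
    genes = list(matrix.index)
    out: dict[tuple[str, ...], float] = {}
    for i, g in enumerate(genes):
        out[signal_key((g,))] = float(matrix.iloc[i, i])
        for j in range(i + 1, len(genes)):
            out[signal_key((g, genes[j]))] = float(matrix.iloc[i, j])
    return out


def rank_correlation(x: Mapping[tuple[str, ...], float] | Sequence[float],
                     y: Mapping[tuple[str, ...], float] | Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties).

    Accepts two aligned sequences, or two mappings keyed by signal, which
    are aligned on their (identical) key sets.
    """
    if isinstance(x, Mapping) or isinstance(y, Mapping):
        if not (isinstance(x, Mapping) and isinstance(y, Mapping)):
            raise ValueError("both arguments must be mappings, or both sequences")
        if set(x) != set(y):
            raise ValueError("misaligned signal keys")
        keys = sorted(x)
        xv = [x[k] for k in keys]
        yv = [y[k] for k in keys]
    else:
        if len(x) != len(y):
            raise ValueError("length mismatch")
        xv, yv = list(x), list(y)
    if len(xv) < 3:
        raise ValueError("need at least 3 paired values")
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


@dataclass
class PCAProjection:
    """Fitted principal components of the pooled processed states."""

    loadings: np.ndarray  # (n_components, n_genes), orthonormal rows
    coords: np.ndarray    # projected input states
    mean: np.ndarray

    def project(self, processed: np.ndarray) -> np.ndarray:
        """Project processed states or trajectories onto the stored axes."""
        return (np.asarray(processed, dtype=float) - self.mean) @ self.loadings.T


def pca_projection(processed_states: np.ndarray,
                   n_components: int | None = None) -> PCAProjection:
    """PCA of the pooled processed steady states; the transform is reusable
    on trajectories passed through the same preprocessing."""
    X = np.asarray(processed_states, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 states")
    if n_components is None:
        n_components = min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return PCAProjection(loadings=pca.components_, coords=coords,
                         mean=pca.mean_)


def trajectory_summary(times: np.ndarray, trajectory: np.ndarray,
                       annotation: NodeAnnotation, topology: Topology,
                       clamped_genes: Sequence[str] = ()) -> pd.DataFrame:
    """Mean E-group and M-group expression over time, clamped genes apart.

    ``trajectory`` is a (time, gene) matrix on whatever scale the caller
    chose (typically processed).  Clamped genes are excluded from the group
    means and reported as their own columns.
    """
    vec = annotation.vector(topology)
    clamped_idx = [topology.index(g) for g in clamped_genes]
    in_group = np.ones(topology.n_nodes, dtype=bool)
    in_group[clamped_idx] = False
    e_idx = np.nonzero((vec == 1) & in_group)[0]
    m_idx = np.nonzero((vec == -1) & in_group)[0]
    data: dict[str, np.ndarray] = {"time": np.asarray(times, dtype=float)}
    traj = np.asarray(trajectory, dtype=float)
    if e_idx.size:
        data["e_mean"] = traj[:, e_idx].mean(axis=1)
    else:
        import warnings
        warnings.warn("no epithelial-scored genes; e_mean omitted")
    if m_idx.size:
        data["m_mean"] = traj[:, m_idx].mean(axis=1)
    else:
        import warnings
        warnings.warn("no mesenchymal-scored genes; m_mean omitted")
    for g, i in zip(clamped_genes, clamped_idx):
        data[f"clamped_{g}"] = traj[:, i]
    return pd.DataFrame(data)
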