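"""Randomized-parameter ODE ensembles on a GRN topology.

For a gene A regulated by transcription factors B_i the dynamics are

    dA/dt = G_A / prod_act lambda_i * prod_i H(B_i; B0_i, n_i, lambda_i) - k_A A

where H is the shifted Hill function

    H(B; B0, n, lambda) = lambda + (1 - lambda) / (1 + (B/B0)^n),

which interpolates from 1 (no regulator) to the fold change lambda at
saturation; lambda > 1 encodes activation, lambda < 1 inhibition.  Dividing
the maximal production rate G_A by the product of activation fold changes
keeps G_A the true expression ceiling.

An ensemble samples many kinetic parameter sets for one topology, finds each
model's stable steady states from random initial conditions, pools the
states, log-transforms and standardizes them, clusters them into two
phenotype groups with a Gaussian mixture, and keeps the models that are
bistable with exactly one state in each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .topology import Topology

__all__ = [
    "EnsembleConfig",
    "RacipeParams",
    "RacipeModel",
    "SteadyStates",
    "Transform",
    "ClusterResult",
    "Ensemble",
    "sample_parameters",
    "rhs",
    "shifted_hill",
    "find_steady_states",
    "preprocess_states",
    "cluster_states",
    "select_bistable",
    "build_ensemble",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Sampling ranges and integration settings for one ensemble.

    Defaults follow the canonical random-circuit-perturbation scheme:
    production G ~ U[1, 100], degradation k ~ U[0.1, 1], integer Hill
    coefficients U{1..6}, fold change lambda ~ U[1, 100] for activation and
    U[0.01, 1] for inhibition, and regulation thresholds drawn by the
    half-functional rule: B0 ~ U[0.02 M, 1.98 M] where M is the median
    unregulated level G/k of the regulator, so each link has roughly even
    odds of being above or below threshold across the ensemble.
    """

    n_models: int = 1000
    n_ics: int = 200
    dedup_decimals: int = 2
    h: float = 0.1
    t_max: float = 200.0
    tol: float = 1e-6
    g_range: tuple[float, float] = (1.0, 100.0)
    k_range: tuple[float, float] = (0.1, 1.0)
    hill_range: tuple[int, int] = (1, 6)
    lambda_act_range: tuple[float, float] = (1.0, 100.0)
    lambda_inh_range: tuple[float, float] = (0.01, 1.0)
    threshold_spread: float = 0.98  # B0 ~ U[(1-s)M, (1+s)M]
    ic_floor: float = 1e-2
    dedup_on: str = "log1p"  # or "raw"

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.n_ics < 1:
            raise ValueError("n_models and n_ics must be positive")
        if self.dedup_decimals < 0:
            raise ValueError("dedup_decimals must be >= 0")
        if self.h <= 0 or self.t_max <= 0 or self.tol <= 0:
            raise ValueError("h, t_max, tol must be positive")
        if self.dedup_on not in ("log1p", "raw"):
            raise ValueError("dedup_on must be 'log1p' or 'raw'")


@dataclass(frozen=True)
class RacipeParams:
    """One randomized parameter set, aligned with the topology's node and
    edge order: per-gene production ``G`` and degradation ``k``; per-edge
    fold change ``lam``, threshold ``thr``, and Hill coefficient ``hill``."""

    G: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    thr: np.ndarray
    hill: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.G <= 0) or np.any(self.k <= 0):
            raise ValueError("G and k must be positive")
        if np.any(self.thr <= 0):
            raise ValueError("thresholds must be positive")
        if np.any(self.hill < 1):
            raise ValueError("Hill coefficients must be >= 1")


@dataclass
class SteadyStates:
    """Unique steady states of one model plus integration diagnostics."""

    states: list[np.ndarray]
    n_unconverged: int = 0
    n_ics: int = 0

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


@dataclass
class RacipeModel:
    """A parameter set with its discovered steady states and cluster labels."""

    model_id: int
    params: RacipeParams
    steady_states: list[np.ndarray]
    labels: list[str] = field(default_factory=list)
    n_unconverged: int = 0

    def state(self, label: str) -> np.ndarray:
        for s, lab in zip(self.steady_states, self.labels):
            if lab == label:
                return s
        raise KeyError(f"model {self.model_id} has no state labeled {label!r}")


class _Structure:
    """Precomputed index arrays for vectorized rhs evaluation."""

    def __init__(self, topology: Topology):
        self.n = topology.n_nodes
        self.src, self.tgt, self.sgn = topology.edge_arrays()
        self.n_edges = len(self.src)
        # edge -> target indicator matrix, so a (batch, E) array of log Hill
        # factors contracts to per-gene log products in one matmul
        self.M = np.zeros((self.n_edges, self.n), dtype=np.float64)
        self.M[np.arange(self.n_edges), self.tgt] = 1.0


@lru_cache(maxsize=64)
def _structure(topology: Topology) -> _Structure:
    return _Structure(topology)


@lru_cache(maxsize=32)
def _median_unregulated_level(g_range: tuple[float, float],
                              k_range: tuple[float, float]) -> float:
    """Monte-Carlo median of G/k over the sampling ranges (fixed stream)."""
    mc = np.random.default_rng(987654321)
    g = mc.uniform(*g_range, size=200_000)
    k = mc.uniform(*k_range, size=200_000)
    return float(np.median(g / k))


def sample_parameters(topology: Topology, config: EnsembleConfig,
                      rng: np.random.Generator) -> RacipeParams:
    """Draw one randomized parameter set for the topology."""
    st = _structure(topology)
    G = rng.uniform(*config.g_range, size=st.n)
    k = rng.uniform(*config.k_range, size=st.n)
    hill = rng.integers(config.hill_range[0], config.hill_range[1] + 1,
                        size=st.n_edges).astype(np.float64)
    lam = np.empty(st.n_edges)
    act = st.sgn > 0
    lam[act] = rng.uniform(*config.lambda_act_range, size=int(act.sum()))
    lam[~act] = rng.uniform(*config.lambda_inh_range, size=int((~act).sum()))
    m = _median_unregulated_level(config.g_range, config.k_range)
    lo = (1.0 - config.threshold_spread) * m
    hi = (1.0 + config.threshold_spread) * m
    thr = rng.uniform(lo, hi, size=st.n_edges)
    return RacipeParams(G=G, k=k, lam=lam, thr=thr, hill=hill)


def shifted_hill(B: np.ndarray, B0: float | np.ndarray, n: float | np.ndarray,
                 lam: float | np.ndarray) -> np.ndarray:
    """Shifted Hill regulation factor, bounded by [min(1, lam), max(1, lam)]."""
    return lam + (1.0 - lam) / (1.0 + (np.asarray(B, dtype=float) / B0) ** n)


def _g_scale(params: RacipeParams, st: _Structure) -> np.ndarray:
    """Effective production prefactor per gene.

    G_A is divided by the product of the *activation* fold changes of A's
    regulators, so that maximal production (all activators saturated, all
    inhibitors absent) equals G_A.  Inhibitory factors lie in [lambda, 1]
    and are not normalized away.
    """
    log_lam = np.where(st.sgn > 0, np.log(params.lam), 0.0)
    return params.G * np.exp(-(log_lam @ st.M))


def _rhs_batch(x: np.ndarray, params: RacipeParams, st: _Structure,
               g_scale: np.ndarray | None = None) -> np.ndarray:
    """Vectorized rhs for a (batch, N) matrix of non-negative states."""
    if st.n_edges == 0:
        return params.G - params.k * x
    if g_scale is None:
        g_scale = _g_scale(params, st)
    B = x[..., st.src]
    H = shifted_hill(B, params.thr, params.hill, params.lam)
    prod = np.exp(np.log(H) @ st.M)
    return g_scale * prod - params.k * x


def rhs(expression: np.ndarray, params: RacipeParams, topology: Topology) -> np.ndarray:
    """Time derivative of the expression vector under the shifted-Hill ODEs."""
    x = np.asarray(expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    st = _structure(topology)
    return _rhs_batch(x[None, :], params, st)[0]


def find_steady_states(params: RacipeParams, topology: Topology,
                       config: EnsembleConfig, rng: np.random.Generator) -> SteadyStates:
    """Enumerate stable steady states from random initial conditions.

    Initial conditions are log-uniform between ``config.ic_floor`` and each
    gene's unregulated ceiling G/k.  Trajectories are integrated with fixed-
    step explicit Euler until the max-norm residual drops below ``tol`` or
    ``t_max`` is reached; unconverged trajectories are excluded and counted.
    Near-identical endpoints are collapsed by rounding (log1p scale by
    default) to ``dedup_decimals`` decimals.
    """
    st = _structure(topology)
    cap = params.G / params.k
    lo = np.log(np.full(st.n, config.ic_floor))
    hi = np.log(np.maximum(cap, config.ic_floor * 1.0001))
    x = np.exp(rng.uniform(lo, hi, size=(config.n_ics, st.n)))
    g_scale = _g_scale(params, st) if st.n_edges else None
    n_steps = int(np.ceil(config.t_max / config.h))
    active = np.ones(config.n_ics, dtype=bool)
    check_every = 10
    for step in range(n_steps):
        if not active.any():
            break
        dx = _rhs_batch(x[active], params, st, g_scale)
        x[active] = np.maximum(x[active] + config.h * dx, 0.0)
        if (step + 1) % check_every == 0:
            res = np.max(np.abs(dx), axis=1)
            idx = np.nonzero(active)[0]
            active[idx[res < config.tol]] = False
    if active.any():  # last-chance residual check at t_max
        res = np.max(np.abs(_rhs_batch(x[active], params, st, g_scale)), axis=1)
        idx = np.nonzero(active)[0]
        active[idx[res < config.tol]] = False
    converged = ~active
    states: list[np.ndarray] = []
    seen: set[tuple] = set()
    for row in np.nonzero(converged)[0]:
        xr = x[row]
        key_vals = np.log1p(xr) if config.dedup_on == "log1p" else xr
        key = tuple(np.round(key_vals, config.dedup_decimals))
        if key not in seen:
            seen.add(key)
            states.append(xr.copy())
    return SteadyStates(states=states, n_unconverged=int(active.sum()),
                        n_ics=config.n_ics)


@dataclass
class Transform:
    """log1p + per-gene z-score transform fitted on pooled steady states."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Transform raw-scale expression (vector, matrix or trajectory)."""
        return (np.log1p(np.asarray(x, dtype=float)) - self.mean) / self.sd


def preprocess_states(states: np.ndarray) -> tuple[np.ndarray, Transform]:
    """log-transform with pseudocount 1 and standardize per gene.

    Returns the processed matrix and the fitted :class:`Transform` for reuse
    on trajectories and perturbed endpoints.  Zero-variance genes are mapped
    to 0 with a warning.
    """
    states = np.asarray(states, dtype=float)
    if np.any(states < 0):
        raise ValueError("states must be non-negative")
    logx = np.log1p(states)
    mean = logx.mean(axis=0)
    sd = logx.std(axis=0)
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s); standardized to 0")
        sd = np.where(zero, 1.0, sd)
    tf = Transform(mean=mean, sd=sd)
    processed = tf.apply(states)
    processed[:, zero] = 0.0
    return processed, tf


@dataclass
class ClusterResult:
    labels: np.ndarray  # 'E' / 'M' per state
    k_selected: int
    silhouette_by_k: dict[int, float]


def cluster_states(processed: np.ndarray, gene_names: Sequence[str],
                   e_marker: str = "Cdh1", random_state: int = 0) -> ClusterResult:
    """Cluster pooled processed states into E and M phenotype groups.

    Fits Gaussian mixtures for k = 2..6 (bounded by the state count) and
    records silhouette scores; the final labels come from the 2-component
    fit, and the cluster with the higher mean expression of ``e_marker`` is
    named "E".
    """
    processed = np.asarray(processed, dtype=float)
    if processed.shape[0] < 2:
        raise ValueError("need at least 2 states to cluster")
    if e_marker not in gene_names:
        raise KeyError(f"e_marker {e_marker!r} not among gene names")
    marker_col = list(gene_names).index(e_marker)
    sil: dict[int, float] = {}
    labels2: np.ndarray | None = None
    for kk in range(2, min(6, processed.shape[0] - 1) + 1):
        gm = GaussianMixture(n_components=kk, covariance_type="diag",
                             n_init=10, random_state=random_state)
        lab = gm.fit_predict(processed)
        if len(np.unique(lab)) > 1:
            sil[kk] = float(silhouette_score(processed, lab))
        else:
            sil[kk] = float("nan")
        if kk == 2:
            labels2 = lab
    assert labels2 is not None
    k_selected = max((k for k in sil if np.isfinite(sil[k])), key=lambda k: sil[k],
                     default=2)
    mean0 = processed[labels2 == 0, marker_col].mean() if np.any(labels2 == 0) else -np.inf
    mean1 = processed[labels2 == 1, marker_col].mean() if np.any(labels2 == 1) else -np.inf
    e_component = 0 if mean0 >= mean1 else 1
    named = np.where(labels2 == e_component, "E", "M")
    return ClusterResult(labels=named, k_selected=int(k_selected),
                         silhouette_by_k=sil)


def select_bistable(models: Sequence[RacipeModel]) -> list[RacipeModel]:
    """Models with exactly two unique states, one labeled E and one M."""
    out = []
    for m in models:
        if len(m.steady_states) == 2 and sorted(m.labels) == ["E", "M"]:
            out.append(m)
    return out


@dataclass
class Ensemble:
    """A simulated ensemble: models, pooled states, transform, clustering."""

    topology: Topology
    config: EnsembleConfig
    models: list[RacipeModel]
    pooled_states: np.ndarray  # raw scale, rows pooled over models
    processed: np.ndarray
    transform: Transform
    clustering: ClusterResult

    def bistable(self) -> list[RacipeModel]:
        return select_bistable(self.models)

    @property
    def pooled_labels(self) -> np.ndarray:
        return self.clustering.labels


def build_ensemble(topology: Topology, config: EnsembleConfig, seed: int,
                   e_marker: str = "Cdh1") -> Ensemble:
    """Sample, simulate, preprocess and cluster a full ensemble.

    Deterministic given ``seed``; per-model parameter and initial-condition
    streams are spawned from one seed sequence.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_models)
    models: list[RacipeModel] = []
    for mid, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_parameters(topology, config, rng)
        found = find_steady_states(params, topology, config, rng)
        models.append(RacipeModel(model_id=mid, params=params,
                                  steady_states=list(found.states),
                                  n_unconverged=found.n_unconverged))
    pooled = np.array([s for m in models for s in m.steady_states])
    if pooled.shape[0] < 2:
        raise RuntimeError("ensemble produced fewer than 2 steady states")
    processed, tf = preprocess_states(pooled)
    clus = cluster_states(processed, topology.nodes, e_marker=e_marker)
    pos = 0
    for m in models:
        k = len(m.steady_states)
        m.labels = [str(lab) for lab in clus.labels[pos:pos + k]]
        pos += k
    return Ensemble(topology=topology, config=config, models=models,
                    pooled_states=pooled, processed=processed, transform=tf,
                    clustering=clus)
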