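"""Clamp-signal perturbation protocols for ODE-ensemble models.

A signal locks one or two genes at the values they take in the model's
target steady state (the continuous analog of toggling a binary node) for a
signal window, optionally with Ornstein-Uhlenbeck transcriptional noise
added to each gene's derivative; the clamp and noise are then removed and
the system relaxes deterministically.  Final states are classified E or M by
k-nearest-neighbor voting against the ensemble's pooled processed steady
states.

The OU term for gene g evolves by the exact discretization

    U(t+h) = U(t) e^{-h/tau} + D_g sqrt(1 - e^{-2h/tau}) z_t,

so D_g is the stationary standard deviation; D_g = D times the gene's mean
expression across the model's known steady states, making noise proportional
to expression scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .racipe_ensemble import Ensemble, RacipeModel, Transform, _structure
from .topology import Topology

__all__ = [
    "SignalSpec",
    "OUNoiseSpec",
    "ProtocolConfig",
    "PerturbationResult",
    "StateClassifier",
    "classifier_consistent",
    "enumerate_signals",
    "ou_step",
    "run_perturbation",
    "classify_state",
    "signal_efficacy",
    "spontaneous_rates",
    "transition_time",
    "noise_threshold_scan",
]


@dataclass(frozen=True)
class SignalSpec:
    """A 1- or 2-gene target-state clamp signal."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signal must name at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signal genes must be distinct")

    def __str__(self) -> str:
        return "+".join(self.genes)


@dataclass(frozen=True)
class OUNoiseSpec:
    """Ornstein-Uhlenbeck noise: stationary sd multiplier D, correlation
    time tau.  Per-gene sd is D scaled by the gene's expected steady-state
    expression."""

    D: float = 0.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class ProtocolConfig:
    """Signal-window protocol: ``t_signal`` units of clamped (and noisy)
    dynamics, then ``t_relax`` units of free deterministic relaxation."""

    t_signal: float = 500.0
    t_relax: float = 50.0
    h: float = 0.1
    knn_k: int = 25
    n_trials: int = 1
    sample_every: float = 1.0

    def __post_init__(self) -> None:
        if self.t_signal < 0 or self.t_relax < 0:
            raise ValueError("durations must be >= 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class PerturbationResult:
    model_id: int
    signal: SignalSpec
    start_label: str
    end_label: str
    target_label: str
    transitioned: bool
    transition_time: float | None = None
    times: np.ndarray | None = None
    trajectory: np.ndarray | None = None  # raw scale, (len(times), N)


def enumerate_signals(topology: Topology) -> list[SignalSpec]:
    """All N single-gene signals plus all C(N,2) unordered pairs, in stable
    node order (singletons first)."""
    if topology.n_nodes < 1:
        raise ValueError("topology must have at least one node")
    singles = [SignalSpec((g,)) for g in topology.nodes]
    pairs = [SignalSpec(pair) for pair in combinations(topology.nodes, 2)]
    return singles + pairs


def ou_step(U, h: float, tau: float, D_g, z):
    """One exact-discretization OU update (works elementwise on arrays)."""
    if h <= 0 or tau <= 0:
        raise ValueError("h and tau must be positive")
    a = np.exp(-h / tau)
    return U * a + D_g * np.sqrt(1.0 - a * a) * z


def classify_state(state_processed: np.ndarray, reference: np.ndarray,
                   reference_labels: Sequence[str], k: int = 25) -> str:
    """Majority label among the k nearest reference states (Euclidean).

    Ties are broken toward "M" (fixed, documented rule)."""
    reference = np.asarray(reference, dtype=float)
    if k > reference.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {reference.shape[0]}")
    d2 = np.sum((reference - np.asarray(state_processed, dtype=float)) ** 2, axis=1)
    nearest = np.argpartition(d2, k - 1)[:k]
    labs = np.asarray(reference_labels)[nearest]
    n_m = int(np.sum(labs == "M"))
    return "M" if n_m >= k - n_m else "E"


@dataclass
class StateClassifier:
    """KNN classifier over the ensemble's processed steady states."""

    transform: Transform
    reference: np.ndarray  # processed
    labels: np.ndarray
    k: int = 25

    @classmethod
    def from_ensemble(cls, ensemble: Ensemble, k: int = 25) -> "StateClassifier":
        return cls(transform=ensemble.transform, reference=ensemble.processed,
                   labels=np.asarray(ensemble.pooled_labels), k=k)

    def classify(self, state_raw: np.ndarray) -> str:
        return classify_state(self.transform.apply(state_raw), self.reference,
                              self.labels, self.k)

    def classify_many(self, states_raw: np.ndarray) -> np.ndarray:
        return np.array([self.classify(s) for s in np.atleast_2d(states_raw)])


def classifier_consistent(models: Sequence[RacipeModel],
                          classifier: "StateClassifier") -> list[RacipeModel]:
    """Bistable models whose own E and M steady states classify correctly.

    With a small pooled reference, a k-nearest-neighbor vote can straddle the
    two clusters and misclassify a boundary model's own endpoint, which would
    register as a spurious transition even with frozen dynamics.  Screens
    should run on this consistent subset; at full study scale (hundreds of
    models, k=25) the filter removes nothing.
    """
    out = []
    for m in models:
        try:
            ok = (classifier.classify(m.state("E")) == "E"
                  and classifier.classify(m.state("M")) == "M")
        except KeyError:
            ok = False
        if ok:
            out.append(m)
    return out


class _ModelBatch:
    """Stacked parameter arrays for integrating many models in lockstep."""

    def __init__(self, models: Sequence[RacipeModel], topology: Topology):
        self.models = list(models)
        self.st = _structure(topology)
        self.G = np.stack([m.params.G for m in models])
        self.k = np.stack([m.params.k for m in models])
        if self.st.n_edges:
            self.lam = np.stack([m.params.lam for m in models])
            self.thr = np.stack([m.params.thr for m in models])
            self.hill = np.stack([m.params.hill for m in models])
            log_lam = np.where(self.st.sgn > 0, np.log(self.lam), 0.0)
            self.g_scale = self.G * np.exp(-(log_lam @ self.st.M))
        # expected expression scale per gene: mean over known steady states
        self.scale = np.stack([np.mean(np.stack(m.steady_states), axis=0)
                               if m.steady_states else np.zeros(self.st.n)
                               for m in models])

    def rhs(self, x: np.ndarray) -> np.ndarray:
        if self.st.n_edges == 0:
            return self.G - self.k * x
        B = x[:, self.st.src]
        H = self.lam + (1.0 - self.lam) / (1.0 + (B / self.thr) ** self.hill)
        return self.g_scale * np.exp(np.log(H) @ self.st.M) - self.k * x


def _integrate_batch(batch: _ModelBatch, x0: np.ndarray, duration: float,
                     h: float, clamp_idx: np.ndarray | None,
                     clamp_vals: np.ndarray | None, D_g: np.ndarray | None,
                     tau: float, rng: np.random.Generator,
                     sample_every: float | None = None
                     ) -> tuple[np.ndarray, list[float], list[np.ndarray]]:
    """Euler-Maruyama integration of a model batch.

    Clamped genes are reset to their target values after every step;
    expression is floored at 0.  If ``sample_every`` is given, states are
    recorded at those intervals (including t=0)."""
    x = np.array(x0, dtype=float)
    if clamp_idx is not None:
        x[:, clamp_idx] = clamp_vals
    n_steps = int(round(duration / h))
    noisy = D_g is not None and np.any(D_g > 0)
    U = np.zeros_like(x) if noisy else None
    times: list[float] = []
    samples: list[np.ndarray] = []
    stride = max(int(round(sample_every / h)), 1) if sample_every else None
    if stride:
        times.append(0.0)
        samples.append(x.copy())
    for step in range(n_steps):
        dx = batch.rhs(x)
        if noisy:
            z = rng.standard_normal(x.shape)
            U = ou_step(U, h, tau, D_g, z)
            dx = dx + U
        x = np.maximum(x + h * dx, 0.0)
        if clamp_idx is not None:
            x[:, clamp_idx] = clamp_vals
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite state at step {step + 1} (t={(step + 1) * h:.2f})")
        if stride and (step + 1) % stride == 0:
            times.append((step + 1) * h)
            samples.append(x.copy())
    return x, times, samples


def run_perturbation(model: RacipeModel, start_state: np.ndarray,
                     target_state: np.ndarray, signal: SignalSpec | None,
                     noise: OUNoiseSpec, protocol: ProtocolConfig,
                     rng: np.random.Generator, topology: Topology,
                     classifier: StateClassifier | None = None,
                     record_trajectory: bool = False) -> PerturbationResult:
    """Run one clamp-signal protocol on one model.

    The signal genes are locked at their values in ``target_state`` for
    ``t_signal`` units with OU noise active, then released (noise removed)
    for ``t_relax`` units of deterministic relaxation.  The final state is
    classified with ``classifier`` when given, otherwise by proximity to the
    start/target states on the log1p scale.
    """
    batch = _ModelBatch([model], topology)
    if signal is not None:
        clamp_idx = np.array([topology.index(g) for g in signal.genes])
        clamp_vals = np.asarray(target_state, dtype=float)[clamp_idx][None, :]
    else:
        clamp_idx = clamp_vals = None
    D_g = noise.D * batch.scale if noise.D > 0 else None
    sample = protocol.sample_every if record_trajectory else None
    x = np.asarray(start_state, dtype=float)[None, :]
    x, t1, s1 = _integrate_batch(batch, x, protocol.t_signal, protocol.h,
                                 clamp_idx, clamp_vals, D_g, noise.tau, rng,
                                 sample_every=sample)
    x, t2, s2 = _integrate_batch(batch, x, protocol.t_relax, protocol.h,
                                 None, None, None, noise.tau, rng,
                                 sample_every=sample)
    final = x[0]

    def _label(state: np.ndarray) -> str:
        if classifier is not None:
            return classifier.classify(state)
        ds = np.linalg.norm(np.log1p(state) - np.log1p(start_state))
        dt = np.linalg.norm(np.log1p(state) - np.log1p(target_state))
        return "target" if dt < ds else "start"

    start_label = _label(np.asarray(start_state, dtype=float))
    target_label = _label(np.asarray(target_state, dtype=float))
    end_label = _label(final)
    transitioned = (end_label == target_label) and (start_label != target_label)
    times = traj = None
    if record_trajectory:
        times = np.array(t1 + [protocol.t_signal + t for t in t2[1:]])
        traj = np.vstack([np.stack(s1)[:, 0, :], np.stack(s2)[1:, 0, :]]) \
            if s2[1:] else np.stack(s1)[:, 0, :]
    return PerturbationResult(model_id=model.model_id, signal=signal,
                              start_label=start_label, end_label=end_label,
                              target_label=target_label,
                              transitioned=transitioned, times=times,
                              trajectory=traj)


def _batch_transition_fraction(models: Sequence[RacipeModel], topology: Topology,
                               signal: SignalSpec | None, noise: OUNoiseSpec,
                               protocol: ProtocolConfig,
                               classifier: StateClassifier,
                               rng: np.random.Generator,
                               start_label: str = "E",
                               target_label: str = "M") -> float:
    """Fraction of models transitioning start_label -> target_label."""
    batch = _ModelBatch(models, topology)
    x0 = np.stack([m.state(start_label) for m in models])
    targets = np.stack([m.state(target_label) for m in models])
    if signal is not None:
        clamp_idx = np.array([topology.index(g) for g in signal.genes])
        clamp_vals = targets[:, clamp_idx]
    else:
        clamp_idx = clamp_vals = None
    D_g = noise.D * batch.scale if noise.D > 0 else None
    x, _, _ = _integrate_batch(batch, x0, protocol.t_signal, protocol.h,
                               clamp_idx, clamp_vals, D_g, noise.tau, rng)
    x, _, _ = _integrate_batch(batch, x, protocol.t_relax, protocol.h,
                               None, None, None, noise.tau, rng)
    end_labels = classifier.classify_many(x)
    return float(np.mean(end_labels == target_label))


def signal_efficacy(models: Sequence[RacipeModel], signal: SignalSpec,
                    noise: OUNoiseSpec, protocol: ProtocolConfig,
                    rng: np.random.Generator, topology: Topology,
                    classifier: StateClassifier) -> float:
    """Percent of E-starting bistable models ending in M, averaged over
    ``protocol.n_trials`` independent trials."""
    models = list(models)
    if not models:
        raise ValueError("empty model set")
    fracs = [_batch_transition_fraction(models, topology, signal, noise,
                                        protocol, classifier, rng)
             for _ in range(protocol.n_trials)]
    return 100.0 * float(np.mean(fracs))


def spontaneous_rates(models: Sequence[RacipeModel], noise_levels: Sequence[float],
                      protocol: ProtocolConfig, rng: np.random.Generator,
                      topology: Topology, classifier: StateClassifier,
                      tau: float = 10.0) -> pd.DataFrame:
    """No-signal controls: switching rates in both directions per noise level."""
    rows = []
    for D in noise_levels:
        noise = OUNoiseSpec(D=D, tau=tau)
        emt = 100.0 * np.mean([_batch_transition_fraction(
            models, topology, None, noise, protocol, classifier, rng,
            "E", "M") for _ in range(protocol.n_trials)])
        met = 100.0 * np.mean([_batch_transition_fraction(
            models, topology, None, noise, protocol, classifier, rng,
            "M", "E") for _ in range(protocol.n_trials)])
        rows.append({"D": D, "emt_percent": float(emt), "met_percent": float(met)})
    return pd.DataFrame(rows)


def transition_time(result: PerturbationResult,
                    classifier: StateClassifier) -> float | None:
    """Earliest sampled time at which the trajectory classifies as the
    target label; None if it never does."""
    if result.trajectory is None or result.times is None:
        raise ValueError("result carries no trajectory; rerun with record_trajectory")
    for t, state in zip(result.times, result.trajectory):
        if classifier.classify(state) == result.target_label:
            return float(t)
    return None


def noise_threshold_scan(model: RacipeModel, signal: SignalSpec,
                         from_state: np.ndarray, to_state: np.ndarray,
                         D_grid: Sequence[float], protocol: ProtocolConfig,
                         rng: np.random.Generator, topology: Topology,
                         clamp_state: np.ndarray | None = None,
                         tau: float = 10.0) -> float | None:
    """Minimal noise level allowing a transition under a sustained clamp.

    The clamped system starts from ``from_state`` (a steady state of the
    clamped dynamics); at each grid noise level, ``protocol.n_trials`` runs
    of length ``t_signal`` are simulated with the clamp held throughout, and
    a run transitions when its endpoint lies closer (log1p Euclidean) to
    ``to_state`` than to ``from_state``.  Returns the smallest grid value
    with at least one transition, or None.
    """
    if len(D_grid) == 0:
        raise ValueError("D_grid must be nonempty")
    batch = _ModelBatch([model], topology)
    clamp_idx = np.array([topology.index(g) for g in signal.genes])
    source = clamp_state if clamp_state is not None else model.state("M")
    clamp_vals = np.asarray(source, dtype=float)[clamp_idx][None, :]
    lf, lt = np.log1p(from_state), np.log1p(to_state)
    for D in sorted(D_grid):
        noise = OUNoiseSpec(D=D, tau=tau)
        D_g = noise.D * batch.scale if noise.D > 0 else None
        for _ in range(protocol.n_trials):
            x = np.asarray(from_state, dtype=float)[None, :]
            x, _, _ = _integrate_batch(batch, x, protocol.t_signal, protocol.h,
                                       clamp_idx, clamp_vals, D_g, tau, rng)
            lx = np.log1p(x[0])
            if np.linalg.norm(lx - lt) < np.linalg.norm(lx - lf):
                return float(D)
    return None
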