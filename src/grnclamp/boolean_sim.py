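"""Boolean spin dynamics on a signed GRN with pseudo-temperature.

The network state is a vector of binary spins s_i = +/-1 (+1 = high
expression).  Dynamics are random-sequential Metropolis updates: a node is
picked uniformly at random, the pseudo-energy change of flipping it is
dE = 2 s_i sum_j J_ij s_j (the Metropolis rule for pseudo-energy
E = -sum_ij s_i J_ij s_j, under which low-frustration states are locally
stable), and the flip is accepted with probability min(1, exp(-dE/T)).
One unit time corresponds to N single-node update attempts.

The transition protocol mimics a transient transcriptional perturbation:
starting from a low-frustration epithelial state, one or two nodes are
clamped to their mesenchymal values for a duration t_c at pseudo-temperature
T, then the clamp is released and the system is quenched at T = 0.5 for a
short relaxation window.  A run counts as a completed transition when the
final epithelial score falls below the mesenchymal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .topology import NodeAnnotation, Topology

__all__ = [
    "BooleanConfig",
    "ClampSpec",
    "ConvergenceError",
    "ProtocolOutcome",
    "frustration",
    "epithelial_score",
    "metropolis_step",
    "find_initial_state",
    "run_clamp_protocol",
    "screen_clamps",
    "mesenchymal_clamp_values",
]


class ConvergenceError(RuntimeError):
    """Raised when no acceptable low-frustration initial state is found."""


@dataclass(frozen=True)
class BooleanConfig:
    """Protocol parameters for the Boolean transition simulations.

    ``T`` is the pseudo-temperature of the clamped phase, ``t_c`` its duration
    in unit times (1 unit = N single-node update attempts).  After the clamp
    is released the system is quenched at ``quench_T`` for ``quench_time``
    units.  Initial states must have frustration <= ``frustration_max`` and
    epithelial score > ``e_score_start_min``; success requires a final score
    < ``m_score_end_max``.  ``energy_sign`` flips the sign convention of the
    pseudo-energy change (kept configurable for auditability; +1 is the
    stable-states-are-low-energy convention used throughout).
    """

    T: float = 2.0
    t_c: float = 400.0
    quench_T: float = 0.5
    quench_time: float = 10.0
    frustration_max: int = 10
    e_score_start_min: int = 4
    m_score_end_max: int = -4
    energy_sign: int = 1
    init_T: float | None = None  # search temperature; defaults to T
    init_search_units: int = 200  # units of dynamics per search attempt
    max_init_attempts: int = 500

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.t_c < 0:
            raise ValueError("t_c must be >= 0")
        if self.energy_sign not in (-1, 1):
            raise ValueError("energy_sign must be +/-1")


@dataclass(frozen=True)
class ClampSpec:
    """Nodes held at fixed spin values during the clamped phase."""

    clamped: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, v in self.clamped.items():
            if v not in (-1, 1):
                raise ValueError(f"clamp value for {gene!r} must be +/-1")

    def arrays(self, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(topology.n_nodes, dtype=np.bool_)
        vals = np.zeros(topology.n_nodes, dtype=np.int64)
        for gene, v in self.clamped.items():
            i = topology.index(gene)
            mask[i] = True
            vals[i] = v
        return mask, vals


@dataclass
class ProtocolOutcome:
    success: bool
    final: np.ndarray
    trace: list[tuple[float, int, int]] | None = None  # (time, node, new spin)


def frustration(state: np.ndarray, J: np.ndarray) -> int:
    """Number of unsatisfied directed links: links with s_i J_ij s_j < 0.

    Each directed edge is counted once; the count is invariant under a global
    spin flip.
    """
    state = np.asarray(state)
    if J.shape != (state.size, state.size):
        raise ValueError(f"shape mismatch: J {J.shape} vs state {state.shape}")
    tgt, src = np.nonzero(J)
    return int(np.count_nonzero(state[tgt] * J[tgt, src] * state[src] < 0))


def epithelial_score(state: np.ndarray, annotation: NodeAnnotation | np.ndarray,
                     topology: Topology | None = None) -> int:
    """Signed sum of annotated marker spins, sum_i score_i * s_i."""
    if isinstance(annotation, NodeAnnotation):
        if topology is None:
            raise ValueError("topology required when annotation is a NodeAnnotation")
        vec = annotation.vector(topology)
    else:
        vec = np.asarray(annotation)
    return int(np.dot(vec, np.asarray(state)))


@njit(cache=True)
def _mc_run(s, J, T, n_attempts, clamp_mask, clamp_vals, sign, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n = s.shape[0]
    for _ in range(n_attempts):
        i = np.random.randint(0, n)
        r = np.random.random()
        if clamp_mask[i]:
            continue
        h = 0.0
        for j in range(n):
            h += J[i, j] * s[j]
        dE = sign * 2.0 * s[i] * h
        if dE <= 0.0:
            s[i] = -s[i]
        elif T > 0.0 and r < np.exp(-dE / T):
            s[i] = -s[i]
    return s


def _run_units(state: np.ndarray, J: np.ndarray, T: float, units: float,
               clamp_mask: np.ndarray, clamp_vals: np.ndarray, sign: int,
               rng: np.random.Generator) -> np.ndarray:
    """Run ``units`` unit times (units*N attempts) with the fast kernel."""
    n_attempts = int(round(units * state.size))
    if n_attempts == 0:
        return state
    seed = int(rng.integers(0, 2**31 - 1))
    s = state.astype(np.float64).copy()
    if clamp_mask.any():
        s[clamp_mask] = clamp_vals[clamp_mask]
    s = _mc_run(s, J.astype(np.float64), float(T), n_attempts,
                clamp_mask, clamp_vals.astype(np.float64), float(sign), seed)
    return s.astype(np.int64)


def metropolis_step(state: np.ndarray, J: np.ndarray, T: float,
                    clamp: ClampSpec | None, rng: np.random.Generator,
                    topology: Topology | None = None,
                    energy_sign: int = 1) -> np.ndarray:
    """A single random-sequential Metropolis update attempt.

    Exactly zero or one spin differs from the input.  Clamped nodes are never
    flipped.  At T = 0 the rule reduces to greedy descent with zero-field
    flips still accepted (min(1, e^0) = 1).
    """
    state = np.asarray(state).copy()
    n = state.size
    mask = np.zeros(n, dtype=bool)
    if clamp is not None and clamp.clamped:
        if topology is None:
            raise ValueError("topology required to resolve clamp gene names")
        mask, _ = clamp.arrays(topology)
    i = int(rng.integers(0, n))
    r = float(rng.random())
    if mask[i]:
        return state
    dE = energy_sign * 2.0 * state[i] * float(J[i] @ state)
    if dE <= 0 or (T > 0 and r < np.exp(-dE / T)):
        state[i] = -state[i]
    return state


def find_initial_state(J: np.ndarray, annotation_vec: np.ndarray, T: float,
                       config: BooleanConfig, rng: np.random.Generator) -> np.ndarray:
    """Search for a low-frustration epithelial starting state.

    Random states are relaxed at pseudo-temperature ``T`` until the
    frustration drops to ``config.frustration_max`` or below; the state is
    accepted if its epithelial score exceeds ``config.e_score_start_min``,
    otherwise the search restarts from a fresh random state.
    """
    if not 0 < T <= 4:
        raise ValueError("initial-state search temperature must be in (0, 4]")
    n = J.shape[0]
    no_clamp_mask = np.zeros(n, dtype=np.bool_)
    no_clamp_vals = np.zeros(n, dtype=np.int64)
    best_f = np.inf
    for _ in range(config.max_init_attempts):
        state = rng.choice(np.array([-1, 1]), size=n)
        for _unit in range(config.init_search_units):
            f = frustration(state, J)
            best_f = min(best_f, f)
            if f <= config.frustration_max:
                break
            state = _run_units(state, J, T, 1.0, no_clamp_mask, no_clamp_vals,
                               config.energy_sign, rng)
        else:
            continue
        if epithelial_score(state, annotation_vec) > config.e_score_start_min:
            return state
    raise ConvergenceError(
        f"no state with frustration <= {config.frustration_max} and epithelial "
        f"score > {config.e_score_start_min} in {config.max_init_attempts} "
        f"attempts (best frustration seen: {best_f})"
    )


def run_clamp_protocol(state0: np.ndarray, J: np.ndarray, annotation_vec: np.ndarray,
                       clamp: ClampSpec, config: BooleanConfig,
                       rng: np.random.Generator, topology: Topology,
                       record_trace: bool = False) -> ProtocolOutcome:
    """Clamp, equilibrate at T for t_c, release, quench, and score.

    Success means the state at the end of the quench phase has epithelial
    score below ``config.m_score_end_max``.
    """
    mask, vals = clamp.arrays(topology)
    no_mask = np.zeros_like(mask)
    no_vals = np.zeros_like(vals)
    if record_trace:
        state = state0.copy()
        state[mask] = vals[mask]
        trace: list[tuple[float, int, int]] = []
        n = state.size
        t_offset = 0.0
        for phase_T, units, m in ((config.T, config.t_c, mask),
                                  (config.quench_T, config.quench_time, no_mask)):
            cspec = ClampSpec({topology.nodes[i]: int(vals[i])
                               for i in np.nonzero(m)[0]})
            for step in range(int(round(units * n))):
                prev = state
                state = metropolis_step(prev, J, phase_T, cspec, rng, topology,
                                        config.energy_sign)
                diff = np.nonzero(state != prev)[0]
                if diff.size:
                    i = int(diff[0])
                    trace.append((t_offset + step / n, i, int(state[i])))
            t_offset += units
        final = state
    else:
        trace = None
        state = _run_units(state0, J, config.T, config.t_c, mask, vals,
                           config.energy_sign, rng)
        final = _run_units(state, J, config.quench_T, config.quench_time,
                           no_mask, no_vals, config.energy_sign, rng)
    success = epithelial_score(final, annotation_vec) < config.m_score_end_max
    return ProtocolOutcome(success=success, final=final, trace=trace)


def mesenchymal_clamp_values(genes: Sequence[str], annotation: NodeAnnotation
                             ) -> list[dict[str, int]]:
    """Candidate clamp assignments driving the network toward M.

    Epithelial genes (+1) are clamped off (-1), mesenchymal genes (-1) are
    clamped on (+1); for unscored genes both values are candidates, so the
    returned list enumerates every combination over the unscored members.
    """
    fixed: dict[str, int] = {}
    free: list[str] = []
    for g in genes:
        s = annotation.score.get(g, 0)
        if s == 1:
            fixed[g] = -1
        elif s == -1:
            fixed[g] = 1
        else:
            free.append(g)
    combos: list[dict[str, int]] = [dict(fixed)]
    for g in free:
        combos = [{**c, g: v} for c in combos for v in (-1, 1)]
    return combos


def screen_clamps(J: np.ndarray, annotation: NodeAnnotation, topology: Topology,
                  node_sets: Sequence[Sequence[str]], config: BooleanConfig,
                  n_runs: int, rng: np.random.Generator) -> pd.DataFrame:
    """Transition-success screen over 1- or 2-node clamp sets.

    Each run draws a fresh low-frustration epithelial initial state, applies
    the clamp protocol, and is scored for a completed transition.  For
    unscored genes both clamp polarities are simulated and the better
    percentage is reported.

    Returns a DataFrame with columns ``node_set``, ``clamp_values``,
    ``n_runs``, ``success_percent``.
    """
    if len(node_sets) == 0:
        raise ValueError("node_sets must be nonempty")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    anno_vec = annotation.vector(topology)
    search_T = config.init_T if config.init_T is not None else config.T
    rows = []
    for genes in node_sets:
        best_pct = -1.0
        best_vals: dict[str, int] = {}
        for values in mesenchymal_clamp_values(list(genes), annotation):
            clamp = ClampSpec(values)
            successes = 0
            for _ in range(n_runs):
                state0 = find_initial_state(J, anno_vec, search_T, config, rng)
                out = run_clamp_protocol(state0, J, anno_vec, clamp, config,
                                         rng, topology)
                successes += int(out.success)
            pct = 100.0 * successes / n_runs
            if pct > best_pct:
                best_pct = pct
                best_vals = values
        rows.append({
            "node_set": ",".join(genes),
            "clamp_values": ",".join(f"{g}:{v:+d}" for g, v in best_vals.items()),
            "n_runs": n_runs,
            "success_percent": best_pct,
        })
    return pd.DataFrame(rows)
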