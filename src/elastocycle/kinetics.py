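"""Driven ring-assembly kinetics on a periodic energy landscape.

M subunits each occupy one of N cyclically ordered conformational states
with reaction coordinate theta(s) = 2 pi s / N. The assembly energy is

    E = sum_m [ dE_el(theta_m) + Ec(theta_m, theta_{m+1}) ],
    Ec(a, b) = (K/M) (1 - cos(b - a - delta)),

a per-state potential (the elastic pseudoenergy landscape, kBT) plus a
Kuramoto-style coupling that favours a phase lag delta between consecutive
subunits (delta = pi/3 keeps a hexamer evenly staggered). One subunit moves
one step at a time; rates obey local detailed balance,

    k_ab = tau^-1 / (1 + exp(E(b) - E(a))),

with driven edges carrying an extra exp(+-delta_mu/2) bias that injects the
chemical free energy of nucleotide exchange. Trajectories are simulated
exactly with the Gillespie algorithm; working units are kBT = 1, tau = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class KineticModel:
    landscape: tuple[float, ...]  # per-state potential, kBT
    M: int = 6
    K: float = 0.0  # coupling strength, kBT
    delta: float = math.pi / 3  # equilibrium phase lag, radians
    delta_mu: float = 0.0  # chemical drive per driven transition, kBT
    tau: float | tuple[float, ...] = 1.0  # scalar or per-edge (s <-> s+1)
    driven_edges: frozenset[int] = frozenset()  # s: s -> s+1 is the driven direction
    kBT: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "landscape", tuple(float(x) for x in self.landscape))
        if self.N < 2:
            raise ValueError("need at least two states per cycle")
        if self.M < 1:
            raise ValueError("need at least one subunit")
        if self.K < 0:
            raise ValueError("coupling strength must be non-negative")
        if isinstance(self.tau, (tuple, list, np.ndarray)):
            taus = tuple(float(t) for t in self.tau)
            if len(taus) != self.N or any(t <= 0 for t in taus):
                raise ValueError("per-edge tau must have length N with positive entries")
            object.__setattr__(self, "tau", taus)
        elif self.tau <= 0:
            raise ValueError("tau must be positive")
        bad = set(self.driven_edges) - set(range(self.N))
        if bad:
            raise ValueError(f"driven edges outside 0..N-1: {sorted(bad)}")
        object.__setattr__(self, "driven_edges", frozenset(int(e) for e in self.driven_edges))

    @property
    def N(self) -> int:
        return len(self.landscape)

    def theta(self, state_index: int) -> float:
        return 2.0 * math.pi * state_index / self.N

    def edge_tau(self, edge: int) -> float:
        if isinstance(self.tau, tuple):
            return self.tau[edge % self.N]
        return float(self.tau)

    def with_landscape(self, landscape: Sequence[float]) -> "KineticModel":
        return KineticModel(
            landscape=tuple(landscape),
            M=self.M,
            K=self.K,
            delta=self.delta,
            delta_mu=self.delta_mu,
            tau=self.tau,
            driven_edges=self.driven_edges,
            kBT=self.kBT,
        )


def coupling_energy(theta_m: float, theta_next: float, model: KineticModel) -> float:
    """Ec between a subunit and its forward neighbour, in [0, 2K/M]."""
    return (model.K / model.M) * (1.0 - math.cos(theta_next - theta_m - model.delta))


def _gamma(dE: float) -> float:
    """(1 + exp(dE))^-1, overflow-safe for arbitrarily large |dE|."""
    if dE > 0:
        e = math.exp(-dE)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(dE))


def _validate_state(state: Sequence[int], model: KineticModel) -> list[int]:
    s = [int(x) for x in state]
    if len(s) != model.M:
        raise ValueError(f"state must have {model.M} entries")
    if any(not 0 <= x < model.N for x in s):
        raise ValueError("state indices must lie in 0..N-1")
    return s


def assembly_energy(state: Sequence[int], model: KineticModel) -> float:
    """Total assembly energy: per-state potentials plus ring coupling.

    Subunit M-1 couples back to subunit 0 (periodic ring indexing).
    """
    s = _validate_state(state, model)
    E = sum(model.landscape[x] for x in s)
    if model.M > 1 and model.K != 0.0:
        for m in range(model.M):
            E += coupling_energy(model.theta(s[m]), model.theta(s[(m + 1) % model.M]), model)
    return E


def _moved_subunit(a: list[int], b: list[int], N: int) -> tuple[int, int]:
    """Index of the single subunit moving one step, and its direction (+-1)."""
    moved = [m for m in range(len(a)) if a[m] != b[m]]
    if len(moved) != 1:
        raise ValueError("states must differ in exactly one subunit")
    m = moved[0]
    if (a[m] + 1) % N == b[m]:
        return m, +1
    if (a[m] - 1) % N == b[m]:
        return m, -1
    raise ValueError("the moving subunit must step to an adjacent state")


def transition_rate(state_a: Sequence[int], state_b: Sequence[int], model: KineticModel) -> float:
    """Rate of the one-subunit transition a -> b.

    k = tau^-1 Gamma, Gamma = (1 + exp((E(b) - E(a))/kBT))^-1, times
    exp(+delta_mu/2 kBT) when a -> b runs along a driven edge and
    exp(-delta_mu/2 kBT) when it runs against one.
    """
    a = _validate_state(state_a, model)
    b = _validate_state(state_b, model)
    m, direction = _moved_subunit(a, b, model.N)
    dE = (assembly_energy(b, model) - assembly_energy(a, model)) / model.kBT
    edge = a[m] if direction == +1 else b[m]
    rate = (1.0 / model.edge_tau(edge)) * _gamma(dE)
    if edge in model.driven_edges:
        rate *= math.exp(direction * model.delta_mu / (2.0 * model.kBT))
    return rate


@dataclass
class Trajectory:
    """Gillespie event history of one simulation run."""

    initial_state: np.ndarray  # (M,)
    times: np.ndarray  # (n_events,) strictly increasing event times
    subunits: np.ndarray  # (n_events,) which subunit moved
    directions: np.ndarray  # (n_events,) +1 forward / -1 backward
    final_state: np.ndarray  # (M,)
    winding: np.ndarray  # (M,) net completed cycles per subunit
    total_time: float
    seed: int | None
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.times)

    def states(self, model: KineticModel) -> np.ndarray:
        """(n_events + 1, M) state matrix: initial state, then after each event."""
        steps = np.zeros((self.n_events, model.M), dtype=np.int64)
        steps[np.arange(self.n_events), self.subunits] = self.directions
        unwrapped = self.initial_state[None, :] + np.concatenate(
            [np.zeros((1, model.M), dtype=np.int64), np.cumsum(steps, axis=0)]
        )
        return unwrapped % model.N

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "subunit": self.subunits, "direction": self.directions}
        )


def gillespie(
    model: KineticModel,
    initial_state: Sequence[int],
    n_events: int | None = None,
    t_max: float | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Statistically exact continuous-time simulation.

    Stops after ``n_events`` events or at time ``t_max``, whichever comes
    first (at least one must be given). After each event only the moved
    subunit's and its two neighbours' rates are recomputed. A state with
    zero total rate terminates the run with ``absorbed=True``.
    """
    if n_events is None and t_max is None:
        raise ValueError("give n_events and/or t_max")
    state = _validate_state(initial_state, model)
    N, M = model.N, model.M
    L = list(model.landscape)
    kBT = model.kBT
    KM = model.K / M
    two_pi_over_N = 2.0 * math.pi / N
    # cosine of (theta difference - delta) on the integer phase grid
    cosd = [math.cos(two_pi_over_N * k - model.delta) for k in range(N)]
    exp_fwd = [
        math.exp(model.delta_mu / (2.0 * kBT)) if s in model.driven_edges else 1.0
        for s in range(N)
    ]
    exp_bwd = [
        math.exp(-model.delta_mu / (2.0 * kBT)) if s in model.driven_edges else 1.0
        for s in range(N)
    ]
    tau_inv = [1.0 / model.edge_tau(s) for s in range(N)]

    def rate(m: int, direction: int) -> float:
        s = state[m]
        s2 = (s + direction) % N
        dE = L[s2] - L[s]
        if M > 1 and KM != 0.0:
            b = state[(m - 1) % M]
            f = state[(m + 1) % M]
            dE += KM * (
                cosd[(s - b) % N]
                - cosd[(s2 - b) % N]
                + cosd[(f - s) % N]
                - cosd[(f - s2) % N]
            )
        edge = s if direction == 1 else s2
        k = tau_inv[edge] * _gamma(dE / kBT)
        return k * (exp_fwd[edge] if direction == 1 else exp_bwd[edge])

    rng = np.random.default_rng(seed)
    rates = [0.0] * (2 * M)  # forward rates at even slots, backward at odd
    for m in range(M):
        rates[2 * m] = rate(m, +1)
        rates[2 * m + 1] = rate(m, -1)

    times: list[float] = []
    moved_subunit: list[int] = []
    moved_dir: list[int] = []
    winding = [0] * M
    t = 0.0
    absorbed = False
    max_events = n_events if n_events is not None else np.iinfo(np.int64).max
    uniforms = rng.random(size=min(max_events, 1_000_000) if n_events else 65536)
    exponentials = rng.exponential(size=len(uniforms))
    cursor = 0

    while len(times) < max_events:
        total = math.fsum(rates)
        if total <= 0.0:
            absorbed = True
            break
        if cursor >= len(uniforms):
            uniforms = rng.random(size=len(uniforms))
            exponentials = rng.exponential(size=len(uniforms))
            cursor = 0
        dt = exponentials[cursor] / total
        if t_max is not None and t + dt > t_max:
            t = t_max
            break
        t += dt
        r = uniforms[cursor] * total
        cursor += 1
        acc = 0.0
        idx = 2 * M - 1
        for i in range(2 * M):
            acc += rates[i]
            if r < acc:
                idx = i
                break
        m, direction = idx // 2, (1 if idx % 2 == 0 else -1)
        s = state[m]
        s2 = (s + direction) % N
        if direction == 1 and s == N - 1:
            winding[m] += 1
        elif direction == -1 and s == 0:
            winding[m] -= 1
        state[m] = s2
        times.append(t)
        moved_subunit.append(m)
        moved_dir.append(direction)
        for neighbour in ({(m - 1) % M, m, (m + 1) % M} if M > 1 else {m}):
            rates[2 * neighbour] = rate(neighbour, +1)
            rates[2 * neighbour + 1] = rate(neighbour, -1)

    if absorbed:
        # an absorbing state dwells until the horizon, if one was set
        total_time = t_max if t_max is not None else t
    elif t_max is not None and len(times) < max_events:
        total_time = min(t, t_max)
    else:
        total_time = t
    return Trajectory(
        initial_state=np.array(_validate_state(initial_state, model)),
        times=np.array(times),
        subunits=np.array(moved_subunit, dtype=np.int64),
        directions=np.array(moved_dir, dtype=np.int64),
        final_state=np.array(state),
        winding=np.array(winding),
        total_time=float(total_time),
        seed=seed,
        absorbed=absorbed,
    )


def default_driven_edges(N: int, n_positions: int = 6) -> frozenset[int]:
    """One driven edge per position block: the last transition of each block.

    For N = 30 with 6 positions this is the block-boundary step (e.g. F5 ->
    E1), the natural site of nucleotide exchange in a hand-over-hand cycle.
    Fully overridable; reproducing a specific system requires its actual
    driven-edge set.
    """
    if N % n_positions:
        raise ValueError(f"N={N} does not divide into {n_positions} blocks")
    block = N // n_positions
    return frozenset(k * block + block - 1 for k in range(n_positions))


def sample_states(trajectory: Trajectory, model: KineticModel, interval: float) -> np.ndarray:
    """Assembly states at regular times k*interval along the trajectory.

    Useful for occupancy statistics where (approximately) independent draws
    are wanted rather than event counts; choose ``interval`` large compared
    to the mixing time.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    states = trajectory.states(model)
    grid = np.arange(interval, trajectory.total_time, interval)
    idx = np.searchsorted(trajectory.times, grid, side="right")
    return states[idx]


def translocation_speed(trajectory: Trajectory, step_size: float = 1.0) -> float:
    """Mean per-subunit winding rate times ``step_size``.

    With step_size=1 the speed is in cycles per time unit; pass the physical
    substrate displacement per completed cycle to convert.
    """
    if trajectory.total_time <= 0:
        raise ValueError("trajectory has zero duration")
    return float(np.mean(trajectory.winding)) / trajectory.total_time * step_size


def occupancy(trajectory: Trajectory, model: KineticModel) -> dict[tuple[int, ...], float]:
    """Time-weighted fraction of time spent in each visited assembly state."""
    states = trajectory.states(model)
    times = np.concatenate([[0.0], trajectory.times, [trajectory.total_time]])
    dwell = np.diff(times)
    weights: dict[tuple[int, ...], float] = {}
    for row, dt in zip(states, dwell):
        if dt <= 0:
            continue
        key = tuple(int(x) for x in row)
        weights[key] = weights.get(key, 0.0) + float(dt)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def boltzmann_distribution(model: KineticModel) -> dict[tuple[int, ...], float]:
    """Exact equilibrium distribution by enumeration (small models only)."""
    n_states = model.N**model.M
    if n_states > 200_000:
        raise ValueError(f"state space of size {n_states} is too large to enumerate")
    states = np.indices((model.N,) * model.M).reshape(model.M, -1).T
    energies = np.array([assembly_energy(s, model) for s in states])
    weights = np.exp(-(energies - energies.min()) / model.kBT)
    weights /= weights.sum()
    return {tuple(int(x) for x in s): float(w) for s, w in zip(states, weights)}


SHUFFLE_MODES = ("ordered", "fully-shuffled", "partially-shuffled")


def shuffle_experiment(
    model: KineticModel,
    mode: str,
    n_samples: int,
    n_events: int = 20_000,
    initial_state: Sequence[int] | None = None,
    seed: int | None = None,
    n_positions: int = 6,
    step_size: float = 1.0,
) -> np.ndarray:
    """Translocation speeds under native, block-shuffled, or fully shuffled
    landscapes.

    "ordered" reruns the native landscape with ``n_samples`` seeds.
    "fully-shuffled" draws a random permutation of all N landscape values
    per sample. "partially-shuffled" keeps the ``n_positions`` position
    blocks in place and permutes the within-block (assembly) order, the same
    permutation in every block; all (N/n_positions)! permutations are
    enumerated when ``n_samples`` covers them, otherwise sampled.
    """
    if mode not in SHUFFLE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {SHUFFLE_MODES}")
    N = model.N
    rng = np.random.default_rng(seed)
    if initial_state is None:
        # evenly staggered start, matching the delta = 2 pi/M lag of a ring
        initial_state = [(m * N // model.M) % N for m in range(model.M)]

    landscapes: list[np.ndarray] = []
    base = np.array(model.landscape)
    if mode == "ordered":
        landscapes = [base] * n_samples
    elif mode == "fully-shuffled":
        landscapes = [rng.permutation(base) for _ in range(n_samples)]
    else:
        if N % n_positions:
            raise ValueError(f"N={N} does not divide into {n_positions} position blocks")
        n_assemblies = N // n_positions
        blocks = base.reshape(n_positions, n_assemblies)
        all_perms = list(permutations(range(n_assemblies)))
        if n_samples >= len(all_perms):
            chosen = all_perms
        else:
            idx = rng.choice(len(all_perms), size=n_samples, replace=False)
            chosen = [all_perms[i] for i in idx]
        landscapes = [blocks[:, list(p)].reshape(-1) for p in chosen]

    speeds = []
    for shuffled in landscapes:
        run_seed = int(rng.integers(0, 2**31 - 1))
        variant = model.with_landscape(shuffled)
        trajectory = gillespie(variant, initial_state, n_events=n_events, seed=run_seed)
        speeds.append(translocation_speed(trajectory, step_size=step_size))
    return np.array(speeds)


def coupling_force(state: Sequence[int], model: KineticModel) -> np.ndarray:
    """Total coupling force on each subunit, positive along the cycle.

    force_m = -d/d theta_m [Ec(theta_{m-1}, theta_m) + Ec(theta_m, theta_{m+1})]
            = (K/M) [sin(theta_{m+1} - theta_m - delta)
                     - sin(theta_m - theta_{m-1} - delta)].
    """
    s = _validate_state(state, model)
    KM = model.K / model.M
    forces = np.zeros(model.M)
    if model.M == 1:
        return forces
    for m in range(model.M):
        th_prev = model.theta(s[(m - 1) % model.M])
        th = model.theta(s[m])
        th_next = model.theta(s[(m + 1) % model.M])
        forces[m] = KM * (
            math.sin(th_next - th - model.delta) - math.sin(th - th_prev - model.delta)
        )
    return forces


def coupling_analysis(trajectory: Trajectory, model: KineticModel) -> pd.DataFrame:
    """Time-weighted mean coupling energies and force per conformation.

    For every conformation a subunit occupied along the trajectory, the
    dwell-time-weighted mean of its backward coupling energy
    Ec(theta_{m-1}, theta_m), forward coupling energy
    Ec(theta_m, theta_{m+1}), and total coupling force. Conformations never
    visited are absent from the result (missing, not zero).
    """
    states = trajectory.states(model)
    times = np.concatenate([[0.0], trajectory.times, [trajectory.total_time]])
    dwell = np.diff(times)
    keep = dwell > 0
    states, dwell = states[keep], dwell[keep]

    N = model.N
    KM = model.K / model.M
    grid = 2.0 * math.pi * np.arange(N) / N
    cos_lag = 1.0 - np.cos(grid - model.delta)  # Ec/(K/M) on the phase grid
    sin_lag = np.sin(grid - model.delta)

    fwd_diff = (np.roll(states, -1, axis=1) - states) % N  # s_{m+1} - s_m
    bwd_diff = (states - np.roll(states, 1, axis=1)) % N  # s_m - s_{m-1}
    ec_fwd = KM * cos_lag[fwd_diff]
    ec_bwd = KM * cos_lag[bwd_diff]
    force = KM * (sin_lag[fwd_diff] - sin_lag[bwd_diff])

    w = np.repeat(dwell, model.M)
    flat_state = states.reshape(-1)
    time_per_state = np.bincount(flat_state, weights=w, minlength=N)
    sums = {
        "backward_Ec": np.bincount(flat_state, weights=(ec_bwd * dwell[:, None]).reshape(-1), minlength=N),
        "forward_Ec": np.bincount(flat_state, weights=(ec_fwd * dwell[:, None]).reshape(-1), minlength=N),
        "force": np.bincount(flat_state, weights=(force * dwell[:, None]).reshape(-1), minlength=N),
    }
    visited = time_per_state > 0
    rows = {
        "state": np.arange(N)[visited],
        "occupancy_time": time_per_state[visited],
    }
    for name, total in sums.items():
        rows[f"mean_{name}"] = total[visited] / time_per_state[visited]
    return pd.DataFrame(rows).set_index("state")
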