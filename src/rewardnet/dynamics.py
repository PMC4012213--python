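"""Coupled rate, feedforward-weight, and recurrent-weight dynamics.

The network integrates three coupled ordinary differential equations with
explicit forward Euler:

    tau_v dv/dt = -v + M . tanh(v) + W u          (rate dynamics)
    tau_W dW/dt = eps * K . W u (r - v)           (reward-modulated Hebbian)
    tau_M dM/dt = (I - M) - (W u) v^T             (Goodall anti-Hebbian)

``u`` and ``r`` are the scalar stimulus and perceived reward at the current
(integer) time step; both are held constant within a step.  The gating
matrix K is defined as ``I - M`` and recomputed after every update of M, so
feedforward learning shuts off exactly when the recurrent weights reach the
identity ("autonomous" units) or when the network's prediction matches the
reward (r = v).  Spikes are a stochastic read-out of the rates — a unit with
rate v fires with probability logistic(v) — and do not feed back into the
rate dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boltzmann import EnergyModel, energy, spike_probability
from .errors import InstabilityError, NumericalStateError, ParameterError, ShapeError
from .stimulus import StimulusRewardPattern


@dataclass
class NetworkState:
    """Instantaneous firing-rate vector and the current time (in time steps)."""

    v: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float).ravel()

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]


@dataclass
class WeightSet:
    """Recurrent matrix M and feedforward weights W (1-D stimulus -> N units)."""

    M: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.W = np.asarray(self.W, dtype=float).ravel()
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ShapeError(f"M must be square, got {self.M.shape}")
        if self.W.shape[0] != self.M.shape[0]:
            raise ShapeError(f"W length {self.W.shape[0]} != N = {self.M.shape[0]}")

    @property
    def n_neurons(self) -> int:
        return self.M.shape[0]

    @property
    def K(self) -> np.ndarray:
        """Reward-learning gate, I - M; zero when the units are autonomous."""
        return np.eye(self.n_neurons) - self.M

    def copy(self) -> "WeightSet":
        return WeightSet(self.M.copy(), self.W.copy())


@dataclass(frozen=True)
class PlasticityParams:
    """Time constants and switches of the coupled dynamics.

    All time constants are in units of stimulus time steps.  ``epsilon`` is
    the associability of the stimulus with the reward, folded into the
    feedforward learning rate.  ``dt`` defaults to one twentieth of the fastest
    time constant.
    """

    tau_v: float = 1.0
    tau_W: float = 20.0
    tau_M: float = 200.0
    epsilon: float = 1.0
    dt: float | None = None
    plastic_W: bool = True
    plastic_M: bool = True
    divergence_bound: float = 1e3

    def __post_init__(self):
        for name in ("tau_v", "tau_W", "tau_M"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.dt is None:
            object.__setattr__(self, "dt", 0.05 * self.min_tau)
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.dt > self.min_tau / 10 + 1e-12:
            raise ParameterError(
                f"dt = {self.dt} too coarse; must be <= min(tau)/10 = {self.min_tau / 10}"
            )

    @property
    def min_tau(self) -> float:
        return min(self.tau_v, self.tau_W, self.tau_M)

    @property
    def substeps(self) -> int:
        """Euler micro-steps per unit time step."""
        return max(1, int(round(1.0 / self.dt)))


@dataclass
class SimulationTrace:
    """Time-indexed record of rates, spikes, energies, and weight snapshots."""

    times: np.ndarray
    v_history: np.ndarray  # (T, N)
    spike_raster: np.ndarray  # (T, N) of 0/1
    energy: np.ndarray  # (T,)
    W_history: np.ndarray | None = None  # (n_snapshots, N)
    M_history: np.ndarray | None = None  # (n_snapshots, N, N)
    snapshot_times: np.ndarray | None = None
    final_weights: WeightSet | None = None
    weights_frozen: bool = False
    condition_label: tuple[str, str] = ("", "")

    @property
    def T(self) -> int:
        return self.v_history.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.v_history.shape[1]


def rate_derivative(state: NetworkState, weights: WeightSet, u: float) -> np.ndarray:
    """dv/dt = (-v + M tanh(v) + W u) / tau_v, without the tau (applied by caller)."""
    v = state.v
    if not np.all(np.isfinite(v)):
        raise NumericalStateError("non-finite entries in rate vector")
    if v.shape[0] != weights.n_neurons:
        raise ShapeError(f"state length {v.shape[0]} != N = {weights.n_neurons}")
    return -v + weights.M @ np.tanh(v) + weights.W * u


def feedforward_derivative(
    weights: WeightSet, u: float, r: float, v: np.ndarray
) -> np.ndarray:
    """dW/dt numerator: K W u, gated elementwise by the prediction error r - v."""
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != weights.n_neurons:
        raise ShapeError(f"v length {v.shape[0]} != N = {weights.n_neurons}")
    return (weights.K @ weights.W) * u * (r - v)


def recurrent_derivative(weights: WeightSet, u: float, v: np.ndarray) -> np.ndarray:
    """dM/dt numerator: (I - M) - outer(W u, v), the Goodall anti-Hebbian rule."""
    v = np.asarray(v, dtype=float).ravel()
    N = weights.n_neurons
    if v.shape[0] != N:
        raise ShapeError(f"v length {v.shape[0]} != N = {N}")
    return (np.eye(N) - weights.M) - np.outer(weights.W * u, v)


def step(
    state: NetworkState,
    weights: WeightSet,
    pattern: StimulusRewardPattern,
    params: PlasticityParams,
) -> tuple[NetworkState, WeightSet]:
    """One forward-Euler micro-step of size dt.

    The stimulus and reward are sampled at the integer time step containing
    the current time.  Inputs are not mutated; K is implicitly recomputed
    from the updated M.  Raises :class:`InstabilityError` if the updated
    rates exceed the divergence guard.
    """
    idx = int(state.t + 1e-9)
    if not (0 <= idx < pattern.T):
        raise ShapeError(f"time {state.t} outside pattern of length {pattern.T}")
    u, r = pattern.u(idx), pattern.r(idx)
    dt = params.dt

    dv = rate_derivative(state, weights, u) / params.tau_v
    v_new = state.v + dt * dv
    W_new, M_new = weights.W, weights.M
    if params.plastic_W:
        dW = params.epsilon * feedforward_derivative(weights, u, r, state.v) / params.tau_W
        W_new = weights.W + dt * dW
    if params.plastic_M:
        dM = recurrent_derivative(weights, u, state.v) / params.tau_M
        M_new = weights.M + dt * dM

    norm = float(np.max(np.abs(v_new)))
    if norm > params.divergence_bound:
        raise InstabilityError(idx, norm, params.divergence_bound)
    return (
        NetworkState(v_new, state.t + dt),
        WeightSet(M_new.copy() if M_new is weights.M else M_new,
                  W_new.copy() if W_new is weights.W else W_new),
    )


def initial_state_near(
    pattern: np.ndarray, flip_fraction: float = 0.05, seed: int | None = None
) -> NetworkState:
    """A state inside the basin of a binary pattern: the pattern with a
    seeded fraction of entries flipped."""
    v = np.asarray(pattern, dtype=float).ravel().copy()
    n_flip = int(round(flip_fraction * v.shape[0]))
    if n_flip > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(v.shape[0], size=n_flip, replace=False)
        v[idx] = 1.0 - v[idx]
    return NetworkState(v, 0.0)


def run_simulation(
    initial: NetworkState,
    weights: WeightSet,
    pattern: StimulusRewardPattern,
    params: PlasticityParams,
    seed: int | None = None,
    sign_convention: str = "hopfield",
    snapshot_every: int | None = 1,
) -> SimulationTrace:
    """Integrate the coupled system over a stimulus-reward pattern.

    At each integer time step the current rates are recorded, a binary spike
    vector is drawn (unit i fires with probability logistic(v_i), seeded),
    and the energy of the rate vector under the current weights and stimulus
    is logged.  Weight snapshots are stored every ``snapshot_every`` recorded
    steps (None disables snapshots).  Inputs are not mutated.
    """
    rng = np.random.default_rng(seed)
    state = NetworkState(initial.v.copy(), 0.0)
    w = weights.copy()
    T, N = pattern.T, w.n_neurons
    substeps = params.substeps
    dt = params.dt

    v_hist = np.empty((T, N))
    raster = np.empty((T, N))
    energies = np.empty(T)
    snaps_W, snaps_M, snap_times = [], [], []
    frozen = not (params.plastic_W or params.plastic_M)

    for t in range(T):
        state.t = float(t)  # avoid floating drift across substeps
        v_hist[t] = state.v
        raster[t] = (rng.random(N) < spike_probability(state.v)).astype(float)
        model = EnergyModel(w.M, w.W, pattern.u(t), sign_convention)
        energies[t] = energy(model, state.v)
        if snapshot_every is not None and t % snapshot_every == 0:
            snaps_W.append(w.W.copy())
            snaps_M.append(w.M.copy())
            snap_times.append(t)
        if t == T - 1:
            break
        for _ in range(substeps):
            state, w = step(state, w, pattern, params)
        state.t = float(t + 1)

    return SimulationTrace(
        times=np.arange(T, dtype=float),
        v_history=v_hist,
        spike_raster=raster,
        energy=energies,
        W_history=np.array(snaps_W) if snaps_W else None,
        M_history=np.array(snaps_M) if snaps_M else None,
        snapshot_times=np.array(snap_times) if snap_times else None,
        final_weights=w,
        weights_frozen=frozen,
        condition_label=pattern.labels,
    )
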