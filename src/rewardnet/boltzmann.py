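"""Glauber spike sampling and Boltzmann energy analysis.

For binary units updated asynchronously with the logistic acceptance rule,
network activity is a Markov chain whose stationary law (for symmetric
recurrent weights) is the Boltzmann distribution P[v] = exp(-E(v)) / Z over
the energy

    E(v, u) = -u * (W . v) - 1/2 * v . M . v        ("hopfield")

The quadratic term can also be taken with the opposite sign
(``sign_convention="as_printed"``); in that convention high-overlap states
are energy maxima, so the hopfield form is the default for all stability
analyses.  Exact enumeration of the distribution is provided for small
networks, and asynchronous heat-bath (Glauber) sampling for any size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .errors import EnumerationTooLargeError, ParameterError, ShapeError

#: largest network for exact 2^N enumeration (~10^6 states)
ENUMERATION_BOUND = 20

SIGN_CONVENTIONS = ("hopfield", "as_printed")


@dataclass(frozen=True)
class EnergyModel:
    """Recurrent matrix M, feedforward weights W, stimulus u, sign convention."""

    M: np.ndarray
    W: np.ndarray
    u: float = 0.0
    sign_convention: str = "hopfield"

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        W = np.asarray(self.W, dtype=float).ravel()
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ShapeError(f"M must be square, got {M.shape}")
        if W.shape[0] != M.shape[0]:
            raise ShapeError(f"W length {W.shape[0]} != N = {M.shape[0]}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ParameterError(f"unknown sign convention {self.sign_convention!r}")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "W", W)

    @property
    def n_neurons(self) -> int:
        return self.M.shape[0]

    @property
    def quad_sign(self) -> float:
        """Sign of the quadratic term in E: -1 for hopfield, +1 as printed."""
        return -1.0 if self.sign_convention == "hopfield" else 1.0


@dataclass(frozen=True)
class StateDistribution:
    """Exact Boltzmann distribution over all 2^N binary states.

    State i has neuron k active iff bit k of i is set (little-endian
    integer bit order).
    """

    energies: np.ndarray
    probabilities: np.ndarray
    Z: float
    sign_convention: str

    @property
    def n_states(self) -> int:
        return self.energies.shape[0]

    def state(self, index: int) -> np.ndarray:
        n = int(np.log2(self.n_states))
        return (index >> np.arange(n)) & 1


def spike_probability(v):
    """Probability that a unit with rate v emits a spike: logistic(v)."""
    return expit(v)


def energy(model: EnergyModel, v: np.ndarray) -> float:
    """Energy of an activity pattern v (binary or rate-valued) under the model."""
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != model.n_neurons:
        raise ShapeError(f"state length {v.shape[0]} != N = {model.n_neurons}")
    lin = -model.u * float(model.W @ v)
    quad = 0.5 * float(v @ model.M @ v)
    return lin + model.quad_sign * quad


def flip_energy_gap(model: EnergyModel, v: np.ndarray, i: int) -> float:
    """Energy change from setting unit i to 1 instead of 0, rest of v fixed."""
    v = np.asarray(v, dtype=float).ravel()
    h_rest = float(model.M[i] @ v) - model.M[i, i] * v[i]
    return -model.u * model.W[i] + model.quad_sign * (h_rest + 0.5 * model.M[i, i])


def _all_states(n: int) -> np.ndarray:
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def exact_distribution(model: EnergyModel, N: int | None = None) -> StateDistribution:
    """Enumerate energies and Boltzmann probabilities over all 2^N states."""
    N = model.n_neurons if N is None else N
    if N != model.n_neurons:
        raise ShapeError(f"requested N={N} but model has {model.n_neurons} neurons")
    if N > ENUMERATION_BOUND:
        raise EnumerationTooLargeError(
            f"N={N} exceeds enumeration bound {ENUMERATION_BOUND}"
        )
    states = _all_states(N)
    lin = -model.u * (states @ model.W)
    quad = 0.5 * np.einsum("ij,ij->i", states @ model.M, states)
    energies = lin + model.quad_sign * quad
    logZ = logsumexp(-energies)
    probabilities = np.exp(-energies - logZ)
    return StateDistribution(energies, probabilities, float(np.exp(logZ)), model.sign_convention)


def glauber_sample(
    model: EnergyModel,
    v0: np.ndarray,
    sweeps: int,
    seed: int | None = None,
) -> np.ndarray:
    """Asynchronous heat-bath sampling of the binary network.

    One randomly chosen unit is updated per micro-step, N micro-steps per
    sweep; the chosen unit is set to 1 with probability
    ``logistic(-(E(v_i=1) - E(v_i=0)))``, the heat-bath rule whose
    stationary law is the model's Boltzmann distribution when M is
    symmetric.  Returns the state after each sweep as a (sweeps, N) array.
    """
    if sweeps < 1:
        raise ParameterError("sweeps must be >= 1")
    v = np.asarray(v0, dtype=float).ravel().copy()
    N = model.n_neurons
    if v.shape[0] != N:
        raise ShapeError(f"v0 length {v.shape[0]} != N = {N}")
    rng = np.random.default_rng(seed)
    units = rng.integers(0, N, size=sweeps * N)
    uniforms = rng.random(size=sweeps * N)
    s = model.quad_sign
    M = model.M
    Wu = model.u * model.W
    diag = np.diag(M)
    h = M @ v  # running local fields, includes self-term
    out = np.empty((sweeps, N))
    k = 0
    for sweep in range(sweeps):
        for _ in range(N):
            i = units[k]
            h_rest = h[i] - diag[i] * v[i]
            gap = -Wu[i] + s * (h_rest + 0.5 * diag[i])
            new = 1.0 if uniforms[k] < expit(-gap) else 0.0
            if new != v[i]:
                h += (new - v[i]) * M[:, i]
                v[i] = new
            k += 1
        out[sweep] = v
    return out


def empirical_frequencies(samples: np.ndarray) -> np.ndarray:
    """Empirical state frequencies of binary samples, indexed by integer bit order."""
    samples = np.asarray(samples)
    n = samples.shape[1]
    idx = (samples.astype(np.int64) @ (1 << np.arange(n, dtype=np.int64)))
    return np.bincount(idx, minlength=2**n) / samples.shape[0]


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two distributions on the same support."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def write_distribution_csv(dist: StateDistribution, path: str | Path) -> Path:
    """Dump a state distribution as CSV (state-index, energy, probability)."""
    path = Path(path)
    pd.DataFrame(
        {
            "state_index": np.arange(dist.n_states),
            "energy": dist.energies,
            "probability": dist.probabilities,
        }
    ).to_csv(path, index=False)
    return path
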