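"""Embedding binary memory patterns into the recurrent matrix.

A finite set of binary patterns is written into the symmetric recurrent
matrix with the sparse covariance (Tsodyks-Feigel'man-style) rule

    M_ij = 1 / ((1 - alpha) * alpha * P) * sum_O (a_i^O - alpha)(a_j^O - alpha)
           - 1 / (alpha * P)

where ``alpha`` is the mean activity (sparseness) of the patterns and P the
pattern count.  The trailing term is a uniform inhibitory offset applied to
every entry; a diagonal-only variant is kept behind ``uniform_offset=False``.
Self-connections are zeroed by default, the usual choice for Hopfield-type
stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyMemoriesError, ParameterError, ShapeError


@dataclass(frozen=True)
class MemorySet:
    """Binary patterns plus the sparseness used to centre the covariance rule."""

    patterns: np.ndarray  # (P, N) of 0/1
    alpha: float

    def __post_init__(self):
        pats = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if pats.size == 0 or pats.shape[0] < 1:
            raise EmptyMemoriesError("memory set must contain at least one pattern")
        if not np.isin(pats, (0.0, 1.0)).all():
            raise ParameterError("memory patterns must be binary 0/1")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        object.__setattr__(self, "patterns", pats)

    @property
    def count(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.patterns.shape[1]


@dataclass(frozen=True)
class RecurrentMatrix:
    """Symmetric recurrent connection matrix with provenance flags."""

    M: np.ndarray
    zero_diagonal: bool

    @property
    def n_neurons(self) -> int:
        return self.M.shape[0]


def empirical_alpha(patterns: np.ndarray) -> float:
    """Mean activity of a pattern array, clipped away from the open-interval ends."""
    a = float(np.mean(patterns))
    if not (0.0 < a < 1.0):
        raise ParameterError(
            "patterns are all-zero or all-one; alpha must be supplied explicitly"
        )
    return a


def make_memory_set(patterns: np.ndarray, alpha: float | None = None) -> MemorySet:
    """Wrap patterns in a :class:`MemorySet`, defaulting alpha to mean activity."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if alpha is None:
        alpha = empirical_alpha(patterns)
    return MemorySet(patterns, alpha)


def random_memory_set(
    n_neurons: int,
    n_patterns: int,
    density: float = 0.25,
    seed: int | None = None,
    alpha: float | None = None,
) -> MemorySet:
    """Draw sparse random binary patterns with a fixed number of active units.

    Each pattern has exactly ``round(density * n_neurons)`` active neurons
    (at least one), chosen uniformly without replacement, so the empirical
    sparseness is identical across patterns.
    """
    rng = np.random.default_rng(seed)
    k = max(1, int(round(density * n_neurons)))
    if k >= n_neurons:
        raise ParameterError("density leaves no inactive neurons")
    pats = np.zeros((n_patterns, n_neurons))
    for p in range(n_patterns):
        pats[p, rng.choice(n_neurons, size=k, replace=False)] = 1.0
    return make_memory_set(pats, alpha)


def embed_memories(
    mem: MemorySet,
    zero_diagonal: bool = True,
    uniform_offset: bool = True,
) -> RecurrentMatrix:
    """Construct the symmetric recurrent matrix from a memory set.

    With ``uniform_offset`` the global inhibition ``-1/(alpha P)`` is
    subtracted from every entry; otherwise only from the diagonal.  With
    ``zero_diagonal`` self-connections are removed after construction.
    """
    a = mem.patterns
    P, N = a.shape
    alpha = mem.alpha
    centered = a - alpha
    M = centered.T @ centered / ((1.0 - alpha) * alpha * P)
    offset = 1.0 / (alpha * P)
    if uniform_offset:
        M = M - offset
    else:
        M[np.diag_indices(N)] -= offset
    if zero_diagonal:
        np.fill_diagonal(M, 0.0)
    return RecurrentMatrix(M, zero_diagonal)


def check_fixed_point(
    M: RecurrentMatrix | np.ndarray,
    pattern: np.ndarray,
    mode: str = "energy",
) -> tuple[bool, dict]:
    """Test whether a binary pattern is stable under the recurrent matrix.

    ``mode="deterministic"``: one synchronous threshold update
    ``v' = [M v > 0]`` must reproduce the pattern (units with exactly zero
    field keep their state).

    ``mode="energy"``: the pattern's energy ``-1/2 v M v`` (no stimulus) must
    not exceed that of any single-bit-flip neighbour; ties count as stable.

    Returns ``(stable, diagnostics)``; diagnostics list the violating units
    (deterministic) or the lower-energy neighbours and energy gaps (energy).
    """
    Mmat = M.M if isinstance(M, RecurrentMatrix) else np.asarray(M, dtype=float)
    v = np.asarray(pattern, dtype=float).ravel()
    if v.shape[0] != Mmat.shape[0]:
        raise ShapeError(
            f"pattern length {v.shape[0]} != matrix dimension {Mmat.shape[0]}"
        )
    if mode == "deterministic":
        h = Mmat @ v
        updated = np.where(h > 0, 1.0, np.where(h < 0, 0.0, v))
        bad = np.flatnonzero(updated != v)
        return bad.size == 0, {"changed_units": bad}
    if mode != "energy":
        raise ParameterError(f"unknown mode {mode!r}")
    # energy of the pattern and of every single-flip neighbour, u = 0
    e0 = -0.5 * v @ Mmat @ v
    h = Mmat @ v
    flips = 1.0 - 2.0 * v  # +1 where v=0, -1 where v=1
    # E(flip i) - E(v) = -(h_i + 0.5 * M_ii * flip_i) * flip_i
    gaps = -(h + 0.5 * np.diag(Mmat) * flips) * flips
    lower = np.flatnonzero(gaps < -1e-12)
    return lower.size == 0, {
        "energy": e0,
        "neighbour_gaps": gaps,
        "lower_energy_neighbours": lower,
    }


def read_patterns_csv(path: str | Path) -> np.ndarray:
    """Read memory patterns from CSV, one pattern per row of 0/1."""
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))


def write_patterns_csv(patterns: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.atleast_2d(patterns), delimiter=",", fmt="%d")
    return path
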