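"""Raster similarity, shuffle nulls, and energy summaries.

Two rasters are compared by treating each neuron's spike train (one row of
the N x T view) as a vector and averaging the cosine of the angle between
corresponding rows:

    q_ab = 1/N * sum_n  v_{n,a} . v_{n,b} / (||v_{n,a}|| ||v_{n,b}||)

For binary non-negative data q lies in [0, 1]; q(a, a) = 1 for every raster,
including rasters with silent neurons (two silent rows are identical, so
their cosine is defined as 1; a silent row against an active one scores 0).
Significance of a change in q is judged against an empirical null built by
permuting neuron-row identities across the pooled rasters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .boltzmann import EnergyModel, energy
from .dynamics import SimulationTrace
from .errors import InsufficientRecordError, ParameterError, ShapeError
from .stimulus import StimulusRewardPattern


@dataclass(frozen=True)
class Raster:
    """Binary spike raster, stored time-major (T x N); rows() is the N x T view."""

    values: np.ndarray
    condition_label: tuple[str, str] = ("", "")

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ParameterError("raster entries must be 0/1")
        object.__setattr__(self, "values", v.astype(float))

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def rows(self) -> np.ndarray:
        """Per-neuron spike trains, one row per neuron (N x T)."""
        return self.values.T


def raster_from_trace(trace: SimulationTrace) -> Raster:
    return Raster(trace.spike_raster, trace.condition_label)


@dataclass(frozen=True)
class SimilarityResult:
    q: float
    per_row_cosines: np.ndarray
    n_zero_pairs: int


@dataclass(frozen=True)
class NullDistribution:
    """Null of |change in q| under row-identity shuffling, with its ECDF."""

    shuffled_q_changes: np.ndarray
    ecdf: Callable[[float], float]
    threshold_percentile: float
    threshold_value: float
    n_shuffles: int
    seed: int | None


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labelled pairwise q matrix; flags mark cells whose deviation from
    baseline self-similarity (1 - q) exceeds a null threshold."""

    labels: tuple[str, ...]
    q: np.ndarray
    flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=list(self.labels), columns=list(self.labels))


def _row_cosines(rows_a: np.ndarray, rows_b: np.ndarray) -> tuple[np.ndarray, int]:
    # single sqrt of the product of squared norms: exact for binary rows,
    # so a row against itself scores exactly 1
    na2 = np.einsum("ij,ij->i", rows_a, rows_a)
    nb2 = np.einsum("ij,ij->i", rows_b, rows_b)
    both_zero = (na2 == 0) & (nb2 == 0)
    one_zero = (na2 == 0) ^ (nb2 == 0)
    denom = np.where((na2 == 0) | (nb2 == 0), 1.0, np.sqrt(na2 * nb2))
    cos = np.einsum("ij,ij->i", rows_a, rows_b) / denom
    cos[both_zero] = 1.0  # identical silence
    cos[one_zero] = 0.0
    return cos, int(both_zero.sum())


def similarity(a: Raster, b: Raster) -> SimilarityResult:
    """Mean row-wise cosine similarity between two rasters."""
    if a.values.shape != b.values.shape:
        raise ShapeError(f"raster shapes differ: {a.values.shape} vs {b.values.shape}")
    cos, n_zero = _row_cosines(a.rows(), b.rows())
    return SimilarityResult(float(cos.mean()), cos, n_zero)


def _pooled_rows(rasters: Sequence[Raster]) -> np.ndarray:
    return np.vstack([r.rows() for r in rasters])


def _q_against_reference(
    pooled: np.ndarray, shapes: Sequence[int], reference: Raster
) -> np.ndarray:
    """q of each raster (concatenated in `pooled`, rows per raster in `shapes`)
    against the reference."""
    ref_rows = reference.rows()
    out = np.empty(len(shapes))
    start = 0
    for k, n in enumerate(shapes):
        cos, _ = _row_cosines(pooled[start : start + n], ref_rows)
        out[k] = cos.mean()
        start += n
    return out


def shuffle_null(
    rasters: Sequence[Raster],
    reference: Raster,
    n_shuffles: int = 10_000,
    percentile: float = 85.0,
    seed: int | None = None,
    exhaustive: bool = False,
) -> NullDistribution:
    """Build the permutation null of |change in q| under row shuffling.

    Neuron-row identities are permuted across the pooled rasters; after each
    permutation the q of every (reshuffled) raster against the reference is
    recomputed and the magnitude of its change from the unshuffled value is
    recorded.  The threshold is the requested percentile of that empirical
    distribution.  With ``exhaustive`` every permutation of the pooled rows
    is enumerated instead of sampled (only sensible for tiny rasters).
    """
    if not exhaustive and n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    N = reference.n_neurons
    for r in rasters:
        if r.values.shape != reference.values.shape:
            raise ShapeError("all rasters must share the reference's shape")
    pooled = _pooled_rows(rasters)
    shapes = [N] * len(rasters)
    q0 = _q_against_reference(pooled, shapes, reference)

    changes = []
    if exhaustive:
        perms = itertools.permutations(range(pooled.shape[0]))
    else:
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(pooled.shape[0]) for _ in range(n_shuffles))
    n_done = 0
    for perm in perms:
        q = _q_against_reference(pooled[list(perm)], shapes, reference)
        changes.append(np.abs(q - q0))
        n_done += 1
    changes = np.concatenate(changes)
    sorted_changes = np.sort(changes)

    def ecdf(x: float) -> float:
        return float(np.searchsorted(sorted_changes, x, side="right")) / sorted_changes.size

    threshold = float(np.percentile(changes, percentile))
    return NullDistribution(changes, ecdf, percentile, threshold, n_done, seed)


def similarity_heatmap(
    rasters: Sequence[Raster],
    null: NullDistribution | None = None,
) -> SimilarityMatrix:
    """Pairwise q between all rasters (conditions plus baseline).

    If a null distribution is given, cells whose deviation from baseline
    self-similarity (1 - q) exceeds the null threshold are flagged.
    """
    labels = tuple("_".join(filter(None, r.condition_label)) or f"raster{k}"
                   for k, r in enumerate(rasters))
    n = len(rasters)
    q = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            q[i, j] = q[j, i] = similarity(rasters[i], rasters[j]).q
    flags = None
    if null is not None:
        flags = (1.0 - q) > null.threshold_value
    return SimilarityMatrix(labels, q, flags)


def energy_trajectory(
    trace: SimulationTrace,
    pattern: StimulusRewardPattern | None = None,
    sign_convention: str = "hopfield",
) -> np.ndarray:
    """Recompute the per-step energy of the recorded rates under the recorded
    weights and stimulus.

    Requires either frozen weights or per-step weight snapshots; raises
    :class:`InsufficientRecordError` otherwise.  With no pattern the
    stimulus is taken as zero throughout.
    """
    T = trace.T
    per_step_snaps = (
        trace.snapshot_times is not None and len(trace.snapshot_times) == T
    )
    if not (trace.weights_frozen or per_step_snaps):
        raise InsufficientRecordError(
            "trace lacks per-step weight snapshots and weights were plastic"
        )
    out = np.empty(T)
    for t in range(T):
        if per_step_snaps:
            M, W = trace.M_history[t], trace.W_history[t]
        else:
            M, W = trace.final_weights.M, trace.final_weights.W
        u = pattern.u(t) if pattern is not None else 0.0
        out[t] = energy(EnergyModel(M, W, u, sign_convention), trace.v_history[t])
    return out


# ---------------------------------------------------------------------------
# writers and figures


def write_similarity_csv(sim: SimilarityMatrix, path: str | Path) -> Path:
    path = Path(path)
    sim.to_frame().to_csv(path)
    return path


def write_null_csv(null: NullDistribution, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"abs_q_change": null.shuffled_q_changes}).to_csv(path, index=False)
    return path


def plot_raster_grid(
    traces: Sequence[SimulationTrace],
    patterns: Sequence[StimulusRewardPattern],
    path: str | Path,
):
    """Per-condition panels: spike raster with the stimulus and reward below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(traces)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows * 3, ncols, figsize=(4 * ncols, 3.2 * nrows),
                             squeeze=False,
                             gridspec_kw={"height_ratios": [3, 1, 1] * nrows})
    for k, (trace, pat) in enumerate(zip(traces, patterns)):
        col, block = k % ncols, (k // ncols) * 3
        ax_r, ax_u, ax_rew = (axes[block + i][col] for i in range(3))
        ax_r.imshow(trace.spike_raster.T, aspect="auto", cmap="Greys",
                    interpolation="nearest")
        ax_r.set_title("/".join(trace.condition_label), fontsize=9)
        ax_r.set_ylabel("neuron")
        ax_u.step(np.arange(pat.T), pat.stimulus.values, where="post")
        ax_u.set_ylabel("u")
        ax_rew.plot(np.arange(pat.T), pat.reward)
        ax_rew.set_ylabel("r")
        ax_rew.set_xlabel("time step")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_similarity_heatmap(sim: SimilarityMatrix, path: str | Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.1 * len(sim.labels) + 2, 1.0 * len(sim.labels) + 1.5))
    im = ax.imshow(sim.q, vmin=0, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(sim.labels)), sim.labels, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(sim.labels)), sim.labels, fontsize=8)
    for i in range(sim.q.shape[0]):
        for j in range(sim.q.shape[1]):
            mark = "*" if sim.flags is not None and sim.flags[i, j] else ""
            ax.text(j, i, f"{sim.q[i, j]:.2f}{mark}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_energy_trajectories(
    energies: dict[str, np.ndarray], path: str | Path
):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    styles = ["-", "--", "-."]
    fig, ax = plt.subplots(figsize=(7, 4))
    for k, (label, e) in enumerate(energies.items()):
        ax.plot(e, styles[k % len(styles)], label=label)
    ax.set_xlabel("time step")
    ax.set_ylabel("energy (arbitrary units)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
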