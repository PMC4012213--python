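"""Stimulus templates, reward-salience kernels, and their convolutions.

Drug-use histories are modelled as binary stimulus trains: a single pulse
("exposure", initiation), a tonic train ("chronic", continual use), and a
train that switches off partway through ("cessation").  Each train is paired
with a reward-salience kernel describing how strongly a unit of stimulus is
experienced as rewarding over time: a right-skewed log-Gaussian for
susceptible individuals (fast rise, long tail) and a symmetric Gaussian for
resilient ones (slower, softer).  The perceived reward r(t) delivered to the
network is the causal convolution of the stimulus train with the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ParameterError, ShapeError, UnsupportedTemplateError

STIMULUS_KINDS = ("exposure", "chronic", "cessation")
KERNEL_KINDS = ("gaussian", "loggaussian")

#: default trial length in time steps
DEFAULT_T = 200

#: default template timing: pulse onset / width, cessation offset
DEFAULT_ONSET = 10
DEFAULT_PULSE_WIDTH = 10
DEFAULT_OFFSET = 100

#: default kernel shape parameters
DEFAULT_KERNEL_PARAMS = {
    "gaussian": {"mu": 20.0, "sigma": 4.0},
    "loggaussian": {"mu_log": float(np.log(10.0)), "sigma_log": 0.8},
}

#: susceptibility label -> kernel kind
SUSCEPTIBILITY_KERNELS = {"susceptible": "loggaussian", "resilient": "gaussian"}


@dataclass(frozen=True)
class StimulusTemplate:
    """A binary stimulus train of length T."""

    kind: str
    values: np.ndarray
    onset: int
    offset: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ParameterError("stimulus values must be binary 0/1")
        object.__setattr__(self, "values", v.astype(float))

    @property
    def T(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RewardKernel:
    """A nonnegative, peak-normalized reward-salience kernel of length T."""

    kind: str
    values: np.ndarray
    params: Mapping[str, float]

    @property
    def T(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StimulusRewardPattern:
    """Paired stimulus u(t) and perceived reward r(t) over T steps."""

    stimulus: StimulusTemplate
    reward: np.ndarray
    labels: tuple[str, str] = field(default=("", ""))  # (usage, susceptibility)

    @property
    def T(self) -> int:
        return self.stimulus.T

    def u(self, t: int) -> float:
        return float(self.stimulus.values[t])

    def r(self, t: int) -> float:
        return float(self.reward[t])


def make_stimulus(
    kind: str,
    T: int = DEFAULT_T,
    onset: int = DEFAULT_ONSET,
    pulse_width: int = DEFAULT_PULSE_WIDTH,
    offset: int = DEFAULT_OFFSET,
) -> StimulusTemplate:
    """Build one of the three binary stimulus templates.

    Parameters
    ----------
    kind
        ``"exposure"`` (single pulse of ``pulse_width`` steps at ``onset``),
        ``"chronic"`` (ON from ``onset`` to the end), or ``"cessation"``
        (ON from ``onset`` to ``offset - 1``, OFF after).
    T
        Trial length in time steps.
    """
    if kind not in STIMULUS_KINDS:
        raise UnsupportedTemplateError(f"unknown stimulus kind {kind!r}")
    if not (0 <= onset < T):
        raise BoundsError(f"onset {onset} outside [0, {T})")
    values = np.zeros(T)
    if kind == "exposure":
        if pulse_width < 1 or onset + pulse_width > T:
            raise BoundsError(f"pulse [{onset}, {onset + pulse_width}) outside [0, {T}]")
        values[onset : onset + pulse_width] = 1.0
        return StimulusTemplate(kind, values, onset)
    if kind == "chronic":
        values[onset:] = 1.0
        return StimulusTemplate(kind, values, onset)
    # cessation
    if not (onset < offset <= T):
        raise BoundsError(f"offset {offset} must satisfy onset < offset <= {T}")
    values[onset:offset] = 1.0
    return StimulusTemplate(kind, values, onset, offset)


def make_kernel(kind: str, T: int = DEFAULT_T, params: Mapping[str, float] | None = None) -> RewardKernel:
    """Build a peak-normalized reward-salience kernel on integer steps 0..T-1.

    ``"gaussian"`` takes ``mu``/``sigma``; ``"loggaussian"`` takes
    ``mu_log``/``sigma_log`` (parameters of the underlying normal of log t).
    The kernel is sampled on the integer grid and divided by its maximum, so
    the peak salience is 1 in arbitrary reward units.
    """
    if kind not in KERNEL_KINDS:
        raise UnsupportedTemplateError(f"unknown kernel kind {kind!r}")
    p = dict(DEFAULT_KERNEL_PARAMS[kind])
    if params:
        p.update(params)
    t = np.arange(T, dtype=float)
    if kind == "gaussian":
        if p["sigma"] <= 0:
            raise ParameterError("sigma must be > 0")
        values = np.exp(-0.5 * ((t - p["mu"]) / p["sigma"]) ** 2)
    else:
        if p["sigma_log"] <= 0:
            raise ParameterError("sigma_log must be > 0")
        values = np.zeros(T)
        pos = t > 0
        logt = np.log(t[pos])
        values[pos] = np.exp(-0.5 * ((logt - p["mu_log"]) / p["sigma_log"]) ** 2) / t[pos]
    peak = values.max()
    if peak <= 0:
        raise ParameterError("kernel is identically zero on the sampling grid")
    return RewardKernel(kind, values / peak, p)


def convolve_pattern(stim: StimulusTemplate, kernel: RewardKernel) -> StimulusRewardPattern:
    """Causally convolve a stimulus train with a reward kernel.

    The perceived reward is ``r[t] = sum_{s<=t} u[s] * kernel[t-s]``: the
    "full" discrete convolution truncated to the first T samples, so reward
    can never precede its stimulus.
    """
    if stim.T != kernel.T:
        raise ShapeError(f"stimulus length {stim.T} != kernel length {kernel.T}")
    reward = np.convolve(stim.values, kernel.values)[: stim.T]
    return StimulusRewardPattern(stim, reward)


def make_condition_grid(
    T: int = DEFAULT_T,
    params: Mapping | None = None,
) -> list[StimulusRewardPattern]:
    """Build the full 3 (usage) x 2 (susceptibility) grid of input patterns.

    ``params`` may override ``onset``, ``pulse_width``, ``offset`` and the
    per-kernel shape parameters (keys ``gaussian`` / ``loggaussian``).
    Returns six labelled patterns ordered usage-major:
    (exposure|chronic|cessation) x (susceptible|resilient).
    """
    params = dict(params or {})
    onset = int(params.get("onset", DEFAULT_ONSET))
    pulse_width = int(params.get("pulse_width", DEFAULT_PULSE_WIDTH))
    offset = int(params.get("offset", DEFAULT_OFFSET))
    kernels = {
        label: make_kernel(kind, T, params.get(kind))
        for label, kind in SUSCEPTIBILITY_KERNELS.items()
    }
    grid = []
    for usage in STIMULUS_KINDS:
        stim = make_stimulus(usage, T, onset=onset, pulse_width=pulse_width, offset=offset)
        for susceptibility in ("susceptible", "resilient"):
            pat = convolve_pattern(stim, kernels[susceptibility])
            grid.append(
                StimulusRewardPattern(pat.stimulus, pat.reward, (usage, susceptibility))
            )
    return grid


def zero_pattern(T: int = DEFAULT_T) -> StimulusRewardPattern:
    """A baseline pattern with no stimulus and no reward."""
    stim = StimulusTemplate("exposure", np.zeros(T), onset=0)
    return StimulusRewardPattern(stim, np.zeros(T), ("baseline", "none"))


def write_pattern_csv(pattern: StimulusRewardPattern, path: str | Path) -> Path:
    """Write one grid cell as CSV with columns time, stimulus, reward."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": np.arange(pattern.T),
            "stimulus": pattern.stimulus.values.astype(int),
            "reward": pattern.reward,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_condition_grid(grid: Sequence[StimulusRewardPattern], out_dir: str | Path) -> list[Path]:
    """Write every pattern of a grid as ``<usage>_<susceptibility>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        write_pattern_csv(p, out_dir / f"{p.labels[0]}_{p.labels[1]}.csv") for p in grid
    ]
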