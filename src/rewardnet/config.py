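"""Experiment configuration: defaults, YAML loading, validation.

Every experiment is fully described by one nested configuration (network,
memories, stimulus, analysis blocks plus a top-level seed).  Unspecified
keys resolve to package defaults, and the fully resolved copy is written to
the run manifest so any run can be reproduced from its output directory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ParameterError

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "network": {
        "n_neurons": 64,
        "tau_v": 1.0,
        "tau_W": 20.0,
        "tau_M": 200.0,
        "epsilon": 0.002,
        "dt": None,  # resolved to 0.05 * min(tau)
        "w_init": 0.05,
        "divergence_bound": 1.0e3,
        "flip_fraction": 0.05,
    },
    "memories": {
        "patterns_file": None,  # CSV, one 0/1 pattern per row; overrides generator
        "n_patterns": 16,
        "density": 0.25,
        "alpha": None,  # default: empirical mean activity
        "zero_diagonal": True,
        "uniform_offset": True,
    },
    "stimulus": {
        "T": 200,
        "onset": 10,
        "pulse_width": 10,
        "offset": 100,
        "gaussian": {"mu": 20.0, "sigma": 4.0},
        "loggaussian": {"mu_log": 2.302585092994046, "sigma_log": 0.8},
    },
    "analysis": {
        "n_shuffles": 10_000,
        "percentile": 85.0,
        "sign_convention": "hopfield",
        "snapshot_every": 1,
    },
}


def _deep_update(base: dict, extra: Mapping) -> dict:
    for key, value in extra.items():
        if (
            key in base
            and isinstance(base[key], dict)
            and isinstance(value, Mapping)
        ):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


@dataclass
class ExperimentConfig:
    """Resolved experiment configuration (all defaults filled in)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))
    output_dir: Path | None = None

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @classmethod
    def from_mapping(cls, mapping: Mapping | None, output_dir=None) -> "ExperimentConfig":
        data = copy.deepcopy(DEFAULT_CONFIG)
        if mapping:
            _deep_update(data, mapping)
        return cls(data, Path(output_dir) if output_dir else None)

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir=None) -> "ExperimentConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ParameterError(f"config file {path} must contain a mapping")
        return cls.from_mapping(loaded, output_dir)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)
        return path


def validate_config(config: ExperimentConfig) -> list[str]:
    """Check a configuration without running anything; returns findings."""
    findings: list[str] = []
    net = config["network"]
    taus = [net["tau_v"], net["tau_W"], net["tau_M"]]
    if any(t <= 0 for t in taus):
        findings.append("all time constants must be > 0")
    else:
        min_tau = min(taus)
        dt = net["dt"]
        if dt is not None:
            if dt <= 0:
                findings.append("dt must be > 0")
            elif dt > min_tau / 10 + 1e-12:
                findings.append(
                    f"dt = {dt} violates the dt <= min(tau)/10 rule (min tau = {min_tau})"
                )
    if net["n_neurons"] < 2:
        findings.append("n_neurons must be >= 2")
    mem = config["memories"]
    alpha = mem["alpha"]
    if alpha is not None and not (0.0 < alpha < 1.0):
        findings.append(f"alpha = {alpha} outside the open interval (0, 1)")
    if mem["patterns_file"] is None:
        if mem["n_patterns"] < 1:
            findings.append("n_patterns must be >= 1")
        if not (0.0 < mem["density"] < 1.0):
            findings.append("memory density must lie in (0, 1)")
    stim = config["stimulus"]
    T = stim["T"]
    if T < 2:
        findings.append("T must be >= 2")
    else:
        if not (0 <= stim["onset"] < T):
            findings.append(f"onset {stim['onset']} outside [0, {T})")
        if not (stim["onset"] < stim["offset"] <= T):
            findings.append(f"offset {stim['offset']} must satisfy onset < offset <= T")
        if stim["pulse_width"] < 1 or stim["onset"] + stim["pulse_width"] > T:
            findings.append("exposure pulse extends outside the trial window")
    if stim["gaussian"]["sigma"] <= 0:
        findings.append("gaussian sigma must be > 0")
    if stim["loggaussian"]["sigma_log"] <= 0:
        findings.append("loggaussian sigma_log must be > 0")
    ana = config["analysis"]
    if ana["n_shuffles"] < 100:
        findings.append("n_shuffles must be >= 100 for a usable null")
    if not (0.0 < ana["percentile"] < 100.0):
        findings.append("percentile must lie in (0, 100)")
    if ana["sign_convention"] not in ("hopfield", "as_printed"):
        findings.append(f"unknown sign_convention {ana['sign_convention']!r}")
    return findings
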