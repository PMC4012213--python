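"""End-to-end experiment driver: embed -> simulate the condition grid -> analyze.

One experiment runs the network against the full 3 x 2 grid of stimulus-
reward conditions (exposure/chronic/cessation x susceptible/resilient) plus
a no-stimulus baseline, all starting from the same initial state inside the
basin of the first embedded pattern, then summarizes the results with the
raster-similarity heatmap, its shuffle null, and per-condition energy
trajectories.  A single top-level seed deterministically derives per-stage
seeds, and every output file is listed with a checksum in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    NullDistribution,
    Raster,
    SimilarityMatrix,
    plot_energy_trajectories,
    plot_raster_grid,
    plot_similarity_heatmap,
    raster_from_trace,
    shuffle_null,
    similarity,
    similarity_heatmap,
    write_null_csv,
    write_similarity_csv,
)
from .config import ExperimentConfig, validate_config
from .dynamics import (
    NetworkState,
    PlasticityParams,
    SimulationTrace,
    WeightSet,
    initial_state_near,
    run_simulation,
)
from .errors import StagedError
from .memories import embed_memories, make_memory_set, random_memory_set, read_patterns_csv
from .stimulus import make_condition_grid, write_pattern_csv, zero_pattern

STAGES = ("memories", "initial_state", "baseline", "conditions", "shuffle")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Derive one independent sub-seed per pipeline stage from the top seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


@dataclass
class ExperimentResult:
    """In-memory results of one experiment (the manifest's computational half)."""

    config: ExperimentConfig
    stage_seeds: dict[str, int]
    memory_patterns: np.ndarray
    baseline: SimulationTrace
    traces: list[SimulationTrace]
    patterns: list
    q_to_baseline: dict[str, float]
    heatmap: SimilarityMatrix
    null: NullDistribution
    energies: dict[str, np.ndarray]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    write_figures: bool = True,
) -> ExperimentResult:
    """Run the full condition grid and its analysis.

    With ``out_dir`` set, writes one directory per condition (raster, rates,
    energy, input CSVs), an ``analysis/`` directory (similarity matrix, null
    distribution, per-condition energies, figures), and ``manifest.json``.
    """
    findings = validate_config(config)
    if findings:
        raise StagedError("validate", "; ".join(findings))
    seeds = derive_stage_seeds(config.seed)
    net, mem_cfg, stim_cfg, ana = (
        config["network"], config["memories"], config["stimulus"], config["analysis"]
    )

    # --- embed memories -----------------------------------------------------
    try:
        if mem_cfg["patterns_file"]:
            mem = make_memory_set(read_patterns_csv(mem_cfg["patterns_file"]),
                                  mem_cfg["alpha"])
        else:
            mem = random_memory_set(
                net["n_neurons"], mem_cfg["n_patterns"], mem_cfg["density"],
                seed=seeds["memories"], alpha=mem_cfg["alpha"],
            )
        recurrent = embed_memories(
            mem, zero_diagonal=mem_cfg["zero_diagonal"],
            uniform_offset=mem_cfg["uniform_offset"],
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StagedError("embedding", str(exc)) from exc

    preset = mem.patterns[0]
    initial = initial_state_near(preset, net["flip_fraction"], seeds["initial_state"])
    weights0 = WeightSet(recurrent.M, np.full(net["n_neurons"], net["w_init"]))
    params = PlasticityParams(
        tau_v=net["tau_v"], tau_W=net["tau_W"], tau_M=net["tau_M"],
        epsilon=net["epsilon"], dt=net["dt"],
        divergence_bound=net["divergence_bound"],
    )
    sign = ana["sign_convention"]
    snapshot_every = ana["snapshot_every"]

    # --- simulate baseline + grid ------------------------------------------
    T = stim_cfg["T"]
    baseline_pattern = zero_pattern(T)
    baseline = run_simulation(
        NetworkState(initial.v.copy()), weights0, baseline_pattern, params,
        seed=seeds["baseline"], sign_convention=sign, snapshot_every=snapshot_every,
    )
    grid = make_condition_grid(T, stim_cfg)
    traces = []
    cond_ss = np.random.SeedSequence(seeds["conditions"]).spawn(len(grid))
    for pat, ss in zip(grid, cond_ss):
        traces.append(
            run_simulation(
                NetworkState(initial.v.copy()), weights0, pat, params,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                sign_convention=sign, snapshot_every=snapshot_every,
            )
        )

    # --- analyze ------------------------------------------------------------
    base_raster = raster_from_trace(baseline)
    rasters = [raster_from_trace(t) for t in traces]
    q_to_baseline = {
        "_".join(t.condition_label): similarity(r, base_raster).q
        for t, r in zip(traces, rasters)
    }
    null = shuffle_null(
        rasters + [base_raster], base_raster,
        n_shuffles=ana["n_shuffles"], percentile=ana["percentile"],
        seed=seeds["shuffle"],
    )
    heatmap = similarity_heatmap(rasters + [base_raster], null)
    energies = {"_".join(t.condition_label): t.energy for t in traces}
    energies["baseline_none"] = baseline.energy

    result = ExperimentResult(
        config=config, stage_seeds=seeds, memory_patterns=mem.patterns,
        baseline=baseline, traces=traces, patterns=list(grid),
        q_to_baseline=q_to_baseline, heatmap=heatmap, null=null, energies=energies,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir), write_figures=write_figures)
    return result


def write_outputs(result: ExperimentResult, out_dir: Path, write_figures: bool = True):
    """Write per-condition and analysis outputs plus the run manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    all_traces = [result.baseline] + result.traces
    all_patterns = [zero_pattern(result.baseline.T)] + result.patterns
    for trace, pat in zip(all_traces, all_patterns):
        cond_dir = out_dir / "_".join(trace.condition_label)
        cond_dir.mkdir(exist_ok=True)
        np.savetxt(cond_dir / "raster.csv", trace.spike_raster, delimiter=",", fmt="%d")
        np.savetxt(cond_dir / "rates.csv", trace.v_history, delimiter=",", fmt="%.8g")
        pd.DataFrame({"time": result.baseline.times, "energy": trace.energy}).to_csv(
            cond_dir / "energy.csv", index=False
        )
        write_pattern_csv(pat, cond_dir / "inputs.csv")
    ana_dir = out_dir / "analysis"
    ana_dir.mkdir(exist_ok=True)
    write_similarity_csv(result.heatmap, ana_dir / "similarity_matrix.csv")
    write_null_csv(result.null, ana_dir / "null_distribution.csv")
    for label, e in result.energies.items():
        pd.DataFrame({"energy": e}).to_csv(ana_dir / f"energy_{label}.csv", index=False)
    pd.DataFrame(
        {"condition": list(result.q_to_baseline), "q": list(result.q_to_baseline.values())}
    ).to_csv(ana_dir / "q_to_baseline.csv", index=False)
    if write_figures:
        plot_raster_grid(result.traces, result.patterns, ana_dir / "raster_grid.png")
        plot_similarity_heatmap(result.heatmap, ana_dir / "similarity_heatmap.png")
        plot_energy_trajectories(result.energies, ana_dir / "energy_trajectories.png")

    manifest = {
        "software": {"name": "rewardnet", "version": __version__},
        "config": result.config.data,
        "stage_seeds": result.stage_seeds,
        "null_threshold": result.null.threshold_value,
        "files": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
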