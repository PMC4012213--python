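# rewardnet

A reward-sensitive attractor-network simulator for studying how the
correlation structure between a stimulus and its perceived reward shapes the
stability of patterns of neural population activity — a computational model
of why some individuals ("susceptible") develop persistent craving after
exposure to a rewarding stimulus while others ("resilient") recover.

## Who this is for

Computational neuroscientists and computational-psychiatry researchers who
want a small, fully seeded rate-network model combining:

- **Hopfield-style memory embedding.** A set of binary patterns `{a^Ω}` with
  sparseness `α` is written into a symmetric recurrent matrix with the
  sparse covariance rule
  `M_ij = 1/((1−α) α P) Σ_Ω (a_i^Ω − α)(a_j^Ω − α) − 1/(α P)`.
- **Rate dynamics.** `τ_v dv/dt = −v + M·tanh(v) + W u`.
- **Reward-modulated Hebbian feedforward plasticity** (Rescorla–Wagner):
  `τ_W dW/dt = ε K W u (r − v)`, gated by `K = I − M` so learning stops when
  the units become autonomous (`M = I`) or the network predicts the reward
  (`v = r`).
- **Anti-Hebbian recurrent plasticity** (Goodall):
  `τ_M dM/dt = (I − M) − (W u) vᵀ`, decorrelating responses and relaxing
  `M` toward the identity.
- **Glauber spike sampling and Boltzmann energy analysis.** Binary spikes
  are read out with `P[spike_i] = 1/(1+e^{−v_i})`; binary network states
  have energy `E(v,u) = −u(W·v) ∓ ½ vᵀMv` with exact partition-function
  enumeration for `N ≤ 20` and asynchronous heat-bath sampling whose
  stationary law is the Boltzmann distribution.
- **Stimulus–reward inputs.** Binary usage templates (exposure / chronic /
  cessation) convolved with a peak-normalized reward-salience kernel —
  log-Gaussian (fast rise, long tail: susceptible) or Gaussian (slower,
  softer: resilient) — give the perceived reward `r(t)`.
- **Raster similarity.** Two spike rasters are compared by the mean
  row-wise cosine `q_ab = 1/N Σ_n v_{n,a}·v_{n,b} / (‖v_{n,a}‖‖v_{n,b}‖)`,
  with significance judged against a row-shuffle permutation null
  (85th-percentile threshold by default).

## Worked example

Run the full default experiment — embed 16 random sparse memories into a
64-neuron network, simulate the six stimulus–reward conditions plus a
no-stimulus baseline for 200 steps from the same initial state near the
first memory, and analyze the rasters:

```bash
rewardnet run-all --seed 0 --out runs/demo
```

which prints (abridged):

```
q(exposure_susceptible, baseline) = 0.5089
q(exposure_resilient, baseline) = 0.5075
q(chronic_susceptible, baseline) = 0.3700
q(chronic_resilient, baseline) = 0.3942
q(cessation_susceptible, baseline) = 0.4252
q(cessation_resilient, baseline) = 0.4372
shuffle-null threshold (p85) = 0.2652
```

Read it like the similarity heatmap of the model's condition grid: every
condition sits below the baseline self-similarity of 1 by more than the
shuffle-null threshold, so every stimulus–reward pairing disturbs the preset
pattern detectably.  The chronic (tonic) stimulus is the most destabilizing
in both rows (lowest `q`), a brief exposure the least; and after cessation
the resilient (Gaussian-salience) network returns closer to the preset
pattern (0.4372) than the susceptible (log-Gaussian) one (0.4252), which
stays nearer its chronic level — persistent craving as a failure to
re-stabilize the old attractor.

`runs/demo/` contains one directory per condition (`raster.csv`,
`rates.csv`, `energy.csv`, `inputs.csv`), an `analysis/` directory
(similarity matrix, null distribution, per-condition energy traces, raster /
heatmap / energy figures), and a `manifest.json` with the resolved
configuration, per-stage seeds and a checksum inventory sufficient to
bit-reproduce the run.

The pieces are also available individually (`generate-inputs`, `embed`,
`simulate`, `analyze`), and as a library:

```python
import rewardnet as rn

mem = rn.random_memory_set(n_neurons=64, n_patterns=16, density=0.25, seed=1)
M = rn.embed_memories(mem).M
stable, diag = rn.check_fixed_point(M, mem.patterns[0], mode="deterministic")
```

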