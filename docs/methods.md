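# Methods

This note documents the model implemented by `rewardnet`, its assumptions,
the parameters that matter, the numerical choices, and what the synthetic
inputs do and do not emulate.

## Model

The simulator couples three ordinary differential equations for a
population of N firing-rate units `v`, a feedforward weight vector `W`
(one-dimensional stimulus `u`), and a recurrent matrix `M`:

    tau_v dv/dt = -v + M . tanh(v) + W u
    tau_W dW/dt = eps * K W u (r - v)          K = I - M
    tau_M dM/dt = (I - M) - (W u) v^T

`r(t)` is the scalar perceived reward.  The feedforward rule is a
network-level Rescorla–Wagner update: weight change is proportional to the
reward-prediction error `r − v`, scaled by the associability `eps`, and
gated by `K = I − M`, which vanishes when units become autonomous
(`M = I`).  `K W u` is an N-vector; the prediction error multiplies it
elementwise with the scalar reward broadcast across units — the only
shape-consistent reading that preserves `W`'s N×1 form.  The recurrent rule
is the Goodall anti-Hebbian update: it relaxes `M` toward the identity
while removing correlations between the filtered input `W u` and the
response `v`.

Memories are embedded with the sparse covariance rule

    M_ij = 1/((1-alpha) alpha P) * sum_O (a_i^O - alpha)(a_j^O - alpha)  -  1/(alpha P)

for P binary patterns of sparseness `alpha` (default: the empirical mean
activity of the supplied patterns).  The trailing term is a uniform
inhibitory offset by default (`uniform_offset=True`); self-connections are
removed (`zero_diagonal=True`).

**Offset reading and small pattern sets.** The placement of the trailing
term admits two readings: subtracted from every entry (uniform global
inhibition) or from the diagonal only.  For small pattern counts the
uniform offset `1/(alpha P)` dominates the covariance term — with one or
two sparse patterns every entry of `M` becomes negative and the silent
state is the unique energy minimum, so no embedded pattern is stable.  The
package therefore uses the diagonal-only reading (where the offset is then
absorbed by the zeroed diagonal) for small-P stability analyses, and keeps
the uniform reading as the default for the large-P default experiment,
where the offset is small (0.25 at P=16, alpha=0.25) and supplies the
global competition that sharpens retrieval.  Both are exposed via
`uniform_offset`.

## Spikes, energy, sampling

Spikes are a stochastic read-out of the rates: unit i fires with
probability `logistic(v_i)` at each recorded step.  Spiking does not feed
back into the rate dynamics; the rates evolve continuously and the raster
is an observation of them.

Binary states are assigned the energy `E(v, u) = -u (W . v) - 1/2 v M v`
(the `hopfield` convention, default).  The opposite quadratic sign
(`as_printed`) is also available; under it high-overlap states are energy
maxima, so all stability analyses use the hopfield convention, under which
the Glauber chain (asynchronous heat-bath updates of one randomly chosen
unit per micro-step, acceptance `logistic(-dE)`) has the Boltzmann
distribution `P[v] = e^{-E}/Z` as its stationary law for symmetric `M` —
verified in the tests by a detailed-balance identity at N ≤ 4 and by
total-variation comparison against exact enumeration at N = 5.  Exact
enumeration is limited to N ≤ 20 (~10^6 states).

Two logistic rules coexist deliberately: the spike read-out applies the
logistic to `v_i` itself (the printed form; `v` already aggregates the
recurrent and feedforward drive), while equilibrium sampling of the binary
energy model applies it to the local field, the only form with a Boltzmann
stationary distribution.

## Stimulus–reward inputs (what the generator emulates)

Usage patterns are binary trains over T = 200 steps: a single 10-step pulse
at step 10 ("exposure", initiation), ON from step 10 to the end
("chronic"), and ON from step 10 through 99 ("cessation").  Reward
salience kernels are sampled on the integer grid and peak-normalized:
log-Gaussian (`mu_log = ln 10`, `sigma_log = 0.8`) for susceptible
dynamics — fast rise, mode near step 5, long tail — and Gaussian
(`mu = 20`, `sigma = 4`) for resilient dynamics — slower and transient.
The perceived reward is the causal convolution of train and kernel
truncated to T samples, with no further normalization: under a sustained
stimulus the susceptible reward plateaus near the kernel's mass (~14.6
units) and the resilient one lower (~10), so susceptibility means both
faster and cumulatively stronger salience.  These are modelling choices,
not fits: the generator emulates the *shape* of positive-reinforcement
dynamics (fast-rising, long-tailed vs slow, soft), not pharmacokinetics,
dose, tolerance, or negative reinforcement during withdrawal.  Passing
tests therefore show that the network's stability phenomena follow from
this salience asymmetry — not that real craving dynamics are log-Gaussian.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| N | 64 | units | large enough for 16 sparse memories, desk-scale |
| tau_v | 1 | steps | rate relaxation sets the basic time scale |
| tau_W | 20 | steps | reward learning slower than rates |
| tau_M | 200 | steps | structural plasticity must outlive the 200-step trial, else the memory decays to `M = I` even without stimulation and no condition can be compared against a stable baseline |
| eps | 0.002 | – | associability; the feedforward loop gain scales with the spectral radius of `K = I − M` (≈17 at the default load), and larger eps makes the reward-tracking loop dynamically unstable |
| dt | 0.05·min(tau) | steps | explicit Euler; the global-inhibition mode of `M` (eigenvalue ≈ −16) is the stiffest direction and needs dt ≲ 2/17; results are unchanged at dt = 0.01 |
| patterns | 16 at density 0.25 | – | sets the covariance-rule scale: fewer patterns make both the uniform offset and the `K` gain proportionally larger and the coupled system explosive |
| w_init | 0.05 | – | small uniform feedforward seed; the multiplicative rule needs W ≠ 0 |
| flip_fraction | 0.05 | – | initial state inside the basin of the first memory |
| divergence bound | 1e3 | – | ‖v‖∞ guard; natural excursions stay below ~10^2, so crossings indicate runaway weight growth and abort loudly |
| n_shuffles | 10,000 | – | permutation null resolution |
| percentile | 85 | – | null threshold |

The dynamical calibration (tau_M, eps, pattern load, kernel widths, dt)
was done by exploratory simulation against three requirements that the
model itself imposes: the no-stimulus baseline must retain its preset
pattern for the whole trial, the six-condition grid must integrate without
tripping the divergence guard, and the susceptible kernel must carry more
cumulative salience than the resilient one (otherwise the
susceptible/resilient contrast inverts).  Within the stable region the
qualitative orderings are insensitive to the exact values and to dt; across
ten random seeds the chronic-stimulus condition is the most destabilizing
in 9/10 and post-cessation recovery favors the resilient network in 10/10.

## Similarity statistic and null

`q_ab` is the arithmetic mean over neuron rows of the cosine between
corresponding rows of two rasters (N×T view).  Conventions: two all-zero
rows have cosine 1 (identical silence), exactly one all-zero row scores 0.
This preserves `q(a,a) = 1` for any raster — computed exactly, because the
denominator uses a single square root of the product of squared norms,
which is exact for binary rows.  The null distribution permutes neuron-row
identities across the pooled rasters, records |change in q| against the
reference, and thresholds at the requested percentile of the resulting
ECDF; an exhaustive mode enumerates all permutations for tiny rasters and
is checked against a brute-force oracle.  The threshold's numerical value
depends strongly on raster statistics and network size, so only orderings
of q, not particular threshold values, are treated as reproducible.

## Energies over a run

`run_simulation` logs the energy of the instantaneous rate vector under
the current weights and stimulus at every recorded step;
`analysis.energy_trajectory` recomputes the same quantity from per-step
weight snapshots (or frozen weights) and is oracle-checked against the
inline record.  Because the rates enter the quadratic form directly, these
trajectories are on an arbitrary scale; only their ordering and trends
across conditions are meaningful.

## Numerical and degenerate-input choices

- Explicit forward Euler; inputs held piecewise-constant over each unit
  step; the integer step index is taken from the accumulated-time floor
  with a 1e-9 guard against drift.
- Energy-mode fixed-point checks treat ties (gap ≥ −1e-12) as stable, so a
  zero matrix leaves all states degenerate-stable.
- Deterministic-mode fixed-point checks keep a unit's state when its local
  field is exactly zero.
- All randomness (memory draw, initial-state flips, spike sampling per
  condition, shuffle null) derives from one top-level seed via independent
  spawned seed sequences; identical configs give bit-identical outputs.
- An all-zero or all-one pattern set has no definable empirical sparseness
  and is rejected unless alpha is supplied explicitly.

## Known limitations

- One-dimensional stimulus only; `W` is a vector.
- Linear interactions between units apart from the tanh rate nonlinearity;
  no neuromodulator models.
- No learning of new memories beyond the drive supplied by the stimulus;
  no negative reinforcement or withdrawal dynamics.
- The stable parameter region for reward learning is narrow: the
  `K = I − M` gating makes the feedforward loop gain proportional to the
  memory-load-dependent scale of `M`, and outside the documented regime
  the coupled system genuinely diverges (the guard reports, rather than
  hides, this).
- Figure-level quantities (similarity values, energy scales, null
  thresholds) depend on the calibration above; only orderings are claimed.
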