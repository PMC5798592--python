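# actinf — belief propagation for active inference

`actinf` implements the neuronal message-passing process theory of active
inference as a reusable engine: agents that both *perceive* (infer the
hidden states behind their observations) and *act* (choose what to observe
next) by minimizing variational free energy under a generative model.  The
package covers the three tiers of that theory and the factor that couples
them:

* **Discrete (MDP) engine** — marginal belief propagation over categorical
  hidden states.  Posteriors over states at each epoch solve

  `s_{π,τ} = σ( ln(B_{π,τ-1} s_{π,τ-1}) + ln(B_{π,τ}· s_{π,τ+1}) + ln(A·o_τ) )`

  where `A` is the likelihood array, `B` the policy-dependent transitions,
  `σ` the softmax, and `·` multiplication by the normalized transpose.
  Policies `π` (action sequences) are scored by expected free energy
  `G(π) = Σ_τ [ o_{π,τ}·(ln o_{π,τ} − C_τ) + s_{π,τ}·H ]` — risk plus
  ambiguity — and the emitted action is the most probable action under
  `π = σ(−γG)`.  Both a fixed-point solver and the neuronally interpretable
  gradient flow (depolarization `ν = ln s` integrating a state prediction
  error) are provided, along with deep temporal (hierarchical) scheduling
  where a higher level's states set the initial-state priors of the level
  below.

* **Continuous engine** — generalized (predictive-coding) filtering.  A
  state and its temporal derivatives `x~ = (x, x′, x″, …)` follow the
  gradient flow `dμ~/dt = Δμ~ − ∂F/∂μ~`, with `Δ` the order-shift operator;
  at first order and for linear-Gaussian models this reduces exactly to the
  conjugate (Kalman-filter-limit) update, which the tests exploit.  Action
  descends the outcome prediction error only.

* **Link node** — the discrete↔continuous interface.  Each discrete
  outcome is a *model* of continuous dynamics, i.e. a Gaussian prior over
  hidden causes.  Descending messages moment-match the Bayesian model
  average of those priors; ascending messages score every outcome model by
  accumulated reduced (post hoc) log evidence,
  `E_m = −ln o_m − ∫ L_m dt`, and return `σ(−E)`.

* **Reading demo** — the full stack in action: a synthetic world of six
  four-word sentences written in pictograms (bird / cat / seeds), read by
  saccadic eye movements.  A sentence level and a word level (discrete)
  sit above a continuous oculomotor level; epistemic (uncertainty-
  resolving) policy selection decides where to look, the link node turns
  each 256 ms visual sample into categorical evidence, and the simulation
  also produces simulated firing-rate rasters and 4–32 Hz band-passed
  local field potentials.

## Worked examples

A two-state agent that can move freely between states and strongly prefers
observing outcome 1:

```python
import numpy as np
from actinf import DiscreteModel, run_trial

B = np.zeros((2, 2, 2)); B[0, :, 0] = 1.0; B[1, :, 1] = 1.0   # action -> state
policies = np.array([[[0], [0]], [[1], [1]]]).transpose(1, 0, 2)
model = DiscreteModel(A=[np.eye(2)], B=[B], D=[np.eye(2)[0]], T=3,
                      C=[np.log([0.05, 0.95])],                # preferences
                      policies=policies, control_factors=(0,))
rec = run_trial(model, model, seed=0)
print(rec.beliefs[0].G.round(3))   # [5.991 0.103]
print(rec.beliefs[0].pi.round(3))  # [0.003 0.997]
print(rec.actions)                 # [(1,), (1,), (0,)]
print(rec.true_states)             # [(0,), (1,), (1,)]
```

The stay-at-0 policy carries high expected free energy (risk 5.99 nats),
so the agent selects the move-to-1 policy with probability 0.997 and the
world duly ends in the preferred state.

The reading simulation, from the shell:

```
$ read-sim run --seed 1 --out reading-out
inferred sentence 0 (true 0) — correct
sentence entropy per word: [0.693, 0.693, 0.693, 0.0]
```

After the first word the reader has narrowed six sentences down to the two
that share their first three words (entropy ln 2 ≈ 0.693 nats); the final
word disambiguates them and the entropy collapses to zero.  The output
directory contains the gaze trajectories (`saccades.png`, `saccades.csv`),
the belief rasters and simulated LFPs (`ephys.png`), and a full HDF5
record.  `read-sim validate-model` checks every probability array of the
generative stack, and a YAML file passed with `--config` can override any
default (sentence set, precisions, saccade length, …).

## Layout

```
src/actinf/discrete_model.py    model arrays, validation, ambiguity
src/actinf/discrete_engine.py   messages, state updates, G, policies, deep scheduling
src/actinf/exact_oracle.py      brute-force references (tests only)
src/actinf/continuous_engine.py generalized filtering, action, curvature
src/actinf/link_node.py         BMA priors, reduced evidence, accumulation
src/actinf/reading_demo.py      the reading world and full simulation
src/actinf/io.py, cli.py        serialization and the read-sim CLI
docs/methods.md                 modelling and numerical choices in detail
```
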