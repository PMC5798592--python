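# Methods

This note documents the models the package implements, the conventions and
numerical choices behind them, and what the synthetic experiments do and do
not establish.

## Discrete belief propagation

A discrete level is a partially observed Markov decision process: per-
modality likelihood arrays `A[m][o, s1..sK]` over the cross-product of
hidden-state factors, per-factor transition arrays `B[f][s', s, u]`,
initial-state priors `D` (vectors, or matrices conditioned on a higher
level's state), log-preferences `C` over outcomes (nats, optionally
time-varying), and an ambiguity vector `H` holding the conditional entropy
of outcomes given each state combination.  Policies are explicit action
sequences; uncontrollable factors carry a single action.

Posterior expectations are factorized over time and state factors (a
mean-field approximation).  The marginal over factor `f` at epoch `tau`
under policy `pi` is the softmax of three log-space messages: forward
`ln(B s_prev)`, backward `ln(B . s_next)` (multiplication by the
separately normalized transpose), and the likelihood `ln(A^T o)`
contracted through the other factors' expectations.  Unobserved epochs
contribute identically zero likelihood messages, so the scheme runs as a
smoother while outcomes are still arriving.  Two solvers share these
messages:

* a fixed-point sweep (`tol = 1e-6` on the max elementwise change, at most
  64 sweeps, raising with the last iterate on failure), and
* a gradient flow in which the depolarization `nu = ln s` integrates the
  state prediction error `eps = (forward + backward + likelihood) - ln s`
  with step 0.25 for 16 iterations per epoch (the iteration count is part
  of the simulation's timing interpretation; the step is a plain Euler
  choice).

**Free energy and its descent.**  The reported marginal free energy is
`F = sum_{tau,f} E_q[ln q - (forward + backward + likelihood)]`, whose
stationary points coincide with the fixed points of the message scheme.
Two properties of this construction deserve honesty.  First, the messages
take logs of *averaged* beliefs (sum-product style) rather than cavity
quantities, so the scheme mildly over-counts shared information — e.g.
with no observations the posterior is very close to, but not exactly, the
forward propagation of `D` (deviations of order 1e-2 in probability), and
posteriors in ambiguous situations are overconfident.  Second, the
prediction-error flow is not the exact gradient of any static functional:
`F` decreases strongly and ends below its starting value on every random
model we generate, but transient per-iteration increases of up to ~1e-2
nats occur on roughly one model in ten.  Both are intrinsic to this
message convention (making the trace exactly monotone would require a
different, double-loop style algorithm); the exactly solvable regimes
below are unaffected.

**Exact regimes used for validation.**  With uniform transitions and a
single observed epoch the factorization is exact and engine posteriors
match brute-force enumeration to ~1e-14.  With permutation transitions and
an identity likelihood the posterior is the generating sequence exactly.
The enumeration oracle (`exact_oracle`) computes unapproximated posteriors
in linear space with extended-precision accumulation and is used only in
tests.

**Policies and action.**  Expected free energy per policy is the sum over
future epochs of outcome risk (KL from preferred outcomes, computed
through the outcome prediction error `ln o - C`) plus state-conditional
ambiguity `s . H`.  The policy posterior is `softmax(-gamma G)` with
`gamma = 1`; an optional `F` argument adds each policy's marginal free
energy, which suppresses policies whose past actions contradict the
realized history (the reading demo uses this; the engine default is
G-only).  The emitted action is the posterior-marginal argmax, ties broken
toward the lowest index for determinism.  The generative process is
sampled from its own arrays with a dedicated random substream, so
model-side computations are seed-independent.

**Deep temporal scheduling.**  Levels are coupled through the initial
state: a `(n_lower, n_higher_joint)` matrix `D` maps the higher level's
Bayesian model average into a descending empirical prior, and the lower
level returns ascending evidence `ln(D^T w)` where `w` is its posterior
over initial states with the descending prior divided out.  The division
prevents the empirical prior from being counted twice; with identity
interfaces and single lower epochs the deep scheduler then reproduces the
single-level scheme exactly, which the tests assert.  Scheduling strictly
alternates: a full lower-level trial runs inside every higher-level epoch.

## Continuous generalized filtering

Continuous states are represented with their temporal derivatives up to a
configurable embedding order (default 2: position and velocity).  The
model supplies a flow `f(x, v)`, a static observation mapping `g(x, v)`,
per-order precisions on state noise and outcomes, and a Gaussian prior
over the causes `v`.  Generalized nonlinearities are propagated to first
order only (Jacobians at the current expansion point); the gradient of
free energy is assembled analytically from the precision-weighted errors,
and the shift operator's adjoint is the true matrix transpose (demoting
orders), which the Kalman-limit equivalence requires.

Two integrators are available.  Explicit Euler is the default and is fine
for the low-dimensional models in the tests.  For stiff regimes — high-
dimensional image likelihoods, strong attractor flows — a local-
linearization step solves `(I - dt J) dmu = dt r(mu)` with the drift
Jacobian assembled from the Gauss-Newton curvature; it is unconditionally
stable for the precision-dominated part of the dynamics and is what the
reading demo uses.  A divergence guard raises once expectations exceed
1e8 in magnitude.

Action can only change outcomes, so its update descends the outcome
prediction error through the process's sensitivity `do/da`; the
sensitivity may be supplied per embedding order, letting a proprioceptive
velocity error act as damping (the oculomotor loop needs this to avoid
servo oscillation).  The curvature diagnostic returns the eigenvalues of a
central-difference Hessian of free energy in the chosen block of
expectations; eigenvalues are positive at minima and their size measures
how fast the corresponding pattern of activity decays.

## The link node

Each discrete outcome is an outcome *model*: a Gaussian prior `(eta_m,
Pi_m)` over the continuous causes.  The descending message moment-matches
the mixture selected by the discrete outcome distribution into one
Gaussian (mean, within- plus between-model covariance), which becomes the
continuous prior for the next integration window.  Ascending evidence uses
Bayesian model reduction: given the posterior obtained under the full
(averaged) prior, the relative log evidence of each reduced prior follows
from quadratic forms and log-determinants of the four precisions involved,
with an explicit error if the reduced posterior precision is not positive
definite.  The identity is validated against direct numerical quadrature
to better than 1e-6 over hundreds of random instances.

During a window the filter maintains a running Laplace posterior over the
causes: its mean is the current expectation and its precision the prior
precision plus observation information accumulated at rate `dt * J' Pi J`.
The accumulated evidence `L_m` sums the per-step *increments* of the
reduced log evidence, which telescopes to the reduced log evidence of the
window's final posterior — the time integral of the instantaneous
log-likelihood ratio.  (Summing the reduced evidences themselves, rather
than their increments, over-weights early half-formed posteriors and
measurably biases the comparison toward priors the early data cannot
falsify.)  Model free energies are `E_m = -ln o_m - L_m` with the
categorical posterior `softmax(-E)`; a zero-length window returns the
prior exactly, and accumulation is exactly additive across consecutive
windows.

## The reading world and simulation

The synthetic environment contains six sentences of four words from the
lexicon {flee, feed, wait}.  A word is a pair of 32x32 pictograms placed
in the quadrants of a [-1, 1]^2 visual field: *flee* puts a bird next to a
cat, *feed* a bird next to seeds, *wait* seeds above (or below) a bird;
two binary hidden states flip the layout vertically (font substitution)
and horizontally (letter order), and empty quadrants are an explicit
"blank" category — seeing nothing is evidence.  The default sentence set
is a reconstruction built so that sentences 1 and 4 share their first
three words; the last word then disambiguates them, and the simulation's
sentence-level entropy sits at ln 2 from the first word until the final
word resolves it.  Pictograms are procedural, blurred, rescaled to a
common energy of 150 (so each supports comparable visual evidence), and
pairwise correlated below 0.5.

Model structure: level 2 has sentence (6) x position (4) factors with a
deterministic position-advance and a proprioceptive position outcome;
level 1 has word (3) x quadrant (4) x vertical flip (2) x horizontal flip
(2) with *what* (pictogram) and *where* (fixation) modalities, a
controllable quadrant, depth-2 policies over the 4 quadrant targets, and
neutral preferences — saccades are chosen purely epistemically.  The flip
priors default to 0.75 on the canonical orientation: under exactly uniform
flip priors the flip group acts transitively on quadrants, every
quadrant's predicted outcome entropy is identical, and epistemic saccade
selection degenerates into tie-breaking; the mild bias orders the
quadrants informatively (the discriminating quadrant strictly wins) and is
also a natural description of text, where canonical orientation is the
common case.

The continuous level has a 2-D gaze state attracted to the location cause
at rate `kappa = 8` per saccade interval, with causes `v = (v_L, v_I)`:
a 2-D target location and a 4-vector of pictogram weights.  Predicted
vision is the weight-mixed pictogram at the target, shifted by the
displacement between target and gaze and contrast-attenuated by
`exp(-|d|^2 / 2 sigma^2)` with `sigma = 0.5` (half a quadrant width);
proprioception reports gaze.  Jacobians are analytic and flow through the
attenuation only — the sub-pixel shift is treated as residual — keeping
the filter well conditioned.  Each saccade is one window of 24 steps of
`dt = 1/24` saccade intervals (~10.7 ms per step, ~256 ms per saccade).
State-noise precision is 8 (fluctuation variance 1/8) in both the model
and the injected process noise; per-pixel visual precision is 1,
proprioceptive precision 8 (position) and 0.5 (velocity), and the
oculomotor sensitivity is 32.  These control-loop numbers were chosen for
a well-damped servo: across seeds and quadrants the eye lands within
~0.2 gaze units of the commanded center (quadrant half-width is 0.5).
Link outcome models are the 16 (pictogram, quadrant) pairs with location
prior precision 16 and identity prior precision 4; the accumulated-
evidence weights (prior removed) become soft *what*/*where* outcomes for
the word level, and the word posterior (descending prior divided out)
ascends to the sentence level, masked to the position actually read.

Simulated electrophysiology treats the per-iteration Bayesian model
averages as firing rates: 16 bins per discrete epoch at 16 ms per bin
(one gradient iteration), 64 bins per word (three word-level epochs plus
one sentence-level update), ~4.1 s in total.  Rates are interpolated to
1 kHz and band-passed 4-32 Hz with a 4th-order zero-phase Butterworth
filter; records shorter than the filter warm-up are padded with a
warning.  Across the default run, over 90% of the pooled LFP power lies
inside the band and a clear deflection follows every saccade onset.

**What the synthetic world does not emulate.**  Pictograms are noiseless
templates rather than natural images; the retina is a uniform 32x32 patch
without foveal magnification; proprioception is noiseless; the sentence
set, layouts and flip statistics are fixed and known to the generative
model (no learning); and the number of saccades per word is fixed at two
by the three-epoch word level rather than emerging from a stopping rule.
Passing tests therefore demonstrate the internal consistency of the
inference machinery and the qualitative phenomenology (epistemic saccade
targeting, evidence accumulation across levels, saccade-locked belief
transients), not performance on natural reading data.

## Degenerate inputs and errors

Zero probabilities are handled by a single package-wide log floor,
`ln(x + e^-32)`: logs stay finite while probabilities above ~1e-13 are
unperturbed, so exactness checks against the enumeration oracle hold to
1e-8 and beyond.  All-zero columns in probability tables, out-of-range
policy indices, shape mismatches between likelihood arrays and the state
factors, non-SPD precisions and ill-posed reductions raise dedicated
errors; fixed-point non-convergence raises carrying the last iterate.
Ties in action selection and argmax reports always break toward the
lowest index.
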