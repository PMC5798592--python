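"""Marginal belief propagation and policy selection for discrete models.

The engine implements the message-passing process theory for active
inference on one or more :class:`~actinf.discrete_model.DiscreteModel`
levels.  The posterior over hidden states at epoch ``tau`` under policy
``pi`` is the softmax of three log-space messages,

    ln s_{pi,tau} = ln(B_{pi,tau-1} s_{pi,tau-1})     (forward)
                  + ln(B_{pi,tau} . s_{pi,tau+1})     (backward)
                  + ln(A^T o_tau)                     (likelihood)

where ``.`` denotes multiplication by the separately normalized transpose
and boldface normalization makes every conditional proper.  Past and future
epochs are represented at all times, so the scheme behaves like a smoother
that runs while outcomes are still arriving.  Two solvers are provided: a
fixed-point sweep and a gradient flow on (marginal) free energy in which the
depolarization ``nu = ln s`` integrates a state prediction error — the
neuronally interpretable scheme.

Policies are scored by expected free energy ``G`` (risk plus ambiguity) and
the action actually emitted is the most probable action under the policy
posterior.  Deep temporal models connect levels through the initial-state
factor: descending messages turn a higher-level Bayesian model average into
an empirical prior for the level below, and ascending messages return the
evidence the lower level gathered.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import LOG_FLOOR, log_stable, normalize, onehot, softmax
from .discrete_model import BeliefState, DiscreteModel, StructuralError


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# messages
# ---------------------------------------------------------------------------

def _norm_columns(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=0, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return M / s


def dot_transpose(M: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Backward multiplication ``M . s`` by the normalized transpose.

    Rows of ``M`` are renormalized before transposition so that the
    transpose is itself a proper conditional (each original row is treated
    as an unnormalized distribution over the leading axis).
    """
    rs = M.sum(axis=1, keepdims=True)
    rs = np.where(rs > 0, rs, 1.0)
    return (M / rs).T @ s


def _A_bar_log(A: np.ndarray) -> np.ndarray:
    """Log of the Eq.-4 normalized transpose of a likelihood array,
    arranged with the outcome on the leading axis: ``ln A[o, s]/sum_s' A[o, s']``."""
    state_axes = tuple(range(1, A.ndim))
    rs = A.sum(axis=state_axes, keepdims=True)
    rs = np.where(rs > 0, rs, 1.0)
    return log_stable(A / rs)


def likelihood_message(A, observed) -> np.ndarray:
    """Log-space likelihood message ``ln(A^T o)`` over (joint) hidden states.

    ``A`` may be one array or a list of per-modality arrays sharing the
    state axes; ``observed`` is then an outcome index (or distribution over
    outcomes, treated as soft evidence) per modality.  Returns a tensor over
    the state axes; for a single-factor model this is a vector.
    """
    if isinstance(A, np.ndarray):
        A = [A]
        observed = [observed]
    if len(observed) != len(A):
        raise StructuralError("one observation per modality required")
    phi = None
    for Am, om in zip(A, observed):
        logA = _A_bar_log(np.asarray(Am, dtype=float))
        if np.isscalar(om) or (isinstance(om, np.ndarray) and om.ndim == 0):
            om = int(om)
            if not 0 <= om < Am.shape[0]:
                raise IndexError(f"outcome index {om} out of range")
            term = logA[om]
        else:
            q = np.asarray(om, dtype=float)
            term = np.tensordot(q, logA, axes=1)
        phi = term if phi is None else phi + term
    return phi


def forward_message(B_slice: np.ndarray, s_prev: np.ndarray) -> np.ndarray:
    """``ln(B s_prev)`` — empirical prior from the preceding epoch."""
    return log_stable(_norm_columns(B_slice) @ s_prev)


def backward_message(B_slice: np.ndarray, s_next: np.ndarray) -> np.ndarray:
    """``ln(B . s_next)`` — empirical prior from the subsequent epoch."""
    return log_stable(dot_transpose(B_slice, s_next))


def contract_to_factor(phi: np.ndarray, s_factors: list, f: int) -> np.ndarray:
    """Mean-field message of a joint log-potential to one state factor:
    the expectation of ``phi`` under the other factors' distributions."""
    out = phi
    axis_of_f = f
    for g in range(len(s_factors) - 1, -1, -1):
        if g == f:
            continue
        out = np.tensordot(out, s_factors[g], axes=([g], [0]))
        if g < f:
            axis_of_f -= 1
    if out.ndim != 1:
        out = np.moveaxis(out, axis_of_f, 0)
    return out


@dataclass
class Message:
    """A single log-space message, mainly for introspection and logging."""

    target: tuple
    kind: str
    payload: np.ndarray

    KINDS = ("forward", "backward", "likelihood", "outcome", "policy",
             "ascending", "descending")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown message kind {self.kind!r}")
        self.payload = np.asarray(self.payload, dtype=float)
        if not np.all(np.isfinite(self.payload)):
            raise ValueError("message payload must be finite after log-floor")


# ---------------------------------------------------------------------------
# state estimation
# ---------------------------------------------------------------------------

def _policy_action(model: DiscreteModel, policy: int, step: int, factor: int) -> int:
    if factor in model.control_factors:
        k = model.control_factors.index(factor)
        step = min(step, model.policies.shape[0] - 1)
        return int(model.policies[step, policy, k])
    return 0


def _obs_logpots(model: DiscreteModel, observations) -> list:
    """Per-epoch joint log-potentials from the observed outcomes.

    ``observations`` is a sequence of length <= T whose entries are ``None``
    (epoch not yet observed; its likelihood message is identically zero) or
    a per-modality sequence of outcome indices / soft outcome vectors.
    """
    pots = [None] * model.T
    if observations is None:
        return pots
    for tau, obs in enumerate(observations):
        if obs is None:
            continue
        pots[tau] = likelihood_message(model.A, obs)
    return pots


def _merge_pots(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def _log_priors(model: DiscreteModel, D_vectors) -> list:
    if D_vectors is None:
        D_vectors = [model.D_vector(f) for f in range(model.n_factors)]
    return [log_stable(np.asarray(d, dtype=float)) for d in D_vectors]


def _factor_messages(model, s, pots, policy, tau, f, log_D):
    n = model.state_dims[f]
    if tau == 0:
        fwd = log_D[f]
    else:
        a = _policy_action(model, policy, tau - 1, f)
        fwd = forward_message(model.B[f][:, :, a], s[f][tau - 1])
    if tau == model.T - 1:
        bwd = np.zeros(n)
    else:
        a = _policy_action(model, policy, tau, f)
        bwd = backward_message(model.B[f][:, :, a], s[f][tau + 1])
    phi = pots[tau]
    lik = np.zeros(n) if phi is None else contract_to_factor(
        phi, [s[g][tau] for g in range(model.n_factors)], f)
    return fwd, bwd, lik


def marginal_free_energy(model, s, pots, policy, log_D) -> float:
    """Marginal free energy of the current expectations.

    ``F = sum_tau sum_f E_q[ln q(s_tau) - (forward + backward +
    likelihood)]`` — the free-energy functional whose stationary points are
    the fixed points of the message-passing scheme (its negative gradient,
    up to the softmax gauge, is the state prediction error).  Because the
    messages themselves are logs of averaged beliefs, the gradient flow is
    not an exact gradient of ``F``; see the methods note for the practical
    consequences.
    """
    F = 0.0
    for tau in range(model.T):
        for f in range(model.n_factors):
            fwd, bwd, lik = _factor_messages(model, s, pots, policy, tau, f, log_D)
            q = s[f][tau]
            F += float(q @ (log_stable(q) - fwd - bwd - lik))
    return F


def state_update_fixed_point(model, observations, policy=0, *, tol=1e-6,
                             max_sweeps=64, extra_logpots=None,
                             D_vectors=None):
    """Iterate ``s <- softmax(forward + backward + likelihood)`` to a fixed
    point, returning per-factor expectations of shape ``(T, n_states)``.

    Raises :class:`ConvergenceError` (carrying the last iterate) if the
    maximum elementwise change stays above ``tol`` after ``max_sweeps``.
    """
    pots = _obs_logpots(model, observations)
    if extra_logpots is not None:
        pots = [_merge_pots(p, e) for p, e in zip(pots, extra_logpots)]
    log_D = _log_priors(model, D_vectors)
    s = [np.full((model.T, n), 1.0 / n) for n in model.state_dims]
    for _ in range(max_sweeps):
        delta = 0.0
        for tau in range(model.T):
            for f in range(model.n_factors):
                fwd, bwd, lik = _factor_messages(model, s, pots, policy, tau, f, log_D)
                new = softmax(fwd + bwd + lik)
                delta = max(delta, float(np.max(np.abs(new - s[f][tau]))))
                s[f][tau] = new
        if delta < tol:
            return s
    raise ConvergenceError(
        f"no fixed point after {max_sweeps} sweeps (delta={delta:.3g})",
        last_iterate=s,
    )


def gradient_iteration(model, s, nu, pots, policy, log_D, step=0.25):
    """One synchronous gradient step of the neuronal update scheme.

    Computes the state prediction error ``eps = (fwd + bwd + lik) - ln s``
    for every epoch and factor, moves the depolarization ``nu`` up the error
    and re-derives ``s = softmax(nu)``.  Returns the prediction errors.
    """
    eps = [np.zeros_like(nu[f]) for f in range(model.n_factors)]
    for tau in range(model.T):
        for f in range(model.n_factors):
            fwd, bwd, lik = _factor_messages(model, s, pots, policy, tau, f, log_D)
            eps[f][tau] = fwd + bwd + lik - log_stable(s[f][tau])
    for f in range(model.n_factors):
        nu[f] += step * eps[f]
        nu[f] -= nu[f].max(axis=1, keepdims=True)  # softmax gauge
        s[f][:] = softmax(nu[f], axis=1)
    return eps


def state_update_gradient(model, observations, policy=0, *, iterations=16,
                          step=0.25, nu0=None, extra_logpots=None,
                          D_vectors=None):
    """Gradient-flow state estimation (the process-theory scheme).

    Returns ``(s, nu, eps, F_trace)`` where ``F_trace`` holds the marginal
    free energy evaluated before each iteration plus once after the last,
    i.e. ``iterations + 1`` values.  A free-energy increase beyond 1e-9
    is reported via a ``RuntimeWarning``-style note on the trace but does
    not raise.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pots = _obs_logpots(model, observations)
    if extra_logpots is not None:
        pots = [_merge_pots(p, e) for p, e in zip(pots, extra_logpots)]
    log_D = _log_priors(model, D_vectors)
    if nu0 is None:
        nu = [np.zeros((model.T, n)) for n in model.state_dims]
    else:
        nu = [np.array(v, dtype=float) for v in nu0]
    s = [softmax(v, axis=1) for v in nu]
    F_trace = np.empty(iterations + 1)
    eps = None
    for it in range(iterations):
        F_trace[it] = marginal_free_energy(model, s, pots, policy, log_D)
        eps = gradient_iteration(model, s, nu, pots, policy, log_D, step=step)
    F_trace[iterations] = marginal_free_energy(model, s, pots, policy, log_D)
    return s, nu, eps, F_trace


# ---------------------------------------------------------------------------
# expected free energy, policies, action
# ---------------------------------------------------------------------------

def expected_outcomes(A, s_factors) -> list:
    """Predicted outcome distributions ``o = A s`` per modality."""
    single = isinstance(A, np.ndarray)
    if single:
        A = [A]
    if isinstance(s_factors, np.ndarray):
        s_factors = [s_factors]
    out = []
    for Am in A:
        o = np.asarray(Am, dtype=float)
        for g in range(len(s_factors) - 1, -1, -1):
            o = np.tensordot(o, s_factors[g], axes=([g + 1], [0]))
        out.append(normalize(o))
    return out[0] if single else out


def expected_free_energy(model: DiscreteModel, s, *, from_epoch=0) -> float:
    """Expected free energy ``G`` of one policy's expectations.

    ``G = sum_tau [ o_tau . (ln o_tau - C_tau) + s_tau . H ]`` over epochs
    ``tau >= from_epoch`` — outcome risk (KL from preferred outcomes,
    via the outcome prediction error) plus state-conditional ambiguity.
    """
    G = 0.0
    for tau in range(from_epoch, model.T):
        s_tau = [s[f][tau] for f in range(model.n_factors)]
        o_pred = expected_outcomes(model.A, s_tau)
        for m, o in enumerate(o_pred):
            eps_out = log_stable(o) - model.C_at(m, tau)
            G += float(o @ eps_out)
        # ambiguity: expectation of H under the (factorized) joint state
        h = model.H
        for g in range(model.n_factors - 1, -1, -1):
            h = np.tensordot(h, s_tau[g], axes=([g], [0]))
        G += float(h)
    return G


def policy_posterior(G: np.ndarray, gamma: float = 1.0,
                     F: np.ndarray | None = None) -> np.ndarray:
    """``pi = softmax(-gamma G - F)`` — policies that minimize expected
    free energy are more probable a priori.

    ``F`` optionally supplies each policy's marginal free energy given the
    outcomes observed so far; including it suppresses policies whose past
    actions are inconsistent with the evidence (they carry large ``F``).
    By default only ``G`` is used.
    """
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("expected free energy must be finite")
    z = -gamma * G
    if F is not None:
        z = z - np.asarray(F, dtype=float)
    return softmax(z)


def bayesian_model_average(s_per_policy, pi) -> list:
    """Policy-averaged state expectations, per factor: ``sum_p pi(p) s_p``."""
    pi = np.asarray(pi, dtype=float)
    n_factors = len(s_per_policy[0])
    bma = []
    for f in range(n_factors):
        acc = sum(pi[p] * s_per_policy[p][f] for p in range(len(s_per_policy)))
        bma.append(acc / acc.sum(axis=-1, keepdims=True))
    return bma


def select_action(pi, policies, t) -> tuple:
    """Most probable action per controllable factor at step ``t``.

    Marginalizes the policy posterior over the action each policy
    prescribes; ties are broken toward the lowest action index.
    """
    policies = np.asarray(policies)
    t = min(int(t), policies.shape[0] - 1)
    actions = []
    for k in range(policies.shape[2]):
        n_a = int(policies[:, :, k].max()) + 1
        u = np.zeros(n_a)
        for p in range(policies.shape[1]):
            u[policies[t, p, k]] += pi[p]
        actions.append(int(np.argmax(u)))
    return tuple(actions)


# ---------------------------------------------------------------------------
# the generative process
# ---------------------------------------------------------------------------

def _sample(rng, p) -> int:
    p = np.asarray(p, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum()))


def sample_initial_states(rng, process: DiscreteModel, context=None) -> tuple:
    return tuple(_sample(rng, process.D_vector(f, context))
                 for f in range(process.n_factors))


def sample_outcome(rng, process: DiscreteModel, states) -> tuple:
    idx = (slice(None),) + tuple(states)
    return tuple(_sample(rng, a[idx]) for a in process.A)


def step_states(rng, process: DiscreteModel, states, action) -> tuple:
    new = []
    for f in range(process.n_factors):
        if f in process.control_factors:
            a = action[process.control_factors.index(f)]
        else:
            a = 0
        new.append(_sample(rng, process.B[f][:, states[f], a]))
    return tuple(new)


def step_process(rng, process: DiscreteModel, states, action):
    """Advance the true states one epoch and sample the new outcome."""
    new = step_states(rng, process, states, action)
    return new, sample_outcome(rng, process, new)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """Everything recorded while closing the action–perception cycle."""

    outcomes: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    true_states: list = field(default_factory=list)
    beliefs: list = field(default_factory=list)
    F_trace: list = field(default_factory=list)
    bma_iter_trace: list = field(default_factory=list)

    @property
    def final(self) -> BeliefState:
        return self.beliefs[-1]


def run_trial(model: DiscreteModel, process: DiscreteModel, *, iterations=16,
              step=0.25, gamma=1.0, seed=None, rng=None, scheme="gradient",
              D_vectors=None, extra_logpots=None, observations=None,
              record_iter_bma=False, tol=1e-6) -> TrialRecord:
    """Run one trial of active inference: observe, update, act, repeat.

    Per epoch the engine observes an outcome from the generative process,
    refreshes the per-policy posteriors (16 gradient iterations by default),
    evaluates expected free energy over the remaining epochs, forms the
    policy posterior and Bayesian model averages, selects the most probable
    action, and steps the process.  The process consumes its own random
    substream so that model-side computations are seed independent.

    ``observations`` may supply a fully observed outcome sequence, in which
    case the process is only used for its shape metadata and no sampling
    occurs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    T = model.T
    rec = TrialRecord()
    obs: list = [None] * T
    driven = observations is not None
    if not driven:
        states = sample_initial_states(rng, process)
    else:
        states = None
    nu = [[np.zeros((T, n)) for n in model.state_dims]
          for _ in range(model.n_policies)]
    pi = np.full(model.n_policies, 1.0 / model.n_policies)
    log_D = _log_priors(model, D_vectors)

    for t in range(T):
        if driven:
            obs[t] = observations[t]
        else:
            obs[t] = sample_outcome(rng, process, states)
        pots = _obs_logpots(model, obs)
        if extra_logpots is not None:
            pots = [_merge_pots(p, e) for p, e in zip(pots, extra_logpots)]

        s_all, eps_all, F_all = [], [], []
        if scheme == "fixed_point":
            for p in range(model.n_policies):
                s = state_update_fixed_point(
                    model, obs, p, tol=tol, extra_logpots=extra_logpots,
                    D_vectors=D_vectors)
                s_all.append(s)
                for f in range(model.n_factors):
                    nu[p][f] = log_stable(s[f])
                eps_all.append(None)
                F_all.append(np.zeros(1))
        else:
            s_all = [[softmax(v, axis=1) for v in nu[p]]
                     for p in range(model.n_policies)]
            F_all = [np.empty(iterations) for _ in range(model.n_policies)]
            eps_all = [None] * model.n_policies
            iter_bma = []
            for it in range(iterations):
                for p in range(model.n_policies):
                    F_all[p][it] = marginal_free_energy(
                        model, s_all[p], pots, p, log_D)
                    eps_all[p] = gradient_iteration(
                        model, s_all[p], nu[p], pots, p, log_D, step=step)
                if record_iter_bma:
                    iter_bma.append(bayesian_model_average(s_all, pi))
            if record_iter_bma:
                rec.bma_iter_trace.append(iter_bma)

        G = np.array([
            expected_free_energy(model, s_all[p], from_epoch=t + 1)
            for p in range(model.n_policies)
        ])
        pi = policy_posterior(G, gamma)
        bma = bayesian_model_average(s_all, pi)
        o_pred = [
            [expected_outcomes(model.A, [s_all[p][f][tt] for f in range(model.n_factors)])
             for tt in range(T)]
            for p in range(model.n_policies)
        ]
        belief = BeliefState(
            s=[[s.copy() for s in s_all[p]] for p in range(model.n_policies)],
            nu=[[v.copy() for v in nu[p]] for p in range(model.n_policies)],
            eps_state=eps_all,
            pi=pi.copy(),
            o_pred=o_pred,
            bma=[b.copy() for b in bma],
            G=G,
            F=np.stack(F_all) if scheme == "gradient" else None,
        )
        rec.beliefs.append(belief)
        rec.F_trace.append(np.stack(F_all) if scheme == "gradient" else None)
        action = select_action(pi, model.policies, t)
        rec.actions.append(action)
        rec.outcomes.append(obs[t])
        rec.true_states.append(states)
        if t < T - 1 and not driven:
            states = step_states(rng, process, states, action)
    return rec


# ---------------------------------------------------------------------------
# deep temporal models
# ---------------------------------------------------------------------------

def descending_message(D_matrix: np.ndarray, bma: np.ndarray) -> np.ndarray:
    """Empirical prior over a lower level's initial state: ``D @ bma``."""
    return normalize(np.asarray(D_matrix, dtype=float) @ np.asarray(bma, dtype=float))


def ascending_message(D_matrix: np.ndarray, q_lower: np.ndarray) -> np.ndarray:
    """Log-evidence over higher states: ``ln sum_j D[j, l] q(j)``.

    ``q_lower`` is a (possibly unnormalized) weighting of the lower level's
    initial states; passing likelihood-ratio weights ``q/p`` (posterior over
    descending prior) makes the message a proper likelihood term for the
    higher level.
    """
    D = np.asarray(D_matrix, dtype=float)
    return log_stable(D.T @ np.asarray(q_lower, dtype=float))


@dataclass
class DeepRecord:
    higher: TrialRecord | None = None
    lower: list = field(default_factory=list)
    descending: list = field(default_factory=list)
    ascending: list = field(default_factory=list)


def run_deep(higher: DiscreteModel, lower: DiscreteModel, interfaces,
             higher_process: DiscreteModel, lower_process: DiscreteModel, *,
             iterations=16, step=0.25, gamma=1.0, seed=None, rng=None,
             scheme="gradient", ascend=True, lower_scheme=None,
             tol=1e-6) -> DeepRecord:
    """Two-level deep temporal inference with strict alternation.

    ``interfaces`` is a list of ``(lower_factor, D_matrix)`` pairs where
    ``D_matrix`` has shape ``(n_lower_states, n_higher_joint_states)`` and
    plays the role of the lower level's matrix-valued initial-state prior.
    For every higher-level epoch the scheduler (i) emits descending
    empirical priors from the current higher-level Bayesian model average,
    (ii) runs a complete lower-level trial, (iii) returns ascending
    evidence (the lower posterior over its initial states with the
    descending prior divided out, so priors are not double counted), and
    only then (iv) updates the higher level.  Setting ``ascend=False``
    severs the ascending messages.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if lower_scheme is None:
        lower_scheme = scheme
    h_dims = higher.state_dims
    n_joint = int(np.prod(h_dims))
    for f, Dm in interfaces:
        Dm = np.asarray(Dm)
        if Dm.shape != (lower.state_dims[f], n_joint):
            raise StructuralError(
                f"interface for lower factor {f}: expected shape "
                f"{(lower.state_dims[f], n_joint)}, got {Dm.shape}")

    rec = DeepRecord()
    T_h = higher.T
    true_h = sample_initial_states(rng, higher_process)
    nu_h = [[np.zeros((T_h, n)) for n in h_dims]
            for _ in range(higher.n_policies)]
    pi_h = np.full(higher.n_policies, 1.0 / higher.n_policies)
    obs_h: list = [None] * T_h
    extra: list = [None] * T_h
    log_D_h = _log_priors(higher, None)
    rec.higher = TrialRecord()

    # prior propagation so the first descending message reflects D and B
    s_h = [state_update_fixed_point(higher, None, p, tol=tol)
           for p in range(higher.n_policies)]
    bma_h = bayesian_model_average(s_h, pi_h)

    for t in range(T_h):
        joint = bma_h[0][t]
        for f in range(1, higher.n_factors):
            joint = np.multiply.outer(joint, bma_h[f][t])
        joint_flat = joint.reshape(-1)

        lower_D = [lower.D_vector(f) for f in range(lower.n_factors)]
        proc_D = [lower_process.D_vector(f) for f in range(lower.n_factors)]
        desc = {}
        true_flat = int(np.ravel_multi_index(true_h, h_dims))
        for f, Dm in interfaces:
            Dm = np.asarray(Dm, dtype=float)
            desc[f] = descending_message(Dm, joint_flat)
            lower_D[f] = desc[f]
            j_true = _sample(rng, Dm[:, true_flat])
            proc_D[f] = onehot(j_true, Dm.shape[0])
        rec.descending.append(desc)

        low_model = DiscreteModel(
            A=lower.A, B=lower.B, D=lower_D, C=lower.C,
            policies=lower.policies, T=lower.T,
            control_factors=lower.control_factors, H=lower.H)
        low_proc = DiscreteModel(
            A=lower_process.A, B=lower_process.B, D=proc_D,
            C=lower_process.C, policies=lower_process.policies,
            T=lower_process.T, control_factors=lower_process.control_factors,
            H=lower_process.H)
        low_rec = run_trial(low_model, low_proc, iterations=iterations,
                            step=step, gamma=gamma, rng=rng,
                            scheme=lower_scheme, tol=tol)
        rec.lower.append(low_rec)

        if ascend:
            ev = np.zeros(h_dims)
            for f, Dm in interfaces:
                q0 = low_rec.final.bma[f][0]
                ratio = q0 / np.maximum(desc[f], LOG_FLOOR)
                ev += ascending_message(np.asarray(Dm, dtype=float),
                                        ratio).reshape(h_dims)
            extra[t] = ev
            rec.ascending.append(ev)

        if higher.n_modalities:
            obs_h[t] = sample_outcome(rng, higher_process, true_h)

        s_h = []
        for p in range(higher.n_policies):
            if scheme == "fixed_point":
                s = state_update_fixed_point(higher, obs_h, p, tol=tol,
                                             extra_logpots=extra)
                nu_h[p] = [log_stable(x) for x in s]
                F_p = np.zeros(1)
            else:
                s, nu_h[p], _, F_p = state_update_gradient(
                    higher, obs_h, p, iterations=iterations, step=step,
                    nu0=nu_h[p], extra_logpots=extra)
            s_h.append(s)
        G = np.array([expected_free_energy(higher, s_h[p], from_epoch=t + 1)
                      for p in range(higher.n_policies)])
        pi_h = policy_posterior(G, gamma)
        bma_h = bayesian_model_average(s_h, pi_h)
        belief = BeliefState(s=s_h, pi=pi_h.copy(),
                             bma=[b.copy() for b in bma_h], G=G)
        rec.higher.beliefs.append(belief)
        rec.higher.outcomes.append(obs_h[t])
        rec.higher.true_states.append(true_h)
        action = select_action(pi_h, higher.policies, t)
        rec.higher.actions.append(action)
        if t < T_h - 1:
            true_h = step_states(rng, higher_process, true_h, action)
    return rec
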