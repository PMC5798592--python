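"""Brute-force reference computations for testing.

Everything here trades efficiency for transparency: posteriors are obtained
by enumerating complete hidden-state sequences in linear probability space,
expected free energy by explicit summation over outcomes and states, and
Gaussian evidence by numerical quadrature.  These routines are the
acceptance authority against which the message-passing engines are checked;
nothing in the package's inference path calls them.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._util import LOG_FLOOR
from .discrete_model import DiscreteModel


@dataclass
class EnumerationResult:
    """Exact posterior summaries from full sequence enumeration."""

    marginals: list            # per factor, (T, n_states) smoothed marginals
    joint_marginals: np.ndarray  # (T, *state_dims) joint per-epoch marginals
    joint: dict                # sequence of joint-state tuples -> probability
    log_evidence: float


def _policy_action(model, policy, step, factor):
    if factor in model.control_factors:
        k = model.control_factors.index(factor)
        step = min(step, model.policies.shape[0] - 1)
        return int(model.policies[step, policy, k])
    return 0


def enumerate_posterior(model: DiscreteModel, observations, policy=0,
                        max_sequences=10**6) -> EnumerationResult:
    """Exact smoothed marginals by summing the joint over all sequences.

    ``observations`` uses the engine convention: a sequence of length <= T
    with ``None`` for unobserved epochs and per-modality outcome indices
    otherwise.  Soft (vector) evidence is honoured as a likelihood weight.
    Works in linear space with extended-precision accumulation — tiny
    instances only (the total sequence count must not exceed
    ``max_sequences``).
    """
    T = model.T
    dims = model.state_dims
    joint_states = list(itertools.product(*[range(n) for n in dims]))
    n_seq = len(joint_states) ** T
    if n_seq > max_sequences:
        raise ValueError(f"{n_seq} sequences exceed the enumeration cap")

    obs = list(observations) + [None] * (T - len(observations)) \
        if observations is not None else [None] * T

    def lik(tau, state):
        if obs[tau] is None:
            return np.longdouble(1.0)
        w = np.longdouble(1.0)
        for m, om in enumerate(obs[tau]):
            col = model.A[m][(slice(None),) + state]
            if np.isscalar(om) or (isinstance(om, np.ndarray) and om.ndim == 0):
                w *= np.longdouble(col[int(om)])
            else:
                w *= np.longdouble(float(np.dot(np.asarray(om, float), col)))
        return w

    joint: dict = {}
    Z = np.longdouble(0.0)
    per_epoch = np.zeros((T,) + dims, dtype=np.longdouble)
    for seq in itertools.product(joint_states, repeat=T):
        p = np.longdouble(1.0)
        for f in range(model.n_factors):
            p *= np.longdouble(model.D_vector(f)[seq[0][f]])
        for tau in range(1, T):
            for f in range(model.n_factors):
                a = _policy_action(model, policy, tau - 1, f)
                p *= np.longdouble(model.B[f][seq[tau][f], seq[tau - 1][f], a])
        for tau in range(T):
            p *= lik(tau, seq[tau])
        if p > 0:
            joint[seq] = joint.get(seq, np.longdouble(0.0)) + p
            Z += p
            for tau in range(T):
                per_epoch[(tau,) + seq[tau]] += p
    if Z <= 0:
        raise ValueError("observation sequence has zero probability")
    per_epoch /= Z
    joint = {k: float(v / Z) for k, v in joint.items()}
    marginals = []
    for f in range(model.n_factors):
        other = tuple(1 + g for g in range(model.n_factors) if g != f)
        marginals.append(np.asarray(per_epoch.sum(axis=other), dtype=float))
    return EnumerationResult(
        marginals=marginals,
        joint_marginals=np.asarray(per_epoch, dtype=float),
        joint=joint,
        log_evidence=float(np.log(Z)),
    )


def enumerate_G(model: DiscreteModel, s, *, from_epoch=0) -> float:
    """Expected free energy by explicit summation (risk plus ambiguity).

    Loops over every outcome and hidden-state combination rather than using
    array contractions, applying the same log-floor convention as the
    engine so agreement is exact rather than merely close.
    """
    dims = model.state_dims
    joint_states = list(itertools.product(*[range(n) for n in dims]))
    G = 0.0
    for tau in range(from_epoch, model.T):
        s_tau = [s[f][tau] for f in range(model.n_factors)]
        p_state = {}
        for state in joint_states:
            w = 1.0
            for f, j in enumerate(state):
                w *= float(s_tau[f][j])
            p_state[state] = w
        for m, Am in enumerate(model.A):
            C = model.C_at(m, tau)
            n_out = Am.shape[0]
            o = np.zeros(n_out)
            for i in range(n_out):
                for state, w in p_state.items():
                    o[i] += float(Am[(i,) + state]) * w
            o = o / o.sum()
            for i in range(n_out):
                G += o[i] * (np.log(o[i] + LOG_FLOOR) - float(C[i]))
        for state, w in p_state.items():
            h = 0.0
            for Am in model.A:
                for i in range(Am.shape[0]):
                    a = float(Am[(i,) + state])
                    h -= a * np.log(a + LOG_FLOOR)
            G += w * max(h, 0.0)
    return G


def gaussian_evidence_quadrature(prior_mean, prior_cov, likelihood_terms,
                                 *, half_width=12.0, n_points=1201) -> float:
    """Log evidence of Gaussian observations under a Gaussian prior, by
    grid quadrature (dimension <= 2).

    ``likelihood_terms`` is a list of ``(H, o, Pi)`` triples meaning an
    observation ``o = H v + noise`` with noise precision ``Pi``.  The grid
    is centred on the analytic posterior mode purely for placement; the
    value itself comes from Simpson integration of the unnormalized
    density.  Refines the grid once and checks convergence to ~1e-8.
    """
    from scipy.integrate import simpson

    eta = np.atleast_1d(np.asarray(prior_mean, dtype=float))
    d = eta.size
    if d > 2:
        raise ValueError("quadrature oracle supports dimension <= 2 only")
    P0 = np.atleast_2d(np.asarray(prior_cov, dtype=float))
    Pi0 = np.linalg.inv(P0)
    terms = [(np.atleast_2d(np.asarray(H, float)).reshape(-1, d),
              np.atleast_1d(np.asarray(o, float)),
              np.atleast_2d(np.asarray(Pi, float)))
             for H, o, Pi in likelihood_terms]

    # posterior mode/covariance for grid placement only
    Pp = Pi0 + sum(H.T @ Pi @ H for H, _, Pi in terms)
    bp = Pi0 @ eta + sum(H.T @ Pi @ o for H, o, Pi in terms)
    mu = np.linalg.solve(Pp, bp)
    sd = np.sqrt(np.diag(np.linalg.inv(Pp)))

    def log_density_grid(V):
        """Vectorized log density over points ``V`` of shape (m, d)."""
        dv = V - eta
        val = -0.5 * np.einsum("mi,ij,mj->m", dv, Pi0, dv) - 0.5 * (
            d * np.log(2 * np.pi) - np.log(np.linalg.det(Pi0)))
        for H, o, Pi in terms:
            e = o[None, :] - V @ H.T
            k = o.size
            val += -0.5 * np.einsum("mi,ij,mj->m", e, Pi, e) - 0.5 * (
                k * np.log(2 * np.pi) - np.log(np.linalg.det(Pi)))
        if not np.all(np.isfinite(val)):
            raise FloatingPointError("non-finite integrand")
        return val

    def integrate(n):
        axes = [mu[i] + np.linspace(-half_width, half_width, n) * sd[i]
                for i in range(d)]
        if d == 1:
            logf = log_density_grid(axes[0][:, None])
            m = logf.max()
            return m + np.log(simpson(np.exp(logf - m), x=axes[0]))
        V0, V1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        V = np.stack([V0.ravel(), V1.ravel()], axis=1)
        logf = log_density_grid(V).reshape(n, n)
        m = logf.max()
        inner = simpson(np.exp(logf - m), x=axes[1], axis=1)
        return m + np.log(simpson(inner, x=axes[0]))

    n = n_points if d == 1 else 241
    v1 = integrate(n)
    v2 = integrate(2 * n - 1)
    if abs(v2 - v1) > 1e-6 * max(1.0, abs(v2)):
        raise RuntimeError("quadrature did not converge")
    return float(v2)
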