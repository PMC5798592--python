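"""The discrete-continuous link factor.

Each discrete outcome is treated, from the continuous level's point of
view, as a *model* of dynamics: a Gaussian prior ``(eta_m, Pi_m)`` over the
hidden causes ``v``.  Descending messages average these priors under the
discrete outcome distribution (Bayesian model averaging, moment-matched to
a single Gaussian).  Ascending messages score every outcome model against
the continuous posterior by post hoc (reduced) Bayesian model comparison,
accumulating the relative log evidence over the integration window:

    E_m(t) = -ln o_m - integral_0^T L_m(t) dt
    L_m(t) = ln P(o~(t) | eta_m) - ln P(o~(t) | eta_bar)

and the ascending categorical posterior is ``softmax(-E)``.  When the
accumulation window shrinks to zero the posterior reduces exactly to the
descending prior.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import LOG_FLOOR, normalize, softmax


class IllPosedReductionError(ValueError):
    """The reduced posterior precision is not positive definite."""


@dataclass
class GaussianBelief:
    """A Gaussian density over hidden causes (Laplace assumption)."""

    mean: np.ndarray
    precision: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.precision = np.atleast_2d(np.asarray(self.precision, dtype=float))
        try:
            np.linalg.cholesky(self.precision)
        except np.linalg.LinAlgError as exc:
            raise ValueError("precision must be symmetric positive definite") from exc

    @property
    def cov(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class LinkSpec:
    """State of the link factor: outcome models and accumulated evidence."""

    models: list                      # list of (eta_m, Pi_m)
    prior_o: np.ndarray               # descending categorical prior
    L: np.ndarray = None              # accumulated relative log evidences
    T_accum: float = 0.0
    _prev_rle: np.ndarray = None      # running baseline within a window

    def __post_init__(self):
        self.models = [
            (np.atleast_1d(np.asarray(e, dtype=float)),
             np.atleast_2d(np.asarray(P, dtype=float)))
            for e, P in self.models
        ]
        self.prior_o = normalize(np.asarray(self.prior_o, dtype=float))
        if self.L is None:
            self.L = np.zeros(len(self.models))
        self.L = np.asarray(self.L, dtype=float)

    @property
    def E(self) -> np.ndarray:
        """Free energy of each outcome model: prior surprise minus
        accumulated log evidence."""
        return -np.log(self.prior_o + LOG_FLOOR) - self.L

    @property
    def posterior_o(self) -> np.ndarray:
        return softmax(-self.E)


def descending_prior(models, prior_o) -> GaussianBelief:
    """Moment-matched Bayesian model average of Gaussian priors.

    Mean ``eta_bar = sum_m o_m eta_m``; covariance is the within-model
    average plus the between-model spread, inverted back to a precision.
    """
    prior_o = normalize(np.asarray(prior_o, dtype=float))
    etas = [np.atleast_1d(np.asarray(e, float)) for e, _ in models]
    covs = [np.linalg.inv(np.atleast_2d(np.asarray(P, float))) for _, P in models]
    mean = sum(o * e for o, e in zip(prior_o, etas))
    second = sum(o * (c + np.outer(e, e))
                 for o, e, c in zip(prior_o, etas, covs))
    cov = second - np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T)
    try:
        precision = np.linalg.inv(cov)
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise IllPosedReductionError("mixture covariance is degenerate") from exc
    return GaussianBelief(mean=mean, precision=precision)


def reduced_log_evidence(posterior: GaussianBelief, full_prior: GaussianBelief,
                         reduced_prior) -> float:
    """Relative log evidence of a reduced prior, without refitting.

    Given a posterior obtained under a full prior, the evidence a reduced
    prior ``(eta_m, Pi_m)`` would have received follows from the Gaussian
    identity ``ln P(o|eta_m) - ln P(o|eta_bar) = ln E_q[p_m(v)/p_full(v)]``,
    which reduces to quadratic forms and log-determinants of the four
    precisions involved.  Zero when the reduced prior equals the full one,
    and zero for any admissible reduction when no data arrived (posterior
    equals the prior).
    """
    eta_m, Pi_m = reduced_prior
    eta_m = np.atleast_1d(np.asarray(eta_m, dtype=float))
    Pi_m = np.atleast_2d(np.asarray(Pi_m, dtype=float))
    Pq, Pf = posterior.precision, full_prior.precision
    mq, mf = posterior.mean, full_prior.mean

    P_red = Pq + Pi_m - Pf
    try:
        np.linalg.cholesky(P_red)
    except np.linalg.LinAlgError as exc:
        raise IllPosedReductionError(
            "reduced posterior precision not positive definite") from exc

    b = Pq @ mq + Pi_m @ eta_m - Pf @ mf
    c = mq @ Pq @ mq + eta_m @ Pi_m @ eta_m - mf @ Pf @ mf
    _, ld_q = np.linalg.slogdet(Pq)
    _, ld_m = np.linalg.slogdet(Pi_m)
    _, ld_f = np.linalg.slogdet(Pf)
    _, ld_r = np.linalg.slogdet(P_red)
    quad = b @ np.linalg.solve(P_red, b)
    return 0.5 * float(ld_q + ld_m - ld_f - ld_r + quad - c)


def accumulate(link: LinkSpec, snapshots, dt: float,
               full_prior: GaussianBelief | None = None) -> LinkSpec:
    """Evidence accumulation over a window of posterior snapshots.

    Each snapshot is the Laplace posterior over causes given the evidence
    gathered *up to* that integration step (precision grows at the
    information rate times ``dt``).  The integrand of the accumulated log
    evidence is therefore the per-step *increment* of the reduced log
    evidence — summing increments telescopes to the reduced log evidence of
    the window's final posterior, which is the time integral of the
    instantaneous log-likelihood ratio.  Accumulating two consecutive
    windows is exactly equivalent to accumulating their concatenation.
    Updates ``L`` and ``T_accum`` in place and returns the link.
    """
    if full_prior is None:
        full_prior = descending_prior(link.models, link.prior_o)
    if link._prev_rle is None:
        link._prev_rle = np.zeros(len(link.models))  # prior's own evidence
    for q in snapshots:
        cur = np.array([reduced_log_evidence(q, full_prior, reduced)
                        for reduced in link.models])
        link.L += cur - link._prev_rle
        link._prev_rle = cur
        link.T_accum += dt
    return link


def link_cycle(link: LinkSpec, model, process, n_steps: int, dt: float, *,
               seed=None, rng=None, with_action: bool = True,
               state=None, method: str = "euler"):
    """One full descending/ascending exchange through the link node.

    Installs the Bayesian-model-average prior in the continuous model, runs
    the generalized filter (with action) against the process for the
    window, accumulates reduced log evidence at every step, and returns
    ``(posterior_o, trajectory)``.
    """
    from .continuous_engine import integrate

    prior = descending_prior(link.models, link.prior_o)
    model.eta = prior.mean
    model.Pi_eta = prior.precision
    link._prev_rle = None  # a fresh window starts at the prior
    if state is not None:
        state.mu_v = np.array(prior.mean)
    traj = integrate(model, process, n_steps, dt, seed=seed, rng=rng,
                     state=state, with_action=with_action, method=method,
                     record_cause_posterior=True)
    accumulate(link, traj.cause_posteriors, dt, full_prior=prior)
    return link.posterior_o, traj
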