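"""Discrete (MDP) generative models for active inference.

A model is specified by the standard partially-observed Markov decision
process arrays used throughout the active-inference literature:

``A``
    one likelihood array per outcome *modality*; ``A[m][o, s1, .., sK]`` is
    the probability of outcome ``o`` in modality ``m`` given the combination
    of hidden-state factors ``(s1, .., sK)``.  Each column (fixing the state
    combination) is a categorical distribution over outcomes.
``B``
    one transition array per hidden-state *factor*; ``B[f][s', s, u]`` is the
    probability of moving to state ``s'`` from ``s`` under action ``u``.
    Uncontrollable factors carry a single action.
``C``
    log-preferences over outcomes per modality, optionally time dependent
    (shape ``(T, n_outcomes)``); a plain vector is broadcast over time.
``D``
    prior over the initial state of each factor.  In deep (hierarchical)
    models ``D`` is promoted to a matrix whose columns are indexed by the
    state of the level above.
``H``
    the outcome ambiguity of each hidden-state combination — the conditional
    entropy of outcomes given the state, summed over modalities.  Computed
    from ``A`` when not supplied.
``policies``
    an integer array of shape ``(n_steps, n_policies, n_control)`` giving,
    for every entertained policy, the action applied to each controllable
    factor at each transition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import LOG_FLOOR, log_stable, softmax


class DegenerateInputError(ValueError):
    """Raised when an input array cannot define a proper distribution."""


class StructuralError(ValueError):
    """Raised when model arrays have mutually inconsistent shapes."""


def normalize_columns(arr: np.ndarray) -> np.ndarray:
    """Rescale a nonnegative array so every column sums to one.

    "Column" means the leading axis: ``out[i, j.. ] = arr[i, j..] / sum_k
    arr[k, j..]``, turning any nonnegative array into a proper conditional
    probability table.  Idempotent.

    Raises
    ------
    DegenerateInputError
        if any entry is negative or any column sums to zero.
    """
    arr = np.asarray(arr, dtype=float)
    if np.any(arr < 0):
        raise DegenerateInputError("negative entries")
    s = arr.sum(axis=0)
    if np.any(s <= 0):
        raise DegenerateInputError("all-zero column")
    return arr / s


def ambiguity(A) -> np.ndarray:
    """Outcome ambiguity ``H`` per hidden-state combination.

    ``H[s] = sum_m -sum_o A[m][o, s] ln A[m][o, s]`` — the conditional
    entropy of outcomes given the state, added over modalities.  Logs use the
    shared log-floor; the tiny negative bias this induces for deterministic
    columns is clamped to zero so that ``H >= 0`` holds exactly.

    ``A`` may be a single array or a list of per-modality arrays.
    """
    if isinstance(A, np.ndarray):
        A = [A]
    H = None
    for Am in A:
        Am = np.asarray(Am, dtype=float)
        h = -(Am * np.log(Am + LOG_FLOOR)).sum(axis=0)
        H = h if H is None else H + h
    return np.clip(H, 0.0, None)


@dataclass
class DiscreteModel:
    """One level of a discrete generative model (see module docstring)."""

    A: list
    B: list
    D: list
    C: list | None = None
    policies: np.ndarray | None = None
    T: int = 1
    control_factors: tuple = ()
    H: np.ndarray | None = None

    def __post_init__(self):
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        self.D = [np.asarray(d, dtype=float) for d in self.D]
        if self.C is None:
            self.C = [np.zeros(a.shape[0]) for a in self.A]
        self.C = [np.asarray(c, dtype=float) for c in self.C]
        self.control_factors = tuple(self.control_factors)
        if self.policies is None:
            n_steps = max(self.T - 1, 1)
            self.policies = np.zeros(
                (n_steps, 1, len(self.control_factors)), dtype=int
            )
        self.policies = np.asarray(self.policies, dtype=int)
        if self.policies.ndim != 3:
            raise StructuralError("policies must have shape (steps, policies, control factors)")
        if self.H is None:
            if self.A:
                self.H = ambiguity(self.A)
            else:  # no outcome modalities (e.g. a purely contextual level)
                self.H = np.zeros(tuple(b.shape[0] for b in self.B))
        self.H = np.asarray(self.H, dtype=float)

    # -- shape helpers -----------------------------------------------------
    @property
    def state_dims(self) -> tuple:
        return tuple(b.shape[0] for b in self.B)

    @property
    def n_factors(self) -> int:
        return len(self.B)

    @property
    def n_modalities(self) -> int:
        return len(self.A)

    @property
    def outcome_dims(self) -> tuple:
        return tuple(a.shape[0] for a in self.A)

    @property
    def n_policies(self) -> int:
        return self.policies.shape[1]

    def n_actions(self, factor: int) -> int:
        return self.B[factor].shape[2]

    def C_at(self, modality: int, tau: int) -> np.ndarray:
        """Log-preference vector for a modality at epoch ``tau``.

        Time-constant preferences (1-D ``C``) are broadcast over epochs.
        """
        c = self.C[modality]
        if c.ndim == 1:
            return c
        return c[min(tau, c.shape[0] - 1)]

    def D_vector(self, factor: int, context: np.ndarray | None = None) -> np.ndarray:
        """Initial-state prior for a factor, averaging matrix-valued ``D``
        over a supplied distribution on the higher-level state."""
        d = self.D[factor]
        if d.ndim == 1:
            return d
        if context is None:
            context = np.full(d.shape[1], 1.0 / d.shape[1])
        return d @ np.asarray(context, dtype=float)


@dataclass
class BeliefState:
    """Posterior quantities tracked by the discrete engine.

    ``s[p][f]`` holds expectations over factor ``f`` under policy ``p`` as an
    array of shape ``(T, n_states)``; ``nu`` are the corresponding
    log-expectations (depolarizations) and ``eps_state`` the state prediction
    errors.  ``pi`` is the policy posterior, ``o_pred[p][m]`` the predicted
    outcomes, ``bma[f]`` the policy-averaged state expectations, ``G`` the
    expected free energy per policy, and ``F`` the per-iteration marginal
    free-energy trace of the last update.
    """

    s: list = field(default_factory=list)
    nu: list = field(default_factory=list)
    eps_state: list = field(default_factory=list)
    pi: np.ndarray | None = None
    o_pred: list = field(default_factory=list)
    bma: list = field(default_factory=list)
    G: np.ndarray | None = None
    F: np.ndarray | None = None


@dataclass
class ValidationReport:
    ok: bool
    problems: list

    def __bool__(self) -> bool:
        return self.ok


def validate_model(model: DiscreteModel, atol: float = 1e-10) -> ValidationReport:
    """Check the structural invariants of a :class:`DiscreteModel`.

    Verifies that every conditional probability table is column-stochastic,
    that likelihood arrays span the cross-product of the state factors, that
    policy entries index valid actions and that ``H`` is nonnegative.
    Returns a report rather than raising so callers can surface all
    violations at once.
    """
    problems: list = []
    dims = model.state_dims

    for m, a in enumerate(model.A):
        if a.shape[1:] != dims:
            problems.append(
                f"A[{m}] state axes {a.shape[1:]} != state factor dims {dims}"
            )
            continue
        if np.any(a < 0):
            problems.append(f"A[{m}] has negative entries")
        colsum = a.sum(axis=0)
        bad = np.argwhere(np.abs(colsum - 1.0) > atol)
        if bad.size:
            j = tuple(int(x) for x in bad[0])
            problems.append(
                f"A[{m}] column {j} sums to {colsum[j]:.6g} (expected 1)"
            )
    for f, b in enumerate(model.B):
        if b.ndim != 3 or b.shape[0] != b.shape[1]:
            problems.append(f"B[{f}] must be (n, n, n_actions), got {b.shape}")
            continue
        if np.any(b < 0):
            problems.append(f"B[{f}] has negative entries")
        colsum = b.sum(axis=0)
        bad = np.argwhere(np.abs(colsum - 1.0) > atol)
        if bad.size:
            j = tuple(int(x) for x in bad[0])
            problems.append(
                f"B[{f}] column {j} sums to {colsum[j]:.6g} (expected 1)"
            )
    for f, d in enumerate(model.D):
        if d.shape[0] != dims[f]:
            problems.append(f"D[{f}] length {d.shape[0]} != factor dim {dims[f]}")
            continue
        colsum = d.sum(axis=0)
        bad = np.argwhere(np.abs(np.atleast_1d(colsum) - 1.0) > atol)
        if bad.size:
            problems.append(f"D[{f}] column {tuple(bad[0])} sums to "
                            f"{np.atleast_1d(colsum)[tuple(bad[0])]:.6g}")
    for m, c in enumerate(model.C):
        if c.shape[-1] != model.outcome_dims[m]:
            problems.append(f"C[{m}] length mismatch with A[{m}]")
    if model.policies.shape[2] != len(model.control_factors):
        problems.append("policies last axis != number of controllable factors")
    else:
        for k, f in enumerate(model.control_factors):
            na = model.n_actions(f)
            u = model.policies[:, :, k]
            if np.any((u < 0) | (u >= na)):
                problems.append(
                    f"policy action index out of range for factor {f} "
                    f"(valid 0..{na - 1})"
                )
    if model.H.shape != dims:
        problems.append(f"H shape {model.H.shape} != state dims {dims}")
    elif np.any(model.H < 0):
        problems.append("H has negative entries")

    return ValidationReport(ok=not problems, problems=problems)


__all__ = [
    "DiscreteModel",
    "BeliefState",
    "ValidationReport",
    "DegenerateInputError",
    "StructuralError",
    "normalize_columns",
    "ambiguity",
    "validate_model",
    "log_stable",
    "softmax",
]
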