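"""Generalized-coordinate variational filtering with active sampling.

Continuous hidden states are represented together with their temporal
derivatives, ``x~ = (x, x', x'', ...)``, up to a configurable embedding
order.  A model supplies a flow ``f(x, v)`` for the state motion, a static
observation mapping ``g(x, v)``, per-order precisions on state noise and
outcomes, and a Gaussian prior ``(eta, Pi_eta)`` over the hidden causes
``v``.  Inference integrates the generalized gradient flow

    d/dt mu~ = Delta mu~ - dF/dmu~

so that, at stationarity, the motion of the mean equals the mean of the
motion.  With a single embedding order and linear mappings this reduces to
the classical conjugate (Kalman-filter-limit) Gaussian update, which the
test-suite exploits as an exact reference.

Action is treated exactly as in the theory: it can only change outcomes, so
its update descends the outcome prediction error through the process's
``do/da`` sensitivity.  Generalized nonlinearities are propagated to first
order (Jacobians evaluated at the current expansion point); higher
derivatives of ``f`` and ``g`` are deliberately ignored.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class IntegrationError(RuntimeError):
    pass


def _as_precision(value, dim: int) -> np.ndarray:
    v = np.asarray(value, dtype=float)
    if v.ndim == 0:
        return float(v) * np.eye(dim)
    if v.ndim == 1:
        return np.diag(v)
    return v


def _precision_list(value, dim: int, n_orders: int) -> list:
    """Broadcast a scalar / vector / matrix / per-order list of precisions."""
    if isinstance(value, (list, tuple)):
        out = [_as_precision(v, dim) for v in value]
        if len(out) != n_orders:
            raise ValueError("need one precision per embedding order")
        return out
    return [_as_precision(value, dim) for _ in range(n_orders)]


def shift(arr: np.ndarray, transpose: bool = False) -> np.ndarray:
    """The order-shift operator ``Delta`` on a generalized vector.

    ``arr`` has shape ``(n_orders, dim)``.  ``Delta`` promotes each
    component to the next order of motion, ``(x, x', x'') -> (x', x'', 0)``.
    With ``transpose=True`` the adjoint (matrix transpose) is applied,
    demoting orders: ``(x, x', x'') -> (0, x, x')``; this is the operator
    that appears in the free-energy gradient.
    """
    out = np.zeros_like(arr)
    if transpose:
        out[1:] = arr[:-1]
    else:
        out[:-1] = arr[1:]
    return out


@dataclass
class ContinuousModel:
    """Generalized state-space model (see module docstring).

    ``g(x, v)`` maps the zeroth-order state and causes to predicted
    outcomes; ``f(x, v)`` gives the state motion (``None`` for a static
    model).  ``Pi_o`` / ``Pi_x`` accept a scalar, vector, matrix, or a
    per-order list thereof.  Jacobians default to central finite
    differences; analytic ones may be supplied via ``gx, gv, fx, fv``.
    """

    g: object
    f: object
    dim_x: int
    dim_v: int
    dim_o: int
    n_orders: int = 2
    Pi_o: object = 1.0
    Pi_x: object = 1.0
    eta: np.ndarray | None = None
    Pi_eta: object = 1.0
    gx: object = None
    gv: object = None
    fx: object = None
    fv: object = None
    jac_eps: float = 1e-6

    def __post_init__(self):
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        self.Pi_o = _precision_list(self.Pi_o, self.dim_o, self.n_orders)
        self.Pi_x = _precision_list(self.Pi_x, self.dim_x, self.n_orders)
        if self.eta is None:
            self.eta = np.zeros(self.dim_v)
        self.eta = np.asarray(self.eta, dtype=float)
        self.Pi_eta = _as_precision(self.Pi_eta, self.dim_v)

    # -- first-order derivative machinery ---------------------------------
    def _fd_jac(self, fn, x, v, wrt: str) -> np.ndarray:
        base = np.asarray(fn(x, v), dtype=float)
        target = x if wrt == "x" else v
        J = np.zeros((base.size, target.size))
        for j in range(target.size):
            dp = np.array(target, dtype=float)
            dm = np.array(target, dtype=float)
            dp[j] += self.jac_eps
            dm[j] -= self.jac_eps
            if wrt == "x":
                hi, lo = fn(dp, v), fn(dm, v)
            else:
                hi, lo = fn(x, dp), fn(x, dm)
            J[:, j] = (np.asarray(hi, float) - np.asarray(lo, float)) / (2 * self.jac_eps)
        return J

    def jac_g(self, x, v):
        Jx = (np.asarray(self.gx(x, v), float) if self.gx is not None
              else self._fd_jac(self.g, x, v, "x")) if self.dim_x else \
            np.zeros((self.dim_o, 0))
        Jv = (np.asarray(self.gv(x, v), float) if self.gv is not None
              else self._fd_jac(self.g, x, v, "v"))
        return Jx, Jv

    def jac_f(self, x, v):
        if self.f is None or self.dim_x == 0:
            return np.zeros((self.dim_x, self.dim_x)), np.zeros((self.dim_x, self.dim_v))
        Jx = (np.asarray(self.fx(x, v), float) if self.fx is not None
              else self._fd_jac(self.f, x, v, "x"))
        Jv = (np.asarray(self.fv(x, v), float) if self.fv is not None
              else self._fd_jac(self.f, x, v, "v"))
        return Jx, Jv


@dataclass
class GeneralizedState:
    """Sufficient statistics carried by the filter."""

    mu_x: np.ndarray
    mu_v: np.ndarray
    a: np.ndarray
    eps_x: np.ndarray | None = None
    eps_o: np.ndarray | None = None
    F: float = np.nan

    @classmethod
    def zeros(cls, model: ContinuousModel, dim_a: int = 0) -> "GeneralizedState":
        return cls(mu_x=np.zeros((model.n_orders, model.dim_x)),
                   mu_v=np.array(model.eta, dtype=float),
                   a=np.zeros(dim_a))


def prediction_errors(model: ContinuousModel, mu_x, mu_v, obs):
    """Generalized prediction errors ``(eps_x, eps_o)``.

    ``eps_x[i] = x[i+1] - f[i]`` (with the order above the embedding taken
    as zero) and ``eps_o[i] = o[i] - g[i]``, where the generalized
    ``f[i], g[i]`` for ``i >= 1`` follow from first-order chain-rule
    propagation of the Jacobians at the zeroth-order expansion point.
    """
    mu_x = np.asarray(mu_x, dtype=float)
    mu_v = np.asarray(mu_v, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = model.n_orders
    x0 = mu_x[0] if model.dim_x else np.zeros(0)

    Jgx, _ = model.jac_g(x0, mu_v)
    Jfx, _ = model.jac_f(x0, mu_v)

    f_gen = np.zeros((n, model.dim_x))
    g_gen = np.zeros((n, model.dim_o))
    if model.f is not None and model.dim_x:
        f_gen[0] = np.asarray(model.f(x0, mu_v), dtype=float)
    g_gen[0] = np.asarray(model.g(x0, mu_v), dtype=float)
    for i in range(1, n):
        if model.dim_x:
            f_gen[i] = Jfx @ mu_x[i]
            g_gen[i] = Jgx @ mu_x[i]

    eps_x = shift(mu_x) - f_gen if model.dim_x else np.zeros((n, 0))
    eps_o = obs - g_gen
    if not (np.all(np.isfinite(eps_x)) and np.all(np.isfinite(eps_o))):
        raise IntegrationError("non-finite prediction error")
    return eps_x, eps_o


def free_energy(model: ContinuousModel, mu_x, mu_v, obs) -> float:
    """Instantaneous free energy (precision-weighted squared errors plus the
    cause prior term; state-independent log-determinants omitted)."""
    eps_x, eps_o = prediction_errors(model, mu_x, mu_v, obs)
    F = 0.0
    for i in range(model.n_orders):
        F += 0.5 * float(eps_o[i] @ model.Pi_o[i] @ eps_o[i])
        if model.dim_x:
            F += 0.5 * float(eps_x[i] @ model.Pi_x[i] @ eps_x[i])
    dv = np.asarray(mu_v, float) - model.eta
    F += 0.5 * float(dv @ model.Pi_eta @ dv)
    return F


def _gradients(model: ContinuousModel, mu_x, mu_v, obs):
    """Analytic ``(dF/dmu_x, dF/dmu_v, eps_x, eps_o)`` from the error form."""
    eps_x, eps_o = prediction_errors(model, mu_x, mu_v, obs)
    x0 = mu_x[0] if model.dim_x else np.zeros(0)
    Jgx, Jgv = model.jac_g(x0, mu_v)
    Jfx, Jfv = model.jac_f(x0, mu_v)
    n = model.n_orders

    dFdx = np.zeros((n, model.dim_x))
    for i in range(n):
        if model.dim_x:
            dFdx[i] = -Jgx.T @ (model.Pi_o[i] @ eps_o[i])
            dFdx[i] -= Jfx.T @ (model.Pi_x[i] @ eps_x[i])
            if i >= 1:
                dFdx[i] += model.Pi_x[i - 1] @ eps_x[i - 1]
    dFdv = -Jgv.T @ (model.Pi_o[0] @ eps_o[0])
    if model.dim_x:
        dFdv -= Jfv.T @ (model.Pi_x[0] @ eps_x[0])
    dFdv += model.Pi_eta @ (np.asarray(mu_v, float) - model.eta)
    return dFdx, dFdv, eps_x, eps_o


def _gauss_newton_curvature(model: ContinuousModel, mu_x, mu_v) -> np.ndarray:
    """Gauss-Newton curvature of F in the stacked mean ``(x~, v)``.

    Assembled from the first-order Jacobians of the error terms (residual
    curvature of ``f`` and ``g`` is ignored, consistent with the first-order
    propagation used everywhere else).  Used by the local-linearization
    integrator for stiff models.
    """
    n, dx, dv = model.n_orders, model.dim_x, model.dim_v
    d = n * dx + dv
    x0 = mu_x[0] if dx else np.zeros(0)
    Jgx, Jgv = model.jac_g(x0, mu_v)
    Jfx, Jfv = model.jac_f(x0, mu_v)
    H = np.zeros((d, d))
    iv = n * dx  # offset of the cause block

    def blk(i):
        return slice(i * dx, (i + 1) * dx)

    for i in range(n):
        # outcome errors: d eps_o[i] = -Jgx dx[i] (and -Jgv dv at order 0)
        E = []
        if dx:
            E.append((blk(i), -Jgx))
        if i == 0:
            E.append((slice(iv, d), -Jgv))
        for sa, Ja in E:
            for sb, Jb in E:
                H[sa, sb] += Ja.T @ model.Pi_o[i] @ Jb
        if not dx:
            continue
        # state errors: d eps_x[i] = dx[i+1] - Jfx dx[i] (- Jfv dv at order 0)
        E = [(blk(i), -Jfx)]
        if i + 1 < n:
            E.append((blk(i + 1), np.eye(dx)))
        if i == 0:
            E.append((slice(iv, d), -Jfv))
        for sa, Ja in E:
            for sb, Jb in E:
                H[sa, sb] += Ja.T @ model.Pi_x[i] @ Jb
    H[iv:, iv:] += model.Pi_eta
    return H


def filter_step(model: ContinuousModel, state: GeneralizedState, obs,
                dt: float, *, bound: float = 1e8,
                method: str = "euler") -> GeneralizedState:
    """One step of ``d/dt mu~ = Delta mu~ - dF/dmu~``.

    ``method="euler"`` is a plain explicit step; ``method="local_linear"``
    solves ``(I - dt J) dmu = dt r(mu)`` with the drift Jacobian assembled
    from the Gauss-Newton curvature — unconditionally stable for the stiff
    precision-dominated regimes (e.g. high-dimensional image likelihoods).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dFdx, dFdv, eps_x, eps_o = _gradients(model, state.mu_x, state.mu_v, obs)
    drift_x = shift(state.mu_x) - dFdx
    drift_v = -dFdv
    if method == "euler":
        mu_x = state.mu_x + dt * drift_x
        mu_v = state.mu_v + dt * drift_v
    elif method == "local_linear":
        n, dx, dv = model.n_orders, model.dim_x, model.dim_v
        d = n * dx + dv
        J = -_gauss_newton_curvature(model, state.mu_x, state.mu_v)
        for i in range(n - 1):  # the Delta block of the drift
            J[i * dx:(i + 1) * dx, (i + 1) * dx:(i + 2) * dx] += np.eye(dx)
        r = np.concatenate([drift_x.reshape(-1), drift_v])
        delta = np.linalg.solve(np.eye(d) - dt * J, dt * r)
        mu_x = state.mu_x + delta[:n * dx].reshape(n, dx)
        mu_v = state.mu_v + delta[n * dx:]
    else:
        raise ValueError(f"unknown integration method {method!r}")
    if max(np.abs(mu_x).max(initial=0.0), np.abs(mu_v).max(initial=0.0)) > bound:
        raise IntegrationError("state norm exceeded divergence bound")
    new = GeneralizedState(mu_x=mu_x, mu_v=mu_v, a=state.a.copy(),
                           eps_x=eps_x, eps_o=eps_o)
    new.F = free_energy(model, mu_x, mu_v, obs)
    return new


def action_update(model: ContinuousModel, state: GeneralizedState, process,
                  obs, dt: float) -> np.ndarray:
    """Action descends the outcome prediction error only:
    ``da/dt = -(do~/da)^T Pi_o eps~_o``.

    The process sensitivity ``do_da`` may be ``(dim_o, dim_a)`` (applied to
    the zeroth order) or ``(n_orders, dim_o, dim_a)`` to let higher orders
    of motion (e.g. proprioceptive velocity error) contribute.
    """
    if not hasattr(process, "do_da"):
        raise AttributeError("process must expose do_da(x, a)")
    _, eps_o = prediction_errors(model, state.mu_x, state.mu_v, obs)
    J = np.asarray(process.do_da(state.a), dtype=float)
    if J.ndim == 2:
        da = -(J.T @ (model.Pi_o[0] @ eps_o[0]))
    else:
        da = -sum(J[i].T @ (model.Pi_o[i] @ eps_o[i])
                  for i in range(min(J.shape[0], model.n_orders)))
    a = state.a + dt * da
    state.a = a
    return a


@dataclass
class ContinuousProcess:
    """The true (acted-upon) dynamics: distinct from the generative model."""

    f: object                      # f(x, a) -> dx/dt
    g: object                      # g(x) -> o
    x0: np.ndarray
    dim_a: int
    noise_x_std: float = 0.0
    noise_o_std: float = 0.0
    _do_da: object = None          # (dim_o, dim_a) sensitivity, or callable
    g1: object = None              # optional first-order outcome g1(x, a)

    def do_da(self, a):
        if self._do_da is None:
            raise AttributeError("process has no do_da sensitivity")
        if callable(self._do_da):
            return self._do_da(a)
        return self._do_da


@dataclass
class Trajectory:
    mu_x: np.ndarray
    mu_v: np.ndarray
    a: np.ndarray
    x_true: np.ndarray
    o: np.ndarray
    F: np.ndarray
    eps_o: np.ndarray
    cause_posteriors: list = field(default_factory=list)


def cause_information_rate(model: ContinuousModel, state: GeneralizedState) -> np.ndarray:
    """Rate at which observations inform the hidden causes: the
    precision-weighted squared Jacobians ``Jgv' Pi_o Jgv + Jfv' Pi_x Jfv``
    evaluated at the current expansion point.  Integrated over a window
    (times ``dt``) this is the data contribution to the Laplace posterior
    precision over ``v``."""
    x0 = state.mu_x[0] if model.dim_x else np.zeros(0)
    _, Jgv = model.jac_g(x0, state.mu_v)
    _, Jfv = model.jac_f(x0, state.mu_v)
    R = Jgv.T @ model.Pi_o[0] @ Jgv
    if model.dim_x:
        R = R + Jfv.T @ model.Pi_x[0] @ Jfv
    return R


def cause_posterior(model: ContinuousModel, state: GeneralizedState,
                    information: np.ndarray | None = None):
    """Laplace posterior over hidden causes.

    Mean is the current filter expectation.  The precision is the prior
    precision plus the accumulated observation information for the window
    (``information``); when no accumulated information is supplied the
    instantaneous rate is used as a one-step approximation.
    """
    from .link_node import GaussianBelief

    if information is None:
        information = cause_information_rate(model, state)
    return GaussianBelief(mean=np.array(state.mu_v),
                          precision=model.Pi_eta + information)


def integrate(model: ContinuousModel, process: ContinuousProcess,
              n_steps: int, dt: float, *, seed=None, rng=None,
              state: GeneralizedState | None = None,
              with_action: bool = True, method: str = "euler",
              record_cause_posterior: bool = False) -> Trajectory:
    """Co-integrate the generative process (with noise and action) and the
    generalized filter for ``n_steps`` steps of size ``dt``.

    Reproducible bit-for-bit for a given ``(model, process, seed, dt)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if state is None:
        state = GeneralizedState.zeros(model, dim_a=process.dim_a)
    x_true = np.array(process.x0, dtype=float)

    rec = Trajectory(
        mu_x=np.zeros((n_steps, model.n_orders, model.dim_x)),
        mu_v=np.zeros((n_steps, model.dim_v)),
        a=np.zeros((n_steps, process.dim_a)),
        x_true=np.zeros((n_steps, x_true.size)),
        o=np.zeros((n_steps, model.dim_o)),
        F=np.zeros(n_steps),
        eps_o=np.zeros((n_steps, model.dim_o)),
    )
    obs = np.zeros((model.n_orders, model.dim_o))
    info_v = np.zeros((model.dim_v, model.dim_v))
    for k in range(n_steps):
        o = np.asarray(process.g(x_true), dtype=float)
        if np.any(np.asarray(process.noise_o_std)):
            o = o + np.asarray(process.noise_o_std) * rng.standard_normal(o.shape)
        obs[0] = o
        if model.n_orders > 1 and getattr(process, "g1", None) is not None:
            obs[1] = np.asarray(process.g1(x_true, state.a), dtype=float)
        state = filter_step(model, state, obs, dt, method=method)
        if with_action:
            action_update(model, state, process, obs, dt)
        rec.mu_x[k] = state.mu_x
        rec.mu_v[k] = state.mu_v
        rec.a[k] = state.a
        rec.x_true[k] = x_true
        rec.o[k] = o
        rec.F[k] = state.F
        rec.eps_o[k] = state.eps_o[0]
        if record_cause_posterior:
            info_v = info_v + dt * cause_information_rate(model, state)
            rec.cause_posteriors.append(cause_posterior(model, state, info_v))
        drift = np.asarray(process.f(x_true, state.a), dtype=float)
        x_true = x_true + dt * drift
        if np.any(np.asarray(process.noise_x_std)):
            x_true = x_true + np.sqrt(dt) * np.asarray(process.noise_x_std) * \
                rng.standard_normal(x_true.shape)
    return rec


def curvature_spectrum(model: ContinuousModel, state: GeneralizedState, obs,
                       *, wrt: str = "x", eps: float = 1e-4,
                       asym_tol: float = 1e-4) -> np.ndarray:
    """Eigenvalues of the free-energy curvature (numerical Hessian).

    The curvature plays the role of a Jacobian for the belief dynamics: its
    eigenvalues are positive at a free-energy minimum, and their size
    controls how fast perturbations of the corresponding expectation decay
    (small curvature means critical slowing).  ``wrt`` selects the block:
    generalized states (``"x"``), causes (``"v"``) or both (``"xv"``).
    """
    def pack():
        parts = []
        if "x" in wrt:
            parts.append(state.mu_x.reshape(-1))
        if "v" in wrt:
            parts.append(state.mu_v.reshape(-1))
        return np.concatenate(parts) if parts else np.zeros(0)

    def F_of(z):
        i = 0
        mu_x = state.mu_x
        mu_v = state.mu_v
        if "x" in wrt:
            k = state.mu_x.size
            mu_x = z[i:i + k].reshape(state.mu_x.shape)
            i += k
        if "v" in wrt:
            mu_v = z[i:i + state.mu_v.size]
        return free_energy(model, mu_x, mu_v, obs)

    z0 = pack()
    d = z0.size
    Hm = np.zeros((d, d))
    F0 = F_of(z0)
    for i in range(d):
        for j in range(i, d):
            zpp = z0.copy(); zpp[i] += eps; zpp[j] += eps
            zpm = z0.copy(); zpm[i] += eps; zpm[j] -= eps
            zmp = z0.copy(); zmp[i] -= eps; zmp[j] += eps
            zmm = z0.copy(); zmm[i] -= eps; zmm[j] -= eps
            if i == j:
                zp = z0.copy(); zp[i] += eps
                zm = z0.copy(); zm[i] -= eps
                Hm[i, i] = (F_of(zp) - 2 * F0 + F_of(zm)) / eps**2
            else:
                Hm[i, j] = (F_of(zpp) - F_of(zpm) - F_of(zmp) + F_of(zmm)) / (4 * eps**2)
                Hm[j, i] = Hm[i, j]
    asym = np.abs(Hm - Hm.T).max(initial=0.0)
    if asym > asym_tol:
        warnings.warn(f"numerical Hessian asymmetry {asym:.3g} beyond tolerance")
    return np.linalg.eigvalsh(0.5 * (Hm + Hm.T))
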