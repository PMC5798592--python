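"""Shared numerical helpers: stabilised logs, softmax, categorical checks."""
from __future__ import annotations

import numpy as np

#: Additive floor used inside every logarithm of a probability.  ``exp(-32)``
#: is ~1.3e-14, so any probability of numerical relevance is essentially
#: unperturbed while exact zeros map to a finite log of -32 nats.
LOG_FLOOR = float(np.exp(-32.0))


def log_stable(x: np.ndarray | float) -> np.ndarray:
    """Elementwise ``ln(x + exp(-32))`` — the package-wide log-floor rule."""
    return np.log(np.asarray(x, dtype=float) + LOG_FLOOR)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def normalize(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize a nonnegative array to sum to one along ``axis``."""
    p = np.asarray(p, dtype=float)
    s = p.sum(axis=axis, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot normalize: nonpositive mass")
    return p / s


def onehot(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())
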