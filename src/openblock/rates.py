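"""Kinetic schemes for open-channel block.

A non-inactivating voltage-gated channel with ``m`` equal and independent
gates (Hodgkin-Huxley style) binds a blocker only in the open state::

    C_m  <->  ...  <->  C_1  <->  O  <->  B

Opening transitions run at (number of closed gates) * alpha, closing
transitions at (number of open gates) * beta.  The O -> B association rate
gamma is proportional to blocker concentration (gamma = kappa * L) and the
B -> O dissociation rate is delta.  The state vector x(t) of occupancy
probabilities evolves as x' = A x, where A is the generator (Q-) matrix
built here, with zero column sums so total probability is conserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RateSet",
    "GeneratorMatrix",
    "build_generator",
    "steady_state",
    "no_block_steady_open",
    "blocked_steady_open",
]


@dataclass(frozen=True)
class RateSet:
    """The four rate constants of a linear open-block scheme plus gate count.

    Parameters
    ----------
    alpha, beta : float
        Per-gate opening / closing rates (1/ms by convention).
    gamma : float
        O -> B association rate, kappa * concentration (1/ms).
    delta : float
        B -> O dissociation rate (1/ms), often written lambda.
    m : int
        Number of closed states (independent gates); total states n = m + 2.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    m: int = 1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m!r}")
        object.__setattr__(self, "m", int(self.m))

    @classmethod
    def from_concentration(
        cls,
        alpha: float,
        beta: float,
        kappa: float,
        concentration: float,
        delta: float,
        m: int = 1,
    ) -> "RateSet":
        """Build a RateSet from a binding rate constant and a concentration.

        gamma = kappa * concentration; kappa in 1/(mM*ms), concentration in mM
        (any consistent pair works).
        """
        return cls(alpha, beta, kappa * concentration, delta, m)

    @property
    def n_states(self) -> int:
        return self.m + 2

    def with_(self, **kwargs) -> "RateSet":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "delta": self.delta,
            "m": self.m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        d = dict(d)
        if "kappa" in d or "concentration" in d:
            if "gamma" in d:
                raise ValueError("give either gamma or (kappa, concentration), not both")
            d["gamma"] = float(d.pop("kappa")) * float(d.pop("concentration"))
        known = {"alpha", "beta", "gamma", "delta", "m"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        return cls(
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
            delta=float(d["delta"]),
            m=int(d.get("m", 1)),
        )


def _state_labels(m: int) -> list[str]:
    # index 0 = C_m (all gates closed) ... index m-1 = C_1, then O, B
    return [f"C{m - i}" for i in range(m)] + ["O", "B"]


@dataclass(frozen=True)
class GeneratorMatrix:
    """Tridiagonal transition-rate matrix A governing x' = A x.

    State order: ``C_m, ..., C_1, O, B`` (most-closed first).  Columns sum
    to zero; off-diagonal entries are nonnegative rates.
    """

    matrix: np.ndarray
    rates: RateSet
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(self, "labels", tuple(_state_labels(self.rates.m)))
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        self.matrix.setflags(write=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def open_index(self) -> int:
        return self.rates.m

    @property
    def blocked_index(self) -> int:
        return self.rates.m + 1

    def initial_state(self) -> np.ndarray:
        """Voltage-clamp initial condition: all channels in the first
        (most hyperpolarized) closed state C_m."""
        x0 = np.zeros(self.n)
        x0[0] = 1.0
        return x0

    def to_csv(self, path_or_buf=None) -> str | None:
        """Dense CSV export with state labels as header row."""
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=list(self.labels))
        if path_or_buf is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format="%.17g")
            return buf.getvalue()
        df.to_csv(path_or_buf, index=False, float_format="%.17g")
        return None


def build_generator(rates: RateSet) -> GeneratorMatrix:
    """Assemble the generator matrix for the m-gate open-block scheme.

    From the state with j open gates the forward (opening) rate is
    (m - j) * alpha and the backward (closing) rate is j * beta, so the
    O -> C_1 rate is m * beta and the C_m -> C_{m-1} rate is m * alpha.
    For m = 1 this is the familiar 3-state C <-> O <-> B scheme.
    """
    m = rates.m
    n = m + 2
    A = np.zeros((n, n))
    # gating chain: index i has i open gates (i = 0..m; index m is O)
    for i in range(m):
        fwd = (m - i) * rates.alpha      # i -> i+1
        A[i + 1, i] += fwd
        A[i, i] -= fwd
    for i in range(1, m + 1):
        back = i * rates.beta            # i -> i-1
        A[i - 1, i] += back
        A[i, i] -= back
    # open-state block
    o, b = m, m + 1
    A[b, o] += rates.gamma
    A[o, o] -= rates.gamma
    A[o, b] += rates.delta
    A[b, b] -= rates.delta
    return GeneratorMatrix(A, rates)


def steady_state(generator: GeneratorMatrix) -> np.ndarray:
    """Stationary distribution: the normalised null vector of A.

    Solved by least squares on the augmented system [A; 1^T] x = [0; 1],
    which stays well conditioned when eigenvalues are nearly degenerate.
    Raises if the chain has no transitions at all (stationary distribution
    not unique).
    """
    A = generator.matrix
    if not np.any(A):
        raise ValueError("all-zero generator: stationary distribution is not unique")
    n = A.shape[0]
    aug = np.vstack([A, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    x, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    # guard against a multidimensional null space (e.g. disconnected chain)
    if np.max(np.abs(A @ x)) > 1e-8 * max(1.0, np.max(np.abs(A))):
        raise ValueError("generator does not admit a unique stationary distribution")
    return x


def blocked_steady_open(rates: RateSet) -> float:
    """Closed-form steady-state open probability with blocker present:

        O_ss = alpha^m * delta / (delta * (alpha+beta)^m + gamma * alpha^m)

    Used as an analytic cross-check of :func:`steady_state`.
    """
    a, b, g, d, m = rates.alpha, rates.beta, rates.gamma, rates.delta, rates.m
    num = a**m * d
    den = d * (a + b) ** m + g * a**m
    if den == 0:
        raise ValueError("degenerate rates: O_ss undefined")
    return num / den


def no_block_steady_open(alpha: float, beta: float, m: int) -> float:
    """Steady-state open probability of the unblocked gating chain,
    (alpha / (alpha + beta))^m — the binomial law of m independent gates."""
    if alpha < 0 or beta < 0:
        raise ValueError("rates must be >= 0")
    if m < 1:
        raise ValueError("m must be >= 1")
    if alpha + beta == 0:
        raise ValueError("alpha + beta must be > 0")
    return (alpha / (alpha + beta)) ** m
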