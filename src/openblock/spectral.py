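"""Exact spectral solution of the master equation x' = A x.

For a linear (tridiagonal) generator with positive off-diagonal rates the
spectrum is real and nonpositive with a single zero eigenvalue, so the
occupancy vector decomposes as

    x(t) = sum_i  c_i V_i  exp(r_i t)

with eigenpairs (r_i, V_i) of A and coefficients c_i fixed by x(0).  Two
independent evaluation routes — a hand-rolled scaling-and-squaring matrix
exponential and the Putzer recursion — serve as oracles for the
eigendecomposition, and the closed-form pre-exponential factor of the
slowest eigenterm in the open-state component is exposed because its sign
decides whether the open probability has an interior peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .rates import GeneratorMatrix, RateSet, build_generator

__all__ = [
    "SpectralSolution",
    "Trajectory",
    "DegenerateEigenvaluesError",
    "generator_eigenvalues",
    "eigendecompose",
    "open_probability",
    "trajectory",
    "matrix_exponential_oracle",
    "putzer_solve",
    "slowest_preexponential",
]

logger = logging.getLogger(__name__)

# |r| below this fraction of the largest matrix entry counts as the zero
# eigenvalue; spacing below this fraction of the spectral range counts as
# degenerate for the distinct-eigenvalue closed forms.
ZERO_EIG_RTOL = 1e-10
DEGENERACY_RTOL = 1e-8


class DegenerateEigenvaluesError(RuntimeError):
    """Raised when a closed form that assumes distinct eigenvalues is asked
    to operate on a (numerically) degenerate spectrum."""


@dataclass(frozen=True)
class SpectralSolution:
    """Eigen-solution of x' = A x for a fixed initial condition.

    ``eigenvalues`` are sorted descending (the zero mode first, then the
    slowest to the fastest relaxation).  ``coefficients[i]`` is the vector
    c_i V_i, so ``x(t) = sum_i coefficients[i] * exp(eigenvalues[i] t)``.
    """

    eigenvalues: np.ndarray          # shape (n,), real, descending
    coefficients: np.ndarray         # shape (n, n); row i = c_i V_i
    x0: np.ndarray                   # shape (n,)
    open_index: int
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    @property
    def r_slow(self) -> float:
        """Slowest nonzero eigenvalue (the least negative relaxation rate)."""
        return float(self.eigenvalues[1])

    @property
    def r_fast(self) -> float:
        return float(self.eigenvalues[-1])

    @property
    def steady_state(self) -> np.ndarray:
        """The zero-mode component: x(t) -> this as t -> infinity."""
        return self.coefficients[0]

    def spacing(self) -> float:
        """Smallest gap between consecutive eigenvalues."""
        return float(np.min(np.abs(np.diff(self.eigenvalues))))

    def is_degenerate(self) -> bool:
        rng = float(self.eigenvalues[0] - self.eigenvalues[-1])
        return self.spacing() < DEGENERACY_RTOL * max(rng, 1e-300)

    def evaluate(self, t) -> np.ndarray:
        """State vector(s) at time(s) t: shape (n,) for scalar t, else
        (len(t), n)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        out = np.exp(np.outer(tt, self.eigenvalues)) @ self.coefficients
        return out[0] if scalar else out


@dataclass(frozen=True)
class Trajectory:
    """Deterministic occupancy time course on a time grid."""

    times: np.ndarray                # shape (T,)
    states: np.ndarray               # shape (T, n); rows are prob. vectors
    labels: tuple[str, ...]

    def open_probability(self, open_index: int) -> np.ndarray:
        return self.states[:, open_index]

    def to_frame(self):
        """Long-format DataFrame: time, state_label, probability."""
        import pandas as pd

        T, n = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "state_label": list(self.labels) * T,
                "probability": self.states.ravel(),
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.17g")


def _check_probability_vector(x0: np.ndarray, n: int) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},)")
    if np.any(x0 < -1e-12) or abs(x0.sum() - 1.0) > 1e-10:
        raise ValueError("x0 must be a probability vector")
    return x0


def _real_sorted_eigenvalues(A: np.ndarray) -> np.ndarray:
    evals = np.linalg.eigvals(A)
    scale = max(np.max(np.abs(evals.real)), 1e-300)
    if np.max(np.abs(evals.imag)) > 1e-10 * scale:
        raise ArithmeticError(
            "complex eigenvalues found for a tridiagonal generator — "
            "this indicates a numerical degeneracy or an invalid matrix"
        )
    evals = np.sort(evals.real)[::-1]
    entry_scale = max(np.max(np.abs(A)), 1e-300)
    zero_mask = np.abs(evals) < ZERO_EIG_RTOL * entry_scale
    if zero_mask.sum() != 1:
        raise ArithmeticError(
            f"expected exactly one zero eigenvalue, found {int(zero_mask.sum())}"
        )
    evals[0] = 0.0
    if np.any(evals[1:] > 0):
        raise ArithmeticError("positive eigenvalue found; generator is invalid")
    return evals


def generator_eigenvalues(generator: GeneratorMatrix) -> np.ndarray:
    """Real spectrum of the generator, sorted descending with the single
    zero mode snapped to exactly 0.  Works for defective (numerically
    degenerate) matrices, unlike the full eigendecomposition."""
    return _real_sorted_eigenvalues(generator.matrix)


def eigendecompose(
    generator: GeneratorMatrix, x0: np.ndarray | None = None
) -> SpectralSolution:
    """Diagonalise the generator and project the initial condition.

    Defaults to the voltage-clamp initial condition (all channels in the
    first closed state).  The spectrum of a valid tridiagonal generator is
    real; imaginary round-off below ``1e-10 * spectral range`` is truncated
    with a warning, anything larger raises.
    """
    A = generator.matrix
    n = A.shape[0]
    x0 = generator.initial_state() if x0 is None else _check_probability_vector(x0, n)

    evals, evecs = np.linalg.eig(A)
    scale = max(np.max(np.abs(evals.real)), 1e-300)
    if np.max(np.abs(evals.imag)) > 1e-10 * scale:
        raise ArithmeticError(
            "complex eigenvalues found for a tridiagonal generator — "
            "this indicates a numerical degeneracy or an invalid matrix"
        )
    if np.max(np.abs(evals.imag)) > 0:
        logger.warning("truncating spurious imaginary eigenvalue parts (< %g)",
                       1e-10 * scale)
    evals = evals.real
    evecs = evecs.real

    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    # snap the zero mode: exactly one eigenvalue must vanish
    entry_scale = max(np.max(np.abs(A)), 1e-300)
    zero_mask = np.abs(evals) < ZERO_EIG_RTOL * entry_scale
    if zero_mask.sum() != 1:
        raise ArithmeticError(
            f"expected exactly one zero eigenvalue, found {int(zero_mask.sum())}"
        )
    evals[0] = 0.0
    if np.any(evals[1:] > 0):
        raise ArithmeticError("positive eigenvalue found; generator is invalid")

    # a defective (degenerate) generator has no usable eigenbasis
    if np.linalg.cond(evecs) > 1e12:
        raise DegenerateEigenvaluesError(
            "eigenvector basis is numerically singular (defective generator); "
            "use the matrix-exponential route instead"
        )
    c = np.linalg.solve(evecs, x0)
    coefficients = (evecs * c).T  # row i = c_i V_i
    return SpectralSolution(
        eigenvalues=evals,
        coefficients=coefficients,
        x0=x0,
        open_index=generator.open_index,
        labels=generator.labels,
    )


def open_probability(solution: SpectralSolution, t) -> float | np.ndarray:
    """O(t), the open-state component of the spectral solution."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    states = solution.evaluate(t)
    return states[..., solution.open_index]


def trajectory(solution: SpectralSolution, times) -> Trajectory:
    """Evaluate the solution on an increasing nonnegative time grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid is empty")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be nonnegative and nondecreasing")
    states = solution.evaluate(times)
    return Trajectory(times=times, states=states, labels=solution.labels)


def matrix_exponential_oracle(
    generator: GeneratorMatrix, x0: np.ndarray | None = None, t: float = 0.0
) -> np.ndarray:
    """exp(A t) x0 by scaling-and-squaring of the truncated Taylor series.

    Deliberately shares no code with :func:`eigendecompose`; used as an
    independent oracle in the test-suite.
    """
    A = generator.matrix
    n = A.shape[0]
    x0 = generator.initial_state() if x0 is None else _check_probability_vector(x0, n)
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return x0.copy()
    # scale so the scaled matrix has norm <= 0.5, square back up
    norm = np.linalg.norm(A * t, 1)
    s = max(0, int(math.ceil(math.log2(norm / 0.5))) if norm > 0.5 else 0)
    B = (A * t) / (2**s)
    E = np.eye(n)
    term = np.eye(n)
    for k in range(1, 30):
        term = term @ B / k
        E = E + term
        if np.max(np.abs(term)) < 1e-18:
            break
    for _ in range(s):
        E = E @ E
    return E @ x0


def _putzer_p(evals: np.ndarray, t: float) -> np.ndarray:
    """Closed-form solutions p_i(t) of the Putzer cascade for pairwise
    distinct eigenvalues:

        p_i(t) = sum_{j<=i} exp(r_j t) / prod_{k<=i, k!=j} (r_j - r_k)

    (for i = 1 this is exp(r_1 t); for n = 3 the last entry is the familiar
    three-term partial-fraction form).
    """
    n = evals.size
    p = np.empty(n)
    for i in range(1, n + 1):
        acc = 0.0
        for j in range(i):
            denom = 1.0
            for k in range(i):
                if k != j:
                    denom *= evals[j] - evals[k]
            acc += math.exp(evals[j] * t) / denom
        p[i - 1] = acc
    return p


def putzer_solve(
    generator: GeneratorMatrix, x0: np.ndarray | None = None, t: float = 0.0
) -> np.ndarray:
    """Evaluate x(t) by the Putzer recursion.

    x(t) = (sum_i p_i(t) M_i) x0 with M_1 = I and
    M_i = (A - r_{i-1} I) M_{i-1}.  Requires pairwise distinct eigenvalues;
    refuses (raises :class:`DegenerateEigenvaluesError`) when the spectrum
    is numerically degenerate rather than silently losing precision.
    """
    A = generator.matrix
    n = A.shape[0]
    x0 = generator.initial_state() if x0 is None else _check_probability_vector(x0, n)
    if t < 0:
        raise ValueError("t must be >= 0")

    evals = np.sort(np.linalg.eigvals(A).real)[::-1]
    rng = max(evals[0] - evals[-1], 1e-300)
    if np.min(np.abs(np.diff(evals))) < DEGENERACY_RTOL * rng:
        raise DegenerateEigenvaluesError(
            "eigenvalues too close for the distinct-eigenvalue Putzer closed form"
        )

    p = _putzer_p(evals, t)
    M = np.eye(n)
    acc = p[0] * M
    for i in range(1, n):
        M = (A - evals[i - 1] * np.eye(n)) @ M
        acc = acc + p[i] * M
    return acc @ x0


def slowest_preexponential(rates: RateSet) -> float:
    """Coefficient of exp(r_slow t) in O(t) for the clamp initial condition.

    Closed form for the n-state chain (n = m + 2):

        (n-2)! * alpha^(n-2) * (delta + r_n) / prod_{i<n} (r_n - r_i)

    where r_n is the slowest nonzero eigenvalue and r_1 = 0.  The factor is
    positive exactly when the open probability has an interior peak.
    """
    if rates.gamma <= 0:
        raise ValueError("gamma must be > 0 (a blocker must be present)")
    evals = generator_eigenvalues(build_generator(rates))
    rng = max(evals[0] - evals[-1], 1e-300)
    if np.min(np.abs(np.diff(evals))) < DEGENERACY_RTOL * rng:
        raise DegenerateEigenvaluesError(
            "closed-form pre-exponential factor requires distinct eigenvalues"
        )
    n = evals.size
    r_n = evals[1]  # slowest nonzero; evals[0] = 0
    denom = 1.0
    for r in np.concatenate([evals[:1], evals[2:]]):
        denom *= r_n - r
    return math.factorial(n - 2) * rates.alpha ** (n - 2) * (rates.delta + r_n) / denom
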