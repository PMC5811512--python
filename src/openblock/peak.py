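"""Existence, timing and height of the open-probability peak.

Under a depolarising voltage step an open-channel blocker turns the
monotone activation time course of a non-inactivating channel into an
inactivation-like waveform: O(t) rises, passes an interior maximum O_p at
time t_p, and relaxes to the blocked steady state O_ss.  The peak exists
precisely when the slowest relaxation rate r_slow of the generator
satisfies delta + r_slow < 0 — equivalently, when the pre-exponential
factor of the slowest eigenterm in O(t) is positive.  For the 3-state
scheme this collapses to the simple criterion alpha > delta; notably the
association rate gamma (hence the blocker concentration) plays no role in
existence, only in height.

The relative peak height psi is defined by O_p = (1 + psi) * O_ss.
Closed forms for t_p and psi exist for the 3-state scheme with distinct
eigenvalues; a numeric argmax detector provides the independent oracle and
the fallback for degenerate or many-state cases.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .rates import GeneratorMatrix, RateSet, build_generator, steady_state
from .spectral import (
    DEGENERACY_RTOL,
    DegenerateEigenvaluesError,
    eigendecompose,
    generator_eigenvalues,
    open_probability,
)

__all__ = [
    "PeakReport",
    "NoPeakError",
    "peak_exists_spectral",
    "peak_exists_3state",
    "peak_exists_4state",
    "peak_time_3state",
    "psi_3state",
    "psi_simplified",
    "psi_limit",
    "analyze_peak",
    "peak_numeric",
]

logger = logging.getLogger(__name__)

# delta + r_slow within this fraction of the largest rate of the boundary
# counts as "no peak" (the pre-exponential factor vanishes there and O(t)
# is asymptotically flat)
BOUNDARY_RTOL = 1e-9


class NoPeakError(RuntimeError):
    """Raised when a peak-only quantity is requested for a monotone waveform."""


@dataclass(frozen=True)
class PeakReport:
    """Summary of the open-probability waveform for one rate set."""

    rates: RateSet
    exists: bool
    O_ss: float
    r_slow: float
    preexp: float
    t_p: float | None = None
    O_p: float | None = None
    psi: float | None = None

    def to_dict(self) -> dict:
        d = self.rates.to_dict()
        d.update(
            exists=self.exists,
            t_p=self.t_p,
            O_p=self.O_p,
            psi=self.psi,
            O_ss=self.O_ss,
            r_slow=self.r_slow,
            preexp=self.preexp,
        )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> str:
        cols = ["alpha", "beta", "gamma", "delta", "m",
                "exists", "t_p", "O_p", "psi", "O_ss", "r_slow"]
        d = self.to_dict()

        def fmt(v):
            if v is None:
                return ""
            if isinstance(v, bool):
                return str(v).lower()
            if isinstance(v, float):
                return format(v, ".17g")
            return str(v)

        return ",".join(fmt(d[c]) for c in cols)

    @staticmethod
    def csv_header() -> str:
        return "alpha,beta,gamma,delta,m,exists,t_p,O_p,psi,O_ss,r_slow"


def _boundary_eps(rates: RateSet) -> float:
    return BOUNDARY_RTOL * max(rates.alpha, rates.beta, rates.gamma, rates.delta, 1e-300)


def peak_exists_spectral(rates: RateSet) -> bool:
    """General spectral criterion: a peak exists iff delta + r_slow < 0,
    with r_slow the slowest nonzero eigenvalue of the generator.

    Holds for any number of closed states, and is independent of gamma as
    long as gamma > 0.  With gamma = 0 the blocked state is unreachable
    and there is nothing to peak: returns False with a logged note.
    """
    if rates.gamma <= 0:
        logger.info("gamma = 0: blocked state unreachable, no induced peak")
        return False
    evals = generator_eigenvalues(build_generator(rates))
    return rates.delta + evals[1] < -_boundary_eps(rates)


def peak_exists_3state(rates: RateSet) -> bool:
    """3-state criterion: the opening rate must beat the dissociation rate,
    alpha > delta.  Boundary alpha = delta counts as no peak."""
    if rates.m != 1:
        raise ValueError("3-state criterion requires m = 1")
    if rates.gamma <= 0:
        logger.info("gamma = 0: blocked state unreachable, no induced peak")
        return False
    return rates.alpha > rates.delta


def peak_exists_4state(rates: RateSet) -> bool:
    """4-state (two-gate) criterion:

        alpha > delta * (3 + b + sqrt(1 + 6 b + b^2)) / 4,   b = beta/alpha

    which is the smaller root of the boundary condition
    delta^2 - (3 alpha + beta) delta + 2 alpha^2 = 0 (where -delta enters
    the spectrum).  For beta = 0 it reduces to alpha > delta.
    """
    if rates.m != 2:
        raise ValueError("4-state criterion requires m = 2")
    if rates.gamma <= 0:
        logger.info("gamma = 0: blocked state unreachable, no induced peak")
        return False
    if rates.alpha == 0:
        return False
    b = rates.beta / rates.alpha
    return rates.alpha > rates.delta * (3.0 + b + math.sqrt(1.0 + 6.0 * b + b * b)) / 4.0


def _nonzero_eigs_3state(rates: RateSet) -> tuple[float, float]:
    """(r2, r3) with r3 > r2 the two nonzero eigenvalues of the 3-state
    generator."""
    evals = generator_eigenvalues(build_generator(rates))
    rng = max(evals[0] - evals[-1], 1e-300)
    if np.min(np.abs(np.diff(evals))) < DEGENERACY_RTOL * rng:
        raise DegenerateEigenvaluesError("3-state closed forms require distinct eigenvalues")
    return float(evals[2]), float(evals[1])


def peak_time_3state(rates: RateSet) -> float:
    """Closed-form peak time for the 3-state scheme:

        t_p = ln((delta + r2) / (delta + r3)) / (r3 - r2)

    Falls back to the numeric argmax (with a logged note) when the
    eigenvalues are numerically degenerate.
    """
    if rates.m != 1:
        raise ValueError("requires m = 1")
    if not peak_exists_3state(rates):
        raise NoPeakError("no interior peak: alpha <= delta")
    try:
        r2, r3 = _nonzero_eigs_3state(rates)
    except DegenerateEigenvaluesError:
        logger.warning("degenerate eigenvalues: using numeric argmax for t_p")
        t_p, _ = peak_numeric(build_generator(rates))
        return t_p
    return math.log((rates.delta + r2) / (rates.delta + r3)) / (r3 - r2)


def psi_3state(rates: RateSet) -> float:
    """Closed-form relative peak height for the 3-state scheme:

        psi = gamma (delta - alpha) / (delta (r3 + delta))
              * ((r2 + delta) / (r3 + delta)) ** (r2 / (r3 - r2))

    satisfying psi = O(t_p)/O_ss - 1.
    """
    if rates.m != 1:
        raise ValueError("requires m = 1")
    if not peak_exists_3state(rates):
        raise NoPeakError("no interior peak: alpha <= delta")
    a, g, d = rates.alpha, rates.gamma, rates.delta
    try:
        r2, r3 = _nonzero_eigs_3state(rates)
    except DegenerateEigenvaluesError:
        logger.warning("degenerate eigenvalues: computing psi numerically")
        gen = build_generator(rates)
        _, O_p = peak_numeric(gen)
        O_ss = steady_state(gen)[gen.open_index]
        return O_p / O_ss - 1.0
    ratio = (r2 + d) / (r3 + d)
    return g * (d - a) / (d * (r3 + d)) * ratio ** (r2 / (r3 - r2))


def psi_simplified(alpha: float, delta: float) -> float:
    """Simplified relative peak height for high voltage steps (beta = 0,
    alpha > gamma + delta) at K_d concentration (gamma = delta):

        psi = (alpha/delta - 1) ** (1 / (1 - alpha/(2 delta)))
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if alpha <= 2 * delta:
        raise ValueError("requires alpha > 2 delta (i.e. alpha > gamma + delta with gamma = delta)")
    r = alpha / delta
    return (r - 1.0) ** (1.0 / (1.0 - r / 2.0))


_PSI_LIMITS = {
    ("alpha", "to_infinity"): lambda r: r.gamma / r.delta,
    ("alpha", "to_zero"): lambda r: 0.0,
    ("beta", "to_infinity"): lambda r: 0.0,
    ("gamma", "to_infinity"): lambda r: r.alpha / r.delta - 1.0,
    ("gamma", "to_zero"): lambda r: 0.0,
    ("delta", "to_infinity"): lambda r: 0.0,
    ("delta", "to_zero"): lambda r: math.inf,
}


def psi_limit(which_rate: str, direction: str, rates: RateSet) -> float:
    """Limit of psi as one rate constant goes to an extreme, the others
    held fixed (3-state scheme).

    Tabulated closed forms: alpha->inf: gamma/delta; alpha->0: 0;
    beta->inf: 0; gamma->inf: alpha/delta - 1; gamma->0: 0;
    delta->inf: 0; delta->0: +inf.  The beta->0 limit has no clean closed
    form here; psi is continuous in beta (through the eigenvalues), so the
    numeric value of the closed-form psi at beta = 0 is returned instead
    (0 when no peak exists there).
    """
    if rates.m != 1:
        raise ValueError("limits tabulated for the 3-state scheme (m = 1)")
    if which_rate not in {"alpha", "beta", "gamma", "delta"}:
        raise ValueError(f"unknown rate selector {which_rate!r}")
    if direction not in {"to_zero", "to_infinity"}:
        raise ValueError(f"unknown direction {direction!r}")
    if (which_rate, direction) == ("beta", "to_zero"):
        at_zero = rates.with_(beta=0.0)
        if not peak_exists_3state(at_zero):
            return 0.0
        return psi_3state(at_zero)
    return _PSI_LIMITS[(which_rate, direction)](rates)


def peak_numeric(
    generator: GeneratorMatrix, x0: np.ndarray | None = None
) -> tuple[float, float]:
    """Numeric interior-maximum detector for O(t).

    Scans the derivative O'(t) on a log-spaced grid starting at
    1e-3/|r_fast| (extended adaptively past 30/|r_slow| while the waveform
    is still rising) and refines the positive-to-negative sign change by
    root bracketing.  Returns (t_p, O_p).  Raises :class:`NoPeakError`
    when O'(t) never changes sign — a supremum attained only as
    t -> infinity is not a peak.
    """
    evals = generator_eigenvalues(generator)
    o = generator.open_index
    try:
        sol = eigendecompose(generator, x0)

        def O_of_t(t):
            return open_probability(sol, t)

        rc = sol.eigenvalues * sol.coefficients[:, o]
        rc_abs = np.abs(rc)

        def dO_of_t(t):
            return float(rc @ np.exp(sol.eigenvalues * t))

        def noise_of_t(t):
            # round-off floor of dO: cancellation between eigenterm slopes
            return 1e-12 * (np.exp(np.outer(np.atleast_1d(t),
                                            sol.eigenvalues)) @ rc_abs)
    except DegenerateEigenvaluesError:
        from scipy.linalg import expm

        A = generator.matrix
        A_abs = np.abs(A)
        x0v = generator.initial_state() if x0 is None else np.asarray(x0, float)

        def O_of_t(t):
            tt = np.atleast_1d(np.asarray(t, dtype=float))
            vals = np.array([(expm(A * ti) @ x0v)[o] for ti in tt])
            return vals if np.ndim(t) else float(vals[0])

        def dO_of_t(t):
            return float((A @ (expm(A * t) @ x0v))[o])

        def noise_of_t(t):
            tt = np.atleast_1d(np.asarray(t, dtype=float))
            return 1e-12 * np.array(
                [(A_abs @ (expm(A * ti) @ x0v))[o] for ti in tt])

    # Detect the interior maximum from a sign change of O'(t).  The
    # derivative kills the constant steady-state term, so a peak of any
    # relative height is resolvable — maximising the amplitude itself hits
    # the sqrt(eps) wall once psi drops below ~1e-12.  Sign flips must
    # clear a per-point noise floor, or pure round-off in a monotone
    # waveform would masquerade as a peak.
    t_scale = 1.0 / abs(evals[1])
    t_lo = 1e-3 / abs(evals[-1])
    t_hi = 30.0 * t_scale
    while dO_of_t(t_hi) > 0.0 and t_hi < 1e9 * t_scale:
        t_hi *= 4.0  # waveform still rising at the horizon: look further out
    grid = np.geomspace(t_lo, t_hi, 600)
    d = np.array([dO_of_t(t) for t in grid])
    tol = noise_of_t(grid)
    pos = np.nonzero(d > tol)[0]
    neg = np.nonzero(d < -tol)[0]
    if pos.size == 0 or neg.size == 0 or neg.max() <= pos.min():
        raise NoPeakError("no interior peak: open probability is monotone")
    j = int(neg[neg > pos.min()].min())
    i = int(pos[pos < j].max())
    t_p = float(brentq(dO_of_t, grid[i], grid[j],
                       xtol=1e-14 * grid[j], rtol=8.9e-16))
    O_p = float(O_of_t(t_p))
    return t_p, O_p


def analyze_peak(rates: RateSet) -> PeakReport:
    """Full waveform summary for one rate set.

    Uses the 3-state closed forms for t_p and psi when m = 1 and the
    eigenvalues are well separated; otherwise (m > 1 or a degenerate
    spectrum) the numeric argmax.  Always reports O_ss, the slowest
    nonzero eigenvalue, and the pre-exponential factor of its eigenterm in
    O(t).
    """
    if rates.gamma <= 0:
        raise ValueError("gamma must be > 0 (a blocker must be present)")
    gen = build_generator(rates)
    evals = generator_eigenvalues(gen)
    rng = max(evals[0] - evals[-1], 1e-300)
    degenerate = float(np.min(np.abs(np.diff(evals)))) < DEGENERACY_RTOL * rng
    O_ss = float(steady_state(gen)[gen.open_index])
    r_slow = float(evals[1])
    if degenerate:
        preexp = math.nan  # no eigenterm coefficient for a defective spectrum
    else:
        sol = eigendecompose(gen)
        preexp = float(sol.coefficients[1, gen.open_index])
    exists = rates.delta + r_slow < -_boundary_eps(rates)
    if not exists:
        return PeakReport(rates=rates, exists=False, O_ss=O_ss,
                          r_slow=r_slow, preexp=preexp)

    if rates.m == 1 and not degenerate:
        t_p = peak_time_3state(rates)
        psi = psi_3state(rates)
        O_p = (1.0 + psi) * O_ss
    else:
        t_p, O_p = peak_numeric(gen)
        psi = O_p / O_ss - 1.0
    return PeakReport(rates=rates, exists=True, O_ss=O_ss, r_slow=r_slow,
                      preexp=preexp, t_p=t_p, O_p=O_p, psi=psi)
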