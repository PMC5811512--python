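"""Exact stochastic (Gillespie) simulation of single channels.

Each channel is a continuous-time Markov chain on the states
C_m ... C_1, O, B: the dwell time in state j is exponential with rate
equal to the total outflow -A[j, j], and the next state is drawn
proportionally to the outgoing rates in column j.  Ensembles of
independent channels give a Monte Carlo estimate of the open probability
whose binomial error bars validate the analytical solution, including the
induced peak.

Reproducibility: every channel draws from its own numpy Generator seeded
by (base_seed, channel_index), so ensembles are deterministic for a given
base seed and embarrassingly parallel in principle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import GeneratorMatrix

__all__ = ["ChannelPath", "EnsembleEstimate", "simulate_channel",
           "ensemble_open_probability"]


@dataclass(frozen=True)
class ChannelPath:
    """One single-channel trajectory: the state after jump_times[i] is
    states[i+1]; states[0] is the initial state at t = 0."""

    jump_times: np.ndarray
    states: np.ndarray
    seed: int

    def state_at(self, t: float) -> int:
        """State occupied at time t (paths are right-continuous)."""
        return int(self.states[np.searchsorted(self.jump_times, t, side="right")])


@dataclass(frozen=True)
class EnsembleEstimate:
    """Monte Carlo open-probability estimate with binomial standard errors."""

    times: np.ndarray
    open_prob_hat: np.ndarray
    stderr: np.ndarray
    N: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "open_prob_hat": self.open_prob_hat,
                "stderr": self.stderr,
                "N": self.N,
                "seed": self.seed,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.17g")


def _gillespie(A: np.ndarray, state: int, duration: float, rng) -> tuple[list, list]:
    """Core jump loop. Returns (jump_times, states_including_initial)."""
    n = A.shape[0]
    times: list[float] = []
    states: list[int] = [state]
    t = 0.0
    while True:
        out_rate = -A[state, state]
        if out_rate <= 0:
            break  # absorbing: legally halt here
        t += rng.exponential(1.0 / out_rate)
        if t >= duration:
            break
        # outgoing rates live in column `state`
        col = A[:, state].copy()
        col[state] = 0.0
        u = rng.random() * out_rate
        nxt = int(np.searchsorted(np.cumsum(col), u, side="right"))
        nxt = min(nxt, n - 1)
        times.append(t)
        states.append(nxt)
        state = nxt
    return times, states


def simulate_channel(
    generator: GeneratorMatrix, initial_state: int, duration: float, seed: int
) -> ChannelPath:
    """Simulate one channel for ``duration`` starting in ``initial_state``."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = generator.n
    if not 0 <= initial_state < n:
        raise ValueError(f"initial_state must be in [0, {n})")
    rng = np.random.default_rng(seed)
    times, states = _gillespie(generator.matrix, initial_state, duration, rng)
    return ChannelPath(
        jump_times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=int),
        seed=seed,
    )


def ensemble_open_probability(
    generator: GeneratorMatrix,
    x0: np.ndarray | None = None,
    times=None,
    N: int = 10_000,
    seed: int = 0,
) -> EnsembleEstimate:
    """Fraction of N independent channels open at each grid time.

    Initial states are drawn from x0 (default: the voltage-clamp
    condition, everything in the first closed state).  The default grid is
    200 log-spaced points up to 5 mean slowest-relaxation times estimated
    crudely from the rates.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    A = generator.matrix
    n = generator.n
    if x0 is None:
        x0 = generator.initial_state()
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (n,) or np.any(x0 < 0) or abs(x0.sum() - 1.0) > 1e-10:
            raise ValueError("x0 must be a probability vector")
    if times is None:
        slowest = max(np.max(np.abs(np.diag(A))), 1e-300)
        times = np.geomspace(1e-3 / slowest, 50.0 / slowest, 200)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")

    open_idx = generator.open_index
    counts = np.zeros(times.size, dtype=np.int64)
    duration = float(times.max()) if times.size else 0.0
    cum_x0 = np.cumsum(x0)
    for i in range(N):
        rng = np.random.default_rng((seed, i))
        s0 = int(np.searchsorted(cum_x0, rng.random(), side="right"))
        s0 = min(s0, n - 1)
        if duration > 0:
            jt, st = _gillespie(A, s0, duration, rng)
        else:
            jt, st = [], [s0]
        jt_arr = np.asarray(jt, dtype=float)
        st_arr = np.asarray(st, dtype=int)
        idx = np.searchsorted(jt_arr, times, side="right")
        counts += st_arr[idx] == open_idx

    p_hat = counts / N
    stderr = np.sqrt(p_hat * (1.0 - p_hat) / N)
    return EnsembleEstimate(times=times, open_prob_hat=p_hat, stderr=stderr,
                            N=N, seed=seed)
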