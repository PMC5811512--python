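"""Voltage dependence of the induced peak.

Gating rates follow Eyring-Polanyi rate theory,

    alpha(V) = k * exp((V - V_half) / s)
    beta(V)  = k * exp(-(V - V_half) / s)

with characteristic frequency k (1/ms), the potential V_half where
alpha = beta (mV), and slope factor s (mV).  The blocker is held at its
K_d concentration (gamma = delta) throughout, so the blocked steady state
tends to one half at strongly depolarised potentials.

Classification of the dissociation-rate/voltage plane:

* A1 — no peak (for one gate: alpha(V) <= delta);
* A2 — peak whose relative amplitude (peak open probability over the
  unblocked steady state) decreases with potential;
* A3 — peak whose relative amplitude increases with potential,
  approaching one.

An analogous scan over the beta-delta plane at fixed alpha labels
peak/no-peak cells and demonstrates that the map does not depend on the
association rate gamma.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .peak import analyze_peak, peak_exists_spectral
from .rates import RateSet, no_block_steady_open

__all__ = [
    "EyringParams",
    "RegionMap",
    "RelativeAmplitude",
    "alpha_of_v",
    "beta_of_v",
    "relative_amplitude",
    "classify_point",
    "scan_delta_v_plane",
    "scan_beta_delta_plane",
]


@dataclass(frozen=True)
class EyringParams:
    """Eyring-Polanyi parameters of the voltage-dependent gating rates.

    Defaults (k = 1/ms, V_half = 0 mV, s = 10 mV) are conventional for Kv
    gating steepness.
    """

    k: float = 1.0
    v_half: float = 0.0
    s: float = 10.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError("k must be finite and > 0")
        if not (math.isfinite(self.s) and self.s > 0):
            raise ValueError("s must be finite and > 0")
        if not math.isfinite(self.v_half):
            raise ValueError("V_half must be finite")

    def to_dict(self) -> dict:
        return {"k": self.k, "v_half": self.v_half, "s": self.s}


def alpha_of_v(p: EyringParams, V: float) -> float:
    """Opening rate alpha(V) = k * exp((V - V_half)/s); increasing in V."""
    return p.k * np.exp((np.asarray(V, dtype=float) - p.v_half) / p.s)


def beta_of_v(p: EyringParams, V: float) -> float:
    """Closing rate beta(V) = k * exp(-(V - V_half)/s); decreasing in V.
    The product alpha(V) * beta(V) = k**2 at every potential."""
    return p.k * np.exp(-(np.asarray(V, dtype=float) - p.v_half) / p.s)


def rates_at(p: EyringParams, delta: float, V: float, m: int = 1) -> RateSet:
    """RateSet at potential V with the blocker at K_d (gamma = delta)."""
    return RateSet(float(alpha_of_v(p, V)), float(beta_of_v(p, V)), delta, delta, m)


class RelativeAmplitude(NamedTuple):
    """Peak (or, absent a peak, steady-state) open probability relative to
    the unblocked steady state."""

    value: float
    peaked: bool


def relative_amplitude(
    p: EyringParams, delta: float, V: float, m: int = 1
) -> RelativeAmplitude:
    """O_p(V) / O_ss_noblock(V) when a peak exists; otherwise
    O_ss(V) / O_ss_noblock(V) flagged unpeaked.  Always in (0, 1]."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    rates = rates_at(p, delta, V, m)
    report = analyze_peak(rates)
    ref = no_block_steady_open(rates.alpha, rates.beta, m)
    top = report.O_p if report.exists else report.O_ss
    return RelativeAmplitude(value=top / ref, peaked=report.exists)


def classify_point(
    p: EyringParams, delta: float, V: float, m: int = 1, dV: float = 0.5
) -> str:
    """Label one (delta, V) point as A1, A2 or A3.

    A1 when no peak exists at the point; otherwise the sign of the central
    finite difference of the relative amplitude over +-dV separates A2
    (decreasing) from A3 (increasing).  Points whose +-dV stencil straddles
    the existence border are labelled A1 (no peak is the verifiable
    statement at the boundary).
    """
    if dV <= 0:
        raise ValueError("dV must be > 0")
    centre = relative_amplitude(p, delta, V, m)
    if not centre.peaked:
        return "A1"
    lo = relative_amplitude(p, delta, V - dV, m)
    hi = relative_amplitude(p, delta, V + dV, m)
    if not (lo.peaked and hi.peaked):
        return "A1"  # straddles the existence border
    return "A3" if hi.value > lo.value else "A2"


@dataclass(frozen=True)
class RegionMap:
    """Labelled grid over a two-parameter plane."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    labels: np.ndarray  # shape (len(axis1), len(axis2)), dtype str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("label grid does not match axes")

    def to_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "label": self.labels.ravel(),
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.17g")

    def metadata_json(self, **kwargs) -> str:
        return json.dumps(self.metadata, **kwargs)

    def plot(self, ax=None):
        """Render the map as a pcolormesh; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cats = sorted(set(self.labels.ravel()))
        codes = np.vectorize({c: i for i, c in enumerate(cats)}.get)(self.labels)
        mesh = ax.pcolormesh(self.axis2, self.axis1, codes, shading="nearest")
        cbar = ax.figure.colorbar(mesh, ax=ax, ticks=range(len(cats)))
        cbar.ax.set_yticklabels(cats)
        ax.set_xlabel(self.axis2_name)
        ax.set_ylabel(self.axis1_name)
        return ax


def scan_delta_v_plane(
    p: EyringParams, delta_grid, V_grid, m: int = 1, dV: float = 0.5
) -> RegionMap:
    """Classify every (delta, V) cell into A1/A2/A3."""
    delta_grid = np.asarray(delta_grid, dtype=float)
    V_grid = np.asarray(V_grid, dtype=float)
    if delta_grid.size == 0 or V_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(delta_grid <= 0):
        raise ValueError("delta grid must be positive")
    labels = np.empty((delta_grid.size, V_grid.size), dtype=object)
    for i, d in enumerate(delta_grid):
        for j, V in enumerate(V_grid):
            labels[i, j] = classify_point(p, d, V, m, dV)
    return RegionMap(
        axis1_name="delta",
        axis1=delta_grid,
        axis2_name="V",
        axis2=V_grid,
        labels=labels,
        metadata={"eyring": p.to_dict(), "m": m, "dV": dV, "gamma": "delta (K_d)"},
    )


def scan_beta_delta_plane(
    alpha: float, m: int, beta_grid, delta_grid, gamma_list=(0.1, 1.0, 10.0)
) -> RegionMap:
    """Label (beta, delta) cells peak/no_peak at fixed alpha.

    Computed for every gamma in gamma_list and verified identical —
    existence of the peak does not depend on the association rate.  For
    one gate the no-peak region is exactly the half-plane delta >= alpha,
    independent of beta.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    beta_grid = np.asarray(beta_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if beta_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("grids must be nonempty")
    gamma_list = list(gamma_list)
    if not gamma_list or any(g <= 0 for g in gamma_list):
        raise ValueError("gamma_list must be nonempty and positive")

    maps = []
    for g in gamma_list:
        lab = np.empty((beta_grid.size, delta_grid.size), dtype=object)
        for i, b in enumerate(beta_grid):
            for j, d in enumerate(delta_grid):
                rates = RateSet(alpha, float(b), float(g), float(d), m)
                lab[i, j] = "peak" if peak_exists_spectral(rates) else "no_peak"
        maps.append(lab)
    for other in maps[1:]:
        if not np.array_equal(maps[0], other):
            raise AssertionError(
                "peak-existence map changed with gamma — violates the "
                "gamma-independence of the criterion"
            )
    return RegionMap(
        axis1_name="beta",
        axis1=beta_grid,
        axis2_name="delta",
        axis2=delta_grid,
        labels=maps[0],
        metadata={"alpha": alpha, "m": m, "gamma_list": gamma_list},
    )
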