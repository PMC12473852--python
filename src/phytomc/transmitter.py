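"""Stress-induced volatile emission: gene regulation, storage pools, release.

The emission signal of a stressed plant is built in three stages:

1. A gene-regulatory stage produces the compound at a synthesis rate

       xi(t) = dG_x/dt = eta_x1 * sigmoid(a_x0 + sum_y a_xy G_y) - eta_x2 G_x

   where ``G_x`` is the expression level of the gene driving synthesis,
   ``a_xy`` are additive regulatory weights from other genes (no
   autoregulation), ``eta_x1`` the maximum synthesis rate (mg/s) and
   ``eta_x2`` a first-order decay rate (1/s).

2. The compound partitions into aqueous and lipid storage pools (fraction
   ``eta`` vs ``1 - eta``), which drain with rates ``u_a`` and ``u_l`` into a
   gas-phase pool that vents to the atmosphere with rate ``u_g``:

       dQ_a/dt = eta xi - u_a Q_a
       dQ_l/dt = (1-eta) xi - u_l Q_l
       dQ_g/dt = u_a Q_a + u_l Q_l - u_g Q_g

   giving the stomatal release rate J(t) = u_g Q_g(t) (mg/s).  The pool
   system is linear, so each step is advanced with the exact matrix
   exponential of the augmented system (including the cumulative emitted
   mass), making the mass-balance audit exact to machine precision.

3. The released signal is convolved with the channel response.  The
   cumulative mass arrived at the receiver by time ``t`` is

       M(t) = integral_0^t J(delta) F_hit(t - delta) d delta

   and an impulsive release of mass ``M`` at t = 0 (the default mode used by
   all experiments, matching the channel's initial condition) gives simply
   M * F_hit(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate
from scipy.linalg import expm
from scipy.special import expit

from .channel import ChannelParams, hit_probability
from .exceptions import ConfigurationError, StepSizeError

__all__ = [
    "GeneNode",
    "GeneTrajectory",
    "PoolState",
    "PoolParams",
    "PoolTrajectory",
    "EmissionProfile",
    "gene_expression_rate",
    "synthesis_timeseries",
    "update_pools",
    "simulate_pools",
    "emission_rate",
    "arrived_mass_profile",
]


# --------------------------------------------------------------------------
# gene-regulatory stage
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneNode:
    """One gene in the synthesis-regulating network.

    ``regulator_weights`` maps regulator gene names to additive weights
    ``a_xy``; self-edges are rejected (no autoregulation).
    """

    name: str
    basal_rate: float = 0.0            # a_x0, dimensionless
    max_rate: float = 1.0              # eta_x1, mg/s
    decay_rate: float = 0.1            # eta_x2, 1/s
    expression_level: float = 0.0      # G_x, dimensionless, >= 0
    regulator_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.basal_rate, self.max_rate, self.decay_rate, self.expression_level]
        vals += list(self.regulator_weights.values())
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError(f"gene node {self.name!r} has non-finite parameters")
        if self.max_rate < 0:
            raise ConfigurationError(f"max_rate must be >= 0, got {self.max_rate}")
        if self.decay_rate <= 0:
            raise ConfigurationError(f"decay_rate must be > 0, got {self.decay_rate}")
        if self.expression_level < 0:
            raise ConfigurationError(f"expression_level must be >= 0, got {self.expression_level}")
        if self.name in self.regulator_weights:
            raise ConfigurationError(f"gene {self.name!r} may not regulate itself")


def gene_expression_rate(node: GeneNode, regulator_levels: Mapping[str, float]) -> float:
    """Synthesis rate eta_x1 * sigmoid(a_x0 + sum a_xy G_y) - eta_x2 G_x (mg/s)."""
    acc = node.basal_rate
    for reg, weight in node.regulator_weights.items():
        if reg not in regulator_levels:
            raise ConfigurationError(
                f"gene {node.name!r} needs regulator level for {reg!r}"
            )
        level = regulator_levels[reg]
        if math.isnan(level):
            raise ValueError(f"regulator level for {reg!r} is NaN")
        acc += weight * level
    return node.max_rate * float(expit(acc)) - node.decay_rate * node.expression_level


@dataclass(frozen=True)
class GeneTrajectory:
    """Expression levels and synthesis rates of a network sampled on a grid."""

    time_grid: np.ndarray
    names: tuple[str, ...]
    levels: np.ndarray      # shape (n_nodes, n_times)
    synthesis: np.ndarray   # xi per node, shape (n_nodes, n_times), mg/s

    def xi(self, name: str) -> np.ndarray:
        return self.synthesis[self.names.index(name)]


def _network_field(nodes: Sequence[GeneNode]):
    names = [n.name for n in nodes]
    index = {n: i for i, n in enumerate(names)}
    for n in nodes:
        for reg in n.regulator_weights:
            if reg not in index:
                raise ConfigurationError(
                    f"gene {n.name!r} references unknown regulator {reg!r}"
                )
    a0 = np.array([n.basal_rate for n in nodes])
    eta1 = np.array([n.max_rate for n in nodes])
    eta2 = np.array([n.decay_rate for n in nodes])
    W = np.zeros((len(nodes), len(nodes)))
    for i, n in enumerate(nodes):
        for reg, w in n.regulator_weights.items():
            W[i, index[reg]] = w

    def field_fn(G: np.ndarray) -> np.ndarray:
        return eta1 * expit(a0 + W @ G) - eta2 * G

    return field_fn


def synthesis_timeseries(
    network: Sequence[GeneNode],
    t_grid,
    initial_levels: Mapping[str, float] | None = None,
) -> GeneTrajectory:
    """Integrate the coupled gene ODEs and sample xi(t) on ``t_grid``.

    Classical fourth-order Runge-Kutta with internal steps capped at
    0.1 / max(decay_rate), deterministic given inputs.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be strictly increasing from 0")
    nodes = list(network)
    names = tuple(n.name for n in nodes)
    f = _network_field(nodes)
    G = np.array(
        [
            (initial_levels or {}).get(n.name, n.expression_level)
            for n in nodes
        ],
        dtype=float,
    )
    dt_cap = 0.1 / max(n.decay_rate for n in nodes)

    levels = np.empty((len(nodes), len(t)))
    synthesis = np.empty_like(levels)
    levels[:, 0] = G
    synthesis[:, 0] = f(G)
    for i in range(1, len(t)):
        span = t[i] - t[i - 1]
        n_sub = max(1, math.ceil(span / dt_cap))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = f(G)
            k2 = f(G + 0.5 * h * k1)
            k3 = f(G + 0.5 * h * k2)
            k4 = f(G + h * k3)
            G = G + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(G)):
            raise StepSizeError(f"gene integration diverged near t = {t[i]:g} s")
        levels[:, i] = G
        synthesis[:, i] = f(G)
    return GeneTrajectory(t, names, levels, synthesis)


# --------------------------------------------------------------------------
# storage pools
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolParams:
    """Partition coefficient and first-order release rates of the three pools."""

    eta: float = 0.5    # aqueous partition fraction, in [0, 1]
    u_a: float = 0.1    # 1/s
    u_l: float = 0.1    # 1/s
    u_g: float = 0.05   # 1/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigurationError(f"eta must lie in [0, 1], got {self.eta}")
        for label, u in (("u_a", self.u_a), ("u_l", self.u_l), ("u_g", self.u_g)):
            if not math.isfinite(u) or u <= 0:
                raise ConfigurationError(f"{label} must be finite and > 0, got {u}")


@dataclass(frozen=True)
class PoolState:
    """Aqueous/lipid/gas pool contents (mg) at time ``t``, plus cumulative emitted mass."""

    Q_a: float = 0.0
    Q_l: float = 0.0
    Q_g: float = 0.0
    t: float = 0.0
    emitted: float = 0.0

    def __post_init__(self) -> None:
        for label, q in (("Q_a", self.Q_a), ("Q_l", self.Q_l), ("Q_g", self.Q_g)):
            if not math.isfinite(q) or q < 0:
                raise ConfigurationError(f"{label} must be finite and >= 0, got {q}")

    @property
    def total(self) -> float:
        return self.Q_a + self.Q_l + self.Q_g


@lru_cache(maxsize=256)
def _pool_propagator(u_a: float, u_l: float, u_g: float, dt: float):
    """Exact propagator (Phi, Psi) with z(t+dt) = Phi z + Psi b for the augmented
    linear system z = (Q_a, Q_l, Q_g, emitted) under piecewise-constant forcing b."""
    A = np.array(
        [
            [-u_a, 0.0, 0.0, 0.0],
            [0.0, -u_l, 0.0, 0.0],
            [u_a, u_l, -u_g, 0.0],
            [0.0, 0.0, u_g, 0.0],
        ]
    )
    # expm of the block matrix [[A, I], [0, 0]] yields [[e^{A dt}, int_0^dt e^{A s} ds], ...]
    blk = np.zeros((8, 8))
    blk[:4, :4] = A * dt
    blk[:4, 4:] = np.eye(4) * dt
    E = expm(blk)
    return E[:4, :4], E[:4, 4:]


def update_pools(state: PoolState, xi: float, params: PoolParams, dt: float) -> PoolState:
    """Advance all three pools one exact step under constant synthesis rate ``xi``.

    Mass balance (produced = pools + emitted) holds to machine precision.  A
    negative pool (possible only for negative ``xi``) raises
    :class:`StepSizeError` so the caller can subdivide rather than truncate.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if math.isnan(xi):
        raise ValueError("xi is NaN")
    Phi, Psi = _pool_propagator(params.u_a, params.u_l, params.u_g, dt)
    z = np.array([state.Q_a, state.Q_l, state.Q_g, state.emitted])
    b = np.array([params.eta * xi, (1.0 - params.eta) * xi, 0.0, 0.0])
    z_new = Phi @ z + Psi @ b
    if np.any(z_new[:3] < -1e-12 * max(1.0, abs(xi) * dt, state.total)):
        raise StepSizeError(
            "a storage pool went negative; reduce dt or check the synthesis rate sign"
        )
    z_new[:3] = np.maximum(z_new[:3], 0.0)
    return PoolState(
        Q_a=float(z_new[0]), Q_l=float(z_new[1]), Q_g=float(z_new[2]),
        t=state.t + dt, emitted=float(z_new[3]),
    )


def emission_rate(state: PoolState, params: PoolParams) -> float:
    """Atmospheric release rate J = u_g Q_g (mg/s)."""
    return params.u_g * state.Q_g


@dataclass(frozen=True)
class PoolTrajectory:
    """Pool contents, release rate and the conservation audit on a time grid."""

    time_grid: np.ndarray
    Q_a: np.ndarray
    Q_l: np.ndarray
    Q_g: np.ndarray
    emitted: np.ndarray
    J: np.ndarray
    produced: np.ndarray

    @property
    def balance_residual(self) -> np.ndarray:
        """produced - (pools + emitted); ~0 at machine precision at every sample."""
        pools = self.Q_a + self.Q_l + self.Q_g
        return self.produced - (pools - pools[0] + self.emitted - self.emitted[0])


def simulate_pools(
    xi, t_grid, params: PoolParams, initial: PoolState | None = None
) -> PoolTrajectory:
    """Drive the pools with a synthesis-rate series and record the trajectory.

    ``xi`` may be a callable of time or an array aligned with ``t_grid``; it is
    held constant over each grid interval (left endpoint value), matching the
    exact-step convention, so the returned ``produced`` integral is exact.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be 1-D and strictly increasing")
    if callable(xi):
        xi_vals = np.array([float(xi(tk)) for tk in t])
    else:
        xi_vals = np.asarray(xi, dtype=float)
        if xi_vals.shape != t.shape:
            raise ConfigurationError("xi array must align with t_grid")
    state = initial or PoolState(t=float(t[0]))

    n = len(t)
    out = {k: np.empty(n) for k in ("Q_a", "Q_l", "Q_g", "emitted", "J", "produced")}
    produced = 0.0
    for i in range(n):
        if i > 0:
            dt = t[i] - t[i - 1]
            state = update_pools(state, xi_vals[i - 1], params, dt)
            produced += xi_vals[i - 1] * dt
        out["Q_a"][i] = state.Q_a
        out["Q_l"][i] = state.Q_l
        out["Q_g"][i] = state.Q_g
        out["emitted"][i] = state.emitted
        out["J"][i] = emission_rate(state, params)
        out["produced"][i] = produced
    return PoolTrajectory(t, out["Q_a"], out["Q_l"], out["Q_g"],
                          out["emitted"], out["J"], out["produced"])


# --------------------------------------------------------------------------
# emission profile and arrival at the receiver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionProfile:
    """Release-rate profile J(t) or an impulsive release of mass ``M`` at t = 0."""

    mode: str = "impulse"                     # "impulse" | "profile"
    M: float = 0.0016                         # mg, used in impulse mode
    time_grid: np.ndarray | None = None       # s, strictly increasing from 0
    J_values: np.ndarray | None = None        # mg/s, aligned with time_grid

    def __post_init__(self) -> None:
        if self.mode not in ("impulse", "profile"):
            raise ConfigurationError(f"mode must be 'impulse' or 'profile', got {self.mode!r}")
        if self.mode == "impulse":
            if not math.isfinite(self.M) or self.M < 0:
                raise ConfigurationError(f"impulse mass M must be >= 0, got {self.M}")
        else:
            t = np.asarray(self.time_grid, dtype=float)
            J = np.asarray(self.J_values, dtype=float)
            if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
                raise ConfigurationError("profile time_grid must be strictly increasing from 0")
            if J.shape != t.shape or np.any(~np.isfinite(J)) or np.any(J < 0):
                raise ConfigurationError("J_values must be finite, >= 0 and aligned with time_grid")
            object.__setattr__(self, "time_grid", t)
            object.__setattr__(self, "J_values", J)

    @classmethod
    def impulse(cls, M: float) -> "EmissionProfile":
        return cls(mode="impulse", M=M)

    @classmethod
    def from_timeseries(cls, time_grid, J_values) -> "EmissionProfile":
        return cls(mode="profile", M=0.0, time_grid=time_grid, J_values=J_values)

    def to_frame(self):
        import pandas as pd

        if self.mode == "impulse":
            raise ConfigurationError("impulse profiles have no time series to export")
        return pd.DataFrame({"t_s": self.time_grid, "J_mg_per_s": self.J_values})


def arrived_mass_profile(profile: EmissionProfile, ch: ChannelParams, t: float) -> float:
    """Expected cumulative mass (mg) arrived at the receiver by time ``t``.

    Impulse mode: M * F_hit(t).  Profile mode: the release rate is convolved
    with the cumulative channel response,
    integral_0^t J(delta) F_hit(t - delta) d delta, with J interpolated
    linearly on its grid.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if profile.mode == "impulse":
        return profile.M * hit_probability(t, ch)
    tg = profile.time_grid
    if t > tg[-1]:
        raise ConfigurationError(
            f"profile covers [0, {tg[-1]:g}] s but arrival requested at t = {t:g} s"
        )
    if t == 0:
        return 0.0

    def integrand(delta: float) -> float:
        J = float(np.interp(delta, tg, profile.J_values))
        return J * hit_probability(t - delta, ch)

    pts = [float(x) for x in tg if 0.0 < x < t]
    val, _ = integrate.quad(
        integrand, 0.0, t, epsabs=1e-12, epsrel=1e-8, limit=400,
        points=pts or None,
    )
    return float(val)
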