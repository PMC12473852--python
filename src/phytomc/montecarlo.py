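"""Stochastic oracles: Brownian-particle channel runs and direct symbol trials.

These simulators are deliberately independent of the analytic formulas in
:mod:`phytomc.channel` and :mod:`phytomc.detection`; they exist to validate
them.

Particle runs release ``N`` independent particles at the point source and
advance them with drift ``v`` along the wind axis plus isotropic Gaussian
increments of per-axis variance ``2 D dt``; a particle is absorbed on the
first step that ends inside the receiver sphere (no Brownian-bridge
correction, so the step must be small near the absorber).  Two stepping
modes are provided:

* ``fixed`` — a single dt for all particles (default
  1e-4 * min(t_peak, R^2/D), refused if too coarse), suitable for short
  horizons;
* ``adaptive`` — per-particle dt proportional to the squared distance to the
  absorber, dt = eps (r - R)^2 / D clipped to [dt_min, dt_max], which keeps
  the step displacement a fixed small fraction (sqrt(2 eps)) of the gap and
  makes very long still-air horizons tractable.

Symbol trials sample the slot-k observation directly — binomial signal,
per-slot Bernoulli transmit coin times binomial interference, Gaussian
noise — scale by the absorption factor, and apply the threshold-exclusion
decision, yielding an empirical detection error rate with a standard error.
Note the trials sample the *exact* coin-times-binomial interference mixture,
whereas the closed form folds the coin into the binomial moments; the trials
are therefore a genuine oracle for that approximation too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .channel import ChannelParams, peak_time
from .exceptions import ConfigurationError
from .molecules import StressAlphabet
from .receiver import LeafParams, absorption_scale
from .detection import SlotScheme, NoiseSpec, noise_from_snr, slot_hit_prob

__all__ = [
    "ParticleRunConfig",
    "ParticleRunResult",
    "SymbolTrialConfig",
    "SymbolTrialResult",
    "simulate_particles",
    "simulate_symbol_trials",
]


# --------------------------------------------------------------------------
# particle oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleRunConfig:
    """Configuration of a Brownian-particle channel run.

    ``seed`` is mandatory: every run is reproducible bit-for-bit.
    """

    N: int
    T: float
    seed: int
    ch: ChannelParams
    dt: float | None = None
    mode: str = "fixed"            # "fixed" | "adaptive"
    eps: float = 0.002             # adaptive: dt = eps (r-R)^2 / D
    dt_min: float = 1e-5
    dt_max: float = 100.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ConfigurationError(f"N must be >= 1, got {self.N}")
        if self.T <= 0:
            raise ConfigurationError(f"T must be > 0, got {self.T}")
        if self.mode not in ("fixed", "adaptive"):
            raise ConfigurationError(f"mode must be 'fixed' or 'adaptive', got {self.mode!r}")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    def resolved_dt(self) -> float:
        """Default fixed step 1e-4 * min(t_peak, R^2/D); user overrides are sanity-checked."""
        scale = min(peak_time(self.ch), self.ch.R**2 / self.ch.D)
        if self.dt is None:
            return 1e-4 * scale
        if self.dt > 0.01 * self.ch.R**2 / self.ch.D:
            raise ConfigurationError(
                f"dt = {self.dt:g} s is too coarse: the per-step rms displacement "
                f"sqrt(2 D dt) must stay well below R; use dt <= "
                f"{0.01 * self.ch.R**2 / self.ch.D:.3g} s or the adaptive mode"
            )
        return self.dt


@dataclass(frozen=True)
class ParticleRunResult:
    """Hit times and the empirical hit fraction of a particle run."""

    hit_times: np.ndarray
    N: int
    T: float

    @property
    def n_absorbed(self) -> int:
        return len(self.hit_times)

    @property
    def hit_fraction(self) -> float:
        return self.n_absorbed / self.N

    @property
    def standard_error(self) -> float:
        p = self.hit_fraction
        return math.sqrt(max(p * (1.0 - p), 1.0 / self.N) / self.N)

    def empirical_hit_probability(self, omega: float) -> float:
        """Empirical F_hit(omega): fraction of all particles absorbed by time omega."""
        return float(np.count_nonzero(self.hit_times <= omega)) / self.N


def simulate_particles(cfg: ParticleRunConfig) -> ParticleRunResult:
    """Run the drift-diffusion particle ensemble against the absorbing sphere.

    The source sits on the wind axis a point-to-surface distance ``d`` upwind
    of the sphere (centre distance R + d); the wind blows the particles
    towards the sphere.
    """
    ch = cfg.ch
    rng = np.random.default_rng(cfg.seed)
    pos = np.zeros((cfg.N, 3))
    pos[:, 0] = -(ch.R + ch.d)
    t = np.zeros(cfg.N)
    hit_times: list[np.ndarray] = []

    fixed_dt = cfg.resolved_dt() if cfg.mode == "fixed" else None

    while pos.shape[0] > 0:
        if cfg.mode == "fixed":
            dt = np.full(pos.shape[0], fixed_dt)
        else:
            r = np.linalg.norm(pos, axis=1)
            gap = np.maximum(r - ch.R, 0.0)
            dt = np.clip(cfg.eps * gap**2 / ch.D, cfg.dt_min, cfg.dt_max)
        dt = np.minimum(dt, cfg.T - t)
        step = rng.normal(scale=1.0, size=pos.shape) * np.sqrt(2.0 * ch.D * dt)[:, None]
        step[:, 0] += ch.v * dt
        pos = pos + step
        t = t + dt
        r = np.linalg.norm(pos, axis=1)
        absorbed = r <= ch.R
        expired = (~absorbed) & (t >= cfg.T)
        if absorbed.any():
            hit_times.append(t[absorbed].copy())
        keep = ~(absorbed | expired)
        pos = pos[keep]
        t = t[keep]

    times = np.sort(np.concatenate(hit_times)) if hit_times else np.empty(0)
    return ParticleRunResult(hit_times=times, N=cfg.N, T=cfg.T)


# --------------------------------------------------------------------------
# symbol-trial oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SymbolTrialConfig:
    """Direct sampling of the slot-k decision, on the molecule-count scale.

    ``M_count`` is the per-slot emitted molecule count, ``q`` the per-window
    hit probabilities (current slot first) per molecule, ``scale`` the
    absorbed-mass factor per molecule and ``thresholds`` the detection
    thresholds on the same (count x scale) axis as the scaled observations.
    """

    n_trials: int
    seed: int
    transmitted: str
    M_count: int
    k: int
    q: Mapping[str, Sequence[float]]
    p: Mapping[str, float]
    noise: Mapping[str, NoiseSpec]
    scale: Mapping[str, float]
    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.M_count < 1:
            raise ConfigurationError(
                f"M_count must be a positive molecule count, got {self.M_count}"
            )
        names = set(self.q)
        for m in (self.p, self.noise, self.scale, self.thresholds):
            if set(m) != names:
                raise ConfigurationError("per-molecule mappings must share the same keys")
        if self.transmitted not in names:
            raise ConfigurationError(f"unknown transmitted molecule {self.transmitted!r}")
        for name, qs in self.q.items():
            if len(qs) != self.k:
                raise ConfigurationError(
                    f"molecule {name!r} needs {self.k} window probabilities, got {len(qs)}"
                )

    @classmethod
    def from_model(
        cls,
        *,
        n_trials: int,
        seed: int,
        transmitted: str,
        M_mg: float,
        alphabet: StressAlphabet,
        scheme: SlotScheme,
        channel_base: ChannelParams,
        lp: LeafParams,
        snr: float,
        k: int,
        molecules_per_mg: float = 1e6,
    ) -> "SymbolTrialConfig":
        """Assemble a trial config by running the analytic chain for each molecule."""
        M_count = int(round(M_mg * molecules_per_mg))
        q: dict[str, list[float]] = {}
        p: dict[str, float] = {}
        noise: dict[str, NoiseSpec] = {}
        scale: dict[str, float] = {}
        thresholds: dict[str, float] = {}
        for mol in alphabet:
            ch = channel_base.replace(D=mol.D)
            q[mol.name] = [slot_hit_prob(m, 1, scheme, ch) for m in range(1, k + 1)]
            p[mol.name] = mol.transmit_prob
            noise[mol.name] = noise_from_snr(snr, M_count, q[mol.name][0])
            scale[mol.name] = absorption_scale(lp, ch.R)
            # thresholds act on the absorbed (count x scale) axis: mg -> counts
            thresholds[mol.name] = mol.threshold * molecules_per_mg
        return cls(
            n_trials=n_trials, seed=seed, transmitted=transmitted, M_count=M_count,
            k=k, q=q, p=p, noise=noise, scale=scale, thresholds=thresholds,
        )


@dataclass(frozen=True)
class SymbolTrialResult:
    der: float
    standard_error: float
    n_trials: int


def simulate_symbol_trials(cfg: SymbolTrialConfig) -> SymbolTrialResult:
    """Empirical detection error rate over ``n_trials`` independent slot decisions."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    success = np.ones(n, dtype=bool)
    for name in cfg.q:
        qs = np.asarray(cfg.q[name], dtype=float)
        noise = cfg.noise[name]
        total = rng.normal(noise.mu_n, noise.sigma_n, size=n) if noise.sigma_n > 0 \
            else np.full(n, noise.mu_n)
        if name == cfg.transmitted:
            total = total + rng.binomial(cfg.M_count, qs[0], size=n)
        # interference from each earlier slot: transmit coin times binomial
        for qm in qs[1:]:
            coin = rng.random(n) < cfg.p[name]
            if qm > 0:
                total = total + coin * rng.binomial(cfg.M_count, qm, size=n)
        observed = total * cfg.scale[name]
        if name == cfg.transmitted:
            success &= observed >= cfg.thresholds[name]
        else:
            success &= observed < cfg.thresholds[name]
    der_hat = 1.0 - float(np.count_nonzero(success)) / n
    se = math.sqrt(max(der_hat * (1.0 - der_hat), 1.0 / n) / n)
    return SymbolTrialResult(der=der_hat, standard_error=se, n_trials=n)
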