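"""Leaf uptake: from leaf-surface concentration to absorbed mass.

Once molecules reach the receiver sphere they establish a leaf-surface
concentration ``C_leaf`` (see :func:`phytomc.channel.leaf_concentration`).
Uptake into leaf tissue follows first-order exchange kinetics

    dC_abs/dt = C_leaf A_L g / m_L - beta C_abs,      beta = A_L rho_L g / (K_L m_L)

whose solution from a clean leaf is

    C_abs(t) = (K_L C_leaf / rho_L) (1 - exp(-beta t)).

Integrating the uptake over a stomatal absorption window ``tau`` gives the
cumulative absorbed mass

    M_abs = M F_hit * 3 m_L K_L / (4 pi R^3 phi rho_L) * I(tau),
    I(tau) = tau - (1 - exp(-beta tau)) / beta.

Units note: the time integral formally gives mg*s; following the source
model's convention the result is treated as a mass in mg and compared
directly against mg detection thresholds.

Leaf conductance is tabulated as 86.4 m/day.  ``conductance_mode="si"``
(default) converts it to 1.0e-3 m/s, giving beta = 0.009 1/s with the default
leaf constants; ``conductance_mode="as_printed"`` uses the numeral 86.4 with
seconds (beta = 777.6 1/s), which reproduces the magnitude scale of the
published absorption and detection-error curves.  The choice is an explicit
switch, never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "LeafParams",
    "UptakeCurve",
    "uptake_concentration",
    "uptake_curve",
    "absorption_integral",
    "absorption_scale",
    "absorbed_mass",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class LeafParams:
    """Leaf constants of the receiver plant.

    A_L : leaf area, m^2
    g : leaf conductance as tabulated, m/day
    rho_L : leaf tissue density, kg/m^3
    m_L : leaf mass, kg
    K_L : leaf-air partition coefficient, dimensionless
    phi : leaf-to-absorption-sphere volume ratio, dimensionless in (0, 1]
    tau : stomatal absorption window, s
    conductance_mode : "si" (g converted to m/s) or "as_printed"
        (the numeral used with seconds)
    """

    A_L: float = 0.009
    g: float = 86.4
    rho_L: float = 1000.0
    m_L: float = 0.05
    K_L: float = 20.0
    phi: float = 0.5
    tau: float = 2.0
    conductance_mode: str = "si"

    def __post_init__(self) -> None:
        for label, value in (
            ("A_L", self.A_L), ("g", self.g), ("rho_L", self.rho_L),
            ("m_L", self.m_L), ("K_L", self.K_L), ("tau", self.tau),
        ):
            if not math.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{label} must be finite and > 0, got {value}")
        if not 0 < self.phi <= 1:
            raise ConfigurationError(f"phi must lie in (0, 1], got {self.phi}")
        if self.conductance_mode not in ("si", "as_printed"):
            raise ConfigurationError(
                f"conductance_mode must be 'si' or 'as_printed', got {self.conductance_mode!r}"
            )

    @property
    def g_effective(self) -> float:
        """Conductance in the units actually used with seconds (m/s in SI mode)."""
        if self.conductance_mode == "si":
            return self.g / SECONDS_PER_DAY
        return self.g

    @property
    def beta(self) -> float:
        """First-order uptake rate beta = A_L rho_L g / (K_L m_L), 1/s."""
        return self.A_L * self.rho_L * self.g_effective / (self.K_L * self.m_L)

    def replace(self, **changes) -> "LeafParams":
        return replace(self, **changes)


def uptake_concentration(C_leaf: float, lp: LeafParams, t):
    """Tissue concentration C_abs(t) = (K_L C_leaf / rho_L)(1 - exp(-beta t)).

    ``t`` may be a scalar or array of times >= 0.
    """
    if C_leaf < 0:
        raise ConfigurationError(f"C_leaf must be >= 0, got {C_leaf}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("uptake_concentration requires t >= 0")
    out = (lp.K_L * C_leaf / lp.rho_L) * (-np.expm1(-lp.beta * t_arr))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class UptakeCurve:
    time_grid: np.ndarray
    C_abs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.time_grid, "C_abs": self.C_abs})


def uptake_curve(C_leaf: float, lp: LeafParams, t_grid) -> UptakeCurve:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ConfigurationError("t_grid must be 1-D, strictly increasing, t >= 0")
    return UptakeCurve(t, uptake_concentration(C_leaf, lp, t))


def absorption_integral(lp: LeafParams, tau: float | None = None) -> float:
    """Closed form of I(tau) = integral_0^tau (1 - exp(-beta t)) dt = tau - (1-e^(-beta tau))/beta."""
    if tau is None:
        tau = lp.tau
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    b = lp.beta
    return tau - (-math.expm1(-b * tau)) / b


def absorption_scale(lp: LeafParams, R: float) -> float:
    """The absorbed-mass scale factor 3 m_L K_L / (4 pi R^3 phi rho_L) * I(tau).

    Multiplying an arrived quantity (mass or Gaussian moment) by this factor
    yields the corresponding absorbed quantity.
    """
    if R <= 0:
        raise ConfigurationError(f"R must be > 0, got {R}")
    geom = 3.0 * lp.m_L * lp.K_L / (4.0 * np.pi * R**3 * lp.phi * lp.rho_L)
    return geom * absorption_integral(lp)


def absorbed_mass(M: float, F_hit: float, lp: LeafParams, R: float) -> float:
    """Cumulative absorbed mass M_abs = M * F_hit * absorption_scale (mg).

    Strictly linear in both the emitted mass ``M`` and the hit probability
    ``F_hit``.
    """
    if M < 0:
        raise ConfigurationError(f"M must be >= 0, got {M}")
    if not 0.0 <= F_hit <= 1.0:
        raise ConfigurationError(f"F_hit must lie in [0, 1], got {F_hit}")
    return M * F_hit * absorption_scale(lp, R)
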