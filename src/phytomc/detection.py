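"""Slotted detection: Gaussian symbol model, detection error rate, demodulation.

Time is divided into symbol slots of duration ``T_s``; a molecule emitted for
slot ``lambda`` leaves the transmitter at (lambda-1) T_s.  The receiver
observes slot ``k`` in a window of width ``T_s`` centred on the channel peak
time, so the window for slot index ``m`` (elapsed slots since emission) is

    [(m-1) T_s + t_peak - T_s/2,  (m-1) T_s + t_peak + T_s/2]

with the lower edge clamped at 0.  The per-window hit probability q_m is the
increment of the cumulative hit probability over that window.

The mass observed in slot k decomposes into the current-slot signal
(binomial with size M and success q_1), inter-symbol interference from each
earlier slot (transmit coin p folded into the moments: mean p M q_m,
variance p M q_m (1 - q_m)), and ambient Gaussian noise N(mu_n, sigma_n^2).
For large M q_1 the total is approximated as Gaussian with

    mu_k    = M q_1 + sum_m p M q_m + mu_n
    sigma_k^2 = M q_1 (1-q_1) + sum_m p M q_m (1-q_m) + sigma_n^2.

Absorption multiplies the mean by the absorbed-mass scale factor ``s`` and
the variance by ``s^2``.  A non-transmitted (interfering) molecule carries
ISI and noise but no current-slot signal.  The detection error rate for a
transmitted molecule i with threshold theta_i is

    DER = 1 - Q((theta_i - mu_abs,i)/sigma_abs,i)
              * prod_{j != i} Q((mu_hat_abs,j - theta_j)/sigma_hat_abs,j)

with Q the standard normal right tail.  Here ``M`` is a molecule count: the
binomial moments are only meaningful on a count scale, so callers working in
mg convert masses and thresholds with a molecules-per-mg constant (see
:mod:`phytomc.experiments`).

Demodulation applies the mutual-exclusion rule: stress s_i is declared iff
exactly molecule b_i meets or exceeds its threshold; no molecule above, or
more than one, is a decision error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfc

from .channel import ChannelParams, peak_time, hit_probability
from .exceptions import ConfigurationError
from .molecules import MoleculeSpec, StressAlphabet
from .receiver import LeafParams, absorption_scale

__all__ = [
    "SlotScheme",
    "NoiseSpec",
    "SymbolStats",
    "AbsorbedStats",
    "DERResult",
    "DEMODULATION_ERROR",
    "qfunc",
    "slot_hit_prob",
    "noise_from_snr",
    "symbol_moments",
    "gaussian_symbol_model",
    "der",
    "demodulate",
]

#: Sentinel returned by :func:`demodulate` when no molecule, or more than
#: one, reaches its threshold.  A valid output, not an exception.
DEMODULATION_ERROR = "error"

#: Below this current-slot expected count the Gaussian approximation of the
#: binomial is dubious; a warning is issued but computation proceeds.
GAUSSIAN_VALIDITY_COUNT = 100.0


def qfunc(x):
    """Standard normal right-tail probability Q(x), via the complementary error function."""
    return 0.5 * erfc(np.asarray(x, dtype=float) / math.sqrt(2.0))


@dataclass(frozen=True)
class SlotScheme:
    """Symbol interval and the peak-centred detection-window rule."""

    T_s: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.T_s) or self.T_s <= 0:
            raise ConfigurationError(f"T_s must be finite and > 0, got {self.T_s}")

    def window(self, m: int, t_peak: float) -> tuple[float, float]:
        """Detection window for slot index ``m`` (1-based), lower edge clamped at 0."""
        if m < 1:
            raise ValueError(f"slot index must be >= 1, got {m}")
        centre = (m - 1) * self.T_s + t_peak
        return max(centre - 0.5 * self.T_s, 0.0), centre + 0.5 * self.T_s


def slot_hit_prob(k: int, lam: int, scheme: SlotScheme, ch: ChannelParams) -> float:
    """Probability q that a molecule emitted for slot ``lam`` lands in slot ``k``'s window.

    Elapsed-time formulation: emission happens at (lam-1) T_s, so the window
    seen from the emission instant is the window of index m = k - lam + 1.
    ``lam > k`` violates causality and is rejected.
    """
    if k < 1 or lam < 1:
        raise ValueError("slot indices are 1-based")
    if lam > k:
        raise ValueError(f"causality violated: emission slot {lam} > observation slot {k}")
    m = k - lam + 1
    lo, hi = scheme.window(m, peak_time(ch))
    q = hit_probability(hi, ch) - hit_probability(lo, ch)
    return max(q, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Ambient-noise model: absorbed-before-scaling noise count ~ N(mu_n, sigma_n^2)."""

    mu_n: float = 0.0
    sigma_n: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_n < 0 or self.sigma_n < 0:
            raise ConfigurationError("noise moments must be >= 0")


def noise_from_snr(snr: float, M: float, q1: float) -> NoiseSpec:
    """Noise spec from a linear SNR: sigma_n = M q_1 / sqrt(snr), mu_n = sigma_n.

    SNR is the ratio of signal power to noise power, (M q_1)^2 / sigma_n^2;
    setting mu_n = sigma_n closes the two-unknown system with a single
    parameter.
    """
    if not snr > 0:
        raise ConfigurationError(f"snr must be > 0, got {snr}")
    sigma = M * q1 / math.sqrt(snr)
    return NoiseSpec(mu_n=sigma, sigma_n=sigma)


@dataclass(frozen=True)
class SymbolStats:
    """Pre-absorption Gaussian moments of the slot-k observation."""

    mu: float
    var: float
    signal_mean: float
    isi_means: tuple[float, ...]
    noise: NoiseSpec


@dataclass(frozen=True)
class AbsorbedStats:
    """Post-absorption moments, plus the interferer (no current-slot signal) estimates."""

    mu: float
    var: float
    mu_hat: float
    var_hat: float
    scale: float


def symbol_moments(
    M: float, q: Sequence[float], p: float, noise: NoiseSpec
) -> tuple[float, float, float, float]:
    """Gaussian moments (mu, var, mu_hat, var_hat) from per-window hit probabilities.

    ``q[0]`` is the current-slot window probability q_1; ``q[m-1]`` is q_m for
    interference from m-1 slots back.  The hatted pair drops the current-slot
    signal (ISI + noise only).
    """
    if M < 0:
        raise ConfigurationError(f"M must be >= 0, got {M}")
    qa = np.asarray(q, dtype=float)
    if qa.ndim != 1 or len(qa) < 1:
        raise ConfigurationError("q must be a non-empty 1-D sequence")
    if np.any(qa < 0) or np.any(qa > 1):
        raise ConfigurationError(f"window probabilities must lie in [0, 1], got {qa}")
    isi_mean = float(np.sum(p * M * qa[1:]))
    isi_var = float(np.sum(p * M * qa[1:] * (1.0 - qa[1:])))
    mu_hat = isi_mean + noise.mu_n
    var_hat = isi_var + noise.sigma_n**2
    mu = M * qa[0] + mu_hat
    var = M * qa[0] * (1.0 - qa[0]) + var_hat
    return mu, var, mu_hat, var_hat


def gaussian_symbol_model(
    M: float,
    mol: MoleculeSpec,
    scheme: SlotScheme,
    ch: ChannelParams,
    lp: LeafParams,
    noise: NoiseSpec,
    k: int,
) -> tuple[SymbolStats, AbsorbedStats]:
    """Build the slot-k Gaussian observation model for one molecule.

    ``ch`` must already carry this molecule's diffusion coefficient.  ``M`` is
    the per-slot emitted quantity on the count scale.
    """
    if k < 1:
        raise ValueError(f"slot index k must be >= 1, got {k}")
    if abs(ch.D - mol.D) > 1e-15 * max(ch.D, mol.D):
        raise ConfigurationError(
            f"channel D={ch.D} does not match molecule {mol.name!r} D={mol.D}"
        )
    q = [slot_hit_prob(m, 1, scheme, ch) for m in range(1, k + 1)]
    if M * q[0] < GAUSSIAN_VALIDITY_COUNT:
        warnings.warn(
            f"current-slot expected count M*q1 = {M * q[0]:.3g} < "
            f"{GAUSSIAN_VALIDITY_COUNT:g}; Gaussian approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    mu, var, mu_hat, var_hat = symbol_moments(M, q, mol.transmit_prob, noise)
    s = absorption_scale(lp, ch.R)
    stats = SymbolStats(
        mu=mu, var=var, signal_mean=M * q[0],
        isi_means=tuple(mol.transmit_prob * M * qm for qm in q[1:]),
        noise=noise,
    )
    absorbed = AbsorbedStats(
        mu=mu * s, var=var * s * s, mu_hat=mu_hat * s, var_hat=var_hat * s * s, scale=s
    )
    return stats, absorbed


def _prob_ge(theta: float, mu: float, var: float) -> float:
    """P(X >= theta) for X ~ N(mu, var); degenerate var = 0 gives a step."""
    if var < 0:
        raise ConfigurationError(f"variance must be >= 0, got {var}")
    if var == 0:
        return 1.0 if mu >= theta else 0.0
    return float(qfunc((theta - mu) / math.sqrt(var)))


def _prob_lt(theta: float, mu: float, var: float) -> float:
    """P(X < theta) for X ~ N(mu, var); degenerate var = 0 gives a step."""
    if var < 0:
        raise ConfigurationError(f"variance must be >= 0, got {var}")
    if var == 0:
        return 1.0 if mu < theta else 0.0
    return float(qfunc((mu - theta) / math.sqrt(var)))


@dataclass(frozen=True)
class DERResult:
    """Detection error rate with its miss/false-alarm breakdown."""

    p_error: float
    detect_prob: float                      # P(transmitted molecule >= its threshold)
    interferer_below: Mapping[str, float]   # P(interferer j < theta_j) per molecule

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_error <= 1.0:
            raise ConfigurationError(f"p_error must lie in [0, 1], got {self.p_error}")


def der(
    transmitted: str,
    absorbed: Mapping[str, AbsorbedStats],
    thresholds: Mapping[str, float],
) -> DERResult:
    """Closed-form detection error rate for the transmitted molecule.

    DER = 1 - P(correct detection) * prod_j P(interferer j stays below its
    threshold).  Degenerate (zero-variance) statistics are handled by the
    step-function limit.
    """
    if transmitted not in absorbed:
        raise ConfigurationError(f"no statistics for transmitted molecule {transmitted!r}")
    st = absorbed[transmitted]
    detect = _prob_ge(thresholds[transmitted], st.mu, st.var)
    below: dict[str, float] = {}
    prod = 1.0
    for name, stats in absorbed.items():
        if name == transmitted:
            continue
        b = _prob_lt(thresholds[name], stats.mu_hat, stats.var_hat)
        below[name] = b
        prod *= b
    p_err = min(max(1.0 - detect * prod, 0.0), 1.0)
    return DERResult(p_error=p_err, detect_prob=detect, interferer_below=below)


def demodulate(absorbed_mass: Mapping[str, float], alphabet: StressAlphabet) -> str:
    """Map absorbed masses to a stress label by single-molecule threshold exclusion.

    Returns the stress of molecule b_i iff exactly b_i meets or exceeds its
    threshold and every other molecule stays strictly below; otherwise the
    sentinel :data:`DEMODULATION_ERROR`.
    """
    for mol in alphabet:
        if mol.name not in absorbed_mass:
            raise ConfigurationError(f"absorbed mass missing for molecule {mol.name!r}")
    above = [mol for mol in alphabet if absorbed_mass[mol.name] >= mol.threshold]
    if len(above) == 1:
        return above[0].stress
    return DEMODULATION_ERROR
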