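"""YAML configuration loading.

A single YAML file with blocks ``molecules``, ``channel``, ``leaf``,
``detection`` and ``simulate`` parameterises every module.  Example::

    molecules:
      - {name: b1, D: 0.007, threshold: 4.0e-5, transmit_prob: 0.5,
         stress: pest, compound: methyl jasmonate}
      - {name: b2, D: 0.009, threshold: 4.0e-5, transmit_prob: 0.5,
         stress: heat, compound: ethanol}
    channel: {d: 1.0, v: 1.0, R: 0.15, omega: 2.0}
    leaf: {A_L: 0.009, g: 86.4, rho_L: 1000.0, m_L: 0.05, K_L: 20.0,
           phi: 0.5, tau: 2.0, conductance_mode: as_printed}
    detection: {T_s: 2.0, snr: 10.0, k: 1, molecules_per_mg: 1.0e6}
    transmitter: {mode: impulse, M: 0.0016}
    simulate: {seed: 1, n_particles: 20000, n_trials: 100000}

Every block is optional; omitted values fall back to the study defaults.
The channel block's ``D`` (if given) is only a placeholder — each molecule's
own diffusion coefficient overrides it wherever molecules are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .channel import ChannelParams
from .detection import SlotScheme
from .exceptions import ConfigurationError
from .molecules import MoleculeSpec, StressAlphabet, default_alphabet
from .receiver import LeafParams
from .transmitter import EmissionProfile

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class RunConfig:
    """Typed bundle of every parameter block."""

    alphabet: StressAlphabet
    channel: ChannelParams
    leaf: LeafParams
    scheme: SlotScheme
    emission: EmissionProfile
    snr: float = 10.0
    k: int = 1
    molecules_per_mg: float = 1e6
    seed: int = 1
    n_particles: int = 20000
    n_trials: int = 100_000


def default_config() -> RunConfig:
    return RunConfig(
        alphabet=default_alphabet(),
        channel=ChannelParams(d=1.0, v=1.0, D=0.007, R=0.15, omega=2.0),
        leaf=LeafParams(conductance_mode="as_printed"),
        scheme=SlotScheme(T_s=2.0),
        emission=EmissionProfile.impulse(0.0016),
    )


def _build(cls, block: Mapping[str, Any], label: str):
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigurationError(f"bad {label} block: {exc}") from None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    base = default_config()

    if "molecules" in raw:
        alphabet = StressAlphabet([_build(MoleculeSpec, m, "molecule") for m in raw["molecules"]])
    else:
        alphabet = base.alphabet

    ch_block = dict(raw.get("channel", {}))
    ch_block.setdefault("D", alphabet[0].D)
    channel = _build(ChannelParams, ch_block, "channel") if "channel" in raw else base.channel

    leaf = _build(LeafParams, raw["leaf"], "leaf") if "leaf" in raw else base.leaf

    det = dict(raw.get("detection", {}))
    scheme = SlotScheme(T_s=float(det.get("T_s", base.scheme.T_s)))

    tx = dict(raw.get("transmitter", {}))
    mode = tx.get("mode", "impulse")
    if mode == "impulse":
        emission = EmissionProfile.impulse(float(tx.get("M", base.emission.M)))
    else:
        emission = EmissionProfile.from_timeseries(tx["time_grid"], tx["J_values"])

    sim = dict(raw.get("simulate", {}))
    return RunConfig(
        alphabet=alphabet,
        channel=channel,
        leaf=leaf,
        scheme=scheme,
        emission=emission,
        snr=float(det.get("snr", base.snr)),
        k=int(det.get("k", base.k)),
        molecules_per_mg=float(det.get("molecules_per_mg", base.molecules_per_mg)),
        seed=int(sim.get("seed", base.seed)),
        n_particles=int(sim.get("n_particles", base.n_particles)),
        n_trials=int(sim.get("n_trials", base.n_trials)),
    )
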