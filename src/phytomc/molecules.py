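"""Stress alphabet: the one-to-one mapping between stress types and signalling volatiles.

Each stress a transmitter plant can experience is modulated onto a single
characteristic biogenic volatile organic compound (BVOC).  A molecule is
described by its air diffusion coefficient ``D`` (m^2/s), the receiver's
detection threshold ``threshold`` on absorbed mass (mg), and the per-slot
transmit probability ``transmit_prob`` used by the interference model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

from .exceptions import ConfigurationError

__all__ = ["MoleculeSpec", "StressAlphabet", "default_alphabet"]


@dataclass(frozen=True)
class MoleculeSpec:
    """One stress-specific signalling compound.

    Parameters
    ----------
    name : short label used in tables and configs (e.g. ``"b1"``).
    D : diffusion coefficient in air, m^2/s.
    threshold : detection threshold on absorbed mass, mg.
    transmit_prob : probability that this molecule is emitted in any given
        symbol slot, used by the inter-symbol-interference model.
    stress : the stress type this molecule encodes (e.g. ``"pest"``).
    compound : optional chemical name (e.g. ``"methyl jasmonate"``).
    """

    name: str
    D: float
    threshold: float
    transmit_prob: float = 0.5
    stress: str = ""
    compound: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("molecule name must be non-empty")
        for label, value in (("D", self.D), ("threshold", self.threshold)):
            if not math.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{label} must be finite and > 0, got {value}")
        if not 0.0 <= self.transmit_prob <= 1.0:
            raise ConfigurationError(
                f"transmit_prob must lie in [0, 1], got {self.transmit_prob}"
            )
        if not self.stress:
            object.__setattr__(self, "stress", f"stress[{self.name}]")

    def with_threshold(self, threshold: float) -> "MoleculeSpec":
        return replace(self, threshold=threshold)


class StressAlphabet:
    """An ordered set of molecules with unique names and unique stress labels."""

    def __init__(self, molecules: Sequence[MoleculeSpec]):
        mols = tuple(molecules)
        if not mols:
            raise ConfigurationError("alphabet must contain at least one molecule")
        names = [m.name for m in mols]
        stresses = [m.stress for m in mols]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"molecule names must be unique, got {names}")
        if len(set(stresses)) != len(stresses):
            raise ConfigurationError(f"stress labels must be unique, got {stresses}")
        self._molecules = mols
        self._by_name = {m.name: m for m in mols}

    def __iter__(self) -> Iterator[MoleculeSpec]:
        return iter(self._molecules)

    def __len__(self) -> int:
        return len(self._molecules)

    def __getitem__(self, i: int) -> MoleculeSpec:
        return self._molecules[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self._molecules)

    def by_name(self, name: str) -> MoleculeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"unknown molecule {name!r}") from None

    def stress_of(self, name: str) -> str:
        return self.by_name(name).stress

    def with_thresholds(self, thresholds: Mapping[str, float]) -> "StressAlphabet":
        """Return a copy with per-molecule detection thresholds replaced."""
        return StressAlphabet(
            [
                m.with_threshold(thresholds[m.name]) if m.name in thresholds else m
                for m in self._molecules
            ]
        )


def default_alphabet(
    threshold_b1: float = 4e-5,
    threshold_b2: float = 4e-5,
    transmit_prob: float = 0.5,
) -> StressAlphabet:
    """Two-molecule alphabet: methyl jasmonate for pest stress, ethanol for heat stress.

    Diffusion coefficients follow the two-molecule detection study
    (D_b1 = 0.007, D_b2 = 0.009 m^2/s).  The threshold defaults are
    convenience values for the CLI; detection experiments normally replace
    them with the optimum found by :func:`phytomc.experiments.optimal_thresholds`.
    """
    return StressAlphabet(
        [
            MoleculeSpec(
                "b1", D=0.007, threshold=threshold_b1, transmit_prob=transmit_prob,
                stress="pest", compound="methyl jasmonate",
            ),
            MoleculeSpec(
                "b2", D=0.009, threshold=threshold_b2, transmit_prob=transmit_prob,
                stress="heat", compound="ethanol",
            ),
        ]
    )
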