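"""Pairwise contact energetics and temperature handling.

Interaction energies ``eps(t1, t2)`` are defined per unordered bead-type
pair in temperature units (k_B = 1).  Only pairs with nonzero eps can form
an anisotropic bond.  The position energy is hard-core: overlaps are never
admitted, so the total energy of a valid state is the sum of eps over
bonded pairs.  The reduced temperature is T* = k_B T / |eps_ref| where
eps_ref is the declared reference sticker-sticker energy.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnergyModel"]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EnergyModel:
    """Symmetric eps matrix by bead-type label plus a simulation temperature."""

    pairs: dict[tuple[str, str], float]
    temperature: float = 1.0
    reference_energy: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        canon: dict[tuple[str, str], float] = {}
        for (a, b), e in self.pairs.items():
            k = _key(a, b)
            if k in canon and canon[k] != float(e):
                raise ValueError(f"asymmetric eps for pair {k}")
            canon[k] = float(e)
        object.__setattr__(self, "pairs", canon)
        if self.reference_energy is not None and self.reference_energy <= 0:
            raise ValueError("reference_energy must be a positive magnitude")

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature

    @property
    def reduced_temperature(self) -> float | None:
        """T* = k_B T / |eps_ref| when a reference energy is declared."""
        if self.reference_energy is None:
            return None
        return self.temperature / self.reference_energy

    def epsilon(self, a: str, b: str) -> float:
        return self.pairs.get(_key(a, b), 0.0)

    def can_bond(self, a: str, b: str) -> bool:
        return self.epsilon(a, b) != 0.0

    # -- derived models ----------------------------------------------------

    def with_temperature(self, temperature: float) -> "EnergyModel":
        return EnergyModel(dict(self.pairs), temperature, self.reference_energy)

    def at_reduced_temperature(self, tstar: float) -> "EnergyModel":
        if self.reference_energy is None:
            raise ValueError("no reference energy declared; cannot set T*")
        return self.with_temperature(tstar * self.reference_energy)

    def zeroed(self) -> "EnergyModel":
        """All eps set to 0: the non-interacting prior system."""
        return EnergyModel({k: 0.0 for k in self.pairs}, self.temperature,
                           self.reference_energy)
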