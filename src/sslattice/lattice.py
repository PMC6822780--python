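"""Cubic periodic lattice geometry.

Positions are integer triples on a simple cubic lattice of edge ``L`` with
periodic boundary conditions; the minimum-image convention makes the largest
possible separation ``sqrt(3) * L / 2``.  Two sites are *adjacent* when their
squared minimum-image distance is at most 3, which yields exactly the 26
sites of the surrounding unit cube.  A tether of length ``l`` generalizes
adjacency to ``d^2 <= 3 * l^2``, so an ``l = 1`` tether reproduces the
26-site neighborhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

__all__ = [
    "LatticeConfig",
    "wrap_position",
    "min_image_sq",
    "min_image_distance",
    "enumerate_neighbor_sites",
    "check_linker",
    "linker_reach",
    "linker_offsets",
]

Triple = tuple[int, int, int]


@dataclass(frozen=True)
class LatticeConfig:
    """Edge length of a periodic simple cubic lattice (L^3 voxels)."""

    L: int
    periodic: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.L, int) or self.L < 4:
            raise ValueError(f"lattice edge must be an integer >= 4, got {self.L!r}")
        if not self.periodic:
            raise ValueError("only periodic lattices are supported")

    @property
    def n_sites(self) -> int:
        return self.L**3

    @property
    def max_distance(self) -> float:
        """Largest minimum-image distance, sqrt(3) * L / 2."""
        return math.sqrt(3.0) * self.L / 2.0


def _edge(lattice: LatticeConfig | int) -> int:
    L = lattice.L if isinstance(lattice, LatticeConfig) else int(lattice)
    if L < 3:
        raise ValueError("lattice edge must be >= 3")
    return L


def wrap_position(p, lattice: LatticeConfig | int) -> Triple:
    """Reduce each coordinate modulo L into [0, L)."""
    L = _edge(lattice)
    return (p[0] % L, p[1] % L, p[2] % L)


def min_image_sq(p1, p2, lattice: LatticeConfig | int) -> int:
    """Squared minimum-image Euclidean distance between two wrapped sites."""
    L = _edge(lattice)
    s = 0
    for a, b in zip(p1, p2):
        d = abs(a - b) % L
        d = min(d, L - d)
        s += d * d
    return s


def min_image_distance(p1, p2, lattice: LatticeConfig | int) -> float:
    return math.sqrt(min_image_sq(p1, p2, lattice))


_OFFSETS_26: tuple[Triple, ...] = tuple(
    o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
)


def enumerate_neighbor_sites(p, lattice: LatticeConfig | int) -> list[Triple]:
    """The 26 wrapped sites with per-coordinate offsets in {-1, 0, 1}.

    These are exactly the sites within squared minimum-image distance 3 of
    ``p``, i.e. where a sticker on ``p`` can place an anisotropic bond.
    """
    L = _edge(lattice)
    x, y, z = p
    return [((x + dx) % L, (y + dy) % L, (z + dz) % L) for dx, dy, dz in _OFFSETS_26]


def check_linker(p1, p2, l: int, lattice: LatticeConfig | int) -> bool:
    """True iff the tether constraint d^2 <= 3 l^2 holds between two sites.

    With ``l = 1`` this is exactly membership in the 26-site neighborhood.
    """
    if l < 1:
        raise ValueError("linker length must be a positive integer")
    return min_image_sq(p1, p2, lattice) <= 3 * l * l


def linker_reach(l: int) -> int:
    """Largest per-coordinate offset compatible with a length-l tether."""
    return math.isqrt(3 * l * l)


@lru_cache(maxsize=None)
def linker_offsets(l: int) -> tuple[Triple, ...]:
    """All nonzero integer offsets v with |v|^2 <= 3 l^2.

    Used both for growing chains during random placement and for sampling
    ideal (phantom-tether) bond vectors; the zero vector is excluded so that
    bonded beads never coincide.
    """
    if l < 1:
        raise ValueError("linker length must be a positive integer")
    r = linker_reach(l)
    lim = 3 * l * l
    return tuple(
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
        if 0 < dx * dx + dy * dy + dz * dz <= lim
    )
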