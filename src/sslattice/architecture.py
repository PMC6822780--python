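"""Molecule architectures: sticker/spacer bead graphs with tether lengths.

A molecule is a connected acyclic graph (chain or tree) of beads.  Each bead
carries a :class:`BeadType`; each edge carries a positive integer tether
length ``l`` constraining the two beads to ``d^2 <= 3 l^2`` on the lattice.
Contour distances are sums of tether lengths along the unique tree path and
are distinct from Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["BeadType", "MoleculeArchitecture", "build_architecture", "ArchitectureError"]


class ArchitectureError(ValueError):
    """Raised for invalid molecule graphs (cycles, disconnection, bad linkers)."""


@dataclass(frozen=True)
class BeadType:
    """A bead species.  Stickers may hold one anisotropic bond at a time."""

    label: str
    is_sticker: bool


@dataclass(frozen=True)
class MoleculeArchitecture:
    """One molecule type: ordered beads plus a tree of tethered bonds.

    ``beads`` holds bead-type labels by 0-based index; ``bonds`` holds
    ``(i, j, l)`` with ``l`` in lattice units.  ``is_linear`` and
    ``homogeneous_linkers`` are derived; reptation is admissible only when
    both hold.
    """

    name: str
    beads: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]
    is_linear: bool = field(init=False)
    homogeneous_linkers: bool = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.beads)
        if n == 0:
            raise ArchitectureError(f"{self.name}: molecule must have at least one bead")
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j, l in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ArchitectureError(f"{self.name}: bad bond indices ({i}, {j})")
            if not isinstance(l, int) or l < 1:
                raise ArchitectureError(f"{self.name}: linker length must be a positive integer, got {l!r}")
            if g.has_edge(i, j):
                raise ArchitectureError(f"{self.name}: duplicate bond ({i}, {j})")
            g.add_edge(i, j, l=l)
        if not nx.is_connected(g):
            raise ArchitectureError(f"{self.name}: bond graph is disconnected")
        if g.number_of_edges() != n - 1:
            raise ArchitectureError(f"{self.name}: bond graph contains a cycle")
        degrees = [d for _, d in g.degree()]
        linear = all(d <= 2 for d in degrees)
        object.__setattr__(self, "is_linear", linear)
        ls = {l for _, _, l in self.bonds}
        object.__setattr__(self, "homogeneous_linkers", len(ls) <= 1)
        object.__setattr__(self, "_graph", g)

    # -- derived structure -------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def graph(self) -> nx.Graph:
        return self._graph  # type: ignore[attr-defined]

    def contour_distance(self, i: int, j: int) -> int:
        """Sum of tether lengths along the unique path between beads i and j."""
        return nx.shortest_path_length(self.graph, i, j, weight="l")

    def path_order(self) -> list[int]:
        """Bead indices in path order (linear molecules only)."""
        if not self.is_linear:
            raise ArchitectureError(f"{self.name}: not a linear molecule")
        if self.n_beads == 1:
            return [0]
        ends = [v for v, d in self.graph.degree() if d == 1]
        return nx.shortest_path(self.graph, min(ends), max(ends))

    def build_order(self) -> list[tuple[int, int, int]]:
        """(child, parent, l) in BFS order from bead 0, for sequential placement."""
        out = []
        for parent, child in nx.bfs_edges(self.graph, 0):
            out.append((child, parent, self.graph.edges[parent, child]["l"]))
        return out

    def sticker_count(self, bead_types: dict[str, BeadType]) -> int:
        return sum(1 for b in self.beads if bead_types[b].is_sticker)


def build_architecture(name, beads, bonds) -> MoleculeArchitecture:
    """Validate and construct a :class:`MoleculeArchitecture`.

    Raises :class:`ArchitectureError` on disconnected or cyclic graphs and
    nonpositive linker lengths.
    """
    return MoleculeArchitecture(name=str(name), beads=tuple(beads),
                                bonds=tuple((int(i), int(j), int(l)) for i, j, l in bonds))
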