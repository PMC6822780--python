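"""System assembly and simulation state.

A :class:`LatticeSystem` is the immutable description of a simulation:
lattice, bead types, molecule architectures with copy numbers, and the
energy model.  It compiles flat integer arrays (bead types, chain tables,
tether adjacency, eps matrix) consumed by the Monte Carlo kernel.

A :class:`SystemState` holds the mutable configuration: per-bead positions,
the site-occupancy table, and the per-bead bond partner (the anisotropic
"rotational state").  Energy bookkeeping is exact: bonds are counted per
unordered type pair in integers, and the total energy is the sum of
count * eps, so incremental updates and full recomputation agree bit for
bit for integer-valued eps.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .architecture import BeadType, MoleculeArchitecture
from .energy import EnergyModel
from .lattice import LatticeConfig, linker_offsets, linker_reach, min_image_sq

__all__ = [
    "SystemComposition",
    "LatticeSystem",
    "SystemState",
    "InvalidStateError",
    "CongestionError",
    "total_energy",
    "randomize_initial_state",
]


class InvalidStateError(RuntimeError):
    """A state invariant (occupancy, bond, linker or energy) is violated."""


class CongestionError(RuntimeError):
    """Random placement failed repeatedly; the system is too dense."""


@dataclass(frozen=True)
class SystemComposition:
    """Molecule copy numbers on a lattice; concentrations are n_i / L^3."""

    counts: dict[str, int]
    lattice: LatticeConfig

    def concentration(self, name: str) -> float:
        return self.counts[name] / self.lattice.n_sites

    @property
    def n_molecules(self) -> int:
        return sum(self.counts.values())


class LatticeSystem:
    """Immutable simulation description with kernel-ready compiled arrays.

    Molecules are laid out chain by chain, molecule type by molecule type,
    with beads of one chain contiguous and indexed in architecture order.
    """

    def __init__(
        self,
        lattice: LatticeConfig,
        bead_types: list[BeadType],
        molecules: list[tuple[MoleculeArchitecture, int]],
        energy: EnergyModel,
    ):
        self.lattice = lattice
        self.bead_types = list(bead_types)
        labels = [t.label for t in self.bead_types]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate bead-type labels")
        self.type_code = {t.label: i for i, t in enumerate(self.bead_types)}
        self.architectures = [a for a, _ in molecules]
        self.counts = {a.name: int(n) for a, n in molecules}
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("molecule counts must be non-negative")
        for arch in self.architectures:
            for lab in arch.beads:
                if lab not in self.type_code:
                    raise ValueError(f"{arch.name}: unknown bead type {lab!r}")
        self.energy = energy
        self._compile()
        if self.n_beads >= lattice.n_sites:
            raise ValueError(
                f"total bead count {self.n_beads} must be below L^3 = {lattice.n_sites}"
            )

    # -- compiled tables ---------------------------------------------------

    def _compile(self) -> None:
        T = len(self.bead_types)
        eps = np.zeros((T, T), dtype=np.float64)
        for i, ti in enumerate(self.bead_types):
            for j, tj in enumerate(self.bead_types):
                eps[i, j] = self.energy.epsilon(ti.label, tj.label)
        self.eps_matrix = eps
        self.is_sticker = np.array([t.is_sticker for t in self.bead_types], dtype=np.bool_)

        n_mt = len(self.architectures)
        self.mt_nbeads = np.array([a.n_beads for a in self.architectures], dtype=np.int64)
        self.mt_linear = np.array([a.is_linear for a in self.architectures], dtype=np.bool_)
        rept_ok, rept_reach, rept_l2, rept_orders = [], [], [], []
        mt_btype = []
        bond_rows = []  # (mt, a, b, l, 3 l^2), a < b
        mt_bond_start = [0]
        for a in self.architectures:
            mt_btype.append([self.type_code[lab] for lab in a.beads])
            for i, j, l in a.bonds:
                lo, hi = (i, j) if i < j else (j, i)
                bond_rows.append((lo, hi, l, 3 * l * l))
            mt_bond_start.append(len(bond_rows))
            ok = a.is_linear and a.homogeneous_linkers and a.n_beads >= 2
            rept_ok.append(ok)
            if ok:
                l = a.bonds[0][2]
                rept_reach.append(linker_reach(l))
                rept_l2.append(3 * l * l)
                rept_orders.append(a.path_order())
            else:
                rept_reach.append(0)
                rept_l2.append(0)
                rept_orders.append(list(range(a.n_beads)))
        self.mt_rept_ok = np.array(rept_ok, dtype=np.bool_)
        self.mt_rept_reach = np.array(rept_reach, dtype=np.int64)
        self.mt_rept_l2 = np.array(rept_l2, dtype=np.int64)
        self.mt_bond_start = np.array(mt_bond_start, dtype=np.int64)
        if bond_rows:
            br = np.array(bond_rows, dtype=np.int64)
        else:
            br = np.zeros((0, 4), dtype=np.int64)
        self.bond_a, self.bond_b, self.bond_l, self.bond_l2 = (
            br[:, 0].copy(), br[:, 1].copy(), br[:, 2].copy(), br[:, 3].copy())

        # chains in molecule-type order
        chain_mt = []
        for mt in range(n_mt):
            chain_mt.extend([mt] * self.counts[self.architectures[mt].name])
        self.chain_mt = np.array(chain_mt, dtype=np.int64)
        self.n_chains = len(chain_mt)
        sizes = self.mt_nbeads[self.chain_mt] if self.n_chains else np.zeros(0, np.int64)
        self.chain_start = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.n_beads = int(self.chain_start[-1])

        self.btype = np.empty(self.n_beads, dtype=np.int64)
        self.chain_of = np.empty(self.n_beads, dtype=np.int64)
        ro = np.empty(self.n_beads, dtype=np.int64)  # path order, per chain
        for c in range(self.n_chains):
            s, mt = self.chain_start[c], self.chain_mt[c]
            nb = self.mt_nbeads[mt]
            self.btype[s:s + nb] = mt_btype[mt]
            self.chain_of[s:s + nb] = c
            ro[s:s + nb] = np.asarray(rept_orders[mt], dtype=np.int64)
        self.rept_order = ro

        # per-bead tether adjacency (global bead ids)
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_beads)]
        for c in range(self.n_chains):
            s, mt = self.chain_start[c], self.chain_mt[c]
            for i, j, l in self.architectures[mt].bonds:
                adj[s + i].append((s + j, 3 * l * l))
                adj[s + j].append((s + i, 3 * l * l))
        self.adj_start = np.zeros(self.n_beads + 1, dtype=np.int64)
        flat_nbr, flat_l2 = [], []
        for b in range(self.n_beads):
            for nbr, l2 in adj[b]:
                flat_nbr.append(nbr)
                flat_l2.append(l2)
            self.adj_start[b + 1] = len(flat_nbr)
        self.adj_nbr = np.array(flat_nbr, dtype=np.int64)
        self.adj_l2 = np.array(flat_l2, dtype=np.int64)

    # -- convenience -------------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return self.n_chains

    @property
    def composition(self) -> SystemComposition:
        return SystemComposition(dict(self.counts), self.lattice)

    def concentration(self, name: str) -> float:
        return self.counts[name] / self.lattice.n_sites

    def boltzmann_table(self, beta: float | None = None) -> np.ndarray:
        """candw[t1, t2] = exp(-beta eps) for bondable pairs, else 0."""
        if beta is None:
            beta = self.energy.beta
        tab = np.where(self.eps_matrix != 0.0, np.exp(-beta * self.eps_matrix), 0.0)
        return tab

    def with_energy(self, energy: EnergyModel) -> "LatticeSystem":
        return LatticeSystem(self.lattice, self.bead_types,
                             list(zip(self.architectures,
                                      [self.counts[a.name] for a in self.architectures])),
                             energy)

    def zeroed(self) -> "LatticeSystem":
        """The matched prior system: identical geometry, all eps = 0."""
        return self.with_energy(self.energy.zeroed())


class SystemState:
    """Mutable configuration of a :class:`LatticeSystem`."""

    def __init__(self, system: LatticeSystem):
        self.system = system
        n = system.n_beads
        self.pos = np.zeros((n, 3), dtype=np.int64)
        self.occ = np.full(system.lattice.n_sites, -1, dtype=np.int64)
        self.partner = np.full(n, -1, dtype=np.int64)
        T = len(system.bead_types)
        self.bond_count = np.zeros((T, T), dtype=np.int64)

    # -- energy ------------------------------------------------------------

    @property
    def energy(self) -> float:
        """E = E_rot (E_pos is identically 0: overlaps are never admitted)."""
        return float(np.sum(self.bond_count * self.system.eps_matrix))

    def recompute_energy(self) -> float:
        """Brute-force scan over the partner map, each bond counted once."""
        e = 0.0
        bt = self.system.btype
        eps = self.system.eps_matrix
        for u in range(self.system.n_beads):
            v = self.partner[u]
            if v > u:
                e += eps[bt[u], bt[v]]
        return e

    # -- copies and identity -----------------------------------------------

    def copy(self) -> "SystemState":
        out = SystemState.__new__(SystemState)
        out.system = self.system
        out.pos = self.pos.copy()
        out.occ = self.occ.copy()
        out.partner = self.partner.copy()
        out.bond_count = self.bond_count.copy()
        return out

    def fingerprint(self) -> bytes:
        return self.pos.tobytes() + self.partner.tobytes()

    def __eq__(self, other) -> bool:
        return (isinstance(other, SystemState)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.partner, other.partner))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every state invariant; raise InvalidStateError on failure.

        Deliberately written against the friendly API (not the kernel) so it
        is an independent cross-check of the kernel's bookkeeping.
        """
        sysd = self.system
        L = sysd.lattice.L
        # occupancy bijection <-> no overlaps (conceptual E_pos = 0)
        occupied = np.flatnonzero(self.occ >= 0)
        if len(occupied) != sysd.n_beads:
            raise InvalidStateError("occupied site count != bead count (overlap?)")
        flat = (self.pos[:, 0] * L + self.pos[:, 1]) * L + self.pos[:, 2]
        if np.any(self.pos < 0) or np.any(self.pos >= L):
            raise InvalidStateError("position out of range")
        if not np.array_equal(self.occ[flat], np.arange(sysd.n_beads)):
            raise InvalidStateError("occupancy table inconsistent with positions")
        # partner map
        bt = sysd.btype
        for u in range(sysd.n_beads):
            v = self.partner[u]
            if v < 0:
                continue
            if v == u:
                raise InvalidStateError(f"bead {u} bonded to itself")
            if self.partner[v] != u:
                raise InvalidStateError(f"partner map not symmetric at {u}<->{v}")
            if not sysd.is_sticker[bt[u]]:
                raise InvalidStateError(f"non-sticker bead {u} holds a bond")
            if sysd.eps_matrix[bt[u], bt[v]] == 0.0:
                raise InvalidStateError(f"bond {u}-{v} between non-interacting types")
            if min_image_sq(self.pos[u], self.pos[v], L) > 3:
                raise InvalidStateError(f"bonded beads {u}-{v} not adjacent")
        # linker constraints
        for u in range(sysd.n_beads):
            for k in range(sysd.adj_start[u], sysd.adj_start[u + 1]):
                v, l2 = sysd.adj_nbr[k], sysd.adj_l2[k]
                if min_image_sq(self.pos[u], self.pos[v], L) > l2:
                    raise InvalidStateError(f"linker violated between beads {u} and {v}")
        # energy bookkeeping
        T = len(sysd.bead_types)
        recount = np.zeros((T, T), dtype=np.int64)
        for u in range(sysd.n_beads):
            v = self.partner[u]
            if v > u:
                a, b = sorted((bt[u], bt[v]))
                recount[a, b] += 1
        if not np.array_equal(recount, self.bond_count):
            raise InvalidStateError("bond-count bookkeeping out of sync")
        if self.energy != self.recompute_energy():
            raise InvalidStateError("incremental energy != recomputed energy")


def total_energy(state: SystemState, model: EnergyModel | None = None) -> float:
    """Sum of eps over bonded pairs, each bond counted once.

    ``model`` defaults to the system's own energy model; passing a different
    one re-prices the current bond pattern (used for temperature sweeps).
    """
    if model is None or model is state.system.energy:
        return state.energy
    e = 0.0
    labels = [t.label for t in state.system.bead_types]
    bt = state.system.btype
    for u in range(state.system.n_beads):
        v = state.partner[u]
        if v > u:
            e += model.epsilon(labels[bt[u]], labels[bt[v]])
    return e


def randomize_initial_state(system: LatticeSystem, seed) -> SystemState:
    """Place all molecules at random with no overlaps and all tethers taut-legal.

    Bead 0 of each molecule lands on a uniform empty site; the remaining
    beads grow in BFS order by rejection sampling inside each bond's tether
    ball (100 tries per bead, 100 tries per molecule, 100 system restarts).
    All beads start unbonded.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    L = system.lattice.L
    build_orders = [a.build_order() for a in system.architectures]
    offset_pool = {l: np.array(linker_offsets(l), dtype=np.int64)
                   for a in system.architectures for _, _, l in a.bonds}

    for _attempt in range(100):
        state = SystemState(system)
        ok = True
        for c in range(system.n_chains):
            if not _place_molecule(state, c, build_orders, offset_pool, rng, L):
                ok = False
                break
        if ok:
            return state
    density = system.n_beads / system.lattice.n_sites
    raise CongestionError(
        f"placement failed after 100 system restarts (bead density {density:.3f})")


def _place_molecule(state, c, build_orders, offset_pool, rng, L) -> bool:
    sysd = state.system
    s = sysd.chain_start[c]
    mt = sysd.chain_mt[c]
    nb = sysd.mt_nbeads[mt]
    order = build_orders[mt]
    for _ in range(100):
        placed: list[int] = []
        # root bead
        root_ok = False
        for _ in range(100):
            p = rng.integers(0, L, size=3)
            f = (p[0] * L + p[1]) * L + p[2]
            if state.occ[f] < 0:
                state.pos[s] = p
                state.occ[f] = s
                placed.append(f)
                root_ok = True
                break
        if not root_ok:
            return False
        grown = True
        for child, parent, l in order:
            offs = offset_pool[l]
            bead_ok = False
            for _ in range(100):
                d = offs[rng.integers(0, len(offs))]
                p = (state.pos[s + parent] + d) % L
                f = (p[0] * L + p[1]) * L + p[2]
                if state.occ[f] < 0:
                    state.pos[s + child] = p
                    state.occ[f] = s + child
                    placed.append(f)
                    bead_ok = True
                    break
            if not bead_ok:
                grown = False
                break
        if grown:
            return True
        for f in placed:  # retract and retry this molecule
            state.occ[f] = -1
    return False
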