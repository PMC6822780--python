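"""Independent validators: exact Boltzmann enumeration and a volume oracle.

These deliberately avoid the Monte Carlo kernel so that they can serve as
independent ground truth for it: the enumeration walks the full
configuration space of a tiny system by brute force, and the volume oracle
estimates the torus shell measure V(x) by direct sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .lattice import linker_offsets
from .system import LatticeSystem, SystemState

__all__ = ["ExactDistribution", "enumerate_exact_boltzmann",
           "state_fingerprint", "fingerprint_from_arrays", "mc_volume_oracle"]


class StateSpaceOverflow(RuntimeError):
    """The configuration space exceeds the enumeration cap."""


@dataclass
class ExactDistribution:
    """Exact Boltzmann measure of a tiny system (translation-reduced).

    ``fingerprints`` maps a translation/point-group invariant projection of
    the configuration (sorted multiset of pairwise squared distances plus
    the multiset of bond kinds) to its exact probability.  Expectations of
    energy, bond number and phi_c come from the same sweep.
    """

    n_placements: int          # translation-reduced placements
    n_states: int              # placements x bond matchings
    n_configurations: int      # full count, including the L^3 translations
    fingerprints: dict
    mean_energy: float
    mean_bonds: float
    bond_fraction: float       # mean fraction of stickers engaged
    phi_c_distribution: dict
    partition_function: float

    @property
    def mean_phi_c(self) -> float:
        return sum(p * v for v, p in self.phi_c_distribution.items())


def _pair_d2(p1, p2, L):
    s = 0
    for a, b in zip(p1, p2):
        d = abs(a - b) % L
        d = min(d, L - d)
        s += d * d
    return s


def fingerprint_from_arrays(pos, partner, chain_of, btype, L):
    """Symmetry-invariant projection of a configuration.

    Invariant under lattice translations, the cubic point group, and
    relabeling of identical molecules: the sorted multiset of all pairwise
    squared minimum-image distances, together with the sorted multiset of
    bond kinds (same-chain flag + sorted bead-type pair).
    """
    n = len(pos)
    d2s = tuple(sorted(_pair_d2(pos[i], pos[j], L)
                       for i in range(n) for j in range(i + 1, n)))
    kinds = []
    for u in range(n):
        v = partner[u]
        if v > u:
            kinds.append((chain_of[u] == chain_of[v],
                          tuple(sorted((int(btype[u]), int(btype[v])))),))
    return d2s, tuple(sorted(kinds))


def state_fingerprint(state: SystemState):
    s = state.system
    return fingerprint_from_arrays(
        [tuple(p) for p in state.pos], state.partner, s.chain_of, s.btype,
        s.lattice.L)


def enumerate_exact_boltzmann(system: LatticeSystem, *, beta: float | None = None,
                              max_states: int = 10_000_000) -> ExactDistribution:
    """Exhaustive enumeration of a tiny system's Boltzmann distribution.

    Places molecule 0's bead 0 at the origin (every configuration class has
    exactly L^3 translated copies with identical weight, so the reduced
    measure equals the full one), walks all placements satisfying excluded
    volume and tether constraints, and for each placement all admissible
    bond matchings; probabilities are proportional to exp(-beta * E_rot).
    """
    L = system.lattice.L
    if beta is None:
        beta = system.energy.beta
    eps = system.eps_matrix
    bt = system.btype
    sticker = system.is_sticker
    chain_of = system.chain_of
    n = system.n_beads
    n_stickers = int(sum(sticker[bt[u]] for u in range(n)))

    # bead placement order: chain by chain, BFS inside each chain
    order, parent_of, link_of = [], {}, {}
    for c in range(system.n_chains):
        s = system.chain_start[c]
        arch = system.architectures[system.chain_mt[c]]
        order.append(s)
        for child, parent, l in arch.build_order():
            order.append(s + child)
            parent_of[s + child] = s + parent
            link_of[s + child] = l

    placements: list[tuple] = []
    pos: dict[int, tuple] = {}
    occupied: set = set()

    def place(k: int) -> None:
        if len(placements) > max_states:
            raise StateSpaceOverflow(
                f"more than {max_states} placements; refuse to enumerate")
        if k == len(order):
            placements.append(tuple(pos[u] for u in range(n)))
            return
        u = order[k]
        if u in parent_of:
            pp = pos[parent_of[u]]
            sites = (tuple((pp[i] + d[i]) % L for i in range(3))
                     for d in linker_offsets(link_of[u]))
        elif u == 0:
            sites = [(0, 0, 0)]
        else:
            sites = ((x, y, z) for x in range(L) for y in range(L)
                     for z in range(L))
        for p in sites:
            if p in occupied:
                continue
            pos[u] = p
            occupied.add(p)
            place(k + 1)
            occupied.discard(p)
        pos.pop(u, None)

    place(0)

    fingerprints: dict = {}
    phi_dist: dict = {}
    Z = 0.0
    mean_E = 0.0
    mean_B = 0.0
    n_states = 0

    pairs_scratch: list[tuple[int, int, float]] = []

    def matchings(avail: list[tuple[int, int, float]], used: set,
                  bonds: list[tuple[int, int]]):
        """Yield every matching (including the empty one) exactly once."""
        yield list(bonds)
        for idx, (u, v, e) in enumerate(avail):
            if u in used or v in used:
                continue
            used.add(u)
            used.add(v)
            bonds.append((u, v))
            yield from matchings(avail[idx + 1:], used, bonds)
            bonds.pop()
            used.discard(u)
            used.discard(v)

    for placement in placements:
        pairs_scratch.clear()
        for u, v in combinations(range(n), 2):
            if not (sticker[bt[u]] and sticker[bt[v]]):
                continue
            e = eps[bt[u], bt[v]]
            if e == 0.0:
                continue
            if _pair_d2(placement[u], placement[v], L) <= 3:
                pairs_scratch.append((u, v, e))
        for bonds in matchings(pairs_scratch, set(), []):
            n_states += 1
            if n_states > max_states:
                raise StateSpaceOverflow(
                    f"more than {max_states} states; refuse to enumerate")
            E = sum(eps[bt[u], bt[v]] for u, v in bonds)
            w = math.exp(-beta * E)
            Z += w
            mean_E += w * E
            mean_B += w * len(bonds)
            partner = [-1] * n
            for u, v in bonds:
                partner[u] = v
                partner[v] = u
            fp = fingerprint_from_arrays(placement, partner, chain_of, bt, L)
            fingerprints[fp] = fingerprints.get(fp, 0.0) + w
            # molecular clustering via intermolecular bonds
            parent = list(range(system.n_chains))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for u, v in bonds:
                cu, cv = chain_of[u], chain_of[v]
                if cu != cv:
                    parent[find(cu)] = find(cv)
            sizes: dict = {}
            for c in range(system.n_chains):
                r = find(c)
                sizes[r] = sizes.get(r, 0) + 1
            phi = max(sizes.values()) / system.n_chains
            phi_dist[phi] = phi_dist.get(phi, 0.0) + w

    for fp in fingerprints:
        fingerprints[fp] /= Z
    for phi in phi_dist:
        phi_dist[phi] /= Z
    return ExactDistribution(
        n_placements=len(placements),
        n_states=n_states,
        n_configurations=n_states * L**3,
        fingerprints=fingerprints,
        mean_energy=mean_E / Z,
        mean_bonds=mean_B / Z,
        bond_fraction=(2.0 * mean_B / Z / n_stickers) if n_stickers else 0.0,
        phi_c_distribution=phi_dist,
        partition_function=Z,
    )


def fingerprints_from_trajectory(traj) -> dict:
    """Empirical fingerprint distribution of a trajectory (vectorized).

    Produces the same projection as :func:`fingerprint_from_arrays` for
    every snapshot and returns {fingerprint: relative frequency}.
    """
    s = traj.system
    L = s.lattice.L
    n = s.n_beads
    pos = traj.pos  # (S, n, 3)
    pairs = list(combinations(range(n), 2))
    P = len(pairs)
    iu = np.array([p[0] for p in pairs])
    ju = np.array([p[1] for p in pairs])
    d = np.abs(pos[:, iu, :] - pos[:, ju, :]) % L
    d = np.minimum(d, L - d)
    d2 = np.sort(np.sum(d * d, axis=2), axis=1)  # (S, P)
    # bond-kind codes per pair: -1 when unbonded
    part = traj.partner  # (S, n)
    codes = np.full((pos.shape[0], P), -1, dtype=np.int64)
    for k, (u, v) in enumerate(pairs):
        bonded = part[:, u] == v
        tmin, tmax = sorted((int(s.btype[u]), int(s.btype[v])))
        same = 1 if s.chain_of[u] == s.chain_of[v] else 0
        codes[bonded, k] = same * 1_000_000 + tmin * 1000 + tmax
    codes = np.sort(codes, axis=1)
    rows = np.concatenate([d2, codes], axis=1)
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    out: dict = {}
    S = pos.shape[0]
    for row, cnt in zip(uniq, counts):
        d2s = tuple(int(x) for x in row[:P])
        kinds = tuple(sorted(
            (bool(c // 1_000_000), (int(c // 1000) % 1000, int(c % 1000)))
            for c in row[P:] if c >= 0))
        out[(d2s, kinds)] = out.get((d2s, kinds), 0.0) + cnt / S
    return out


def tv_distance(p: dict, q: dict) -> float:
    """Total-variation distance between two distributions over fingerprints."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def mc_volume_oracle(n_samples: int, seed, bin_width: float = 0.01):
    """Monte Carlo estimate of the torus shell measure V(x).

    Histograms the minimum-image distance of uniform point pairs in the unit
    periodic cube.  Returns (bin centers, density estimates, standard
    errors); the density integrates to 1 over (0, sqrt(3)/2].
    """
    if n_samples < 10**6:
        raise ValueError("need at least 1e6 samples for a useful oracle")
    rng = np.random.default_rng(seed)
    xmax = math.sqrt(3.0) / 2.0
    nbins = int(math.ceil(xmax / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    counts = np.zeros(nbins, dtype=np.int64)
    chunk = 2_000_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        u = rng.random((m, 3)) - 0.5  # minimum-image displacement directly
        d = np.sqrt(np.sum(u * u, axis=1))
        idx = np.minimum((d / bin_width).astype(np.int64), nbins - 1)
        counts += np.bincount(idx, minlength=nbins)
        done += m
    p = counts / n_samples
    dens = p / bin_width
    se = np.sqrt(np.maximum(p * (1 - p), 0.0) / n_samples) / bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens, se
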