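"""Order parameters from snapshot ensembles.

The density-inhomogeneity pipeline is: histogram all inter-bead
minimum-image distances into unit bins over (0, sqrt(3) L / 2]  ->  P2(r);
do the same for the matched non-interacting system  ->  P0(r); form
g(r) = P2 / P0; and integrate the V-weighted absolute deviation of g from 1,

    rho_bar = (1/L) * integral |g(r) - 1| V(r/L) dr,

where V(x) is the exact surface measure of the minimum-image sphere of
normalized radius x in the unit periodic cube.  A state point is classified
phase separated when rho_bar >= 0.025 (a cutoff universal to all systems).
Networking is quantified by phi_c, the fraction of molecules in the single
largest bond-connected cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import LatticeConfig, linker_offsets
from .system import LatticeSystem, SystemState
from .mc import RunConfig, Trajectory, run_mc

__all__ = [
    "DistanceHistogram", "RdfResult", "ClusterReport",
    "pair_distance_histogram", "prior_distribution", "sample_ideal_positions",
    "radial_distribution", "cube_shell_volume", "density_inhomogeneity",
    "crossing_radius", "phase_densities", "find_clusters", "phi_c_series",
    "rescale_distance", "compute_rdf", "PHASE_SEP_CUTOFF",
]

#: rho_bar value separating homogeneous from phase-separated state points
PHASE_SEP_CUTOFF = 0.025

SQRT3 = math.sqrt(3.0)


# ----------------------------------------------------------------------
# histograms
# ----------------------------------------------------------------------

@dataclass
class DistanceHistogram:
    """Unit-width histogram of minimum-image distances on (0, sqrt(3) L/2]."""

    edges: np.ndarray          # nbins + 1 integer edges, bin i covers (i, i+1]
    counts: np.ndarray         # int64 counts summed over snapshots
    n_snapshots: int
    n_pairs: int               # pairs per snapshot

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:]).astype(np.float64)

    def density(self) -> np.ndarray:
        """Probability density per unit r (bin width is 1)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / total


@njit(cache=True)
def _pair_hist_kernel(pos, L, counts):
    S, n, _ = pos.shape
    for s in range(S):
        for i in range(n):
            xi = pos[s, i, 0]
            yi = pos[s, i, 1]
            zi = pos[s, i, 2]
            for j in range(i + 1, n):
                dx = xi - pos[s, j, 0]
                if dx < 0:
                    dx = -dx
                if dx > L - dx:
                    dx = L - dx
                dy = yi - pos[s, j, 1]
                if dy < 0:
                    dy = -dy
                if dy > L - dy:
                    dy = L - dy
                dz = zi - pos[s, j, 2]
                if dz < 0:
                    dz = -dz
                if dz > L - dz:
                    dz = L - dz
                d2 = dx * dx + dy * dy + dz * dz
                if d2 == 0:
                    continue  # coincident beads (ideal/phantom mode only)
                # exact integer binning: bin k-1 where (k-1)^2 < d2 <= k^2
                k = int(np.sqrt(np.float64(d2)))
                while k * k < d2:
                    k += 1
                while k >= 1 and (k - 1) * (k - 1) >= d2:
                    k -= 1
                counts[k - 1] += 1


def n_distance_bins(L: int) -> int:
    return int(math.ceil(SQRT3 * L / 2.0))


def pair_distance_histogram(snapshots, lattice: LatticeConfig | int | None = None
                            ) -> DistanceHistogram:
    """Histogram of all unordered bead-pair distances, averaged over snapshots.

    ``snapshots`` is a :class:`Trajectory` or an integer array (S, n, 3);
    includes intra- and inter-molecular pairs of all species.
    """
    if isinstance(snapshots, Trajectory):
        pos = snapshots.pos
        L = snapshots.system.lattice.L
    else:
        pos = np.asarray(snapshots, dtype=np.int64)
        if lattice is None:
            raise ValueError("lattice required for raw position arrays")
        L = lattice.L if isinstance(lattice, LatticeConfig) else int(lattice)
    if pos.ndim != 3 or pos.shape[0] == 0 or pos.shape[1] < 2:
        raise ValueError("need at least one snapshot of at least two beads")
    nb = n_distance_bins(L)
    counts = np.zeros(nb, dtype=np.int64)
    _pair_hist_kernel(pos, L, counts)
    S, n, _ = pos.shape
    return DistanceHistogram(np.arange(nb + 1), counts, S, n * (n - 1) // 2)


def sample_ideal_positions(system: LatticeSystem, n_snapshots: int, seed
                           ) -> np.ndarray:
    """Direct samples of the ideal (phantom, fully non-interacting) system.

    Molecules are independent: bead 0 is uniform on the lattice and each
    tether vector is uniform on the nonzero offsets with |v|^2 <= 3 l^2.
    Excluded volume is ignored, which is exactly the ideal-chain reference
    used for finite-size calibration.
    """
    rng = np.random.default_rng(seed)
    L = system.lattice.L
    n = system.n_beads
    pos = np.zeros((n_snapshots, n, 3), dtype=np.int64)
    for c in range(system.n_chains):
        s = system.chain_start[c]
        mt = system.chain_mt[c]
        arch = system.architectures[mt]
        pos[:, s, :] = rng.integers(0, L, size=(n_snapshots, 3))
        for child, parent, l in arch.build_order():
            offs = np.asarray(linker_offsets(l), dtype=np.int64)
            pick = rng.integers(0, len(offs), size=n_snapshots)
            pos[:, s + child, :] = (pos[:, s + parent, :] + offs[pick]) % L
    return pos


def prior_distribution(system: LatticeSystem, run: RunConfig | int,
                       mode: str = "excluded", seed: int = 0
                       ) -> DistanceHistogram:
    """P0(r): pair distribution of the matched non-interacting system.

    ``mode="excluded"`` (default) keeps excluded volume and runs the MC with
    all eps set to zero; ``mode="ideal"`` also drops overlap rejection and
    samples chain configurations directly.  The binodal pipeline uses the
    default.
    """
    if mode == "ideal":
        n_snap = run if isinstance(run, int) else max(run.n_snapshots, 1)
        pos = sample_ideal_positions(system, n_snap, seed)
        return pair_distance_histogram(pos, system.lattice)
    if mode != "excluded":
        raise ValueError(f"unknown prior mode {mode!r}")
    from .system import randomize_initial_state
    prior_sys = system.zeroed()
    st = randomize_initial_state(prior_sys, seed)
    res = run_mc(st, run)
    return pair_distance_histogram(res.trajectory)


# ----------------------------------------------------------------------
# radial distribution and rho_bar
# ----------------------------------------------------------------------

def radial_distribution(p2: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """g(r) = P2 / P0 elementwise; bins with P0 = 0 are masked as NaN."""
    p2 = np.asarray(p2, dtype=np.float64)
    p0 = np.asarray(p0, dtype=np.float64)
    if p2.shape != p0.shape:
        raise ValueError("P2 and P0 must share one binning")
    out = np.full_like(p2, np.nan)
    ok = p0 > 0
    out[ok] = p2[ok] / p0[ok]
    return out


def cube_shell_volume(x: float) -> float:
    """Surface measure V(x) of the minimum-image sphere in the unit 3-torus.

    V(x) dx is the probability that the minimum-image distance between two
    uniform points in the periodic unit cube lies in [x, x + dx]; it
    integrates to 1 over (0, sqrt(3)/2].  Branches:

      (0, 1/2]            4 pi x^2                       (full sphere)
      (1/2, sqrt(2)/2]    2 pi x (3 - 4 x)               (6 caps removed)
      (sqrt(2)/2, sqrt(3)/2]  caps overlap pairwise near the 12 edges; the
          overlap area is the closed form below, derived from the sphere-
          cube intersection with c = 1/(2x) the normalized half-width.
    """
    if not (0.0 < x <= SQRT3 / 2.0 + 1e-12):
        raise ValueError(f"x = {x} outside (0, sqrt(3)/2]")
    x = min(x, SQRT3 / 2.0)
    if x <= 0.5:
        return 4.0 * math.pi * x * x
    if x <= math.sqrt(2.0) / 2.0:
        return 2.0 * math.pi * x * (3.0 - 4.0 * x)
    c = 1.0 / (2.0 * x)
    a = math.sqrt(1.0 - c * c)
    # J = int_c^a z^2 / ((1 - z^2) sqrt(a^2 - z^2)) dz, in closed form
    one_minus_2c2 = max(1.0 - 2.0 * c * c, 0.0)
    J = (-math.pi / 2.0 + math.pi / (2.0 * c)
         + math.asin(c / a)
         - (1.0 / c) * math.atan2(c * c, math.sqrt(one_minus_2c2)))
    # I = int_c^a arccos(c / sqrt(1 - z^2)) dz  (half of one cap-cap overlap)
    I = -c * math.acos(c / a) + c * J
    omega = 4.0 * math.pi - 12.0 * math.pi * (1.0 - c) + 24.0 * I
    return x * x * max(omega, 0.0)


def _bin_weights(n_bins: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    """V-measure weight and clipped midpoint for each unit bin."""
    rmax = SQRT3 * L / 2.0
    w = np.zeros(n_bins)
    mid = np.zeros(n_bins)
    for i in range(n_bins):
        lo, hi = float(i), min(float(i + 1), rmax)
        if hi <= lo:
            continue
        m = 0.5 * (lo + hi)
        mid[i] = m
        w[i] = cube_shell_volume(m / L) * (hi - lo) / L if m > 0 else 0.0
    return w, mid


def density_inhomogeneity(gtilde: np.ndarray, lattice: LatticeConfig | int) -> float:
    """rho_bar: the V-weighted mean absolute deviation of g(r) from 1.

    Midpoint-rule quadrature on the unit bins; masked (NaN) bins contribute
    nothing.  rho_bar = 0 iff g == 1 on its support.
    """
    L = lattice.L if isinstance(lattice, LatticeConfig) else int(lattice)
    g = np.asarray(gtilde, dtype=np.float64)
    w, _ = _bin_weights(len(g), L)
    dev = np.abs(g - 1.0)
    ok = ~np.isnan(dev)
    return float(np.sum(dev[ok] * w[ok]))


def crossing_radius(gtilde: np.ndarray, r: np.ndarray | None = None) -> float | None:
    """First downward crossing of g through 1 after its initial peak.

    Located by linear interpolation between adjacent (valid) bins; None when
    g never exceeds 1.
    """
    g = np.asarray(gtilde, dtype=np.float64)
    if r is None:
        r = np.arange(len(g)) + 0.5
    ok = ~np.isnan(g)
    g = g[ok]
    r = np.asarray(r, dtype=np.float64)[ok]
    above = np.flatnonzero(g > 1.0)
    if len(above) == 0:
        return None
    for j in range(above[0], len(g) - 1):
        if g[j] >= 1.0 > g[j + 1]:
            frac = (g[j] - 1.0) / (g[j] - g[j + 1])
            return float(r[j] + frac * (r[j + 1] - r[j]))
    return None


def phase_densities(gtilde: np.ndarray, r_b: float | None, c_bulk: float,
                    lattice: LatticeConfig | int) -> tuple[float, float]:
    """(c_dilute, c_dense) estimated from g(r).

    c_dense scales c_bulk by the V-weighted mean of g over r < r_b; c_dilute
    by the V-weighted mean over the large-r plateau (last quartile of the
    domain).  With no crossing radius both equal c_bulk.
    """
    if r_b is None:
        return c_bulk, c_bulk
    L = lattice.L if isinstance(lattice, LatticeConfig) else int(lattice)
    g = np.asarray(gtilde, dtype=np.float64)
    w, mid = _bin_weights(len(g), L)
    ok = ~np.isnan(g) & (w > 0)
    rmax = SQRT3 * L / 2.0

    def vmean(sel) -> float:
        sel = sel & ok
        tot = w[sel].sum()
        return float(np.sum(g[sel] * w[sel]) / tot) if tot > 0 else 1.0

    c_dense = c_bulk * vmean(mid < r_b)
    c_dilute = c_bulk * vmean(mid >= 0.75 * rmax)
    return c_dilute, c_dense


def rescale_distance(r, lattice: LatticeConfig | int):
    """r* = 2 r / (sqrt(3) L), mapping (0, sqrt(3) L / 2] onto (0, 1]."""
    L = lattice.L if isinstance(lattice, LatticeConfig) else int(lattice)
    return np.asarray(r, dtype=np.float64) * 2.0 / (SQRT3 * L)


# ----------------------------------------------------------------------
# clusters
# ----------------------------------------------------------------------

@dataclass
class ClusterReport:
    sizes: np.ndarray       # cluster sizes in molecules, descending
    phi_c: float            # largest-cluster fraction
    n_clusters: int


def _clusters_from_arrays(partner, chain_of, n_chains) -> ClusterReport:
    u = np.flatnonzero(partner >= 0)
    ci = chain_of[u]
    cj = chain_of[partner[u]]
    inter = ci != cj  # intramolecular bonds do not create edges
    m = coo_matrix((np.ones(inter.sum()), (ci[inter], cj[inter])),
                   shape=(n_chains, n_chains))
    n_comp, labels = connected_components(m, directed=False)
    sizes = np.sort(np.bincount(labels, minlength=n_comp))[::-1]
    return ClusterReport(sizes, float(sizes[0]) / n_chains, int(n_comp))


def find_clusters(state: SystemState) -> ClusterReport:
    """Connected components of molecules linked by inter-molecular bonds."""
    s = state.system
    if s.n_chains == 0:
        raise ValueError("empty system has no clusters")
    return _clusters_from_arrays(state.partner, s.chain_of, s.n_chains)


def phi_c_series(traj: Trajectory) -> np.ndarray:
    """phi_c for every snapshot of a trajectory."""
    s = traj.system
    return np.array([
        _clusters_from_arrays(traj.partner[i], s.chain_of, s.n_chains).phi_c
        for i in range(traj.n_snapshots)])


# ----------------------------------------------------------------------
# assembled result
# ----------------------------------------------------------------------

@dataclass
class RdfResult:
    """g(r) analysis of one state point."""

    r: np.ndarray
    P2: np.ndarray
    P0: np.ndarray
    gtilde: np.ndarray
    r_b: float | None
    rho_bar: float

    @property
    def phase_separated(self) -> bool:
        return self.rho_bar >= PHASE_SEP_CUTOFF


def compute_rdf(p2: DistanceHistogram, p0: DistanceHistogram,
                lattice: LatticeConfig | int) -> RdfResult:
    """Assemble g(r), r_b and rho_bar from target and prior histograms."""
    if len(p2.counts) != len(p0.counts):
        raise ValueError("histograms have different binnings")
    d2, d0 = p2.density(), p0.density()
    g = radial_distribution(d2, d0)
    rb = crossing_radius(g)
    rho = density_inhomogeneity(g, lattice)
    return RdfResult(p2.midpoints, d2, d0, g, rb, rho)
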