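import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import sslattice as ss
from sslattice.observables import (PHASE_SEP_CUTOFF, ClusterReport,
                                   _clusters_from_arrays, compute_rdf,
                                   crossing_radius, cube_shell_volume,
                                   density_inhomogeneity, find_clusters,
                                   n_distance_bins, pair_distance_histogram,
                                   phase_densities, radial_distribution,
                                   rescale_distance, sample_ideal_positions)

from conftest import make_state_with_bonds

SQRT3 = math.sqrt(3.0)


# ----------------------------------------------------------------------
# pair distance histogram
# ----------------------------------------------------------------------

def test_histogram_single_pair_and_antipode():
    pos = np.array([[[0, 0, 0], [1, 0, 0]]], dtype=np.int64)
    h = pair_distance_histogram(pos, 10)
    assert h.counts[0] == 1 and h.counts.sum() == 1  # bin (0, 1]
    pos = np.array([[[0, 0, 0], [5, 5, 5]]], dtype=np.int64)
    h = pair_distance_histogram(pos, 10)
    assert h.counts[-1] == 1  # sqrt(75) lands in the last bin
    assert len(h.counts) == n_distance_bins(10) == 9


def test_histogram_counts_all_pairs():
    rng = np.random.default_rng(0)
    L, n, S = 12, 20, 7
    sites = np.array([(x, y, z) for x in range(L) for y in range(L)
                      for z in range(L)], dtype=np.int64)
    pos = np.stack([sites[rng.choice(len(sites), n, replace=False)]
                    for _ in range(S)])
    h = pair_distance_histogram(pos, L)
    assert h.counts.sum() == S * (n * (n - 1)) // 2


def test_histogram_uniform_gas_matches_shell_counts():
    """iid uniform beads: bin probabilities equal the exact lattice shell
    counts (the discrete analogue of the V(r/L) law)."""
    rng = np.random.default_rng(1)
    L = 16
    pos = rng.integers(0, L, size=(3000, 40, 3))
    h = pair_distance_histogram(pos, L)
    dens = h.density()
    # exact minimum-image displacement census of the lattice
    d = np.indices((L, L, L)).reshape(3, -1).T
    dm = np.minimum(d, L - d)
    d2 = (dm**2).sum(axis=1)
    d2 = d2[d2 > 0]
    r = np.ceil(np.sqrt(d2)).astype(int)
    expected = np.bincount(r - 1, minlength=len(dens)) / len(d2)
    for i in range(len(dens)):
        assert dens[i] == pytest.approx(expected[i], rel=0.03, abs=2e-4)


def test_histogram_errors():
    with pytest.raises(ValueError):
        pair_distance_histogram(np.zeros((0, 5, 3), dtype=np.int64), 8)
    with pytest.raises(ValueError):
        pair_distance_histogram(np.zeros((1, 1, 3), dtype=np.int64), 8)


# ----------------------------------------------------------------------
# V(x): the periodic-cube shell measure
# ----------------------------------------------------------------------

def test_shell_volume_branch_values_and_continuity():
    assert cube_shell_volume(0.25) == pytest.approx(4 * math.pi * 0.0625)
    # both printed branch forms give pi at x = 1/2
    assert cube_shell_volume(0.5) == pytest.approx(math.pi, abs=1e-12)
    assert 2 * math.pi * 0.5 * (3 - 4 * 0.5) == pytest.approx(math.pi)
    x2 = math.sqrt(2) / 2
    assert cube_shell_volume(x2 - 1e-9) == pytest.approx(
        cube_shell_volume(x2 + 1e-9), abs=1e-6)
    assert abs(cube_shell_volume(x2 - 1e-12) - cube_shell_volume(x2)) < 1e-9
    assert cube_shell_volume(SQRT3 / 2) == pytest.approx(0.0, abs=1e-9)


def test_shell_volume_integrates_to_one():
    val, _ = quad(cube_shell_volume, 1e-12, SQRT3 / 2, limit=300)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_shell_volume_domain():
    with pytest.raises(ValueError):
        cube_shell_volume(0.0)
    with pytest.raises(ValueError):
        cube_shell_volume(0.9)


# ----------------------------------------------------------------------
# g(r), rho_bar, r_b, phase densities
# ----------------------------------------------------------------------

def test_radial_distribution_masking():
    g = radial_distribution([0.0, 0.2, 0.4], [0.0, 0.2, 0.2])
    assert np.isnan(g[0])          # 0/0 is undefined, not 1
    assert g[1] == pytest.approx(1.0)
    assert g[2] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        radial_distribution([1.0], [1.0, 2.0])


def test_rho_bar_zero_iff_flat():
    L = 100
    g = np.ones(n_distance_bins(L))
    assert density_inhomogeneity(g, L) == 0.0


def test_rho_bar_step_profile_closed_form():
    """g = 2 on r/L <= 1/2, 1 beyond: rho_bar = int_0^{1/2} 4 pi x^2 dx = pi/6."""
    L = 2000
    nb = n_distance_bins(L)
    mids = np.arange(nb) + 0.5
    g = np.where(mids / L <= 0.5, 2.0, 1.0)
    rho = density_inhomogeneity(g, L)
    assert rho == pytest.approx(math.pi / 6, rel=1e-5)
    assert rho >= PHASE_SEP_CUTOFF  # classified phase separated


def test_crossing_radius_interpolation():
    g = np.ones(20)
    assert crossing_radius(g) is None
    g = np.concatenate([np.full(5, 1.5), np.full(15, 0.8)])
    # crossing between mids 4.5 and 5.5 at fraction 0.5/0.7
    assert crossing_radius(g) == pytest.approx(4.5 + 0.5 / 0.7)
    g = np.concatenate([np.full(5, 0.4), np.full(15, 0.9)])
    assert crossing_radius(g) is None  # never exceeds 1


def test_phase_densities_step():
    L = 200
    nb = n_distance_bins(L)
    mids = np.arange(nb) + 0.5
    r_b = 30.0
    g = np.where(mids < r_b, 2.0, 0.5)
    dil, den = phase_densities(g, r_b, 1e-3, L)
    assert den == pytest.approx(2e-3)
    assert dil == pytest.approx(0.5e-3)
    # no crossing radius: both collapse onto the bulk value
    assert phase_densities(np.ones(nb), None, 1e-3, L) == (1e-3, 1e-3)


def test_compute_rdf_identical_histograms(toy_fixture):
    system = toy_fixture.system(8, {"dimer": 6})
    pos = sample_ideal_positions(system, 50, 3)
    h = pair_distance_histogram(pos, system.lattice)
    rdf = compute_rdf(h, h, system.lattice)
    valid = ~np.isnan(rdf.gtilde)
    assert np.allclose(rdf.gtilde[valid], 1.0)
    assert rdf.rho_bar == 0.0 and not rdf.phase_separated


# ----------------------------------------------------------------------
# clusters
# ----------------------------------------------------------------------

def test_clusters_examples(toy_system):
    # no bonds: n singletons, phi_c = 1/n
    st = make_state_with_bonds(toy_system, [(0, 0, 0), (1, 1, 1), (3, 3, 3),
                                            (3, 3, 2)], [])
    rep = find_clusters(st)
    assert rep.n_clusters == 2 and rep.phi_c == 0.5
    # one intermolecular bond joins both molecules: phi_c = 1
    st2 = make_state_with_bonds(toy_system, [(0, 0, 0), (0, 0, 1), (1, 1, 1),
                                             (1, 1, 0)], [(0, 3)])
    assert find_clusters(st2).phi_c == 1.0
    # intramolecular bonds create no edges
    st3 = make_state_with_bonds(toy_system, [(0, 0, 0), (1, 1, 1), (3, 3, 3),
                                             (3, 3, 2)], [(0, 1), (2, 3)])
    rep3 = find_clusters(st3)
    assert rep3.phi_c == 0.5 and rep3.n_clusters == 2


def test_clusters_four_molecules_single_bond():
    partner = np.array([1, 0, -1, -1, -1, -1, -1, -1])
    chain_of = np.array([0, 1, 2, 2, 3, 3, 0, 1])
    rep = _clusters_from_arrays(partner, chain_of, 4)
    assert rep.phi_c == 0.5 and rep.n_clusters == 3


@given(st.integers(0, 2**31 - 1))
def test_phi_c_monotone_under_added_bonds(seed):
    """Adding intermolecular bonds can only grow the largest cluster."""
    rng = np.random.default_rng(seed)
    n_chains = 12
    chain_of = np.repeat(np.arange(n_chains), 2)
    pairs = rng.permutation(len(chain_of))
    partner = np.full(len(chain_of), -1)
    prev = 0.0
    for k in range(0, len(pairs) - 1, 2):
        u, v = pairs[k], pairs[k + 1]
        if partner[u] == -1 and partner[v] == -1 and u != v:
            partner[u], partner[v] = v, u
        phi = _clusters_from_arrays(partner, chain_of, n_chains).phi_c
        assert phi >= prev - 1e-12
        prev = phi


def test_rescale_distance():
    L = 50
    assert rescale_distance(SQRT3 * L / 2, L) == pytest.approx(1.0)
    assert rescale_distance(0.0, L) == 0.0
    assert rescale_distance(L / 2, L) == pytest.approx(1 / SQRT3)
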