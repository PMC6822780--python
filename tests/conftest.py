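import math

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import sslattice as ss
from sslattice.fixtures import build_fus_like, build_n130_rpl5, build_toy_dimer_pair
from sslattice.mc import RunConfig, run_mc
from sslattice.observables import (compute_rdf, pair_distance_histogram,
                                   phi_c_series, prior_distribution)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_fixture():
    return build_toy_dimer_pair()


@pytest.fixture(scope="session")
def toy_system(toy_fixture):
    """Two A-B dimers on a 4^3 lattice, eps_AB = -3, T = 1."""
    return toy_fixture.system(4, {"dimer": 2})


@pytest.fixture()
def toy_state(toy_system):
    return ss.randomize_initial_state(toy_system, 11)


@pytest.fixture(scope="session")
def fus_split_fixture():
    return build_fus_like("split")


@pytest.fixture(scope="session")
def fus_joined_fixture():
    return build_fus_like("joined")


@pytest.fixture(scope="session")
def n130_fixture():
    return build_n130_rpl5()


def make_state_with_bonds(system, placements, bonds):
    """Hand-build a state: explicit positions plus an explicit bond set."""
    st = ss.SystemState(system)
    L = system.lattice.L
    for b, p in enumerate(placements):
        st.pos[b] = p
        st.occ[(p[0] * L + p[1]) * L + p[2]] = b
    for u, v in bonds:
        st.partner[u] = v
        st.partner[v] = u
        a, b2 = sorted((system.btype[u], system.btype[v]))
        st.bond_count[a, b2] += 1
    st.validate()
    return st


def measure_state_point(fixture, counts, c, tstar, seed, *, steps,
                        prior_steps=1_500_000, want_rho=True):
    """Shared scaled-down state-point evaluation used across the suite.

    Returns (rho_bar or None, mean phi_c).  The lattice edge is chosen so
    the first-listed molecule type sits at bulk concentration c.
    """
    fx = fixture if tstar is None else type(fixture)(
        fixture.name, fixture.bead_types, fixture.architectures,
        fixture.energy.at_reduced_temperature(tstar), fixture.schedule)
    n_ref = counts[fx.architectures[0].name]
    L = max(8, round((n_ref / c) ** (1.0 / 3.0)))
    system = fx.system(int(L), counts)
    st = ss.randomize_initial_state(system, seed)
    run = RunConfig(fx.schedule, steps=steps, equilibration=steps // 2,
                    sample_every=max(steps // 25, 1), seed=seed + 1,
                    debug_check_every=0)
    res = run_mc(st, run)
    phi = float(phi_c_series(res.trajectory).mean())
    if not want_rho:
        return None, phi
    p2 = pair_distance_histogram(res.trajectory)
    pr = RunConfig(fx.schedule, steps=prior_steps,
                   equilibration=prior_steps // 4,
                   sample_every=prior_steps // 25, seed=seed + 2,
                   debug_check_every=0)
    p0 = prior_distribution(system, pr, seed=seed + 3)
    rdf = compute_rdf(p2, p0, system.lattice)
    return rdf.rho_bar, phi
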