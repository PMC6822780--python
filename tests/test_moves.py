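import math

import numpy as np
import pytest

import sslattice as ss
from sslattice import _kernel as K
from sslattice.architecture import BeadType, build_architecture
from sslattice.energy import EnergyModel
from sslattice.mc import (MoveSchedule, RunConfig, candidate_partners,
                          move_cluster_translation, move_double_pivot,
                          move_local, move_reptation, move_rotation,
                          rosenbluth_weight, run_mc, run_replicas)

from conftest import make_state_with_bonds


def _rng(seed):
    return K.seed_rng(seed)


def _singles_system(labels, L=6, eps=-3.0, temperature=1.0):
    """One single-bead molecule per label entry (stickers unless 'N')."""
    types = [BeadType("A", True), BeadType("B", True), BeadType("N", False)]
    archs, counts = [], {}
    mols = []
    for lab in set(labels):
        arch = build_architecture(f"mono_{lab}", [lab], [])
        mols.append((arch, labels.count(lab)))
    em = EnergyModel({("A", "B"): eps}, temperature=temperature,
                     reference_energy=abs(eps))
    return ss.LatticeSystem(ss.LatticeConfig(L), types, mols, em)


# ----------------------------------------------------------------------
# candidate partners and Rosenbluth weights
# ----------------------------------------------------------------------

def test_candidate_partners_rules():
    system = _singles_system(["A", "A", "B", "B", "B", "N"], L=6)
    labels = [system.bead_types[t].label for t in system.btype]
    a1, a2 = [i for i, l in enumerate(labels) if l == "A"]
    bs = [i for i, l in enumerate(labels) if l == "B"]
    n = labels.index("N")
    placements = [None] * 6
    placements[a1] = (0, 0, 0)
    placements[bs[0]] = (1, 0, 0)   # adjacent to a1, unbonded
    placements[bs[1]] = (0, 1, 1)   # adjacent to a1, bonded to a2 below
    placements[bs[2]] = (1, 1, 0)   # adjacent to a1, unbonded
    placements[a2] = (0, 2, 1)      # adjacent to bs[1]
    placements[n] = (0, 0, 1)       # spacer adjacent to a1
    st = make_state_with_bonds(system, placements, [(bs[1], a2)])
    # the B bonded to another sticker is unavailable; the bonded-to-self case
    # (its own current partner) stays available
    assert candidate_partners(st, a1) == sorted([bs[0], bs[2]])
    assert sorted(candidate_partners(st, a2)) == sorted([bs[1], bs[2]])
    # a spacer has no candidates (eps_iN = 0)
    assert candidate_partners(st, n) == []
    # an isolated sticker has none either (all sites pairwise d^2 >= 4)
    st2 = make_state_with_bonds(system, [(0, 0, 0), (0, 0, 2), (0, 2, 0),
                                         (2, 0, 0), (2, 2, 2), (4, 4, 4)], [])
    assert candidate_partners(st2, a1) == []


def test_rosenbluth_weight_examples():
    system = _singles_system(["A", "B", "B", "N"], L=6)
    labels = [system.bead_types[t].label for t in system.btype]
    a = labels.index("A")
    bs = [i for i, l in enumerate(labels) if l == "B"]
    n = labels.index("N")
    placements = [None] * 4
    placements[a] = (0, 0, 0)
    placements[bs[0]] = (1, 0, 0)
    placements[bs[1]] = (1, 1, 1)
    placements[n] = (5, 5, 5)
    st = make_state_with_bonds(system, placements, [])
    # W = 1 + N exp(-beta eps): N = 2, eps = -3, T = 1
    assert rosenbluth_weight(st, a) == pytest.approx(1 + 2 * math.e**3, rel=1e-12)
    # spacers and isolated stickers have W = 1
    assert rosenbluth_weight(st, n) == 1.0
    st2 = make_state_with_bonds(system, [(0, 0, 0), (0, 2, 2), (2, 0, 2),
                                         (2, 2, 0)], [])
    assert rosenbluth_weight(st2, a) == 1.0


# ----------------------------------------------------------------------
# rotation
# ----------------------------------------------------------------------

def test_rotation_rejected_for_spacer():
    system = _singles_system(["N", "N"], L=6)
    st = make_state_with_bonds(system, [(0, 0, 0), (3, 3, 3)], [])
    rng = _rng(5)
    for _ in range(20):
        out = move_rotation(st, rng)
        assert not out.accepted
    st.validate()


def test_rotation_heat_bath_two_state_probability():
    """Single A-B contact: P(bonded) = e^3 / (1 + e^3) ~ 0.9526."""
    system = _singles_system(["A", "B"], L=6)
    st = make_state_with_bonds(system, [(0, 0, 0), (1, 0, 0)], [])
    rng = _rng(123)
    bonded = 0
    n_trials = 40_000
    for _ in range(n_trials):
        move_rotation(st, rng)
        bonded += st.partner[0] >= 0
    p = bonded / n_trials
    expected = math.e**3 / (1 + math.e**3)
    assert p == pytest.approx(expected, abs=0.01)
    st.validate()


def test_rotation_with_no_candidates_accepts_unbound():
    system = _singles_system(["A", "B"], L=8)
    st = make_state_with_bonds(system, [(0, 0, 0), (4, 4, 4)], [])
    rng = _rng(9)
    out = move_rotation(st, rng)
    assert out.accepted and np.all(st.partner == -1)


# ----------------------------------------------------------------------
# local move
# ----------------------------------------------------------------------

def test_local_move_weight_ratio_matches_printed_form():
    """With one interaction type, A = (N_j + 1)/(N_i + 1) in the weak-bias
    limit: W ratios evaluated at the two sites reproduce 1/3 for
    N_i = 2, N_j = 0."""
    system = _singles_system(["A", "B", "B"], L=8, temperature=1e7)
    labels = [system.bead_types[t].label for t in system.btype]
    a = labels.index("A")
    bs = [i for i, l in enumerate(labels) if l == "B"]
    placements = [None] * 3
    placements[a] = (0, 0, 0)       # N_i = 2 here
    placements[bs[0]] = (1, 0, 0)
    placements[bs[1]] = (0, 1, 0)
    st = make_state_with_bonds(system, placements, [])
    w_old = rosenbluth_weight(st, a)
    st.pos[a] = (5, 5, 5)           # N_j = 0 there
    st.occ[:] = -1
    L = system.lattice.L
    flat = (st.pos[:, 0] * L + st.pos[:, 1]) * L + st.pos[:, 2]
    st.occ[flat] = np.arange(3)
    w_new = rosenbluth_weight(st, a)
    assert w_new / w_old == pytest.approx(1.0 / 3.0, rel=1e-5)


def test_local_move_free_bead_always_accepted():
    system = _singles_system(["N"], L=8)
    st = make_state_with_bonds(system, [(2, 2, 2)], [])
    rng = _rng(3)
    for _ in range(200):
        out = move_local(st, rng)
        assert out.accepted
    st.validate()


def test_local_move_respects_linkers(toy_system):
    st = make_state_with_bonds(toy_system, [(0, 0, 0), (1, 1, 1), (3, 3, 3),
                                            (3, 3, 2)], [])
    rng = _rng(17)
    for _ in range(2000):
        move_local(st, rng)
    st.validate()


# ----------------------------------------------------------------------
# reptation
# ----------------------------------------------------------------------

def test_reptation_rejects_branched(n130_fixture):
    system = n130_fixture.system(12, {"n130": 2, "rpl5": 0})
    st = ss.randomize_initial_state(system, 4)
    rng = _rng(21)
    for _ in range(50):
        out = move_reptation(st, rng)
        assert not out.accepted
    st.validate()


def test_reptation_rejects_heterogeneous_linkers():
    types = [BeadType("A", True), BeadType("N", False)]
    arch = build_architecture("het", ["A", "N", "A"], [(0, 1, 1), (1, 2, 2)])
    em = EnergyModel({("A", "A"): -1.0}, temperature=1.0)
    system = ss.LatticeSystem(ss.LatticeConfig(8), types, [(arch, 2)], em)
    st = ss.randomize_initial_state(system, 4)
    rng = _rng(22)
    assert not any(move_reptation(st, rng).accepted for _ in range(50))


def test_reptation_free_chain_mostly_accepted(n130_fixture):
    system = n130_fixture.system(16, {"n130": 0, "rpl5": 1})
    st = ss.randomize_initial_state(system, 4)
    rng = _rng(23)
    acc = sum(move_reptation(st, rng).accepted for _ in range(2000))
    assert acc / 2000 > 0.95  # only the rare exhausted trial cap rejects
    st.validate()


# ----------------------------------------------------------------------
# double pivot and cluster translation conserve the energy exactly
# ----------------------------------------------------------------------

def test_double_pivot_conserves_energy_and_composition(fus_joined_fixture):
    system = fus_joined_fixture.system(16, {"fus": 8})
    st = ss.randomize_initial_state(system, 6)
    # bond things up first
    run = RunConfig(MoveSchedule(0, 0, 1, 1, 0, 0), steps=20_000, seed=3,
                    debug_check_every=0)
    st = run_mc(st, run).final_state
    rng = _rng(31)
    before_counts = st.bond_count.copy()
    accepted = 0
    for _ in range(3000):
        out = move_double_pivot(st, rng)
        assert out.delta_e == 0.0
        accepted += out.accepted
    assert accepted > 0
    assert np.array_equal(st.bond_count, before_counts)
    st.validate()


def test_double_pivot_strict_mode_rejects_branched(fus_joined_fixture):
    system = fus_joined_fixture.system(16, {"fus": 8})
    st = ss.randomize_initial_state(system, 6)
    rng = _rng(33)
    for _ in range(100):
        assert not move_double_pivot(st, rng, strict_dp=True).accepted


def test_cluster_translation_conserves_energy(toy_system):
    st = ss.randomize_initial_state(toy_system, 8)
    run = RunConfig(MoveSchedule(0, 0, 1, 1, 0, 0), steps=5_000, seed=3,
                    debug_check_every=0)
    st = run_mc(st, run).final_state
    rng = _rng(41)
    accepted = 0
    for _ in range(500):
        out = move_cluster_translation(st, rng)
        assert out.delta_e == 0.0
        accepted += out.accepted
    assert accepted > 0
    st.validate()


# ----------------------------------------------------------------------
# generic move/state contracts
# ----------------------------------------------------------------------

def test_rejected_moves_leave_state_bit_identical(fus_joined_fixture):
    system = fus_joined_fixture.system(12, {"fus": 6})
    st = ss.randomize_initial_state(system, 9)
    rng = _rng(55)
    movers = [move_rotation, move_local, move_reptation, move_double_pivot,
              move_cluster_translation]
    rejections = 0
    for k in range(3000):
        before = st.fingerprint()
        out = movers[k % len(movers)](st, rng)
        if not out.accepted:
            rejections += 1
            assert st.fingerprint() == before
    assert rejections > 100
    st.validate()


def test_energy_bookkeeping_exact_over_1e5_moves(toy_fixture):
    system = toy_fixture.system(6, {"dimer": 8})
    st = ss.randomize_initial_state(system, 13)
    run = RunConfig(toy_fixture.schedule, steps=100_000, seed=5,
                    debug_check_every=0)
    final = run_mc(st, run).final_state
    assert final.energy == final.recompute_energy()
    final.validate()


def test_run_mc_zero_steps_returns_initial(toy_state, toy_fixture):
    run = RunConfig(toy_fixture.schedule, steps=0, seed=1)
    res = run_mc(toy_state, run)
    assert res.trajectory.n_snapshots == 1
    assert np.array_equal(res.trajectory.pos[0], toy_state.pos)
    assert res.stats.attempts.sum() == 0


def test_run_mc_deterministic_and_input_untouched(toy_state, toy_fixture):
    run = RunConfig(toy_fixture.schedule, steps=50_000, equilibration=1_000,
                    sample_every=1_000, seed=77, debug_check_every=10_000)
    before = toy_state.fingerprint()
    r1 = run_mc(toy_state, run)
    r2 = run_mc(toy_state, run)
    assert toy_state.fingerprint() == before
    assert np.array_equal(r1.trajectory.pos, r2.trajectory.pos)
    assert np.array_equal(r1.trajectory.partner, r2.trajectory.partner)
    assert np.array_equal(r1.stats.attempts, r2.stats.attempts)
    assert r1.stats.attempts.sum() == run.steps


def test_protocol_fields_round_trip():
    run = RunConfig(MoveSchedule(), steps=5 * 10**8, equilibration=5 * 10**6,
                    sample_every=5 * 10**5, seed=1, replicas=5)
    assert run.replica_seeds() == [1, 2, 3, 4, 5]
    assert run.n_snapshots == (5 * 10**8 - 5 * 10**6) // (5 * 10**5)


def test_move_schedule_validation():
    with pytest.raises(ValueError):
        MoveSchedule(0, 0, 0, 0, 0, 0).as_array()
    probs = MoveSchedule(1, 10, 100, 250, 0, 50).probabilities
    assert probs.sum() == pytest.approx(1.0)
    assert probs[4] == 0.0


def test_acceptance_ratio_concentration_trends(fus_joined_fixture):
    """Translation moves die off with density while double pivots take over
    as the configuration-altering channel in the dense regime.

    (At these scaled sizes the dense system is a single bond-connected
    cluster, so whole-cluster translation stays clash-free; the published
    decline of cluster-move acceptance needs many coexisting clusters and
    is not asserted here — see docs/methods.md.)
    """
    fx = type(fus_joined_fixture)(
        fus_joined_fixture.name, fus_joined_fixture.bead_types,
        fus_joined_fixture.architectures,
        fus_joined_fixture.energy.at_reduced_temperature(0.383),
        fus_joined_fixture.schedule)
    ratios = []
    for i, c in enumerate((1e-4, 1e-3, 8e-3)):
        system = fx.system_at_concentration(c, {"fus": 100})
        st = ss.randomize_initial_state(system, 3 + i)
        run = RunConfig(fx.schedule, steps=1_500_000, equilibration=0,
                       sample_every=0, seed=4 + i, debug_check_every=0)
        stats = run_mc(st, run).stats
        ratios.append({m: stats.ratio(m) for m in
                       ("chain_translation", "local", "double_pivot",
                        "cluster_translation")})
    chain = [r["chain_translation"] for r in ratios]
    assert chain[0] > chain[1] > chain[2]       # monotone decline
    assert chain[2] < 0.02                      # ~0 in the dense regime
    dense = ratios[-1]
    assert dense["double_pivot"] > dense["local"]
    assert dense["double_pivot"] > dense["chain_translation"]
    assert ratios[0]["cluster_translation"] > 0.5  # dilute clusters move


def test_run_replicas_distinct_seeds(toy_fixture, toy_system):
    run = RunConfig(toy_fixture.schedule, steps=20_000, equilibration=1_000,
                    sample_every=1_000, seed=10, replicas=3)
    results = run_replicas(lambda seed: ss.randomize_initial_state(toy_system, seed),
                           run)
    fps = {r.final_state.fingerprint() for r in results}
    assert len(fps) == 3
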