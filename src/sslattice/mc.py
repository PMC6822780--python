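"""Monte Carlo driver: move schedule, run configuration, and the simulator.

One MC step is one attempted move of any type; move types are drawn with
probabilities proportional to the schedule weights (relative attempt
frequencies, as in the engine's frequency tables).  Snapshots are recorded
every ``sample_every`` steps after ``equilibration`` steps; replica ``r``
runs with seed ``seed + r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel as K
from .system import LatticeSystem, SystemState, InvalidStateError

__all__ = [
    "MoveSchedule", "RunConfig", "MoveStats", "MoveOutcome", "Trajectory",
    "MCResult", "run_mc", "run_replicas",
    "move_rotation", "move_local", "move_reptation", "move_double_pivot",
    "move_chain_translation", "move_cluster_translation",
    "candidate_partners", "rosenbluth_weight",
]

MOVE_NAMES = K.MOVE_NAMES


@dataclass(frozen=True)
class MoveSchedule:
    """Relative attempt frequencies for the six move types."""

    cluster_translation: float = 1.0
    chain_translation: float = 10.0
    rotation: float = 100.0
    local: float = 250.0
    reptation: float = 0.0
    double_pivot: float = 50.0

    def as_array(self) -> np.ndarray:
        w = np.array([self.cluster_translation, self.chain_translation,
                      self.rotation, self.local, self.reptation,
                      self.double_pivot], dtype=np.float64)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("need non-negative weights with at least one positive")
        return w

    @property
    def probabilities(self) -> np.ndarray:
        w = self.as_array()
        return w / w.sum()

    def cumulative(self) -> np.ndarray:
        c = np.cumsum(self.probabilities)
        c[-1] = 1.0
        return c

    def without(self, **zeroed) -> "MoveSchedule":
        return replace(self, **{k: 0.0 for k in zeroed if zeroed[k]})


@dataclass(frozen=True)
class RunConfig:
    schedule: MoveSchedule
    steps: int
    equilibration: int = 0
    sample_every: int = 0
    seed: int = 0
    replicas: int = 1
    debug_check_every: int = 10_000
    strict_double_pivot: bool = False

    def __post_init__(self) -> None:
        if self.steps < 0 or self.equilibration < 0:
            raise ValueError("steps and equilibration must be non-negative")
        if self.sample_every < 0:
            raise ValueError("sample_every must be non-negative")
        if self.replicas < 1:
            raise ValueError("need at least one replica")

    @property
    def n_snapshots(self) -> int:
        if self.sample_every == 0 or self.steps <= self.equilibration:
            return 0
        return (self.steps - self.equilibration) // self.sample_every

    def replica_seeds(self) -> list[int]:
        return [self.seed + r for r in range(self.replicas)]


@dataclass
class MoveStats:
    """Per-move-type attempt and acceptance counters."""

    attempts: np.ndarray = field(default_factory=lambda: np.zeros(K.N_MOVES, dtype=np.int64))
    accepts: np.ndarray = field(default_factory=lambda: np.zeros(K.N_MOVES, dtype=np.int64))

    def ratio(self, move: str) -> float:
        i = MOVE_NAMES.index(move)
        return self.accepts[i] / self.attempts[i] if self.attempts[i] else float("nan")

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            ratios = np.where(self.attempts > 0, self.accepts / np.maximum(self.attempts, 1),
                              np.nan)
        return pd.DataFrame({"move": MOVE_NAMES, "attempts": self.attempts,
                             "accepts": self.accepts, "ratio": ratios})


@dataclass(frozen=True)
class MoveOutcome:
    move: str
    accepted: bool
    delta_e: float
    beads: tuple[int, ...] = ()


class Trajectory:
    """Stacked snapshots (positions and bond partners) of one run."""

    def __init__(self, system: LatticeSystem, steps, pos, partner):
        self.system = system
        self.steps = np.asarray(steps, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.partner = np.asarray(partner, dtype=np.int64)

    @property
    def n_snapshots(self) -> int:
        return len(self.steps)

    def state_at(self, i: int) -> SystemState:
        st = SystemState(self.system)
        st.pos[:] = self.pos[i]
        L = self.system.lattice.L
        flat = (st.pos[:, 0] * L + st.pos[:, 1]) * L + st.pos[:, 2]
        st.occ[flat] = np.arange(self.system.n_beads)
        st.partner[:] = self.partner[i]
        bt = self.system.btype
        for u in range(self.system.n_beads):
            v = st.partner[u]
            if v > u:
                a, b = sorted((bt[u], bt[v]))
                st.bond_count[a, b] += 1
        return st


@dataclass
class MCResult:
    trajectory: Trajectory
    stats: MoveStats
    final_state: SystemState


def _kernel_args(state: SystemState, beta: float):
    s = state.system
    return dict(
        pos=state.pos, occ=state.occ, partner=state.partner,
        bond_count=state.bond_count,
        btype=s.btype, chain_of=s.chain_of, chain_start=s.chain_start,
        chain_mt=s.chain_mt, mt_nbeads=s.mt_nbeads, mt_linear=s.mt_linear,
        adj_start=s.adj_start, adj_nbr=s.adj_nbr, adj_l2=s.adj_l2,
        mt_bond_start=s.mt_bond_start, bond_a=s.bond_a, bond_b=s.bond_b,
        bond_l2=s.bond_l2, mt_rept_ok=s.mt_rept_ok,
        mt_rept_reach=s.mt_rept_reach, mt_rept_l2=s.mt_rept_l2,
        rept_order=s.rept_order, is_sticker=s.is_sticker,
        candw=s.boltzmann_table(beta), eps=s.eps_matrix, L=s.lattice.L,
    )


def run_mc(initial: SystemState, run: RunConfig, *, beta: float | None = None) -> MCResult:
    """Run the Markov chain; the input state is not mutated.

    Returns the sampled trajectory, the per-move statistics and the final
    state.  With ``steps == 0`` the trajectory holds the initial state only.
    Fully reproducible given ``run.seed``.
    """
    state = initial.copy()
    sysd = state.system
    if beta is None:
        beta = sysd.energy.beta
    a = _kernel_args(state, beta)
    nsnap_max = run.n_snapshots
    snap_pos = np.empty((nsnap_max, sysd.n_beads, 3), dtype=np.int64)
    snap_partner = np.empty((nsnap_max, sysd.n_beads), dtype=np.int64)
    snap_steps = np.empty(nsnap_max, dtype=np.int64)
    stats = MoveStats()
    rng = K.seed_rng(run.seed)
    code, at_step, nsnap = K.run_kernel(
        a["pos"], a["occ"], a["partner"], a["bond_count"],
        a["btype"], a["chain_of"], a["chain_start"], a["chain_mt"],
        a["mt_nbeads"], a["mt_linear"],
        a["adj_start"], a["adj_nbr"], a["adj_l2"],
        a["mt_bond_start"], a["bond_a"], a["bond_b"], a["bond_l2"],
        a["mt_rept_ok"], a["mt_rept_reach"], a["mt_rept_l2"], a["rept_order"],
        a["is_sticker"], a["candw"], a["eps"], a["L"],
        run.schedule.cumulative(), run.steps, run.equilibration,
        run.sample_every, run.strict_double_pivot, run.debug_check_every,
        rng, snap_pos, snap_partner, snap_steps,
        stats.attempts, stats.accepts)
    if code != 0:
        raise InvalidStateError(
            f"state invariant violated (code {-code}) at step {at_step}")
    if run.steps == 0:
        traj = Trajectory(sysd, [0], initial.pos[None, :, :].copy(),
                          initial.partner[None, :].copy())
    else:
        traj = Trajectory(sysd, snap_steps[:nsnap], snap_pos[:nsnap],
                          snap_partner[:nsnap])
    return MCResult(traj, stats, state)


def run_replicas(initial_factory, run: RunConfig) -> list[MCResult]:
    """Independent replicas; replica r uses seed ``run.seed + r``.

    ``initial_factory(seed)`` must build the (randomized) initial state.
    """
    out = []
    for r, seed in enumerate(run.replica_seeds()):
        rcfg = replace(run, seed=seed, replicas=1)
        out.append(run_mc(initial_factory(seed), rcfg))
    return out


# ----------------------------------------------------------------------
# single-move API (used by unit tests and for interactive inspection)
# ----------------------------------------------------------------------

def candidate_partners(state: SystemState, bead: int) -> list[int]:
    """Beads on the 26 neighboring sites this sticker could bond to now."""
    s = state.system
    if not s.is_sticker[s.btype[bead]]:
        return []
    cand = np.empty(130, dtype=np.int64)
    wbuf = np.empty(130, dtype=np.float64)
    n, _ = K._collect(bead, state.pos[bead, 0], state.pos[bead, 1],
                      state.pos[bead, 2], state.occ, state.partner, s.btype,
                      s.boltzmann_table(), s.lattice.L, cand, wbuf)
    return sorted(int(c) for c in cand[:n])


def rosenbluth_weight(state: SystemState, bead: int,
                      beta: float | None = None) -> float:
    """W = 1 + sum over available partners of exp(-beta eps); 1 for spacers."""
    s = state.system
    if not s.is_sticker[s.btype[bead]]:
        return 1.0
    return float(K._weight_at(bead, state.pos[bead, 0], state.pos[bead, 1],
                              state.pos[bead, 2], state.occ, state.partner,
                              s.btype, s.boltzmann_table(beta), s.lattice.L))


def _apply_single(state: SystemState, kind: int, rng, *, strict_dp=False,
                  beta=None) -> MoveOutcome:
    s = state.system
    a = _kernel_args(state, beta if beta is not None else s.energy.beta)
    e0 = state.energy
    cand = np.empty(130, dtype=np.int64)
    wbuf = np.empty(130, dtype=np.float64)
    save = np.empty((max(s.n_beads, 1), 3), dtype=np.int64)
    if kind == 2:
        acc = K.move_rotation(a["pos"], a["occ"], a["partner"], a["bond_count"],
                              a["btype"], a["is_sticker"], a["candw"], a["L"],
                              rng, cand, wbuf)
    elif kind == 3:
        acc = K.move_local(a["pos"], a["occ"], a["partner"], a["bond_count"],
                           a["btype"], a["is_sticker"], a["candw"], a["L"],
                           a["adj_start"], a["adj_nbr"], a["adj_l2"], rng,
                           cand, wbuf)
    elif kind == 4:
        acc = K.move_reptation(a["pos"], a["occ"], a["partner"], a["bond_count"],
                               a["btype"], a["is_sticker"], a["candw"], a["L"],
                               a["chain_start"], a["chain_mt"], a["mt_rept_ok"],
                               a["mt_rept_reach"], a["mt_rept_l2"],
                               a["rept_order"], rng, cand, wbuf, save)
    elif kind == 1:
        acc = K.move_chain_translation(a["pos"], a["occ"], a["partner"],
                                       a["bond_count"], a["btype"],
                                       a["is_sticker"], a["candw"], a["L"],
                                       a["chain_start"], a["chain_of"], rng,
                                       cand, wbuf, save)
    elif kind == 0:
        stamp = np.full(max(s.n_chains, 1), -1, dtype=np.int64)
        queue = np.empty(max(s.n_chains, 1), dtype=np.int64)
        acc = K.move_cluster_translation(a["pos"], a["occ"], a["partner"],
                                         a["L"], a["chain_start"],
                                         a["chain_of"], rng, stamp, 1, queue)
    else:
        op1 = np.empty(max(s.n_beads, 1), dtype=np.int64)
        op2 = np.empty(max(s.n_beads, 1), dtype=np.int64)
        acc = K.move_double_pivot(a["pos"], a["occ"], a["partner"], a["L"],
                                  a["chain_start"], a["chain_of"],
                                  a["chain_mt"], a["mt_nbeads"],
                                  a["mt_linear"], a["mt_bond_start"],
                                  a["bond_a"], a["bond_b"], a["bond_l2"],
                                  strict_dp, rng, cand, op1, op2)
    return MoveOutcome(MOVE_NAMES[kind], bool(acc), state.energy - e0)


def move_rotation(state, rng, **kw):
    return _apply_single(state, 2, rng, **kw)


def move_local(state, rng, **kw):
    return _apply_single(state, 3, rng, **kw)


def move_reptation(state, rng, **kw):
    return _apply_single(state, 4, rng, **kw)


def move_chain_translation(state, rng, **kw):
    return _apply_single(state, 1, rng, **kw)


def move_cluster_translation(state, rng, **kw):
    return _apply_single(state, 0, rng, **kw)


def move_double_pivot(state, rng, **kw):
    return _apply_single(state, 5, rng, **kw)
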