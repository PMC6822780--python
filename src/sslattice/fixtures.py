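"""Built-in system builders for the two archetypal systems plus a toy oracle.

Two archetypes are shipped:

* FUS-like linear multivalent proteins.  Each block is a comb: a backbone of
  five neutral spacer beads bonded N-N with tether length 4, each carrying
  one pendant sticker at tether length 1, so consecutive stickers are
  1 + 4 + 1 = 6 lattice units apart along the contour.  ``split`` mode
  (A_n + B_n) mixes the A-comb and B-comb 1:1; ``joined`` mode (A_n - B_n)
  concatenates the two backbones with an l = 4 N-N link into one 20-bead
  molecule.

* N130 + rpL5, a branched/linear heterotypic pair.  N130 is an 11-bead star:
  a neutral hub of degree 5 whose arms carry two stickers each (hub-A1
  tether 1, A1-A2 tether 3), ten stickers total; rpL5 is a 2-sticker linear
  peptide with tether length 3.  Only A-B contacts are attractive.

Both use eps_AB = -3 (temperature units), eps_ii = eps_iN = 0, and the
published move-frequency tables.  ``toy_dimer_pair`` is the smallest system
exercising excluded volume, tethers, bond exclusivity and clustering while
remaining exactly enumerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import BeadType, build_architecture
from .energy import EnergyModel
from .lattice import LatticeConfig
from .mc import MoveSchedule
from .system import LatticeSystem

__all__ = ["FixtureSpec", "SystemFixture", "build_fus_like", "build_n130_rpl5",
           "build_toy_dimer_pair", "build_fixture", "FIXTURE_NAMES",
           "FUS_SCHEDULE", "N130_SCHEDULE"]

#: move frequencies (cluster, chain, rotation, local, reptation, double pivot)
FUS_SCHEDULE = MoveSchedule(1, 10, 100, 250, 0, 50)
N130_SCHEDULE = MoveSchedule(1, 10, 100, 250, 50, 10)

EPS_AB = -3.0

FIXTURE_NAMES = ("fus_split", "fus_joined", "n130_rpl5", "toy_dimer_pair")


@dataclass
class SystemFixture:
    """Architectures + energy model + schedule, ready to assemble."""

    name: str
    bead_types: list[BeadType]
    architectures: list
    energy: EnergyModel
    schedule: MoveSchedule

    def system(self, L: int, counts: dict[str, int]) -> LatticeSystem:
        mols = [(a, counts.get(a.name, 0)) for a in self.architectures]
        return LatticeSystem(LatticeConfig(L), self.bead_types, mols, self.energy)

    def system_at_concentration(self, c: float, counts: dict[str, int],
                                min_L: int = 8) -> LatticeSystem:
        """Pick L so the total molecule concentration n / L^3 is closest to c."""
        n = sum(counts.values())
        L = max(min_L, round((n / c) ** (1.0 / 3.0)))
        return self.system(int(L), counts)


@dataclass(frozen=True)
class FixtureSpec:
    """Named fixture with optional parameter overrides."""

    name: str
    tstar: float | None = None

    def build(self) -> SystemFixture:
        return build_fixture(self.name, tstar=self.tstar)


def _comb(name: str, sticker: str, n_teeth: int) -> list:
    """Backbone of neutral spacers (l=4 N-N) with one pendant sticker each."""
    beads, bonds = [], []
    for k in range(n_teeth):
        nk = 2 * k        # backbone spacer
        beads.append("N")
        beads.append(sticker)  # pendant sticker at 2k + 1
        bonds.append((nk, nk + 1, 1))
        if k > 0:
            bonds.append((nk - 2, nk, 4))
    return [beads, bonds]


def build_fus_like(mode: str = "split", tstar: float | None = None) -> SystemFixture:
    """FUS-like linear multivalent system (split A_n+B_n or joined A_n-B_n)."""
    types = [BeadType("A", True), BeadType("B", True), BeadType("N", False)]
    energy = EnergyModel({("A", "B"): EPS_AB}, temperature=1.0,
                         reference_energy=abs(EPS_AB))
    if tstar is not None:
        energy = energy.at_reduced_temperature(tstar)
    if mode == "split":
        a_beads, a_bonds = _comb("a_block", "A", 5)
        b_beads, b_bonds = _comb("b_block", "B", 5)
        archs = [build_architecture("a_block", a_beads, a_bonds),
                 build_architecture("b_block", b_beads, b_bonds)]
        return SystemFixture("fus_split", types, archs, energy, FUS_SCHEDULE)
    if mode == "joined":
        beads, bonds = _comb("fus", "A", 5)
        nb = len(beads)  # 10
        b_beads, b_bonds = _comb("fus", "B", 5)
        beads = beads + b_beads
        bonds = bonds + [(i + nb, j + nb, l) for i, j, l in b_bonds]
        bonds.append((nb - 2, nb, 4))  # join the two backbones N-N
        archs = [build_architecture("fus", beads, bonds)]
        return SystemFixture("fus_joined", types, archs, energy, FUS_SCHEDULE)
    raise ValueError(f"mode must be 'split' or 'joined', got {mode!r}")


def build_n130_rpl5(tstar: float | None = None,
                    rpl5_stickers: int = 2) -> SystemFixture:
    """N130 pentamer star + rpL5 peptide, obligate heterotypic interactions.

    By default rpL5 carries two stickers (the two Arg-rich motifs); the star
    displays ten, two per arm.  ``rpl5_stickers=5`` builds the variant with
    five stickers per peptide (the published parameter table prints
    s_B = 5), which reproduces the published stoichiometry windows; the
    the two published readings disagree, so both are exposed.
    """
    types = [BeadType("A", True), BeadType("B", True), BeadType("N", False)]
    energy = EnergyModel({("A", "B"): EPS_AB}, temperature=1.0,
                         reference_energy=abs(EPS_AB))
    if tstar is not None:
        energy = energy.at_reduced_temperature(tstar)
    beads = ["N"]
    bonds = []
    for arm in range(5):
        a1 = len(beads)
        beads.extend(["A", "A"])
        bonds.append((0, a1, 1))       # hub to A1
        bonds.append((a1, a1 + 1, 3))  # A1 to A2
    n130 = build_architecture("n130", beads, bonds)
    if rpl5_stickers < 2:
        raise ValueError("rpL5 needs at least 2 stickers")
    rpl5 = build_architecture("rpl5", ["B"] * rpl5_stickers,
                              [(k, k + 1, 3) for k in range(rpl5_stickers - 1)])
    return SystemFixture("n130_rpl5", types, [n130, rpl5], energy, N130_SCHEDULE)


def build_toy_dimer_pair(tstar: float | None = None) -> SystemFixture:
    """Two A-B dimers on a small lattice: the exactly enumerable oracle system."""
    types = [BeadType("A", True), BeadType("B", True)]
    energy = EnergyModel({("A", "B"): EPS_AB}, temperature=1.0,
                         reference_energy=abs(EPS_AB))
    if tstar is not None:
        energy = energy.at_reduced_temperature(tstar)
    dimer = build_architecture("dimer", ["A", "B"], [(0, 1, 1)])
    return SystemFixture("toy_dimer_pair", types, [dimer], energy,
                         MoveSchedule(1, 10, 100, 250, 50, 50))


def build_fixture(name: str, tstar: float | None = None) -> SystemFixture:
    if name == "fus_split":
        return build_fus_like("split", tstar)
    if name == "fus_joined":
        return build_fus_like("joined", tstar)
    if name == "n130_rpl5":
        return build_n130_rpl5(tstar)
    if name == "toy_dimer_pair":
        return build_toy_dimer_pair(tstar)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
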