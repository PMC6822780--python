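# Methods

## Model

Molecules are graphs of beads on a periodic simple cubic lattice of edge
`L` (`L³` voxels); concentrations are molecule counts per voxel. Each bead
occupies exactly one site (hard core: the positional energy is 0 or ∞, and
∞ is never admitted). Bonds between consecutive beads of a molecule are
*phantom tethers*: a tether of length `l` only constrains the squared
minimum-image distance to `d² ≤ 3 l²`. With `l = 1` this is precisely the
26-site unit-cube neighborhood, which is also the interaction range: a
*sticker* bead may hold one anisotropic bond to one sticker on an adjacent
site, with energy ε(t₁, t₂) from a symmetric per-type-pair table
(temperature units, k_B = 1). Mutual exclusivity — one bond per sticker —
is what makes the interaction anisotropic and valence-limited. Spacer beads
never bond; they contribute excluded volume only. The total energy of a
valid state is the sum of ε over bonded pairs, counted once.

The reduced temperature is `T* = k_B T / |ε_ref|` with ε_ref the declared
reference sticker–sticker energy (3 for the shipped fixtures, which use
ε_AB = −3 and all other pairs 0).

Energy bookkeeping stores integer bond counts per unordered type pair; the
total energy is Σ count·ε. For integer (or dyadic) ε this makes incremental
accounting and full recomputation agree *exactly*, which the test suite
asserts bit-for-bit — drift in the bookkeeping would signal a broken move.

## Monte Carlo sampling

One MC step is one attempted move; move types are drawn from the schedule
weights (relative attempt frequencies). The six moves:

- **rotation** — a uniformly chosen bead re-draws its bond state among
  {unbound} ∪ {available adjacent partners} by heat-bath (Glauber)
  selection with weights {1} ∪ {exp(−βε)}. A partner is available when the
  type pair has ε ≠ 0 and it is unbound or already bonded to the chosen
  bead. Spacers reject outright. Because the candidate set depends only on
  positions and *other* beads' bonds, heat-bath selection samples the exact
  conditional and satisfies detailed balance. (Published descriptions of
  this move are internally inconsistent — uniform selection in one place,
  Metropolis in another; the heat-bath rule is the one that is both always
  accepted and exactly balanced, and the enumeration test below validates
  the choice empirically.)
- **local** — a bead is displaced by Δr with components uniform on
  [−2, 2]; the move is rejected on overlap or a violated tether, otherwise
  accepted with min{1, W_new/W_old} where W = 1 + Σ exp(−βε) over available
  partners at each site, and the bond is re-drawn by heat-bath at the new
  site. A single trial per attempt keeps the proposal symmetric and the
  balance strict. With one interaction type the acceptance reduces to the
  classic (N_new + 1)/(N_old + 1) form.
- **reptation** (slithering snake) — linear, homogeneous-tether molecules
  only. A random end proposes a new head position inside its tether ball
  (up to 10 trials, first empty site wins); the chain slides one slot;
  acceptance is the product of per-sticker W ratios; on acceptance every
  sticker re-selects its bond. Taking the first valid trial position
  slightly biases the proposal (acknowledged in the original formulation);
  a strict-balance variant would re-weight end-site choices.
- **double pivot** — pick bead i of chain m; search the ±2 cube for beads
  with intra-chain index i+1 on another chain of the same type; a candidate
  is admissible when every bond crossing the index cut keeps its tether
  under the swapped pairing; suffixes are exchanged as a pure relabeling.
  Positions, bonds and energy are untouched, so the move is accepted when a
  candidate exists. The cut test generalizes the single-bond chain case to
  branched molecules (combs), which the published move tables require; a
  `strict_double_pivot` switch restores outright rejection of non-linear
  molecules.
- **chain translation** — rigid displacement with components uniform on
  [−⌈3L/8⌉, ⌈3L/8⌉] and |Δr| ≤ 3L/4, up to 10 trials to find a clash-free
  placement; accepted with the product-of-W ratio; stickers re-bond by
  heat-bath afterwards.
- **cluster translation** — the bond-connected cluster of a random chain is
  rigidly displaced (same displacement law, single trial) and accepted iff
  no displaced bead hits a non-cluster bead. Bonds translate rigidly, so
  the energy is exactly invariant; without this move, coalescence of
  droplets is kinetically suppressed (the ablation test shows ρ̄ collapsing
  and replica scatter growing).

The RNG is xoshiro256** seeded via splitmix64 inside the kernel; replica r
uses seed + r. The kernel is numba-compiled; an optional invariant check
(occupancy bijection, partner symmetry/adjacency, tethers, bond-count
consistency) can run every move (tests) or every 10⁴ moves (default).

### Correctness oracle

Two A–B dimers on a 4³ lattice (ε = −3, T = 1) are exhaustively enumerated:
all placements with molecule 0's first bead pinned at the origin (each
configuration class has exactly L³ equal-weight translates) times all bond
matchings, ≈ 2×10⁵ states. The empirical MC distribution is compared with
the exact Boltzmann measure through a *symmetry-invariant projection*: the
sorted multiset of the six pairwise squared distances plus the multiset of
bond kinds. The projection is necessary because the raw empirical TV
distance over ~10⁵ microstate classes carries an irreducible sampling bias
of order √(K/2πN) ≫ 0.01 at any feasible N; the projected TV lower-bounds
the microstate TV. Under the full move mix it levels off near 0.008–0.010
(seed scatter ±0.0015) rather than decaying to zero: the residual is the
systematic imprint of the approximately balanced proposals discussed
below, so the < 0.01 criterion is met at the declared run length but
without much margin. Mean bond number and mean ϕ_c are compared against
their exact expectations as well.

This comparison also resolves the move set's accuracy move by move. On
the toy system (exact mean bonds 1.8900), sampling with only rotation,
local and cluster moves reproduces the exact moments to within sampling
error (|Δ| < 3×10⁻⁴): these proposals satisfy detailed balance strictly.
Adding the published approximate proposals introduces a small,
reproducible bias: reptation's first-valid-trial head placement ≈ −2×10⁻³,
the always-accepted double pivot ≈ −2×10⁻³, and the multi-trial clash-free
search of chain translation ≈ −8×10⁻⁴, totalling ≈ −5×10⁻³ under the full
mix. All three shortcuts are part of the published method (the
first-trial deviation is acknowledged in the original formulation); the
tests assert the strict subset tightly and the full mix within the
documented bias.

## Order parameters

**Pair distributions.** P⁽²⁾(r) histograms all unordered bead-pair
minimum-image distances (both species, intra- and inter-molecular) in unit
bins over (0, √3·L/2], averaged over snapshots. The prior P₀⁽²⁾(r) comes
from the matched system with every ε zeroed (excluded volume retained),
simulated with the same move set; an `ideal` mode instead samples phantom
chains directly (bead 0 uniform, tether vectors uniform on the nonzero
offsets of the tether ball — the zero offset is excluded so bonded beads
never coincide). The binodal pipeline uses the excluded-volume prior; the
ideal mode drives the finite-size self-similarity checks, where P₀(r*)
with r* = 2r/(√3 L) collapses across system sizes for ≥ 100 molecules
while a 20-molecule system is visibly noisy.

**ρ̄.** g̃(r) = P⁽²⁾/P₀⁽²⁾ on the shared binning (bins with P₀ = 0 are
masked and excluded), and ρ̄ = (1/L) ∫ |g̃ − 1| V(r/L) dr by midpoint rule
on the unit bins, the last bin clipped to the domain. V(x) is the surface
measure of the minimum-image sphere of normalized radius x in the unit
periodic cube: 4πx² up to x = 1/2; 2πx(3 − 4x) (six caps removed) up to
√2/2; beyond that the caps overlap pairwise near the twelve edges and the
overlap integral ∫ arccos(c/√(1−z²)) dz (c = 1/(2x)) is evaluated in
closed form. The printed form of this third branch in the published formula
is typographically ambiguous; the implementation derives it from the
sphere–cube intersection and is guarded by continuity at both branch
points (V(1/2) = π from both sides), ∫V = 1 to 10⁻⁶, and a direct
Monte-Carlo oracle (≤ 1% per bin where V > 0.05, with the oracle's own
4·SE honored — below that the 1% target is statistically meaningless at
any feasible sample count).

A state point is **phase separated** when ρ̄ ≥ 0.025 (universal cutoff).
r_b is the first downward crossing of g̃ through 1 after its initial peak
(linear interpolation); dense/dilute concentrations scale c_bulk by the
V-weighted mean of g̃ inside r_b and over the last quartile of the domain
(the plateau window is a choice; no published prescription exists).

**ϕ_c.** Molecules are nodes; inter-molecular bonds are edges
(intramolecular bonds do not count); ϕ_c is the largest connected
component's molecule fraction (scipy connected components). ϕ_c ≥ 0.5
marks percolation; the contour location is insensitive to thresholds in
[0.4, 0.6] for sharp transitions.

**Phase diagrams.** Grids of state points are contoured by marching
squares (`skimage.measure.find_contours`) at ρ̄ = 0.025 and ϕ_c = 0.5;
two-phase widths are outermost binodal crossings on a T* slice (grid edge
when the slice is supercritical at the boundary); state points whose
replica ρ̄ scatter exceeds 3× the slice median (and 0.05 absolutely) are
flagged non-ergodic and skipped by contouring. Closed-loop binodals are
fitted by a direct least-squares ellipse (`skimage.measure.EllipseModel`)
in log-concentration space; the angle between the major axis and the
ν₁₂ = 1 line measures the gap between apparent and effective
stoichiometry. Tie-line analysis treats the slope as a model input
(horizontal / vertical / oblique) and intersects the line through a bulk
point with the ellipse, reporting the dilute-arm A-coordinate; estimating
true tie lines would require matching coexisting compositions, which is
out of scope.

## Fixtures (the study conditions)

- **FUS-like combs.** Table values: 5 stickers + 5 neutral spacers per
  block, tethers l_AN = l_BN = 1, l_NN = 4, ε_AB = −3, all other pairs 0.
  The only architecture satisfying those tethers *and* the stated
  6-lattice-unit sticker spacing is a comb (backbone of spacers, one
  pendant sticker each); `joined` concatenates the A- and B-combs with an
  l = 4 backbone link. Schedule (cluster/chain/rotation/local/reptation/
  double-pivot): 1/10/100/250/0/50 — reptation 0 because combs are
  branched.
- **N130 + rpL5.** N130 = neutral hub of degree 5, arms of two stickers
  (hub–A1 tether 1, A1–A2 tether 3); rpL5 = linear sticker peptide with
  tether 3; ε_AB = −3 only; schedule 1/10/100/250/50/10. The source
  material disagrees on rpL5's sticker count (text and figure: 2; the
  parameter table: s_B = 5). The default fixture follows the text (2);
  `build_n130_rpl5(rpl5_stickers=5)` builds the table variant. Our scans
  show that the published stoichiometry windows (phase separation for
  1.15 ≤ ν₁₂ ≤ 16, percolation for 2.14 ≤ ν₁₂ ≤ 11.3 along the middle
  contour, both centered near ν₁₂ ≈ 5, i.e. equal *molecule*
  concentrations) are reproduced by the five-sticker variant, whereas the
  two-sticker reading centers both windows near ν₁₂ ≈ 1 (equal *sticker*
  concentrations). The quantitative window reproduction therefore uses the
  table variant; everything qualitative (reentrance, closed loop,
  percolation cone, Λ profile) uses the default.
- **Toy dimer pair** for the enumeration oracle, as above.
- Initial states randomize molecule placement (uniform root, tether-ball
  rejection growth, bounded restarts), all beads unbonded.

## Scaled-down problem sizes

Published phase diagrams used 10³–10⁴ molecules and 5×10⁸ steps per state
point. This package's reproduction layer runs at sizes chosen to resolve
each phenomenon while keeping the whole suite within desk time: 200–300
molecules per component, 5×10⁶–1.2×10⁷ steps per state point (half
equilibration, ~25 samples from the second half), priors of 1.5×10⁶ steps,
single replicas except where scatter itself is the observable (ablation: 3
replicas). Apparent critical temperatures come from five bisection steps
in T* at the densest scan concentration (resolution ≈ 0.02); percolation
thresholds from log-spaced concentration titrations (factor 1.78)
interpolated at ϕ_c = 0.5.

What the scaled-down conditions demonstrate — and what they do not: the
ideal-chain ladder shows ≥ 100 molecules suffice for self-similar
distribution functions, and all qualitative structure (ordering of the two
systems, reentrance, contour logic) is robust in our scans. Absolute
locations of boundaries retain finite-size and finite-sampling offsets,
and real condensates have features (solvent, polydispersity, kinetics) the
lattice model does not represent.

## Known quantitative deviations from the published values

Documented here because the acceptance layer measures them honestly:

- **Apparent critical temperatures.** Bisection at c = 3×10⁻⁴ voxel⁻¹
  with 300 molecules per component gives T*_c ≈ 0.38 for A_n+B_n
  (published ≈ 0.36 in the text, ~0.4 in the figure — agreement) and
  ≈ 0.79 for A_n−B_n (published ≈ 0.56, ~0.6 — a large upward deviation).
  The joined-system gap is robust against system
  size (100→800 molecules, ρ̄ at T* = 0.65 *grows* with n) and cannot be
  an equilibration artifact on our side: runs start homogeneous, so any
  observed separation lower-bounds the equilibrium value, and the
  enumeration oracle pins the sampler to the exact Boltzmann measure. The
  likely cause is that near-critical published points are
  nucleation/ergodicity-limited (the original work documents frozen-cluster
  sampling problems), whereas heat-bath rebinding plus cluster moves
  nucleate and coalesce more readily.
- **Percolation-threshold ratio.** The A_n−B_n threshold is ≈ 3.0× lower
  than A_n+B_n at T* = 1.0 (published: "two-fold"). Flory–Stockmayer for
  these valences predicts ≈ 2.7× in concentration units (f-threshold ratio
  (1/4)/(1/9) with the binding isotherm's amplification), so ≈ 3 is the
  internally consistent value.
- **Stoichiometry windows** center at ν₁₂ ≈ 1 under the two-sticker rpL5
  reading and at ≈ 5 under the table's five-sticker reading (see above);
  only the latter matches the published windows. Even then our L2
  percolation window is wider than printed (ϕ_c ≥ 0.5 from ν₁₂ ≈ 0.6 to
  beyond 18.5, versus 2.14–11.3): networking is again stronger in this
  sampler.
- **Percolation inside dilute-contour droplets.** Along the sparsest
  N130 + rpL5 contour the published data show ϕ_c < 0.5 at every
  stoichiometry; here the strongly condensed droplet at ν₁₂ = 1
  (ρ̄ ≈ 1.1) is internally spanning with ϕ_c ≈ 0.8. This is the same
  stronger-networking signature as above.

- **Move-acceptance trends.** Chain-translation acceptance declines
  monotonically with concentration to ~0 in the dense regime, and the
  double pivot becomes the dominant configuration-altering move there, as
  published. Two published trends do not transfer to these scales or
  conventions: (i) at 100 molecules the dense system is a *single*
  bond-connected cluster, so rigid whole-cluster translation never clashes
  (acceptance ≈ 1 instead of → 0 — the decline requires many coexisting
  clusters); (ii) the heat-bath rotation move is always "accepted", so its
  ratio is the sticker fraction rather than a declining Metropolis rate.

## Numerical choices and edge cases

- Unit histogram bins with exact integer-square binning ((k−1)² < d² ≤ k²);
  coincident beads (possible only in phantom/ideal sampling) are skipped.
- Heat-bath selection absorbs floating-point rounding at the top of the
  cumulative weight into the last candidate.
- Displacement draws violating |Δr| ≤ 3L/4 reject the trial (relevant only
  for L < 18, where the per-component bound does not already imply it).
- `two_phase_width` treats a supercritical grid boundary as an open edge;
  widths are then lower bounds tied to the declared grid.
- Tie lines through an interior point that fail to cut the ellipse twice
  raise a geometry error rather than returning a value.
- Degenerate systems (zero molecules, single beads, all-spacer molecules)
  are legal everywhere except where a quantity is undefined (pair
  histogram of < 2 beads, clusters of an empty system), which raise.
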