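"""Reentrant phase behavior of an obligate-heterotypic two-component system.

Holds the branched N130 pentamer concentration fixed and titrates the rpL5
peptide: the mixture enters and then exits the two-phase regime, the
signature of a closed-loop (elliptical) binodal.
"""

import math

import sslattice as ss
from sslattice.fixtures import build_n130_rpl5
from sslattice.mc import RunConfig, run_mc
from sslattice.observables import (PHASE_SEP_CUTOFF, compute_rdf,
                                   pair_distance_histogram, phi_c_series,
                                   prior_distribution)
from sslattice.phase import stoichiometry

fx = build_n130_rpl5(tstar=0.25)
c1 = 1.1e-3  # N130 concentration, voxel^-1

print(f"{'c2 (rpL5)':>12} {'nu12':>7} {'rho_bar':>8} {'phi_c':>6}  phase")
for c2 in (1.1e-4, 5.5e-3, 5.0e-2):
    nu, cb = stoichiometry(c1, c2, 10, 2)
    L = max(8, round((100 / c1) ** (1 / 3)))
    n2 = round(c2 * L**3)
    system = fx.system(L, {"n130": 100, "rpl5": n2})
    st = ss.randomize_initial_state(system, seed=7)
    run = RunConfig(fx.schedule, steps=6_000_000, equilibration=3_000_000,
                    sample_every=250_000, seed=8)
    res = run_mc(st, run)
    prior_run = RunConfig(fx.schedule, steps=1_200_000, equilibration=300_000,
                          sample_every=50_000, seed=9)
    p0 = prior_distribution(system, prior_run, seed=10)
    rdf = compute_rdf(pair_distance_histogram(res.trajectory), p0,
                      system.lattice)
    phi = phi_c_series(res.trajectory).mean()
    tag = "two-phase" if rdf.rho_bar >= PHASE_SEP_CUTOFF else "one-phase"
    print(f"{c2:12.2e} {nu:7.2f} {rdf.rho_bar:8.3f} {phi:6.2f}  {tag}")

# Expected: one-phase -> two-phase -> one-phase as c2 grows.  With rpL5 in
# large excess every N130 sticker is capped by a peptide that cannot bridge,
# so the density transition dissolves: reentrance.
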