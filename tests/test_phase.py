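import math

import numpy as np
import pytest

from sslattice.phase import (EllipseFit, PhasePoint, binodal_contour,
                             contour_from_grid, crossing_1d,
                             fit_binodal_ellipse, flory_stockmayer_percolates,
                             lambda_parameter, percolation_line,
                             stoichiometry, tie_line_dilute_scan,
                             two_phase_width, finite_size_scan)


# ----------------------------------------------------------------------
# scalar relations
# ----------------------------------------------------------------------

def test_lambda_parameter():
    assert lambda_parameter(0.0, 0.9) == 0.0
    assert lambda_parameter(0.1, 1.0) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        lambda_parameter(-0.1, 0.5)


def test_stoichiometry():
    nu, cb = stoichiometry(1e-3, 1e-3, 10, 2)
    assert nu == pytest.approx(5.0)
    assert cb == pytest.approx(1e-3)
    nu, cb = stoichiometry(4e-3, 1e-3, 10, 2)
    assert nu == pytest.approx(20.0)
    assert cb == pytest.approx(2e-3)
    with pytest.raises(ValueError):
        stoichiometry(0.0, 1e-3, 10, 2)


def test_flory_stockmayer():
    assert flory_stockmayer_percolates(1.0, 1.0, 10, 2)      # 9 > 1
    assert not flory_stockmayer_percolates(0.0, 1.0, 10, 2)  # f1 -> 0
    assert not flory_stockmayer_percolates(1.0, 1.0, 10, 1)  # monovalent
    assert not flory_stockmayer_percolates(0.3, 0.3, 10, 2)  # 0.81 < 1


# ----------------------------------------------------------------------
# contours
# ----------------------------------------------------------------------

def test_contour_empty_for_flat_field():
    x = np.linspace(0, 1, 8)
    y = np.linspace(0, 1, 9)
    assert binodal_contour(np.zeros((8, 9)), x=x, y=y) == []


def test_contour_recovers_disc_level_set():
    x = np.linspace(-1, 1, 41)
    y = np.linspace(-1, 1, 41)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    field = np.clip(0.05 * (0.6 - rr) / 0.6, 0.0, None)  # cone, zero at r=0.6
    segs = binodal_contour(field, cutoff=0.025, x=x, y=y)
    assert len(segs) == 1
    radii = np.hypot(segs[0][:, 0], segs[0][:, 1])
    assert np.allclose(radii, 0.3, atol=0.05)  # analytic level set r = 0.3


def test_percolation_line_from_sigmoid_field():
    c = np.linspace(0, 1, 101)
    phi = 1 / (1 + np.exp(-(c - 0.42) / 0.02))
    xs = crossing_1d(c, phi, 0.5)
    assert len(xs) == 1 and xs[0] == pytest.approx(0.42, abs=0.005)


def test_percolation_threshold_robustness():
    """Sharp sigmoid: the contour moves by less than one grid cell when the
    threshold varies in [0.4, 0.6]."""
    x = np.linspace(0, 1, 21)   # concentration axis, cell 0.05
    y = np.linspace(0, 1, 5)    # dummy second axis
    xx = np.tile(1 / (1 + np.exp(-(x - 0.5) / 0.01)), (5, 1)).T
    locs = []
    for thr in (0.4, 0.5, 0.6):
        segs = percolation_line(xx, threshold=thr, x=x, y=y)
        locs.append(np.mean(segs[0][:, 0]))
    assert max(locs) - min(locs) < 0.05


def test_two_phase_width_parabola():
    """Synthetic parabola-shaped rho_bar(c): width matches the closed form."""
    cutoff = 0.025
    c0, half, peak = 5e-4, 4e-4, 0.1
    cs = np.linspace(c0 - half, c0 + half, 81)
    pts = []
    for t, scale in ((0.3, 1.0), (0.5, 0.0)):
        for c in cs:
            rho = scale * max(peak * (1 - ((c - c0) / half) ** 2), 0.0)
            pts.append(PhasePoint(tstar=t, c_bulk=float(c), rho_bar=rho))
    w = two_phase_width(pts, 0.3, cutoff)
    expected = 2 * half * math.sqrt(1 - cutoff / peak)
    assert w == pytest.approx(expected, rel=0.01)
    assert two_phase_width(pts, 0.5, cutoff) is None  # above critical


# ----------------------------------------------------------------------
# ellipse fit and tie lines
# ----------------------------------------------------------------------

def _ellipse_points(xc, yc, a, b, theta, n=40):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    u, v = a * np.cos(t), b * np.sin(t)
    ct, st = math.cos(theta), math.sin(theta)
    return np.column_stack([xc + ct * u - st * v, yc + st * u + ct * v])


def test_ellipse_fit_recovers_exact_parameters():
    fit = fit_binodal_ellipse(_ellipse_points(1.0, -2.0, 3.0, 1.0, 0.4))
    assert fit.center[0] == pytest.approx(1.0, abs=1e-6)
    assert fit.center[1] == pytest.approx(-2.0, abs=1e-6)
    assert fit.semi_axes[0] == pytest.approx(3.0, abs=1e-6)
    assert fit.semi_axes[1] == pytest.approx(1.0, abs=1e-6)
    assert fit.theta == pytest.approx(0.4, abs=1e-6)
    assert fit.residual < 1e-6


def test_ellipse_aligned_with_unity_line_has_zero_angle():
    fit = fit_binodal_ellipse(_ellipse_points(0, 0, 2.0, 0.5, math.pi / 4))
    assert fit.angle_to_line(1.0) == pytest.approx(0.0, abs=1e-6)
    tilted = fit_binodal_ellipse(_ellipse_points(0, 0, 2.0, 0.5, math.pi / 3))
    assert tilted.angle_to_line(1.0) == pytest.approx(math.pi / 12, abs=1e-6)


def test_ellipse_fit_rejects_degenerate_input():
    line = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
    with pytest.raises(ValueError):
        fit_binodal_ellipse(line)
    with pytest.raises(ValueError):
        fit_binodal_ellipse(line[:4])


def test_tie_lines_outside_identity_and_horizontal_linear():
    ell = EllipseFit((0.0, 0.0), (2.0, 1.0), 0.0, 0.0)
    a_grid = np.linspace(-3, 3, 61)
    curves = tie_line_dilute_scan(ell, "horizontal", [0.0], a_grid)
    # horizontal tie lines: [A]_Sol tracks [A] everywhere (linear inside)
    assert np.allclose(curves[0.0], a_grid)


def test_tie_lines_vertical_plateau():
    ell = EllipseFit((0.0, 0.0), (2.0, 1.0), 0.0, 0.0)
    a_grid = np.linspace(-3, 3, 121)
    curves = tie_line_dilute_scan(ell, "vertical", [0.0, 1.0], a_grid)
    for b in (0.0, 1.0):
        inside = np.array([ell.contains(b, a) for a in a_grid])
        lower = -math.sqrt(1 - (b / 2.0) ** 2)  # dilute arm of the ellipse
        assert np.allclose(curves[b][inside], lower, atol=1e-9)
        assert np.allclose(curves[b][~inside], a_grid[~inside])
    # the plateau tracks the ellipse's dilute arm as [B] changes
    assert curves[1.0][60] > curves[0.0][60]


def test_tie_lines_oblique_nonlinear():
    ell = EllipseFit((0.0, 0.0), (2.0, 1.0), 0.0, 0.0)
    a_grid = np.linspace(-0.9, 0.9, 31)
    curves = tie_line_dilute_scan(ell, 0.5, [0.0], a_grid)
    inside = np.array([ell.contains(0.0, a) for a in a_grid])
    vals = curves[0.0][inside]
    diffs = np.diff(vals)
    assert not np.allclose(diffs, diffs[0])  # nonlinear variation


# ----------------------------------------------------------------------
# state-point scanning
# ----------------------------------------------------------------------

def test_scan_phase_points_grid(toy_fixture):
    """A tiny (T*, c) scan returns consistent, classified state points."""
    from sslattice.mc import RunConfig
    from sslattice.phase import scan_phase_points

    def build_system(c):
        return toy_fixture.system_at_concentration(c, {"dimer": 24})

    run = RunConfig(toy_fixture.schedule, steps=150_000, equilibration=50_000,
                    sample_every=10_000, seed=5, replicas=2,
                    debug_check_every=0)
    prior_run = RunConfig(toy_fixture.schedule, steps=80_000,
                          equilibration=20_000, sample_every=6_000, seed=55,
                          debug_check_every=0)
    pts = scan_phase_points(build_system, [0.4, 1.2], [5e-3, 2e-2], run,
                            prior_run)
    assert len(pts) == 4
    for p in pts:
        assert p.lam == p.rho_bar * p.phi_c
        assert 0 <= p.phi_c <= 1 and p.rho_bar >= 0
        assert p.c_bulk in (5e-3, 2e-2) and p.tstar in (0.4, 1.2)
        assert isinstance(p.ergodic, bool) or p.ergodic in (True, False)


# ----------------------------------------------------------------------
# finite-size ladder (ideal chains)
# ----------------------------------------------------------------------

def test_ideal_chain_collapse(fus_split_fixture):
    report = finite_size_scan(
        fus_split_fixture, [{"a_block": 10, "b_block": 10},
                            {"a_block": 50, "b_block": 50},
                            {"a_block": 100, "b_block": 100}],
        c_bulk=2e-4, n_snapshots=150, seed=3)
    sup = report["sup_norm"]
    assert sup[(100, 200)] < sup[(20, 100)]
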