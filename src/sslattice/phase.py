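"""Phase diagrams: state-point scans, binodal and percolation contours,
two-phase widths, stoichiometry, ellipse fits and tie-line geometry.

State points are classified by two order parameters: rho_bar (density
inhomogeneity; the rho_bar = 0.025 contour proxies the binodal) and phi_c
(largest-cluster fraction; the phi_c = 0.5 contour proxies the percolation
line).  Lambda = rho_bar * phi_c couples the density and networking
transitions.  For two-component mixtures the bulk concentration is
c_bulk = sqrt(c1 c2) and the apparent stoichiometric ratio is
nu12 = (s1 c1) / (s2 c2) with s_i the sticker valences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import EllipseModel, find_contours

from .mc import RunConfig, run_mc
from .observables import (PHASE_SEP_CUTOFF, compute_rdf,
                          pair_distance_histogram, phase_densities,
                          phi_c_series, prior_distribution)
from .system import randomize_initial_state

__all__ = [
    "PhasePoint", "PhaseDiagram", "EllipseFit",
    "compute_phase_point", "scan_phase_points",
    "binodal_contour", "percolation_line", "contour_from_grid",
    "two_phase_width", "lambda_parameter", "stoichiometry",
    "flory_stockmayer_percolates", "fit_binodal_ellipse",
    "tie_line_dilute_scan", "finite_size_scan", "crossing_1d",
    "PERCOLATION_THRESHOLD",
]

PERCOLATION_THRESHOLD = 0.5


@dataclass
class PhasePoint:
    """Order parameters of one state point (replica-averaged)."""

    tstar: float
    c_bulk: float
    c1: float | None = None
    c2: float | None = None
    rho_bar: float = 0.0
    rho_bar_sd: float = 0.0
    phi_c: float = 0.0
    phi_c_sd: float = 0.0
    r_b: float | None = None
    c_dilute: float = 0.0
    c_dense: float = 0.0
    ergodic: bool = True

    @property
    def lam(self) -> float:
        return lambda_parameter(self.rho_bar, self.phi_c)

    @property
    def phase_separated(self) -> bool:
        return self.rho_bar >= PHASE_SEP_CUTOFF

    @property
    def percolated(self) -> bool:
        return self.phi_c >= PERCOLATION_THRESHOLD


@dataclass
class PhaseDiagram:
    """A grid of state points plus interpolated contours."""

    points: list
    binodal: list = field(default_factory=list)
    percolation: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def lambda_parameter(rho_bar: float, phi_c: float) -> float:
    """Lambda = rho_bar * phi_c (the AND-gate convolution of the two
    transitions, which for scalars is a simple product)."""
    if rho_bar < 0 or phi_c < 0:
        raise ValueError("order parameters must be non-negative")
    return rho_bar * phi_c


def stoichiometry(c1: float, c2: float, s1: int, s2: int) -> tuple[float, float]:
    """(nu12_app, c_bulk): sticker-concentration ratio and geometric-mean
    bulk concentration of a two-component mixture."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("concentrations must be positive")
    return (s1 * c1) / (s2 * c2), math.sqrt(c1 * c2)


def flory_stockmayer_percolates(f1: float, f2: float, s1: int, s2: int) -> bool:
    """Flory-Stockmayer gelation criterion f1 f2 (s1-1)(s2-1) > 1."""
    if s1 < 1 or s2 < 1:
        raise ValueError("valences must be >= 1")
    if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
        raise ValueError("bound fractions must lie in [0, 1]")
    return f1 * f2 * (s1 - 1) * (s2 - 1) > 1.0


# ----------------------------------------------------------------------
# state-point evaluation
# ----------------------------------------------------------------------

def compute_phase_point(system, run: RunConfig, *, tstar: float,
                        c_bulk: float, c1=None, c2=None,
                        prior_run: RunConfig | None = None,
                        prior_hist=None) -> PhasePoint:
    """Run replicas of one state point and assemble its order parameters.

    A matched prior (all eps = 0) is computed once per composition and can
    be passed in as ``prior_hist`` to share across temperatures.
    """
    if prior_hist is None:
        if prior_run is None:
            raise ValueError("need prior_run or a precomputed prior histogram")
        prior_hist = prior_distribution(system, prior_run, seed=run.seed + 900_001)
    rhos, phis, rbs, dils, dens = [], [], [], [], []
    for r, seed in enumerate(run.replica_seeds()):
        st = randomize_initial_state(system, seed + 500_000)
        res = run_mc(st, replace(run, seed=seed, replicas=1))
        p2 = pair_distance_histogram(res.trajectory)
        rdf = compute_rdf(p2, prior_hist, system.lattice)
        rhos.append(rdf.rho_bar)
        phis.append(float(phi_c_series(res.trajectory).mean()))
        rbs.append(rdf.r_b)
        dl, dn = phase_densities(rdf.gtilde, rdf.r_b, c_bulk, system.lattice)
        dils.append(dl)
        dens.append(dn)
    rhos = np.array(rhos)
    phis = np.array(phis)
    rb_vals = [r for r in rbs if r is not None]
    return PhasePoint(
        tstar=tstar, c_bulk=c_bulk, c1=c1, c2=c2,
        rho_bar=float(rhos.mean()), rho_bar_sd=float(rhos.std()),
        phi_c=float(phis.mean()), phi_c_sd=float(phis.std()),
        r_b=float(np.mean(rb_vals)) if rb_vals else None,
        c_dilute=float(np.mean(dils)), c_dense=float(np.mean(dens)))


def flag_non_ergodic(points: list) -> None:
    """Exclude state points whose replicas disagree wildly on rho_bar.

    A point is flagged when its between-replica sd exceeds 3x the median sd
    of its slice (plus a floor); flagged points are skipped by contouring.
    """
    sds = np.array([p.rho_bar_sd for p in points])
    med = float(np.median(sds))
    for p in points:
        p.ergodic = not (p.rho_bar_sd > 3.0 * med + 1e-4 and p.rho_bar_sd > 0.05)


def scan_phase_points(build_system, tstars, concentrations, run: RunConfig,
                      prior_run: RunConfig, *, flag=True) -> list:
    """Evaluate a (T*, c) grid for a one-axis (pseudo one-component) system.

    ``build_system(c)`` must return the LatticeSystem at bulk concentration
    ``c``; the matched prior is computed once per concentration (eps = 0
    makes it temperature independent) and shared across the T* column.
    """
    points = []
    for ci, c in enumerate(concentrations):
        system = build_system(c)
        phist = prior_distribution(system, replace(prior_run, seed=prior_run.seed + ci),
                                   seed=prior_run.seed + 7 * ci + 1)
        for ti, t in enumerate(tstars):
            sys_t = system.with_energy(system.energy.at_reduced_temperature(t))
            rcfg = replace(run, seed=run.seed + 1000 * ci + ti)
            points.append(compute_phase_point(
                sys_t, rcfg, tstar=t, c_bulk=c, prior_hist=phist))
    if flag:
        flag_non_ergodic(points)
    return points


# ----------------------------------------------------------------------
# contours and widths
# ----------------------------------------------------------------------

def contour_from_grid(x, y, field2d, level) -> list[np.ndarray]:
    """Marching-squares level set of a field sampled on a rectilinear grid.

    ``field2d[i, j]`` corresponds to (x[i], y[j]); returns polylines as
    (m, 2) arrays of (x, y) pairs in data coordinates, linearly
    interpolated, never extrapolated beyond the grid hull.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    f = np.asarray(field2d, dtype=np.float64)
    if f.shape != (len(x), len(y)):
        raise ValueError("field shape must be (len(x), len(y))")
    out = []
    for seg in find_contours(f, level):
        xi = np.interp(seg[:, 0], np.arange(len(x)), x)
        yi = np.interp(seg[:, 1], np.arange(len(y)), y)
        out.append(np.column_stack([xi, yi]))
    return out


def binodal_contour(points_or_field, cutoff: float = PHASE_SEP_CUTOFF, *,
                    x=None, y=None) -> list[np.ndarray]:
    """rho_bar = cutoff polylines from a 2-D field (closed loop when the
    two-phase region is interior to the grid)."""
    return contour_from_grid(x, y, points_or_field, cutoff)


def percolation_line(points_or_field, threshold: float = PERCOLATION_THRESHOLD,
                     *, x=None, y=None) -> list[np.ndarray]:
    """phi_c = threshold polylines from a 2-D field."""
    return contour_from_grid(x, y, points_or_field, threshold)


def crossing_1d(xs, values, level) -> list[float]:
    """All linear-interpolated crossings of a 1-D sampled curve through
    ``level`` (used for slice widths and titration thresholds)."""
    xs = np.asarray(xs, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64) - level
    out = []
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            out.append(float(xs[i]))
        if v[i] * v[i + 1] < 0:
            frac = v[i] / (v[i] - v[i + 1])
            out.append(float(xs[i] + frac * (xs[i + 1] - xs[i])))
    if len(v) and v[-1] == 0.0:
        out.append(float(xs[-1]))
    return out


def two_phase_width(points: list, tstar: float,
                    cutoff: float = PHASE_SEP_CUTOFF) -> float | None:
    """w(T*): spread between the outermost binodal crossings on a T* slice.

    None above the apparent critical temperature (no crossing, or the slice
    never exceeds the cutoff).
    """
    slice_pts = sorted((p for p in points
                        if p.tstar == tstar and p.ergodic), key=lambda p: p.c_bulk)
    if len(slice_pts) < 2:
        return None
    cs = [p.c_bulk for p in slice_pts]
    rhos = [p.rho_bar for p in slice_pts]
    if max(rhos) < cutoff:
        return None
    crossings = crossing_1d(cs, rhos, cutoff)
    # interior two-phase region: treat a supercritical first/last point as
    # an open boundary at the grid edge
    lo = crossings[0] if rhos[0] < cutoff else cs[0]
    hi = crossings[-1] if rhos[-1] < cutoff else cs[-1]
    if hi <= lo:
        return None
    return hi - lo


# ----------------------------------------------------------------------
# ellipse fit and tie lines
# ----------------------------------------------------------------------

@dataclass
class EllipseFit:
    """A fitted ellipse (typically in log-concentration coordinates)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]   # (major, minor)
    theta: float                     # major-axis angle, radians
    residual: float

    @property
    def major_axis_direction(self) -> tuple[float, float]:
        return (math.cos(self.theta), math.sin(self.theta))

    def angle_to_line(self, slope: float = 1.0) -> float:
        """Smallest angle (radians) between the major axis and a line of
        given slope (the nu12 = 1 line has slope 1 in log coordinates)."""
        ref = math.atan(slope)
        d = abs(self.theta - ref) % math.pi
        return min(d, math.pi - d)

    def contains(self, x: float, y: float) -> bool:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dx, dy = x - self.center[0], y - self.center[1]
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def line_intersections(self, point: tuple[float, float],
                           slope: float | None) -> list[tuple[float, float]]:
        """Intersections of the line through ``point`` (slope None means
        vertical) with the ellipse boundary."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        a, b = self.semi_axes
        x0, y0 = point
        if slope is None:
            dx, dy = 0.0, 1.0
        else:
            nrm = math.hypot(1.0, slope)
            dx, dy = 1.0 / nrm, slope / nrm
        # transform to ellipse frame
        px, py = x0 - self.center[0], y0 - self.center[1]
        pu, pv = ct * px + st * py, -st * px + ct * py
        du, dv = ct * dx + st * dy, -st * dx + ct * dy
        A = (du / a) ** 2 + (dv / b) ** 2
        B = 2 * (pu * du / a**2 + pv * dv / b**2)
        C = (pu / a) ** 2 + (pv / b) ** 2 - 1.0
        disc = B * B - 4 * A * C
        if disc < 0:
            return []
        roots = [(-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)]
        return [(x0 + t * dx, y0 + t * dy) for t in sorted(roots)]


def fit_binodal_ellipse(points) -> EllipseFit:
    """Direct least-squares ellipse fit to binodal points (>= 6 required)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 6 or pts.shape[1] != 2:
        raise ValueError("need at least 6 (x, y) points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear; no ellipse")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if a < b:  # normalize: major axis first
        a, b = b, a
        theta += math.pi / 2.0
    theta = math.atan2(math.sin(theta), math.cos(theta))
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    res = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return EllipseFit((float(xc), float(yc)), (float(a), float(b)),
                      float(theta), res)


def tie_line_dilute_scan(ellipse: EllipseFit, slope, b_values, a_grid):
    """[A]_Sol as a function of bulk [A] for fixed [B] values.

    ``slope`` is the tie-line model: "horizontal", "vertical", or a number
    m = d[A]/d[B].  Outside the ellipse [A]_Sol = [A]; inside, [A]_Sol is
    the A-coordinate of the dilute-arm intersection of the tie line with
    the ellipse.  Horizontal tie lines give linear variation of [A]_Sol
    with [A]; vertical tie lines give a plateau that shifts with [B].
    The plane is ([B] along x, [A] along y).
    """
    if slope == "horizontal":
        m: float | None = 0.0
    elif slope == "vertical":
        m = None
    else:
        m = float(slope)
    out = {}
    for b in b_values:
        curve = []
        for a in a_grid:
            if not ellipse.contains(b, a):
                curve.append(a)
                continue
            hits = ellipse.line_intersections((b, a), m)
            if len(hits) < 2:
                raise ValueError("tie line through an interior point must "
                                 "cross the ellipse twice")
            # dilute arm: the end with the smaller [A]; a horizontal tie
            # line keeps [A]_Sol = [A]
            a_sol = min(h[1] for h in hits)
            curve.append(a_sol)
        out[b] = np.asarray(curve, dtype=np.float64)
    return out


# ----------------------------------------------------------------------
# finite-size ladder
# ----------------------------------------------------------------------

def finite_size_scan(fixture, counts_list, *, c_bulk, n_snapshots=200,
                     seed=0, r_grid=None):
    """Self-similarity of the ideal-chain P0(r*) across system sizes.

    For each molecule count the lattice is rescaled to keep the bulk
    concentration fixed, P0 is sampled from the ideal-chain ensemble, and
    curves are compared on a common r* grid.  Returns per-count curves and
    the sup-norm discrepancy between consecutive sizes.
    """
    from .observables import pair_distance_histogram, rescale_distance, sample_ideal_positions
    if r_grid is None:
        r_grid = np.linspace(0.02, 0.98, 97)
    curves = {}
    for k, n in enumerate(counts_list):
        counts = dict(n) if isinstance(n, dict) else None
        if counts is None:
            # single-architecture fixture: all molecules of the first type
            counts = {fixture.architectures[0].name: int(n)}
        system = fixture.system_at_concentration(c_bulk, counts)
        pos = sample_ideal_positions(system, n_snapshots, seed + k)
        h = pair_distance_histogram(pos, system.lattice)
        rstar = rescale_distance(h.midpoints, system.lattice)
        dens = h.density() / np.gradient(rstar)  # density per unit r*
        curves[sum(counts.values())] = np.interp(r_grid, rstar, dens)
    keys = sorted(curves)
    discrepancy = {}
    for a, b in zip(keys[:-1], keys[1:]):
        discrepancy[(a, b)] = float(np.max(np.abs(curves[a] - curves[b])))
    return {"r_star": r_grid, "curves": curves, "sup_norm": discrepancy}
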