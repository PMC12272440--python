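"""Tumor delineation: sandpile energy landscape + greedy active contour.

Stage one converts the classifier's probability map into a *sandpile energy
landscape*, slice by slice.  Each tumor-classified pixel is poured an amount
of sand proportional to its tumor probability; pixels classified healthy act
as finite sinks (background and off-grid pixels as unlimited sinks).  The
pile then topples: any pixel whose height exceeds a critical value sheds its
entire load in equal quarters to its four direct neighbours, and sand
arriving at a sink is absorbed up to the sink's remaining capacity, the
overflow toppling onward (sinks hold no sand).  At the fixed point, isolated
misclassified specks -- whose sand fits in the surrounding sink capacity --
have been erased entirely, while coherent tumor regions retain a broad mass
of sand whose footprint spreads with the amount poured.  Sand is conserved
exactly: poured == remaining height + absorbed (including the boundary).

Stage two wraps each stabilized landscape with a closed active contour
(snake).  The contour starts on the dilated convex hull of the positive-sand
region and descends an energy combining homogeneity (spacing), stiffness
(curvature), a gravitational pull toward the landscape's centre of mass, and
an external attraction to the landscape's rim; moves are greedy over a 3x3
pixel neighbourhood per vertex and only energy-decreasing, intersection-free
moves are accepted, so the energy trace is non-increasing and the final
polygon is simple by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .core_io import VoxelGeometry
from .classifier import ProbabilityMap
from .labeling import HEALTHY, NONHEALTHY, LabelMap

__all__ = [
    "SandpileParams", "EnergyLandscape", "ContourParams", "SliceContour",
    "build_energy_landscape", "init_contour", "evolve_contour",
    "delineate_volume", "rasterize_contours",
]


# ---------------------------------------------------------------------------
# sandpile landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SandpileParams:
    """Toppling parameters.

    ``pour_gain`` (sand per unit probability), ``h_crit`` (height above
    which a pixel topples), ``sink_capacity`` (sand each healthy pixel can
    absorb), ``max_sweeps`` (parallel toppling sweeps before giving up).
    """

    pour_gain: float = 10.0
    h_crit: float = 1.0
    sink_capacity: float = 2.0
    max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if self.pour_gain <= 0 or self.h_crit <= 0:
            raise ValueError("pour_gain and h_crit must be positive")
        if self.sink_capacity < 0:
            raise ValueError("sink_capacity must be >= 0")


@dataclass
class EnergyLandscape:
    """Stabilized sand-height field for one slice, with the absorbed ledger.

    Conservation holds exactly (to accumulation error):
    ``poured == height.sum() + absorbed.sum() + boundary_absorbed``.
    """

    height: np.ndarray
    absorbed: np.ndarray
    boundary_absorbed: float
    poured: float
    sweeps: int
    converged: bool
    h_crit: float = 1.0
    slice_index: int = 0

    @property
    def conservation_error(self) -> float:
        return float(self.poured - (self.height.sum() + self.absorbed.sum()
                                    + self.boundary_absorbed))

    def support(self) -> np.ndarray:
        """Significant footprint: connected components of positive sand
        whose retained mass reaches at least one critical-height unit.
        Sub-critical residues (e.g. what is left of an isolated speck after
        its surroundings absorbed most of it) are noise on the landscape's
        own scale and are excluded."""
        pos = self.height > 0
        labeled, n = ndimage.label(pos)
        if n == 0:
            return pos
        masses = ndimage.sum_labels(self.height, labeled, index=np.arange(1, n + 1))
        keep = np.flatnonzero(masses >= self.h_crit) + 1
        return np.isin(labeled, keep)

    @property
    def n_components(self) -> int:
        """Connected components of the significant footprint."""
        _, n = ndimage.label(self.support())
        return int(n)


def _topple_slice(h0: np.ndarray, is_sink: np.ndarray, capacity: np.ndarray,
                  params: SandpileParams) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Run parallel toppling sweeps on one padded slice until stable."""
    nz, nx = h0.shape
    H = np.zeros((nz + 2, nx + 2))
    H[1:-1, 1:-1] = h0
    sink = np.ones((nz + 2, nx + 2), dtype=bool)
    sink[1:-1, 1:-1] = is_sink
    cap = np.full((nz + 2, nx + 2), np.inf)
    cap[1:-1, 1:-1] = capacity
    A = np.zeros_like(H)
    poured = float(h0.sum())
    tol = 1e-12 * max(poured, 1.0)
    threshold = np.where(sink, 0.0, params.h_crit)

    converged = False
    sweeps = 0
    for sweeps in range(1, params.max_sweeps + 1):
        take = np.minimum(H, cap)
        take[~sink] = 0.0
        A += take
        cap -= take
        H -= take
        move = np.where(H > threshold, H, 0.0)
        total = move.sum()
        if total <= tol:
            converged = True
            break
        H -= move
        q = 0.25 * move
        H[1:, :] += q[:-1, :]
        H[:-1, :] += q[1:, :]
        H[:, 1:] += q[:, :-1]
        H[:, :-1] += q[:, 1:]
    # final absorption pass so sinks end empty
    take = np.minimum(H, cap)
    take[~sink] = 0.0
    A += take
    H -= take
    # sub-tolerance dust left wandering between exhausted sinks is booked as
    # absorbed so the footprint (H > 0) stays meaningful and conservation exact
    dust = np.where(sink & (H <= tol), H, 0.0)
    A += dust
    H -= dust
    boundary = float(A[0, :].sum() + A[-1, :].sum() + A[1:-1, 0].sum() + A[1:-1, -1].sum())
    return H[1:-1, 1:-1], A[1:-1, 1:-1], boundary, sweeps, converged


def build_energy_landscape(
    pmap: ProbabilityMap,
    final_labels: LabelMap,
    params: SandpileParams | None = None,
) -> list[EnergyLandscape]:
    """Build one stabilized landscape per slice.

    Sand ``pour_gain * p`` is poured on pixels classified non-healthy;
    healthy pixels are sinks of ``sink_capacity``; background (and the ring
    just outside the grid) absorbs without limit, which closes the
    conservation ledger.
    """
    params = params or SandpileParams()
    labels = final_labels.labels
    if labels.shape != pmap.prob.shape:
        raise ValueError("probability map and label map shapes do not match")
    landscapes = []
    for s in range(labels.shape[0]):
        sl = labels[s]
        tumor = sl == NONHEALTHY
        p = np.nan_to_num(pmap.prob[s], nan=0.0)
        h0 = np.where(tumor, params.pour_gain * p, 0.0)
        is_sink = ~tumor
        capacity = np.where(sl == HEALTHY, params.sink_capacity, np.inf)
        capacity[tumor] = 0.0
        H, A, boundary, sweeps, converged = _topple_slice(h0, is_sink, capacity, params)
        landscapes.append(EnergyLandscape(
            height=H, absorbed=A, boundary_absorbed=boundary,
            poured=float(h0.sum()), sweeps=sweeps, converged=converged,
            h_crit=params.h_crit, slice_index=s,
        ))
    return landscapes


# ---------------------------------------------------------------------------
# active contour
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourParams:
    """Snake parameters.

    ``alpha`` weighs point-spacing homogeneity, ``beta`` curvature stiffness,
    ``gravity`` the pull toward the landscape's centre of mass, ``kappa`` the
    external attraction; ``external`` selects the attraction field: ``"rim"``
    (Gaussian-smoothed gradient magnitude of the landscape -- a ridge along
    the tumor boundary) or ``"height"`` (smoothed height itself).
    ``n_points=None`` sizes the polygon adaptively at ~1.5 px spacing.
    """

    n_points: Optional[int] = None
    alpha: float = 0.01
    beta: float = 0.01
    gravity: float = 1e-3
    kappa: float = 4.0
    external: str = "rim"
    smooth_sigma: float = 1.0
    init_dilate_px: float = 1.5
    step_px: float = 1.0
    min_spacing_px: float = 0.5
    refine_levels: int = 2
    max_iters: int = 300
    tol_px: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gravity", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_points is not None and self.n_points < 8:
            raise ValueError("need at least 8 contour points")
        if self.external not in ("rim", "height"):
            raise ValueError("external must be 'rim' or 'height'")


@dataclass
class SliceContour:
    """Closed snake polygon for one slice, in (z, x) pixel coordinates."""

    points_px: np.ndarray
    slice_index: int
    energy_trace: list[float] = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False
    multi_component: bool = False

    def points_mm(self, geometry: VoxelGeometry) -> np.ndarray:
        return self.points_px * np.array([geometry.axial_mm, geometry.lateral_mm])

    @property
    def final_energy(self) -> float:
        return self.energy_trace[-1] if self.energy_trace else float("nan")


def _external_field(landscape: EnergyLandscape, params: ContourParams) -> np.ndarray:
    H = landscape.height
    if params.external == "rim":
        # Ridge along the boundary of the stabilized landscape's significant
        # footprint.  The binary footprint is used rather than the raw
        # heights so that the uneven residual heights inside the pile do not
        # drag the ridge off the true rim.
        F = ndimage.gaussian_gradient_magnitude(
            landscape.support().astype(float), sigma=params.smooth_sigma)
    else:
        F = ndimage.gaussian_filter(H, sigma=params.smooth_sigma)
    m = F.max()
    return F / m if m > 0 else F


def _bilinear(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``field`` at float (row, col) points; zero outside."""
    nz, nx = field.shape
    r = np.clip(pts[:, 0], 0.0, nz - 1.0)
    c = np.clip(pts[:, 1], 0.0, nx - 1.0)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, nz - 1)
    c1 = np.minimum(c0 + 1, nx - 1)
    fr = r - r0
    fc = c - c0
    return (field[r0, c0] * (1 - fr) * (1 - fc) + field[r1, c0] * fr * (1 - fc)
            + field[r0, c1] * (1 - fr) * fc + field[r1, c1] * fr * fc)


def init_contour(landscape: EnergyLandscape,
                 params: ContourParams | None = None) -> Optional[SliceContour]:
    """Initial snake: the convex hull of the positive-sand region, dilated
    and resampled uniformly by arc length.  ``None`` for a zero-mass slice."""
    params = params or ContourParams()
    pos = np.argwhere(landscape.support())
    if len(pos) == 0:
        return None
    hull = MultiPoint([(float(r), float(c)) for r, c in pos]).convex_hull
    poly = hull.buffer(params.init_dilate_px)
    ring = poly.exterior
    length = ring.length
    n = params.n_points if params.n_points is not None else int(np.clip(round(length / 1.5), 16, 200))
    pts = np.array([ring.interpolate(i * length / n).coords[0] for i in range(n)])
    # shapely may orient rings either way; normalize to a consistent order
    return SliceContour(points_px=pts, slice_index=landscape.slice_index,
                        multi_component=landscape.n_components > 1)


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _segments_cross(p1, p2, q1, q2) -> np.ndarray:
    """Vectorized proper-intersection test of segment (p1,p2) vs many (q1,q2)."""
    d1 = _cross2(q2 - q1, p1 - q1)
    d2 = _cross2(q2 - q1, p2 - q1)
    d3 = _cross2(p2 - p1, q1 - p1)
    d4 = _cross2(p2 - p1, q2 - p1)
    eps = 1e-12  # near-collinear float noise must not count as a crossing
    return ((d1 * d2) < -eps) & ((d3 * d4) < -eps)


def _move_keeps_simple(pts: np.ndarray, i: int, new_v: np.ndarray) -> bool:
    """Would moving vertex i to new_v keep the closed polygon simple?"""
    n = len(pts)
    prev_i, next_i = (i - 1) % n, (i + 1) % n
    seg_starts = pts
    seg_ends = np.roll(pts, -1, axis=0)
    # the two replaced segments are (i-1 -> i) and (i -> i+1); every other
    # segment is a crossing candidate -- the strict test never flags
    # segments that merely share an endpoint
    for a, b, own in ((pts[prev_i], new_v, prev_i), (new_v, pts[next_i], i)):
        keep = np.ones(n, dtype=bool)
        keep[[prev_i, i]] = False
        if np.any(_segments_cross(a, b, seg_starts[keep], seg_ends[keep])):
            return False
    return True


class _SnakeEnergy:
    """Total and local snake energy on a fixed external field.

    The homogeneity term penalizes the deviation of each segment length
    from the initial mean spacing ``d_bar`` (not raw segment length, which
    would reward vertices bunching up)."""

    def __init__(self, field: np.ndarray, center: np.ndarray,
                 d_bar: float, params: ContourParams):
        self.F = field
        self.c = center
        self.d_bar = d_bar
        self.p = params

    def total(self, pts: np.ndarray) -> float:
        d = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        curv = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
        grav = np.sum((pts - self.c) ** 2, axis=1)
        ext = _bilinear(self.F, pts)
        return float(self.p.alpha * np.sum((d - self.d_bar) ** 2)
                     + self.p.beta * np.sum(curv ** 2)
                     + self.p.gravity * grav.sum()
                     - self.p.kappa * ext.sum())

    def local(self, pts: np.ndarray, i: int, v: np.ndarray) -> float:
        """Energy of the terms that involve vertex i, with pts[i] := v."""
        n = len(pts)
        get = lambda j: v if j % n == i else pts[j % n]
        e = 0.0
        for j in (i - 1, i):  # spacing terms touching v
            a, b = get(j), get(j + 1)
            e += self.p.alpha * (float(np.linalg.norm(b - a)) - self.d_bar) ** 2
        for j in (i - 1, i, i + 1):  # curvature terms touching v
            cvec = get(j + 1) - 2 * get(j) + get(j - 1)
            e += self.p.beta * float(np.sum(cvec ** 2))
        e += self.p.gravity * float(np.sum((v - self.c) ** 2))
        e -= self.p.kappa * float(_bilinear(self.F, v[None, :])[0])
        return e


_OFFSETS = np.array([(dz, dx) for dz in (-1, 0, 1) for dx in (-1, 0, 1)
                     if not (dz == 0 and dx == 0)], dtype=float)


def evolve_contour(contour: SliceContour, landscape: EnergyLandscape,
                   params: ContourParams | None = None) -> SliceContour:
    """Greedy descent of the snake energy.

    Each pass visits every vertex, tries the 8 one-step moves of a 3x3 pixel
    neighbourhood and accepts the best strictly energy-decreasing move that
    keeps the polygon simple; the run stops when a full pass moves no vertex
    (or at ``max_iters``).  The recorded energy trace is non-increasing by
    construction.
    """
    params = params or ContourParams()
    F = _external_field(landscape, params)
    if landscape.height.sum() > 0:
        center = np.array(ndimage.center_of_mass(landscape.height))
    else:
        center = contour.points_px.mean(axis=0)
    pts = contour.points_px.copy()
    d0 = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    energy = _SnakeEnergy(F, center, float(d0.mean()), params)
    trace = [energy.total(pts)]
    converged = False
    it = 0
    # coarse-to-fine: after the walk stalls at one step size, halve the step
    steps = [params.step_px * 0.5 ** lvl for lvl in range(params.refine_levels + 1)]
    level = 0
    moves = _OFFSETS * steps[level]
    for it in range(1, params.max_iters + 1):
        moved = False
        for i in range(len(pts)):
            e_old = energy.local(pts, i, pts[i])
            prev_v, next_v = pts[i - 1], pts[(i + 1) % len(pts)]
            candidates = []
            for mv in moves:
                v = pts[i] + mv
                # degenerate (near-zero) segments defeat the crossing test
                if (np.linalg.norm(v - prev_v) < params.min_spacing_px
                        or np.linalg.norm(v - next_v) < params.min_spacing_px):
                    continue
                gain = e_old - energy.local(pts, i, v)
                if gain > 1e-12:
                    candidates.append((gain, v))
            candidates.sort(key=lambda gv: -gv[0])
            for gain, v in candidates:
                # fast proper-crossing filter, then an exact simplicity check
                # (the fast test cannot see measure-zero self-touches)
                if not _move_keeps_simple(pts, i, v):
                    continue
                trial = pts.copy()
                trial[i] = v
                if Polygon(trial).is_valid:
                    pts[i] = v
                    moved = True
                    break
        trace.append(energy.total(pts))
        if not moved:
            if level == len(steps) - 1:
                converged = True
                break
            level += 1
            moves = _OFFSETS * steps[level]
    return SliceContour(points_px=pts, slice_index=contour.slice_index,
                        energy_trace=trace, n_iters=it, converged=converged,
                        multi_component=contour.multi_component)


def delineate_volume(
    pmap: ProbabilityMap,
    final_labels: LabelMap,
    sand_params: SandpileParams | None = None,
    contour_params: ContourParams | None = None,
) -> list[Optional[SliceContour]]:
    """Full per-slice delineation: sandpile landscape, then active contour.

    Returns one contour per slice; slices whose landscape retains no sand
    yield ``None``.
    """
    landscapes = build_energy_landscape(pmap, final_labels, sand_params)
    contours: list[Optional[SliceContour]] = []
    for ls in landscapes:
        init = init_contour(ls, contour_params)
        if init is None:
            contours.append(None)
            continue
        contours.append(evolve_contour(init, ls, contour_params))
    return contours


def rasterize_contours(contours: list[Optional[SliceContour]],
                       spatial_shape: tuple[int, int, int],
                       include_boundary: bool = False) -> np.ndarray:
    """Voxelize per-slice contours into a boolean (slice, z, x) mask."""
    mask = np.zeros(spatial_shape, dtype=bool)
    for ct in contours:
        if ct is None:
            continue
        r, c = ct.points_px[:, 0], ct.points_px[:, 1]
        rr, cc = draw_polygon(r, c, shape=spatial_shape[1:])
        mask[ct.slice_index, rr, cc] = True
        if include_boundary:
            rr, cc = polygon_perimeter(r, c, shape=spatial_shape[1:])
            mask[ct.slice_index, rr, cc] = True
    return mask
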