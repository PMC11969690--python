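"""Bifurcation geometry, tortuosity and fractal dimension.

The extension block of the per-eye parameter set is computed in zone C:

* per-bifurcation asymmetry and structure — branching angle BA = θ1 + θ2,
  angle asymmetry AA = θ2 − θ1, branching coefficient BC = (d1² + d2²)/d0²,
  asymmetry ratio AR = (d2/d1)², optimality deviation
  OD = |(d1³ + d2³)^{1/3} − d0| / d0 (relative departure from Murray's
  cube-law optimum), and the junctional exponent deviation JED = x − 3
  where x solves d0^x = d1^x + d2^x;
* tortuosity — simple tortuosity ST = arc/chord and a dimensionless
  curvature tortuosity CT = L · ∫ κ(s)² ds;
* the box-counting fractal dimension FrD of the pooled skeleton.

d0 is the trunk (widest) vessel at a junction, d1 ≥ d2 the daughters, and
θ1 ≤ θ2 the daughter angles measured against the trunk direction continued
through the junction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .graph import GraphNode, VesselGraph, VesselSegment, smooth_centerline

logger = logging.getLogger(__name__)


@dataclass
class Bifurcation:
    """Measured trunk/daughter calibers and daughter angles at one junction."""

    vessel_class: int
    position: tuple[float, float]
    d0: float
    d1: float
    d2: float
    theta1: float
    theta2: float
    zone: str | None = None

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.d1 > 0 and self.d2 > 0):
            raise ValueError("diameters must be positive")
        if self.d1 < self.d2:
            self.d1, self.d2 = self.d2, self.d1
        if self.theta1 > self.theta2:
            self.theta1, self.theta2 = self.theta2, self.theta1
        if not (0 < self.theta1 <= self.theta2 < 180):
            raise ValueError("angles must lie in (0, 180)")


def _oriented(seg: VesselSegment, junction: GraphNode) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed points and widths ordered away from the junction."""
    pts, wid = seg.smooth_points, seg.widths
    d_first = math.hypot(*(seg.points[0] - np.array(junction.position)))
    d_last = math.hypot(*(seg.points[-1] - np.array(junction.position)))
    if d_last < d_first:
        return pts[::-1].copy(), wid[::-1].copy()
    return pts, wid


def _window(pts: np.ndarray, widths: np.ndarray, exclude: float, extent: float):
    """Points/widths with arc position in (exclude, exclude + extent]."""
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    sel = (s > exclude) & (s <= exclude + extent)
    return pts[sel], widths[sel]


def _direction(pts: np.ndarray) -> np.ndarray | None:
    """Unit direction of a point run by least-squares (principal axis)."""
    if len(pts) < 2:
        return None
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def measure_bifurcation(
    graph: VesselGraph, junction: GraphNode, window_factor: float = 2.0,
    border_margin: float = 3.0,
) -> Bifurcation | None:
    """Measure trunk/daughter calibers and branching angles at a junction.

    The trunk is the incident segment with the largest mean width over its
    measurement window; each window starts one local width past the junction
    (junction blobs corrupt both the distance transform and the tangent) and
    extends ``window_factor * d0`` of arc.  Daughter angles are taken between
    each daughter's least-squares direction and the trunk direction continued
    through the junction.  Returns None (logged) when any incident segment is
    too short to host a window, or when a window reaches within
    ``border_margin`` px of the image border — vessels clipped by the field
    of view carry corrupted widths and directions.
    """
    incident = graph.incident(junction.id)
    if len(incident) != 3:
        return None
    oriented = [_oriented(s, junction) for s in incident]
    w_j = max(float(max(w[0], w[-1])) for _, w in oriented)
    w_j = max(w_j, 2.0)
    h, w_img = graph.shape

    # provisional calibers over everything beyond the junction exclusion
    provisional = []
    for pts, wid in oriented:
        _, ww = _window(pts, wid, w_j, np.inf)
        if len(ww) == 0:
            logger.info("bifurcation at %s skipped: segment too short", junction.position)
            return None
        provisional.append(float(np.mean(ww)))
    trunk_idx = int(np.argmax(provisional))
    d0_prov = provisional[trunk_idx]

    diameters, directions = [], []
    for pts, wid in oriented:
        wpts, ww = _window(pts, wid, w_j, window_factor * d0_prov)
        if len(ww) < 3:
            wpts, ww = _window(pts, wid, w_j, np.inf)
        if len(ww) < 2:
            logger.info("bifurcation at %s skipped: window too short", junction.position)
            return None
        if (
            wpts[:, 0].min() < border_margin
            or wpts[:, 1].min() < border_margin
            or wpts[:, 0].max() > h - 1 - border_margin
            or wpts[:, 1].max() > w_img - 1 - border_margin
        ):
            logger.info("bifurcation at %s skipped: window clipped by image border", junction.position)
            return None
        diameters.append(float(np.mean(ww)))
        directions.append(_direction(wpts))
    if any(d is None for d in directions):
        return None

    trunk_dir = directions[trunk_idx]
    continued = -trunk_dir  # trunk direction continued through the junction
    thetas = []
    for i, d in enumerate(directions):
        if i == trunk_idx:
            continue
        cosang = float(np.clip(np.dot(d, continued), -1.0, 1.0))
        thetas.append(math.degrees(math.acos(cosang)))
    daughters = sorted((diameters[i] for i in range(3) if i != trunk_idx), reverse=True)
    if min(thetas) <= 0 or max(thetas) >= 180:
        return None
    return Bifurcation(
        vessel_class=graph.vessel_class,
        position=junction.position,
        d0=diameters[trunk_idx],
        d1=daughters[0],
        d2=daughters[1],
        theta1=min(thetas),
        theta2=max(thetas),
        zone=junction.zone,
    )


def trunk_diameter(graph: VesselGraph, junction: GraphNode) -> float | None:
    """d0 at a junction (convenience for the length-diameter ratio)."""
    b = measure_bifurcation(graph, junction)
    return None if b is None else b.d0


def branching_params(b: Bifurcation) -> tuple[float, float, float, float]:
    """(BA, AA, BC, AR) from measured angles and diameters."""
    ba = b.theta1 + b.theta2
    aa = b.theta2 - b.theta1
    bc = (b.d1**2 + b.d2**2) / b.d0**2
    ar = (b.d2 / b.d1) ** 2
    return ba, aa, bc, ar


def optimality_deviation(b: Bifurcation) -> float:
    """OD = |(d1³ + d2³)^(1/3) − d0| / d0, zero at Murray's optimum."""
    ideal = (b.d1**3 + b.d2**3) ** (1.0 / 3.0)
    return abs(ideal - b.d0) / b.d0


def junctional_exponent(
    d0: float, d1: float, d2: float, bracket: tuple[float, float] = (0.2, 10.0), tol: float = 1e-10
) -> float | None:
    """Solve d0^x = d1^x + d2^x for x by bisection; None when no root exists.

    A finite exponent requires d0 > max(d1, d2); even then the root can fall
    outside the accepted bracket for near-degenerate junctions.
    """
    if d0 <= max(d1, d2):
        return None
    a, b = bracket

    def f(x: float) -> float:
        return (d1 / d0) ** x + (d2 / d0) ** x - 1.0

    fa, fb = f(a), f(b)
    if fa < 0 or fb > 0:  # f is strictly decreasing in x
        return None
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = f(m)
        if abs(fm) < tol:
            return m
        if fm > 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def junctional_exponent_deviation(b: Bifurcation, sign: int = 1) -> float | None:
    """JED = x − 3 (x the junctional exponent); None when x is undefined.

    ``sign=-1`` flips the convention (3 − x) for comparison with tools that
    report the deviation with the opposite orientation.
    """
    x = junctional_exponent(b.d0, b.d1, b.d2)
    if x is None:
        return None
    return sign * (x - 3.0)


def count_first_branches(graph: VesselGraph, zone: str = "C") -> int:
    """Number of first-order vessels entering zone C that bifurcate inside it.

    A first-order vessel is a segment crossing the zone-B/zone-C boundary;
    it counts (once) if any bifurcation reachable on its outer side — without
    re-entering zone B — lies inside zone C.
    """
    if graph.disc is None:
        raise ValueError("graph must have zones assigned")
    disc = graph.disc
    boundary = 1.5 * disc.dd_px

    def radius(p) -> float:
        return math.hypot(p[0] - disc.center[0], p[1] - disc.center[1])

    count = 0
    for seg in graph.segments:
        r = np.hypot(seg.points[:, 0] - disc.center[0], seg.points[:, 1] - disc.center[1])
        if not (r.min() <= boundary < r.max()):
            continue
        # outer end node of the crossing segment
        n0, n1 = (graph.node(i) for i in seg.end_nodes)
        outer = n0 if radius(n0.position) > radius(n1.position) else n1
        # BFS outward through nodes beyond the boundary
        seen_nodes, seen_segs = {outer.id}, {seg.id}
        queue = [outer]
        found = False
        while queue and not found:
            node = queue.pop()
            if node.node_type == "bifurcation" and node.zone == zone:
                found = True
                break
            for s in graph.incident(node.id):
                if s.id in seen_segs:
                    continue
                seen_segs.add(s.id)
                other = s.end_nodes[0] if s.end_nodes[1] == node.id else s.end_nodes[1]
                nxt = graph.node(other)
                if other in seen_nodes or radius(nxt.position) <= boundary:
                    continue
                seen_nodes.add(other)
                queue.append(nxt)
        if found:
            count += 1
    return count


def tortuosity(
    points: np.ndarray, min_points: int = 5, presmoothed: bool = False
) -> tuple[float, float] | None:
    """(ST, CT) of one centerline.

    ST is arc length over chord length (>= 1).  CT is the dimensionless
    curvature tortuosity L * integral(kappa^2 ds), zero for a straight
    vessel; curvature comes from finite differences on the Gaussian-smoothed
    centerline.  Returns None for curves with fewer than ``min_points``.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < min_points:
        return None
    if not presmoothed:
        pts = smooth_centerline(pts)
    d1 = np.gradient(pts, axis=0)
    d2 = np.gradient(d1, axis=0)
    speed = np.linalg.norm(d1, axis=1)
    speed = np.where(speed == 0, 1e-12, speed)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    kappa = np.abs(cross) / speed**3
    ds = speed  # per unit index
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0 or arc == 0:
        return None
    st = arc / chord
    ct = arc * float(np.trapezoid(kappa**2 * ds))
    return st, ct


def zone_runs(seg: VesselSegment, zone: str, min_points: int = 5) -> list[np.ndarray]:
    """Maximal contiguous in-zone point runs of a segment (smoothed coords)."""
    if seg.point_zones is None:
        raise ValueError("segment has no zone labels")
    in_zone = seg.point_zones == zone
    runs, start = [], None
    for i, flag in enumerate(np.append(in_zone, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_points:
                runs.append(seg.smooth_points[start:i])
            start = None
    return runs


def network_tortuosity(graph: VesselGraph, zone: str = "C") -> tuple[float | None, float | None]:
    """Length-weighted mean (ST, CT) over the zone-restricted segments of a class."""
    st_vals, ct_vals, weights = [], [], []
    for seg in graph.segments:
        for run in zone_runs(seg, zone):
            res = tortuosity(run, presmoothed=True)
            if res is None:
                continue
            arc = float(np.sum(np.linalg.norm(np.diff(run, axis=0), axis=1)))
            st_vals.append(res[0])
            ct_vals.append(res[1])
            weights.append(arc)
    if not weights:
        return None, None
    w = np.asarray(weights)
    return (
        float(np.average(st_vals, weights=w)),
        float(np.average(ct_vals, weights=w)),
    )


def fractal_dimension(occupancy: np.ndarray) -> float | None:
    """Box-counting dimension of a binary pattern.

    Boxes are dyadic (2, 4, 8, ... up to min(H, W)/4), anchored at the image
    origin; FrD is minus the slope of the least-squares fit of log N(s)
    against log s.  Returns None for an empty pattern or fewer than 3 usable
    box sizes.
    """
    occ = np.asarray(occupancy, dtype=bool)
    if not occ.any():
        return None
    h, w = occ.shape
    max_size = min(h, w) // 4
    sizes = []
    s = 2
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        return None
    counts = []
    for s in sizes:
        hh = math.ceil(h / s) * s
        ww = math.ceil(w / s) * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = occ
        blocks = padded.reshape(hh // s, s, ww // s, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    slope, _ = np.polyfit(np.log(sizes), np.log(counts), 1)
    return float(-slope)
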