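"""Vessel caliber, density and length-ratio parameters.

This covers the morphology block of the per-eye parameter set: the standard
deviation of the six largest arteriole/venule calibers in zone B (SDa/SDv),
the central retinal artery and vein equivalents (CRAE/CRVE) by the revised
Knudtson pairing formulas, the arteriole-to-venule ratio (AVR), the zone-C
vessel area and length densities (VAD/VLD), and the length-diameter ratio
(LDR) between consecutive bifurcations.

The Knudtson summary combines the six largest vessel calibers pairwise
(largest with smallest, and so on), each pair collapsing to
``k * sqrt(w1^2 + w2^2)`` with k = 0.88 for arterioles and 0.95 for venules,
iterating until a single equivalent trunk caliber remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import VesselGraph, VesselSegment
from .mask import ARTERY, VEIN, DiscSpec, SegmentationMask, zone_annulus

KNUDTSON_K = {ARTERY: 0.88, VEIN: 0.95}


@dataclass
class CaliberSet:
    """Mean zone-B calibers of the largest vessels of one class, descending."""

    vessel_class: int
    calibers: list[float]
    complete: bool  # True when six candidates were available

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.calibers):
            raise ValueError("calibers must be positive")
        self.calibers = sorted(self.calibers, reverse=True)


def interior_width_mask(seg: VesselSegment, graph: VesselGraph) -> np.ndarray:
    """Points of a segment not within one local width of a junction end.

    Junction blobs inflate the distance transform, so caliber statistics
    exclude the first local-width of arc at any end whose node is a
    bifurcation or crossing.
    """
    s = seg.arc_positions()
    keep = np.ones(len(s), dtype=bool)
    for end_idx, node_id in enumerate(seg.end_nodes):
        if graph.node(node_id).node_type == "endpoint":
            continue
        w_local = float(seg.widths[0 if end_idx == 0 else -1])
        w_local = max(w_local, 1.0)
        if end_idx == 0:
            keep &= s > w_local
        else:
            keep &= s < s[-1] - w_local
    return keep


def six_largest(graph: VesselGraph, vessel_class: int | None = None, zone: str = "B", n: int = 6) -> CaliberSet:
    """The six largest mean in-zone calibers of a class, SIVA-style.

    Candidates are segments with at least 5 centerline points inside the
    zone; a candidate's caliber is its mean width over in-zone points with
    junction-adjacent points excluded.  Ties break by longer in-zone length,
    then by segment id.
    """
    vessel_class = graph.vessel_class if vessel_class is None else vessel_class
    candidates: list[tuple[float, float, int]] = []
    for seg in graph.segments:
        if seg.vessel_class != vessel_class or seg.point_zones is None:
            continue
        in_zone = seg.point_zones == zone
        if in_zone.sum() < 5:
            continue
        usable = in_zone & interior_width_mask(seg, graph)
        if not usable.any():
            usable = in_zone
        caliber = float(np.mean(seg.widths[usable]))
        s = seg.arc_positions()
        in_len = float(s[in_zone].max() - s[in_zone].min())
        candidates.append((caliber, in_len, seg.id))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    top = [c for c, _, _ in candidates[:n]]
    return CaliberSet(vessel_class, top, complete=len(candidates) >= n)


def diameter_sd(cal: CaliberSet) -> float | None:
    """Sample standard deviation (n-1) of the caliber set; None below n=2."""
    if len(cal.calibers) < 2:
        return None
    return float(np.std(cal.calibers, ddof=1))


def knudtson_equivalent(cal: CaliberSet) -> float | None:
    """CRAE/CRVE by iterative pairwise Knudtson combination.

    Sort descending, pair the largest with the smallest, the second-largest
    with the second-smallest, etc.; with an odd count the median caliber is
    carried unpaired into the next round; repeat until one value remains.
    """
    values = sorted(cal.calibers, reverse=True)
    if not values:
        return None
    k = KNUDTSON_K[cal.vessel_class]
    while len(values) > 1:
        values.sort(reverse=True)
        nxt = []
        lo, hi = 0, len(values) - 1
        while lo < hi:
            nxt.append(k * math.hypot(values[lo], values[hi]))
            lo += 1
            hi -= 1
        if lo == hi:  # odd count: median carried to the next round
            nxt.append(values[lo])
        values = nxt
    return float(values[0])


def avr(crae: float | None, crve: float | None) -> float | None:
    """Arteriole-to-venule ratio CRAE / CRVE."""
    if crae is None or crve is None:
        return None
    if crae <= 0 or crve <= 0:
        raise ValueError("CRAE and CRVE must be positive")
    return crae / crve


def skeleton_length(skeleton: np.ndarray, within: np.ndarray | None = None) -> float:
    """Polyline length (px) of a 1-px skeleton: unit steps, diagonals sqrt(2).

    Adjacent pixel pairs are counted once each; a diagonal pair that shares
    an orthogonal skeleton neighbor is skipped, since the path runs through
    that neighbor rather than cutting the corner.
    """
    sk = skeleton.astype(bool)
    if within is not None:
        sk = sk & within
    h, w = sk.shape
    length = 0.0
    # orthogonal steps
    length += float(np.sum(sk[:, :-1] & sk[:, 1:]))
    length += float(np.sum(sk[:-1, :] & sk[1:, :]))
    # diagonal steps without an orthogonal shortcut
    for dr, dc in ((1, 1), (1, -1)):
        a = sk[:-1, :-1] if dc == 1 else sk[:-1, 1:]
        b = sk[1:, 1:] if dc == 1 else sk[1:, :-1]
        pair = a & b
        # common orthogonal neighbors of the diagonal pair
        if dc == 1:
            o1 = sk[:-1, 1:]  # (r, c+1)
            o2 = sk[1:, :-1]  # (r+1, c)
        else:
            o1 = sk[:-1, :-1]  # (r, c-1)
            o2 = sk[1:, 1:]  # (r+1, c)
        pair &= ~(o1 | o2)
        length += math.sqrt(2.0) * float(np.sum(pair))
    return length


def vessel_densities(
    mask: SegmentationMask,
    skeletons: dict[int, np.ndarray],
    disc: DiscSpec,
    zone: str = "C",
) -> tuple[float | None, float | None]:
    """(VAD, VLD) in the zone-C annulus, pooling arteries and veins.

    VAD is the fraction of in-annulus pixels carrying any vessel label; VLD
    is the pooled skeleton length per unit annulus area (px^-1).
    """
    annulus = zone_annulus(mask.shape, disc, zone)
    area = float(annulus.sum())
    if area == 0:
        return None, None
    vad = float((mask.vessel_mask & annulus).sum()) / area
    total_len = sum(skeleton_length(sk, within=annulus) for sk in skeletons.values())
    return vad, total_len / area


def length_diameter_ratio(
    graph: VesselGraph,
    measure_trunk,
    zone: str = "C",
    aggregate: str = "mean",
) -> float | None:
    """Mean ratio of inter-bifurcation centerline length to proximal trunk caliber.

    Qualifying segments connect two bifurcation nodes that both lie inside
    the zone; the denominator is the trunk diameter d0 measured at the more
    disc-proximal of the two junctions (``measure_trunk(graph, node) -> d0``).
    """
    if graph.disc is None:
        raise ValueError("graph must have zones assigned")
    ratios = []
    for seg in graph.segments:
        n0, n1 = (graph.node(i) for i in seg.end_nodes)
        if not all(n.node_type == "bifurcation" and n.zone == zone for n in (n0, n1)):
            continue
        r0, r1 = (
            math.hypot(n.position[0] - graph.disc.center[0], n.position[1] - graph.disc.center[1])
            for n in (n0, n1)
        )
        proximal = n0 if r0 <= r1 else n1
        d0 = measure_trunk(graph, proximal)
        if d0 is None or d0 <= 0:
            continue
        ratios.append(seg.arc_length / d0)
    if not ratios:
        return None
    return float(np.median(ratios) if aggregate == "median" else np.mean(ratios))
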