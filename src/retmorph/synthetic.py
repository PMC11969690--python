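"""Ground-truthed synthetic inputs: vessel-tree eyes and patient cohorts.

Two generators stand in for data that clinical studies of this kind cannot
publish:

* **Eyes** — binary-branching artery/vein trees radiating from the optic
  disc.  Daughter calibers follow a power-law branching rule
  (d1^x + d2^x = d0^x with configurable exponent x, Murray's law at x = 3),
  branching angles and asymmetry ratios are drawn from configurable ranges,
  and centerlines are straight paths plus a windowed sinusoidal normal
  displacement.  Every sampled quantity is recorded as ground truth, so the
  whole measurement pipeline can be validated end to end.

* **Cohorts** — patient tables with prescribed Spearman rank correlations
  between vascular parameters and clinical scores, via a Gaussian copula
  (latent Pearson correlation 2·sin(π·ρs/6) for target Spearman ρs),
  normal marginals for continuous variables and quantile-binned ordinal
  marginals for the imaging scores.

Arteries and veins are interleaved angularly so the two classes never cross;
a label-priority rule (artery over vein) resolves any residual overlap at
render time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    branching_params,
    junctional_exponent,
    optimality_deviation,
)
from .mask import ARTERY, VEIN, DiscSpec, SegmentationMask, zone_of_radius

# --------------------------------------------------------------------------
# vessel trees
# --------------------------------------------------------------------------

#: dense centerline sampling step (px)
_STEP = 0.5


@dataclass
class TreeSpec:
    """Parameters of one class's arcade ensemble."""

    vessel_class: int
    n_arcades: int = 6
    root_diameter_px: float = 13.0
    murray_exponent: float = 3.0
    asymmetry_ratio_range: tuple[float, float] = (0.5, 0.9)
    branch_angle_range_deg: tuple[float, float] = (20.0, 45.0)
    inter_branch_length_factor: float = 12.0
    tortuosity_amplitude_px: float = 2.0
    tortuosity_wavelength_px: float = 70.0
    root_diameter_jitter: float = 0.10
    max_depth: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_arcades < 1:
            raise ValueError("n_arcades must be >= 1")
        if not self.root_diameter_px > 0:
            raise ValueError("root_diameter_px must be positive")
        lo, hi = self.asymmetry_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("asymmetry_ratio_range must lie in (0, 1]")
        lo, hi = self.branch_angle_range_deg
        if not (10 < lo <= hi < 90):
            raise ValueError("branch_angle_range_deg must lie in (10, 90)")
        if self.tortuosity_amplitude_px < 0:
            raise ValueError("tortuosity amplitude must be >= 0")
        if self.tortuosity_amplitude_px >= self.tortuosity_wavelength_px / 2:
            raise ValueError("amplitude must be < wavelength/2")


@dataclass
class TrueSegment:
    vessel_class: int
    arcade: int
    depth: int
    points: np.ndarray  # dense (N, 2) centerline
    radius: float  # tube radius (half the diameter), px
    id: int = -1
    parent_id: int | None = None  # segment feeding this one, None at the root

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def st(self) -> float:
        """Analytic-sampling simple tortuosity (arc / chord)."""
        return self.arc_length / self.chord_length


@dataclass
class TrueBifurcation:
    vessel_class: int
    arcade: int
    depth: int
    position: tuple[float, float]
    d0: float
    d1: float
    d2: float
    theta1: float
    theta2: float
    parent_segment: int = -1  # id of the segment terminating at this junction

    def derived(self) -> dict[str, float | None]:
        """BA/AA/BC/AR/OD/JED from the defining formulas, exactly."""
        from .geometry import Bifurcation

        b = Bifurcation(self.vessel_class, self.position, self.d0, self.d1, self.d2,
                        self.theta1, self.theta2)
        ba, aa, bc, ar = branching_params(b)
        x = junctional_exponent(self.d0, self.d1, self.d2)
        return {
            "BA": ba, "AA": aa, "BC": bc, "AR": ar,
            "OD": optimality_deviation(b),
            "JED": None if x is None else x - 3.0,
        }


@dataclass
class GroundTruth:
    segments: list[TrueSegment] = field(default_factory=list)
    bifurcations: list[TrueBifurcation] = field(default_factory=list)

    def nfb(self, disc: DiscSpec, zone: str = "C") -> int:
        """First-order vessels entering the zone that bifurcate inside it.

        Mirrors the measurement definition: a segment crossing the inner
        zone boundary counts once if its downstream subtree contains a
        bifurcation whose junction point lies inside the zone.
        """
        boundary = 1.5 * disc.dd_px
        children: dict[int, list[int]] = {}
        for s in self.segments:
            if s.parent_id is not None:
                children.setdefault(s.parent_id, []).append(s.id)
        bif_at: dict[int, TrueBifurcation] = {b.parent_segment: b for b in self.bifurcations}

        def in_zone(pos) -> bool:
            r = math.hypot(pos[0] - disc.center[0], pos[1] - disc.center[1])
            return zone_of_radius(np.atleast_1d(r), disc.dd_px)[0] == zone

        def subtree_has_bif(seg_id: int) -> bool:
            b = bif_at.get(seg_id)
            if b is not None and in_zone(b.position):
                return True
            return any(subtree_has_bif(c) for c in children.get(seg_id, ()))

        count = 0
        for s in self.segments:
            r = np.hypot(s.points[:, 0] - disc.center[0], s.points[:, 1] - disc.center[1])
            if r.min() <= boundary < r.max() and subtree_has_bif(s.id):
                count += 1
        return count


def _wiggly_path(
    p0: np.ndarray,
    direction: np.ndarray,
    length: float,
    amplitude: float,
    wavelength: float,
    phase: float,
) -> np.ndarray:
    """Straight path plus windowed sinusoidal normal displacement.

    The sin^2 envelope pins both endpoints (value and tangent), so segments
    join smoothly at junctions and the chord direction equals ``direction``.
    """
    n = max(int(round(length / _STEP)), 4)
    s = np.linspace(0.0, length, n + 1)
    normal = np.array([-direction[1], direction[0]])
    disp = amplitude * np.sin(2 * np.pi * s / wavelength + phase) * np.sin(np.pi * s / length) ** 2
    return p0[None, :] + s[:, None] * direction[None, :] + disp[:, None] * normal[None, :]


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _grow(
    spec: TreeSpec,
    rng: np.random.Generator,
    truth: GroundTruth,
    arcade: int,
    p0: np.ndarray,
    direction: np.ndarray,
    diameter: float,
    depth: int,
    parent_id: int | None,
) -> None:
    if diameter < 1.5 or depth > spec.max_depth:
        return
    length = spec.inter_branch_length_factor * diameter
    path = _wiggly_path(
        p0, direction, length,
        spec.tortuosity_amplitude_px, spec.tortuosity_wavelength_px,
        phase=float(rng.uniform(0, 2 * np.pi)),
    )
    seg_id = len(truth.segments)
    truth.segments.append(
        TrueSegment(spec.vessel_class, arcade, depth, path, diameter / 2.0,
                    id=seg_id, parent_id=parent_id)
    )
    if depth == spec.max_depth:
        return

    x = spec.murray_exponent
    ar = float(rng.uniform(*spec.asymmetry_ratio_range))
    d1 = diameter / (1.0 + ar ** (x / 2.0)) ** (1.0 / x)
    d2 = d1 * math.sqrt(ar)
    if d2 < 1.5:
        return  # daughters would be sub-resolution: branch truncates here
    th_small, th_large = sorted(rng.uniform(*spec.branch_angle_range_deg, size=2))
    side = 1.0 if rng.random() < 0.5 else -1.0
    # the larger daughter takes the smaller deflection (Murray-type junction)
    dir1 = _rotate(direction, side * th_small)
    dir2 = _rotate(direction, -side * th_large)
    end = path[-1]
    truth.bifurcations.append(
        TrueBifurcation(
            spec.vessel_class, arcade, depth, (float(end[0]), float(end[1])),
            d0=diameter, d1=d1, d2=d2, theta1=th_small, theta2=th_large,
            parent_segment=seg_id,
        )
    )
    _grow(spec, rng, truth, arcade, end, dir1, d1, depth + 1, seg_id)
    _grow(spec, rng, truth, arcade, end, dir2, d2, depth + 1, seg_id)


def generate_tree(
    spec: TreeSpec,
    rng: np.random.Generator | None = None,
    roots: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> GroundTruth:
    """Grow the arcade ensemble of one vessel class.

    ``roots`` gives an (origin, unit direction) pair per arcade; by default
    arcades fan out from the coordinate origin at evenly spaced azimuths.
    Deterministic given the spec seed (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if roots is None:
        roots = []
        for k in range(spec.n_arcades):
            az = 2 * np.pi * k / spec.n_arcades
            d = np.array([math.sin(az), math.cos(az)])
            roots.append((np.zeros(2), d))
    if len(roots) != spec.n_arcades:
        raise ValueError("roots must have one entry per arcade")
    truth = GroundTruth()
    for arcade, (origin, direction) in enumerate(roots):
        jitter = 1.0 + float(rng.uniform(-spec.root_diameter_jitter, spec.root_diameter_jitter))
        _grow(spec, rng, truth, arcade, np.asarray(origin, float),
              np.asarray(direction, float) / np.linalg.norm(direction),
              spec.root_diameter_px * jitter, depth=1, parent_id=None)
    return truth


def render_eye(
    truths: list[GroundTruth],
    disc: DiscSpec,
    shape: tuple[int, int] = (512, 512),
) -> SegmentationMask:
    """Stamp tree centerlines as disks of local radius into a label image.

    Veins are rendered first and arteries after, so artery overwrites vein
    at any overlap; the disc interior is cleared to background.  The output
    round-trips through mask I/O.
    """
    canvas = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    ordered = sorted(
        (seg for t in truths for seg in t.segments),
        key=lambda s: 0 if s.vessel_class == VEIN else 1,
    )
    for seg in ordered:
        # pixel-center geometry: a tube of radius r covers pixels whose
        # centers lie within r - 1/2, giving a rendered width of ~2r
        r = max(seg.radius - 0.5, 0.5)
        ri = int(math.ceil(r))
        dr, dc = np.mgrid[-ri:ri + 1, -ri:ri + 1]
        disk = (dr**2 + dc**2) <= r**2
        drs, dcs = dr[disk], dc[disk]
        for p in seg.points:
            rr = np.round(p[0]).astype(int) + drs
            cc = np.round(p[1]).astype(int) + dcs
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[keep], cc[keep]] = seg.vessel_class
    # disc interior is never vessel territory in this model
    interior = disc.radii(shape) <= 0.5 * disc.dd_px
    canvas[interior] = 0
    return SegmentationMask(canvas)


@dataclass
class EyeSpec:
    """Convenience bundle: disc frame plus per-class tree specs."""

    shape: tuple[int, int] = (512, 512)
    dd_px: float = 120.0
    artery: TreeSpec = None
    vein: TreeSpec = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artery is None:
            self.artery = TreeSpec(ARTERY, root_diameter_px=12.0, seed=self.seed)
        if self.vein is None:
            # veins are wider; a shorter inter-branch factor keeps their first
            # bifurcations inside the measurable field of view
            self.vein = TreeSpec(VEIN, root_diameter_px=15.0,
                                 inter_branch_length_factor=10.0, seed=self.seed + 1)

    @property
    def disc(self) -> DiscSpec:
        return DiscSpec(center=(self.shape[0] / 2.0, self.shape[1] / 2.0), dd_px=self.dd_px)


def generate_eye(spec: EyeSpec) -> tuple[SegmentationMask, DiscSpec, dict[int, GroundTruth]]:
    """Generate a complete synthetic eye: mask, disc and per-class ground truth.

    Artery and vein arcades are interleaved at alternating azimuths on the
    disc margin, so the two classes do not cross.
    """
    disc = spec.disc
    center = np.array(disc.center)
    n_a, n_v = spec.artery.n_arcades, spec.vein.n_arcades
    total = n_a + n_v
    # alternate classes around the disc while either still has arcades left
    classes = []
    rem = {ARTERY: n_a, VEIN: n_v}
    turn = ARTERY
    for _ in range(total):
        if rem[turn] == 0:
            turn = VEIN if turn == ARTERY else ARTERY
        classes.append(turn)
        rem[turn] -= 1
        turn = VEIN if turn == ARTERY else ARTERY
    roots_a, roots_v = [], []
    for k, cls in enumerate(classes):
        az = 2 * np.pi * k / total
        d = np.array([math.sin(az), math.cos(az)])
        origin = center + 0.5 * disc.dd_px * d
        (roots_a if cls == ARTERY else roots_v).append((origin, d))
    truth_a = generate_tree(spec.artery, np.random.default_rng(spec.artery.seed), roots_a)
    truth_v = generate_tree(spec.vein, np.random.default_rng(spec.vein.seed), roots_v)
    mask = render_eye([truth_v, truth_a], disc, spec.shape)
    return mask, disc, {ARTERY: truth_a, VEIN: truth_v}


def make_junction(
    d0: float,
    d1: float,
    d2: float,
    theta1: float,
    theta2: float,
    vessel_class: int = ARTERY,
    size: int = 256,
    trunk_len: float = 80.0,
    daughter_len: float = 80.0,
    orientation_deg: float = 0.0,
) -> tuple[SegmentationMask, tuple[float, float], TrueBifurcation]:
    """Render a single clean Y-junction with known geometry.

    The trunk runs from the image border toward the center; the two straight
    daughters leave the junction at ``theta1``/``theta2`` on opposite sides
    of the continued trunk direction (the larger daughter on the theta1
    side).  Returns the mask, the junction point and the ground truth.
    """
    center = np.array([size / 2.0, size / 2.0])
    direction = _rotate(np.array([0.0, 1.0]), orientation_deg)
    p0 = center - trunk_len * direction
    truth = GroundTruth()
    trunk = _wiggly_path(p0, direction, trunk_len, 0.0, 50.0, 0.0)
    truth.segments.append(TrueSegment(vessel_class, 0, 1, trunk, d0 / 2.0, id=0))
    for d, th, sgn, sid in ((d1, theta1, 1.0, 1), (d2, theta2, -1.0, 2)):
        ddir = _rotate(direction, sgn * th)
        path = _wiggly_path(center, ddir, daughter_len, 0.0, 50.0, 0.0)
        truth.segments.append(TrueSegment(vessel_class, 0, 2, path, d / 2.0, id=sid, parent_id=0))
    tb = TrueBifurcation(
        vessel_class, 0, 1, (float(center[0]), float(center[1])),
        d0=d0, d1=max(d1, d2), d2=min(d1, d2),
        theta1=min(theta1, theta2), theta2=max(theta1, theta2),
        parent_segment=0,
    )
    truth.bifurcations.append(tb)
    # stamp directly (no disc interior to clear in this fixture)
    canvas = np.zeros((size, size), dtype=np.uint8)
    for seg in truth.segments:
        # pixel-center geometry: a tube of radius r covers pixels whose
        # centers lie within r - 1/2, giving a rendered width of ~2r
        r = max(seg.radius - 0.5, 0.5)
        ri = int(math.ceil(r))
        dr, dc = np.mgrid[-ri:ri + 1, -ri:ri + 1]
        disk = (dr**2 + dc**2) <= r**2
        drs, dcs = dr[disk], dc[disk]
        for p in seg.points:
            rr = np.round(p[0]).astype(int) + drs
            cc = np.round(p[1]).astype(int) + dcs
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[keep], cc[keep]] = seg.vessel_class
    return SegmentationMask(canvas), (float(center[0]), float(center[1])), tb


def recovery_report(mask, disc: DiscSpec, truths: dict[int, "GroundTruth"]) -> dict[int, dict]:
    """Run the measurement pipeline on a rendered eye and score it against truth.

    Measured zone-C bifurcations are matched to ground-truth junctions by
    nearest position (within 8 px); the angle and caliber-ratio errors are
    aggregate differences over the matched population — junctions the
    pipeline correctly declines to measure (e.g. clipped by the image
    border) are validated through NFB and the density terms instead.
    Returns, per class: matched-aggregate errors for BA/AA/BC/AR, the
    relative error of length-weighted ST, measured and true NFB, and the
    matched-junction count.
    """
    from . import graph as gr
    from .geometry import branching_params, count_first_branches, measure_bifurcation, network_tortuosity

    report: dict[int, dict] = {}
    for cls, truth in truths.items():
        skel = gr.skeletonize_class(mask, cls)
        widths = gr.estimate_widths(mask.class_mask(cls), skel)
        g = gr.assign_zones(gr.build_graph(skel, widths, cls), disc)
        measured = [measure_bifurcation(g, n) for n in g.bifurcations()]
        measured = [b for b in measured if b is not None]
        pairs = []
        for tb in truth.bifurcations:
            cands = [
                b for b in measured
                if math.hypot(b.position[0] - tb.position[0], b.position[1] - tb.position[1]) < 8.0
            ]
            if not cands:
                continue
            b = min(cands, key=lambda b: math.hypot(b.position[0] - tb.position[0],
                                                    b.position[1] - tb.position[1]))
            pairs.append((b, tb))
        errs = {}
        for key in ("BA", "AA", "BC", "AR"):
            meas, true = [], []
            for b, tb in pairs:
                ba, aa, bc, ar = branching_params(b)
                meas.append({"BA": ba, "AA": aa, "BC": bc, "AR": ar}[key])
                true.append(tb.derived()[key])
            errs[key] = float(np.mean(meas) - np.mean(true)) if pairs else float("nan")
        st_meas, _ = network_tortuosity(g, zone="C")
        st_true = float(np.average([s.st for s in truth.segments],
                                   weights=[s.arc_length for s in truth.segments]))
        report[cls] = {
            **errs,
            "st_rel_err": abs(st_meas - st_true) / st_true if st_meas else float("nan"),
            "nfb_measured": count_first_branches(g),
            "nfb_true": truth.nfb(disc),
            "n_matched": len(pairs),
        }
    return report


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

#: continuous clinical marginals (mean, sd) for the synthetic disease group
CLINICAL_CONTINUOUS: dict[str, tuple[float, float]] = {
    "age": (38.9, 14.9),
    "onset_age": (7.7, 2.9),
    "alpha_gal": (4.04, 7.27),
    "lyso_gb3": (59.66, 54.26),
    "mssi": (20.5, 11.2),
}

#: ordinal imaging-score ranges (inclusive maxima)
ORDINAL_RANGES: dict[str, int] = {
    "arwmc": 30,
    "fazekas": 3,
    "epvs": 4,
    "mars": 10,
    "lacuna": 5,
    "svds": 4,
    "gca": 15,
}

#: correlation structure the simulator emulates by default: reported
#: vascular-clinical rank correlations plus the inter-variable correlations
#: (imaging scores mutually, biomarker-linked parameters mutually) that any
#: jointly consistent latent model requires.
DEFAULT_SPEARMAN_TARGETS: dict[tuple[str, str], float] = {
    ("STa", "alpha_gal"): -0.459,
    ("NFBa", "alpha_gal"): 0.450,
    ("CRAE", "lyso_gb3"): -0.696,
    ("AVR", "lyso_gb3"): -0.657,
    ("NFBa", "lyso_gb3"): -0.535,
    ("LDRv", "lyso_gb3"): -0.643,
    ("AAv", "mssi"): -0.431,
    ("ARa", "arwmc"): -0.683,
    ("ARa", "fazekas"): -0.673,
    ("ARa", "lacuna"): -0.453,
    ("ARa", "svds"): -0.721,
    ("ARa", "gca"): -0.582,
    ("FrD", "fazekas"): 0.446,
    ("CTv", "lacuna"): 0.482,
    ("VAD", "svds"): 0.580,
    # inter-variable correlations required for joint consistency: imaging
    # scores are mutually correlated, the biomarker-linked vascular
    # parameters are mutually correlated, and each of FrD/CTv/VAD carries
    # the sign its reported imaging-score link implies (see docs/methods.md)
    ("arwmc", "fazekas"): 0.65,
    ("arwmc", "lacuna"): 0.65,
    ("arwmc", "svds"): 0.65,
    ("arwmc", "gca"): 0.65,
    ("fazekas", "lacuna"): 0.65,
    ("fazekas", "svds"): 0.65,
    ("fazekas", "gca"): 0.65,
    ("lacuna", "svds"): 0.65,
    ("lacuna", "gca"): 0.65,
    ("svds", "gca"): 0.65,
    ("CRAE", "AVR"): 0.50,
    ("CRAE", "NFBa"): 0.50,
    ("CRAE", "LDRv"): 0.50,
    ("AVR", "NFBa"): 0.50,
    ("AVR", "LDRv"): 0.50,
    ("NFBa", "LDRv"): 0.50,
    ("STa", "NFBa"): -0.35,
    ("alpha_gal", "lyso_gb3"): -0.50,
    ("alpha_gal", "CRAE"): 0.35,
    ("alpha_gal", "AVR"): 0.35,
    ("alpha_gal", "LDRv"): 0.35,
    ("ARa", "FrD"): -0.40,
    ("ARa", "CTv"): -0.40,
    ("ARa", "VAD"): -0.45,
    ("FrD", "CTv"): 0.30,
    ("FrD", "VAD"): 0.30,
    ("FrD", "arwmc"): 0.30,
    ("FrD", "lacuna"): 0.25,
    ("FrD", "svds"): 0.30,
    ("FrD", "gca"): 0.25,
    ("CTv", "VAD"): 0.30,
    ("CTv", "arwmc"): 0.35,
    ("CTv", "fazekas"): 0.35,
    ("CTv", "svds"): 0.40,
    ("CTv", "gca"): 0.30,
    ("VAD", "arwmc"): 0.40,
    ("VAD", "fazekas"): 0.40,
    ("VAD", "lacuna"): 0.35,
    ("VAD", "gca"): 0.35,
}

#: default missingness rates, matching the observed fixture pattern
DEFAULT_MISSINGNESS: dict[str, float] = {
    "alpha_gal": 5 / 27,
    "lyso_gb3": 12 / 27,
    "mssi": 5 / 27,
    **{k: 5 / 27 for k in ORDINAL_RANGES},
}


_REF_CACHE: dict[str, dict[str, tuple[float, float]]] = {}


def reference_rmp_params(group: str = "fd") -> dict[str, tuple[float, float]]:
    """Default (mean, sd) per vascular parameter from the packaged group table.

    Median/IQR rows are converted to (median, IQR/1.349), the normal-theory
    spread equivalent.
    """
    from importlib.resources import files

    if group in _REF_CACHE:
        return dict(_REF_CACHE[group])
    ref = pd.read_csv(files("retmorph.data").joinpath("rmp_group_reference.csv"))
    prefix = "fd_" if group == "fd" else "ctrl_"
    out = {}
    for _, row in ref.iterrows():
        center = float(row[prefix + "center"])
        if row["summary_type"] == "mean_sd":
            sd = float(row[prefix + "spread_low"])
        else:
            sd = (float(row[prefix + "spread_high"]) - float(row[prefix + "spread_low"])) / 1.349
        out[row["param"]] = (center, max(sd, 1e-6))
    _REF_CACHE[group] = out
    return dict(out)


@dataclass
class CohortSpec:
    n_fd: int = 27
    n_ctrl: int = 27
    rmp_params: dict[str, tuple[float, float]] | None = None
    clinical_params: dict[str, tuple[float, float]] | None = None
    spearman_targets: dict[tuple[str, str], float] | None = None
    missingness: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fd < 3 or self.n_ctrl < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.rmp_params is None:
            self.rmp_params = reference_rmp_params("fd")
        if self.clinical_params is None:
            self.clinical_params = dict(CLINICAL_CONTINUOUS)
        if self.spearman_targets is None:
            self.spearman_targets = dict(DEFAULT_SPEARMAN_TARGETS)
        if self.missingness is None:
            self.missingness = dict(DEFAULT_MISSINGNESS)


class CorrelationError(ValueError):
    """Raised when the implied latent correlation matrix is not PSD."""


def _latent_matrix(variables: list[str], targets: dict[tuple[str, str], float]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(variables)}
    r = np.eye(len(variables))
    for (a, b), rho in targets.items():
        if a not in idx or b not in idx:
            raise KeyError(f"unknown variable in target pair ({a}, {b})")
        if not -1 < rho < 1:
            raise ValueError(f"target Spearman for ({a}, {b}) must be in (-1, 1)")
        pear = 2.0 * math.sin(math.pi * rho / 6.0)
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = pear
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < -1e-8:
        v = vecs[:, 0]
        blame = sorted(
            targets,
            key=lambda p: -abs(v[idx[p[0]]] * v[idx[p[1]]] * targets[p]),
        )[:5]
        raise CorrelationError(
            "implied latent correlation matrix is not positive semi-definite; "
            f"most offending pairs: {blame}"
        )
    return r


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize (disease, control) tables with the requested rank structure.

    Continuous variables get normal marginals at the configured mean/sd;
    imaging scores are quantile-binned onto their ordinal ranges; missingness
    is Bernoulli per variable.  Deterministic given the spec seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    continuous = dict(spec.clinical_params) | {k: v for k, v in spec.rmp_params.items()}
    variables = list(continuous) + list(ORDINAL_RANGES)
    r = _latent_matrix(variables, spec.spearman_targets)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(len(variables)))

    def draw(n: int) -> pd.DataFrame:
        z = rng.standard_normal((n, len(variables))) @ chol.T
        cols = {}
        for j, v in enumerate(variables):
            if v in continuous:
                mu, sd = continuous[v]
                cols[v] = mu + sd * z[:, j]
            else:
                from scipy.stats import norm

                k = ORDINAL_RANGES[v]
                u = norm.cdf(z[:, j])
                cols[v] = np.clip(np.floor(u * (k + 1)), 0, k).astype(float)
        return pd.DataFrame(cols)

    fd = draw(spec.n_fd)
    for v, rate in spec.missingness.items():
        if v in fd and rate > 0:
            fd.loc[rng.random(spec.n_fd) < rate, v] = np.nan
    fd.insert(0, "patient_id", np.arange(1, spec.n_fd + 1))

    ctrl_rmp = reference_rmp_params("ctrl") if spec.rmp_params == reference_rmp_params("fd") else spec.rmp_params
    zc = rng.standard_normal((spec.n_ctrl, len(ctrl_rmp)))
    ctrl = pd.DataFrame(
        {p: mu + sd * zc[:, j] for j, (p, (mu, sd)) in enumerate(ctrl_rmp.items())}
    )
    ctrl.insert(0, "patient_id", np.arange(1, spec.n_ctrl + 1))
    ctrl["age"] = spec.clinical_params["age"][0] + spec.clinical_params["age"][1] * rng.standard_normal(spec.n_ctrl)
    return fd, ctrl
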