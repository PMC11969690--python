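"""Bifurcation geometry, tortuosity and fractal dimension."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retmorph as rm
from retmorph.geometry import (
    Bifurcation,
    branching_params,
    count_first_branches,
    fractal_dimension,
    junctional_exponent,
    junctional_exponent_deviation,
    measure_bifurcation,
    optimality_deviation,
    tortuosity,
)
from retmorph.mask import DiscSpec
from retmorph.synthetic import EyeSpec, TreeSpec, generate_eye, make_junction


def _measure_y(d0, d1, d2, th1, th2, orientation=0.0):
    mask, _, tb = make_junction(d0, d1, d2, th1, th2, orientation_deg=orientation)
    skel = rm.skeletonize_class(mask, rm.ARTERY)
    wmap = rm.estimate_widths(mask.class_mask(rm.ARTERY), skel)
    g = rm.assign_zones(rm.build_graph(skel, wmap, rm.ARTERY), DiscSpec((128.0, 128.0), 64.0))
    bifs = g.bifurcations()
    assert len(bifs) == 1
    return measure_bifurcation(g, bifs[0]), tb


class TestMeasureBifurcation:
    def test_known_y_recovered(self):
        b, tb = _measure_y(10, 8, 6, 30, 45)
        assert b is not None
        assert b.d0 == pytest.approx(10, abs=1.0)
        assert b.d1 == pytest.approx(8, abs=1.0)
        assert b.d2 == pytest.approx(6, abs=1.0)
        assert b.theta1 == pytest.approx(30, abs=5.0)
        assert b.theta2 == pytest.approx(45, abs=5.0)

    def test_symmetric_y(self):
        b, _ = _measure_y(12, 9.52, 9.52, 35, 35)
        assert b is not None
        assert abs(b.d1 - b.d2) / b.d1 < 0.05
        assert abs(b.theta1 - b.theta2) < 3.0

    def test_tiny_daughter_stub_skipped(self):
        # a few-px daughter stub is a spur: pruning removes it and no
        # measurable junction remains (or measurement declines gracefully)
        from retmorph.mask import SegmentationMask
        from retmorph.synthetic import GroundTruth, TrueSegment, _wiggly_path, render_eye

        center = np.array([128.0, 128.0])
        trunk = _wiggly_path(np.array([128.0, 40.0]), np.array([0.0, 1.0]), 88.0, 0.0, 50.0, 0.0)
        daughter = _wiggly_path(center, np.array([0.5, 0.866]), 80.0, 0.0, 50.0, 0.0)
        stub = _wiggly_path(center, np.array([-0.5, 0.866]), 4.0, 0.0, 50.0, 0.0)
        truth = GroundTruth(segments=[
            TrueSegment(rm.ARTERY, 0, 1, trunk, 5.0, id=0),
            TrueSegment(rm.ARTERY, 0, 2, daughter, 4.0, id=1),
            TrueSegment(rm.ARTERY, 0, 2, stub, 1.5, id=2),
        ])
        mask = render_eye([truth], DiscSpec((5.0, 5.0), 4.0), (256, 256))
        skel = rm.skeletonize_class(mask, rm.ARTERY)
        wmap = rm.estimate_widths(mask.class_mask(rm.ARTERY), skel)
        g = rm.build_graph(skel, wmap, rm.ARTERY)
        for node in g.bifurcations():
            measure_bifurcation(g, node)  # must not raise
        assert len(g.bifurcations()) == 0

    def test_rotation_invariance_of_measured_angles(self):
        results = []
        for ori in (0.0, 90.0, 180.0, 270.0):
            b, _ = _measure_y(10, 8, 6, 30, 45, orientation=ori)
            assert b is not None
            results.append((b.theta1, b.theta2))
        arr = np.array(results)
        assert np.ptp(arr[:, 0]) < 3.0 and np.ptp(arr[:, 1]) < 3.0


class TestBranchingParams:
    def test_direct_formulas(self):
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 8, 6, 30, 45)
        ba, aa, bc, ar = branching_params(b)
        assert ba == 75 and aa == 15
        assert bc == pytest.approx(1.00) and ar == pytest.approx(0.5625)

    def test_symmetric(self):
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 7, 7, 40, 40)
        _, aa, _, ar = branching_params(b)
        assert aa == 0 and ar == 1

    @given(st.floats(1.1, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        b1 = Bifurcation(rm.ARTERY, (0, 0), 10, 8, 6, 30, 45)
        b2 = Bifurcation(rm.ARTERY, (0, 0), 10 * k, 8 * k, 6 * k, 30, 45)
        _, _, bc1, ar1 = branching_params(b1)
        _, _, bc2, ar2 = branching_params(b2)
        assert bc2 == pytest.approx(bc1) and ar2 == pytest.approx(ar1)
        assert optimality_deviation(b2) == pytest.approx(optimality_deviation(b1))
        assert junctional_exponent_deviation(b2) == pytest.approx(junctional_exponent_deviation(b1), abs=1e-6)


class TestOptimalityDeviation:
    def test_murray_exact_is_zero(self):
        d0 = (8.0**3 + 6.0**3) ** (1 / 3)
        b = Bifurcation(rm.ARTERY, (0, 0), d0, 8, 6, 30, 45)
        assert optimality_deviation(b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 8, 6, 30, 45)
        assert optimality_deviation(b) == pytest.approx(0.1004, abs=2e-4)


class TestJunctionalExponent:
    def test_pythagorean_triple(self):
        assert junctional_exponent(10, 8, 6) == pytest.approx(2.0, abs=1e-6)
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 8, 6, 30, 45)
        assert junctional_exponent_deviation(b) == pytest.approx(-1.0, abs=1e-6)

    def test_murray_exact_zero(self):
        d0 = (8.0**3 + 6.0**3) ** (1 / 3)
        b = Bifurcation(rm.ARTERY, (0, 0), d0, 8, 6, 30, 45)
        assert junctional_exponent_deviation(b) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_bracket_missing(self):
        # equal daughters at 9.8: x = ln2/ln(10/9.8) = 34.3, beyond the bracket
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 9.8, 9.8, 30, 45)
        assert junctional_exponent_deviation(b) is None

    def test_trunk_not_widest_missing(self):
        assert junctional_exponent(8, 9, 3) is None

    def test_sign_flip(self):
        b = Bifurcation(rm.ARTERY, (0, 0), 10, 8, 6, 30, 45)
        assert junctional_exponent_deviation(b, sign=-1) == pytest.approx(1.0, abs=1e-6)


class TestTortuosity:
    def test_straight_segment(self):
        pts = np.column_stack([np.linspace(0, 100, 201), np.zeros(201)])
        st_, ct = tortuosity(pts)
        assert st_ == pytest.approx(1.0, abs=1e-9)
        assert ct == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_closed_form(self):
        t = np.linspace(0, np.pi, 1000)
        pts = np.column_stack([100 * np.sin(t), 100 - 100 * np.cos(t)])
        st_, ct = tortuosity(pts)
        assert st_ == pytest.approx(np.pi / 2, rel=0.005)
        assert ct == pytest.approx(np.pi**2, rel=0.015)

    def test_sinusoid_matches_quadrature_and_ct_monotone(self):
        from scipy.integrate import quad

        lam, length = 50.0, 200.0
        cts = []
        for a in (2.0, 4.0, 6.0):
            x = np.linspace(0, length, 2000)
            pts = np.column_stack([x, a * np.sin(2 * np.pi * x / lam)])
            st_, ct = tortuosity(pts)
            arc = quad(lambda u: math.hypot(1.0, a * 2 * np.pi / lam * math.cos(2 * np.pi * u / lam)),
                       0, length, limit=200)[0]
            assert st_ == pytest.approx(arc / length, rel=0.02)
            cts.append(ct)
        assert cts[0] < cts[1] < cts[2]

    def test_short_curve_excluded(self):
        assert tortuosity(np.zeros((4, 2))) is None

    @given(st.floats(0, 2 * np.pi), st.floats(0.5, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_and_scale_invariance(self, angle, scale):
        t = np.linspace(0, np.pi, 400)
        pts = np.column_stack([50 * np.sin(t), 50 - 50 * np.cos(t)])
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        pts2 = scale * pts @ rot.T + np.array([17.0, -4.0])
        st1, ct1 = tortuosity(pts)
        st2, ct2 = tortuosity(pts2)
        assert st2 == pytest.approx(st1, rel=1e-6)
        assert ct2 == pytest.approx(ct1, rel=0.02)


class TestFractalDimension:
    def test_line(self):
        occ = np.zeros((512, 512), bool)
        occ[256, :] = True
        assert 0.95 <= fractal_dimension(occ) <= 1.05

    def test_filled_plane(self):
        assert 1.9 <= fractal_dimension(np.ones((512, 512), bool)) <= 2.05

    def test_sierpinski_depth7(self):
        s = np.array([[True]])
        for _ in range(7):
            z = np.zeros_like(s)
            s = np.block([[s, s], [s, z]])
        assert fractal_dimension(s) == pytest.approx(math.log(3) / math.log(2), abs=0.05)

    def test_degenerate_inputs(self):
        assert fractal_dimension(np.zeros((64, 64), bool)) is None
        assert fractal_dimension(np.ones((8, 8), bool)) is None  # < 3 box sizes

    def test_tree_depth_monotonicity(self):
        frds = {}
        for depth in (2, 6):
            spec = EyeSpec(
                seed=11,
                artery=TreeSpec(rm.ARTERY, root_diameter_px=12.0, max_depth=depth,
                                inter_branch_length_factor=6.0, seed=11),
                vein=TreeSpec(rm.VEIN, root_diameter_px=14.0, max_depth=depth,
                              inter_branch_length_factor=6.0, seed=12),
            )
            mask, disc, _ = generate_eye(spec)
            from retmorph.mask import zone_annulus

            skels = rm.skeletonize_class(mask, rm.ARTERY) | rm.skeletonize_class(mask, rm.VEIN)
            frds[depth] = fractal_dimension(skels & zone_annulus(mask.shape, disc, "C"))
        assert frds[6] > frds[2]


class TestCountFirstBranches:
    def test_default_eye_exact(self, zoned_graphs, default_eye):
        _, disc, truths = default_eye
        for cls, g in zoned_graphs.items():
            assert count_first_branches(g) == truths[cls].nfb(disc) == 6

    def test_all_bifurcations_in_zone_b_gives_zero(self):
        spec = EyeSpec(
            seed=2,
            artery=TreeSpec(rm.ARTERY, root_diameter_px=12.0, max_depth=2,
                            inter_branch_length_factor=6.0, seed=2),
            vein=TreeSpec(rm.VEIN, root_diameter_px=14.0, max_depth=2,
                          inter_branch_length_factor=6.0, seed=3),
        )
        mask, disc, truths = generate_eye(spec)
        for cls in (rm.ARTERY, rm.VEIN):
            # all junctions land in zone B (radius 60 + ~6*d < 180)
            for b in truths[cls].bifurcations:
                r = math.hypot(b.position[0] - disc.center[0], b.position[1] - disc.center[1])
                assert r <= 1.5 * disc.dd_px
            skel = rm.skeletonize_class(mask, cls)
            wmap = rm.estimate_widths(mask.class_mask(cls), skel)
            g = rm.assign_zones(rm.build_graph(skel, wmap, cls), disc)
            assert count_first_branches(g) == 0

    def test_multiple_zone_c_bifurcations_count_once(self):
        # single arcade bifurcating twice inside zone C counts one entry
        spec = EyeSpec(
            seed=4,
            artery=TreeSpec(rm.ARTERY, n_arcades=1, root_diameter_px=12.0, max_depth=3,
                            inter_branch_length_factor=10.5, branch_angle_range_deg=(20.0, 30.0),
                            seed=4),
            vein=TreeSpec(rm.VEIN, n_arcades=1, root_diameter_px=1.6, max_depth=1, seed=5),
        )
        mask, disc, truths = generate_eye(spec)
        truth = truths[rm.ARTERY]
        n_in_c = sum(
            1.5 * disc.dd_px < math.hypot(b.position[0] - disc.center[0], b.position[1] - disc.center[1]) <= 2.5 * disc.dd_px
            for b in truth.bifurcations
        )
        assert n_in_c >= 2
        skel = rm.skeletonize_class(mask, rm.ARTERY)
        wmap = rm.estimate_widths(mask.class_mask(rm.ARTERY), skel)
        g = rm.assign_zones(rm.build_graph(skel, wmap, rm.ARTERY), disc)
        assert count_first_branches(g) == 1


class TestParameterRecovery:
    def test_fifty_junction_mean_absolute_errors(self):
        rng = np.random.default_rng(42)
        errs = {"BA": [], "AA": [], "BC": [], "AR": []}
        measured = 0
        for _ in range(50):
            d0 = rng.uniform(9, 14)
            ar = rng.uniform(0.5, 0.9)
            d1 = d0 / (1 + ar**1.5) ** (1 / 3)
            d2 = d1 * math.sqrt(ar)
            th1, th2 = sorted(rng.uniform(20, 45, 2))
            mask, _, tb = make_junction(d0, d1, d2, th1, th2, orientation_deg=rng.uniform(0, 360))
            skel = rm.skeletonize_class(mask, rm.ARTERY)
            wmap = rm.estimate_widths(mask.class_mask(rm.ARTERY), skel)
            g = rm.assign_zones(rm.build_graph(skel, wmap, rm.ARTERY), DiscSpec((128.0, 128.0), 64.0))
            bifs = g.bifurcations()
            if len(bifs) != 1:
                continue
            b = measure_bifurcation(g, bifs[0])
            if b is None:
                continue
            measured += 1
            truth = tb.derived()
            ba, aa, bc, arr = branching_params(b)
            errs["BA"].append(abs(ba - truth["BA"]))
            errs["AA"].append(abs(aa - truth["AA"]))
            errs["BC"].append(abs(bc - truth["BC"]))
            errs["AR"].append(abs(arr - truth["AR"]))
        assert measured >= 45
        assert np.mean(errs["BA"]) <= 5.0
        assert np.mean(errs["AA"]) <= 5.0
        assert np.mean(errs["BC"]) <= 0.15
        assert np.mean(errs["AR"]) <= 0.15
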