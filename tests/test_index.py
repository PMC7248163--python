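import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facesym.errors import AnalysisError, ValidationError
from facesym.index import (
    PROFILE_ORDER,
    AsymmetryProfile,
    AsymmetryResult,
    bilateral_index,
    compute_profile,
    midsagittal_index,
    read_profile,
)
from facesym.landmarks import Point3
from facesym.synthetic import TEMPLATE_POINTS, mirror, template

from conftest import make_set, perturb_points, random_rigid, transform_points
from oracles import bilateral_oracle, midsagittal_oracle

# Frozen oracle values: computed by hand-evaluated distance arithmetic
# (tests/oracles.py) before the implementation existed.
OR_L_PLUS3_INDEX = 4.1038671497513155     # Or(L) (35,65,15) -> (38,65,15)
GO_L_DOWN6_INDEX = 8.617745363892002      # Go(L) (50,5,-80) -> (50,5,-86)
ME_PLUS6_INDEX = 6.707756754140476        # Me (0,70,-100) -> (6,70,-100)
ME_PLUS6_DZ = -4.049530497681474
ME_PLUS6_DPO = -5.347457659585984


def displaced(key, xyz):
    points = dict(TEMPLATE_POINTS)
    points[key] = xyz
    return make_set(points)


class TestBilateralIndex:
    def test_symmetric_template_is_zero(self, template_set):
        for name in ("Or", "Co", "Go", "U6", "L6"):
            r = bilateral_index(template_set, name)
            assert r.magnitude == pytest.approx(0.0, abs=1e-12)
            assert r.direction == "none"
            assert r.signed_value == 0.0

    def test_or_left_shift_worked_example(self):
        r = bilateral_index(displaced(("Or", "L"), (38, 65, 15)), "Or")
        assert r.magnitude == pytest.approx(OR_L_PLUS3_INDEX, abs=1e-9)
        assert r.direction == "left"
        assert r.signed_value == pytest.approx(OR_L_PLUS3_INDEX, abs=1e-9)

    def test_go_vertical_shift_no_transverse_deviation(self):
        r = bilateral_index(displaced(("Go", "L"), (50, 5, -86)), "Go")
        assert r.magnitude == pytest.approx(GO_L_DOWN6_INDEX, abs=1e-9)
        assert r.direction == "none"  # perpendicular distances stay 50 vs 50
        assert r.signed_value == pytest.approx(GO_L_DOWN6_INDEX, abs=1e-9)

    def test_right_shift_gives_negative_sign(self):
        r = bilateral_index(displaced(("Or", "R"), (-38, 65, 15)), "Or")
        assert r.magnitude == pytest.approx(OR_L_PLUS3_INDEX, abs=1e-9)
        assert r.direction == "right"
        assert r.signed_value == pytest.approx(-OR_L_PLUS3_INDEX, abs=1e-9)

    def test_components_enter_sum_of_squares(self):
        r = bilateral_index(displaced(("Or", "L"), (38, 65, 15)), "Or")
        assert len(r.components) == 3
        assert r.magnitude == pytest.approx(
            float(np.sqrt(np.sum(np.square(r.components)))), abs=1e-12
        )

    def test_midline_landmark_rejected(self, template_set):
        with pytest.raises(AnalysisError, match="not a bilateral"):
            bilateral_index(template_set, "Me")

    def test_missing_pair_rejected(self):
        points = {k: v for k, v in TEMPLATE_POINTS.items() if k[0] != "Or"}
        with pytest.raises(ValidationError, match="Or"):
            bilateral_index(make_set(points), "Or")


class TestMidsagittalIndex:
    def test_template_me_is_zero(self, template_set):
        r = midsagittal_index(template_set, "Me")
        assert r.magnitude == pytest.approx(0.0, abs=1e-12)
        assert r.direction == "none"

    def test_me_left_shift_worked_example(self):
        r = midsagittal_index(displaced(("Me", "M"), (6, 70, -100)), "Me")
        assert r.magnitude == pytest.approx(ME_PLUS6_INDEX, abs=1e-9)
        assert r.direction == "left"
        assert r.components[0] == pytest.approx(ME_PLUS6_DZ, abs=1e-9)
        assert r.components[1] == pytest.approx(ME_PLUS6_DPO, abs=1e-9)

    def test_mirrored_shift_is_right_with_same_magnitude(self):
        r = midsagittal_index(displaced(("Me", "M"), (-6, 70, -100)), "Me")
        assert r.magnitude == pytest.approx(ME_PLUS6_INDEX, abs=1e-9)
        assert r.direction == "right"
        assert r.signed_value == pytest.approx(-ME_PLUS6_INDEX, abs=1e-9)

    def test_bilateral_landmark_rejected(self, template_set):
        with pytest.raises(AnalysisError, match="not a midline"):
            midsagittal_index(template_set, "Go")

    def test_monotone_in_transverse_displacement(self):
        mags = []
        for delta in range(0, 16):
            r = midsagittal_index(displaced(("Me", "M"), (float(delta), 70, -100)), "Me")
            mags.append(r.magnitude)
        assert mags[0] == pytest.approx(0.0, abs=1e-12)
        assert all(b > a for a, b in zip(mags, mags[1:]))


class TestComputeProfile:
    def test_symmetric_template_all_zero(self, template_set):
        profile = compute_profile(template_set)
        assert profile.landmarks() == list(PROFILE_ORDER)
        for r in profile:
            assert r.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_partial_set_only_me(self):
        keys = [("N", "M"), ("S", "M"), ("Z", "L"), ("Z", "R"),
                ("Po", "L"), ("Po", "R"), ("Me", "M")]
        profile = compute_profile(make_set({k: TEMPLATE_POINTS[k] for k in keys}))
        assert profile.landmarks() == ["Me"]

    def test_locality_of_displacements(self):
        points = dict(TEMPLATE_POINTS)
        points[("Me", "M")] = (6, 70, -100)
        points[("Or", "L")] = (38, 65, 15)
        profile = compute_profile(make_set(points))
        nonzero = {r.landmark for r in profile if r.magnitude > 1e-9}
        assert nonzero == {"Me", "Or"}
        assert profile.get("Me").magnitude == pytest.approx(ME_PLUS6_INDEX, abs=1e-9)
        assert profile.get("Or").magnitude == pytest.approx(OR_L_PLUS3_INDEX, abs=1e-9)


class TestOracleEquivalence:
    def test_100_random_sets_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            points = perturb_points(rng, scale=5.0)
            lm_set = make_set(points)
            for name in ("Or", "Co", "Go", "U6", "L6"):
                mag, direction = bilateral_oracle(points, name)
                r = bilateral_index(lm_set, name)
                assert r.magnitude == pytest.approx(mag, abs=1e-9)
                assert r.direction == direction
            for name in ("ANS", "U1", "L1", "B", "Me"):
                mag, direction = midsagittal_oracle(points, name)
                r = midsagittal_index(lm_set, name)
                assert r.magnitude == pytest.approx(mag, abs=1e-9)
                assert r.direction == direction


class TestInvariances:
    def test_rigid_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            points = perturb_points(rng, scale=4.0)
            base = compute_profile(make_set(points))
            for _ in range(5):
                moved = compute_profile(make_set(transform_points(points, random_rigid(rng))))
                for r0, r1 in zip(base, moved):
                    assert r1.magnitude == pytest.approx(r0.magnitude, abs=1e-6)
                    assert r1.direction == r0.direction

    def test_label_swap_negates_signed_values(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            points = perturb_points(rng, scale=4.0)
            swapped = {(n, {"L": "R", "R": "L", "M": "M"}[s]): xyz
                       for (n, s), xyz in points.items()}
            p0 = compute_profile(make_set(points))
            p1 = compute_profile(make_set(swapped))
            for r0, r1 in zip(p0, p1):
                assert r1.magnitude == pytest.approx(r0.magnitude, abs=1e-9)
                assert r1.signed_value == pytest.approx(-r0.signed_value, abs=1e-9)
                assert {("left", "right"), ("right", "left"), ("none", "none")} >= {
                    (r0.direction, r1.direction)
                }

    def test_mirror_negates_profiles(self):
        # Pure reflection across the reference plane preserves every
        # distance and perpendicular-distance magnitude, so it is the
        # identity on the profile; the L/R relabelling then negates all
        # signed values.  A mirrored face deviates the other way.
        rng = np.random.default_rng(8)
        flip = {"left": "right", "right": "left", "none": "none"}
        for _ in range(5):
            lm_set = make_set(perturb_points(rng, scale=4.0))
            p0 = compute_profile(lm_set)
            p1 = compute_profile(mirror(lm_set))
            for r0, r1 in zip(p0, p1):
                assert r1.magnitude == pytest.approx(r0.magnitude, abs=1e-6)
                assert r1.direction == flip[r0.direction]
                assert r1.signed_value == pytest.approx(-r0.signed_value, abs=1e-6)

    def test_pure_reflection_without_relabel_is_identity(self):
        rng = np.random.default_rng(18)
        swap = {"L": "R", "R": "L", "M": "M"}
        for _ in range(5):
            lm_set = make_set(perturb_points(rng, scale=4.0))
            # mirror() reflects and relabels; relabelling again isolates
            # the pure reflection.
            reflected_only = make_set({
                (n, swap[s]): p.as_tuple()
                for (n, s), p in mirror(lm_set).points.items()
            })
            p0 = compute_profile(lm_set)
            p1 = compute_profile(reflected_only)
            for r0, r1 in zip(p0, p1):
                assert r1.magnitude == pytest.approx(r0.magnitude, abs=1e-6)
                assert r1.direction == r0.direction
                assert r1.signed_value == pytest.approx(r0.signed_value, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(k=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
    def test_scaling_scales_magnitudes(self, k, seed):
        rng = np.random.default_rng(seed)
        points = perturb_points(rng, scale=4.0)
        center = rng.uniform(-50, 50, 3)
        scaled = {
            key: tuple(center + k * (np.asarray(xyz, float) - center))
            for key, xyz in points.items()
        }
        p0 = compute_profile(make_set(points))
        p1 = compute_profile(make_set(scaled))
        for r0, r1 in zip(p0, p1):
            assert r1.magnitude == pytest.approx(k * r0.magnitude, rel=1e-9, abs=1e-9)

    def test_bilateral_zero_iff_coincident_or_mirror(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            points = perturb_points(rng, scale=4.0)
            # Case A: right point made coincident with left -> zero index.
            a = dict(points)
            a[("Or", "R")] = a[("Or", "L")]
            assert bilateral_index(make_set(a), "Or").magnitude < 1e-9
            # Case B: right point = mirror of left across the reference
            # plane -> equidistant from all 3 references -> zero index.
            b = dict(points)
            from facesym.geometry import plane_from_points, signed_plane_distance
            from facesym.landmarks import derive_midz
            s = make_set(b)
            plane = plane_from_points(
                s.get("N"), s.get("S"), derive_midz(s),
                left_witness=s.get("Z", "L"), fallback_witness=s.get("Po", "L"))
            pl = np.asarray(b[("Or", "L")], float)
            d = signed_plane_distance(plane, Point3(*pl))
            b[("Or", "R")] = tuple(pl - 2 * d * np.asarray(plane.normal))
            assert bilateral_index(make_set(b), "Or").magnitude < 1e-9
            # Case C: generic perturbed right point -> nonzero.
            c = dict(points)
            c[("Or", "R")] = tuple(np.asarray(c[("Or", "R")], float) + (1.0, 2.0, 0.5))
            assert bilateral_index(make_set(c), "Or").magnitude > 1e-6


class TestProfileSerialization:
    @pytest.fixture
    def profile(self):
        points = dict(TEMPLATE_POINTS)
        points[("Me", "M")] = (6, 70, -100)
        points[("Or", "R")] = (-38, 65, 15)
        return compute_profile(make_set(points, subject="s1", timepoint="pre"))

    def test_json_round_trip(self, profile):
        again = read_profile(profile.to_json(), format="json")
        assert again.landmarks() == profile.landmarks()
        for r0, r1 in zip(profile, again):
            assert r1.magnitude == pytest.approx(r0.magnitude, abs=1e-12)
            assert r1.direction == r0.direction
            assert tuple(r1.components) == pytest.approx(tuple(r0.components), abs=1e-12)

    def test_csv_round_trip_preserves_signed_values(self, profile):
        again = read_profile(profile.to_csv(), format="csv")
        for r0, r1 in zip(profile, again):
            assert r1.signed_value == pytest.approx(r0.signed_value, abs=1e-12)

    def test_duplicate_landmark_rejected(self):
        r = AsymmetryResult("Me", 1.0, "left", (1.0,))
        with pytest.raises(ValueError, match="duplicate"):
            AsymmetryProfile(results=[r, r])

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            AsymmetryResult("Me", 1.0, "up", (1.0,))
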