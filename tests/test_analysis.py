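"""Fork-frame geometry, angles, contacts, survival curves, spatial densities
and the recycling classifier."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import forkcg
from forkcg.analysis import (ClassifierThresholds, ForkFrame, SurvivalCurve,
                             association_survival, circular_mean_sd,
                             classify_recycling, contact_timeseries,
                             define_fork_frame, dyad_distance_nt,
                             junction_distance_3d, orientation_angles,
                             region_overlap_fraction,
                             residue_contact_probability, spatial_density)
from forkcg.dynamics import Trajectory


def _traj(frames):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames, np.arange(1, len(frames) + 1))


def _ring_coords(n=24, radius=10.0):
    a = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.stack([radius * np.cos(a), radius * np.sin(a),
                     np.zeros(n)], axis=1)


class TestContacts:
    def test_fixed_pair_counts_one_every_frame(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 5.0
        counts, sets = contact_timeseries(_traj(frames), [0], [1], 10.0)
        np.testing.assert_array_equal(counts, 1)
        assert all(list(s) == [0] for s in sets)

    def test_all_beyond_cutoff_zero(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 50.0
        counts, _ = contact_timeseries(_traj(frames), [0], [1], 10.0)
        np.testing.assert_array_equal(counts, 0)

    def test_scripted_approach_is_monotone_until_plateau(self):
        """Beads approaching a target one by one give a non-decreasing
        count that plateaus once all are inside the cutoff."""
        n_frames, n_beads = 30, 6
        frames = np.zeros((n_frames, n_beads + 1, 3))
        for f in range(n_frames):
            for b in range(n_beads):
                start = 50.0 - 2.0 * f + 3.0 * b
                frames[f, b, 0] = max(start, 2.0)
        counts, _ = contact_timeseries(_traj(frames), list(range(n_beads)),
                                       [n_beads], 10.0)
        diffs = np.diff(counts)
        assert np.all(diffs >= 0)
        assert counts[-1] == n_beads

    def test_residue_contact_probability_exact_fractions(self):
        frames = np.zeros((10, 3, 3))
        frames[:, 1, 0] = 50.0          # never in contact
        frames[5:, 2, 0] = 50.0         # contact in first half only
        p = residue_contact_probability([_traj(frames)], [1, 2], [0], 10.0)
        np.testing.assert_allclose(p, [0.0, 0.5])


class TestSurvival:
    def test_single_unbroken_episode(self):
        frames = np.zeros((100, 2, 3))
        frames[:, 1, 0] = 5.0
        s = association_survival([_traj(frames)], [0], [1], 10.0)
        assert s.survival[0] == 1.0
        assert s.survival[100] == 1.0
        assert s.survival[101] == 0.0
        assert np.all(np.diff(s.survival) <= 0)

    def test_gap_merging(self):
        dist = np.full(30, 5.0)
        dist[10:12] = 50.0  # 2-frame interruption
        frames = np.zeros((30, 2, 3))
        frames[:, 1, 0] = dist
        merged = association_survival([_traj(frames)], [0], [1], 10.0,
                                      min_gap_frames=3)
        split = association_survival([_traj(frames)], [0], [1], 10.0)
        assert len(merged.episodes) == 1 and merged.episodes[0] == 30
        assert len(split.episodes) == 2

    def test_no_contact_flagged_undefined(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 100.0
        s = association_survival([_traj(frames)], [0], [1], 10.0)
        assert not s.defined and len(s.episodes) == 0

    def test_exponential_durations_mean_recovered(self):
        """Survival of exponential episodes: fitted mean within 10% of 1/λ."""
        rng = np.random.default_rng(8)
        lam = 0.1
        durations = np.maximum(1, rng.exponential(1 / lam, 500).astype(int))
        episodes = []
        curve = SurvivalCurve(None, None, durations)
        assert durations.mean() == pytest.approx(1 / lam, rel=0.10)


class TestForkFrame:
    def test_planar_ring_axes(self):
        coords = np.vstack([_ring_coords(), [[15.0, 0.0, 0.0]]])
        fr = define_fork_frame(coords, np.arange(24), [24])
        np.testing.assert_allclose(np.abs(fr.Z), [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(fr.X, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(fr.origin, 0.0, atol=1e-9)

    def test_equivariance_under_rotation(self):
        coords = np.vstack([_ring_coords(), [[15.0, 2.0, 1.0]]])
        R = Rotation.from_rotvec([0.4, -0.9, 1.3]).as_matrix()
        ref_point = np.array([0.0, 0.0, 30.0])
        fr1 = define_fork_frame(coords, np.arange(24), [24],
                                n_tier_reference=ref_point)
        fr2 = define_fork_frame(coords @ R.T, np.arange(24), [24],
                                n_tier_reference=R @ ref_point)
        np.testing.assert_allclose(fr2.X, R @ fr1.X, atol=1e-8)
        np.testing.assert_allclose(fr2.Y, R @ fr1.Y, atol=1e-8)
        np.testing.assert_allclose(fr2.Z, R @ fr1.Z, atol=1e-8)

    def test_noisy_ring_plane_within_two_degrees(self):
        rng = np.random.default_rng(4)
        ring = _ring_coords(60)
        noisy = ring + rng.normal(scale=1.0, size=ring.shape)
        coords = np.vstack([noisy, [[15.0, 0.0, 0.0]]])
        fr = define_fork_frame(coords, np.arange(60), [60],
                               n_tier_reference=[0, 0, 50.0])
        tilt = math.degrees(math.acos(abs(fr.Z @ np.array([0, 0, 1.0]))))
        assert tilt < 2.0

    def test_collinear_ring_errors(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 5, 5]])
        with pytest.raises(ValueError, match="collinear"):
            define_fork_frame(coords, [0, 1, 2], [3])


class TestOrientationAngles:
    @pytest.fixture
    def frame(self):
        return ForkFrame(np.zeros(3), np.array([1.0, 0, 0]),
                         np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def test_along_x(self, frame):
        a = orientation_angles(frame, [10.0, 0, 0])
        assert (a.elevation_phi, a.azimuth_theta) == (0.0, 0.0)

    def test_along_z_elevation_90(self, frame):
        a = orientation_angles(frame, [0, 0, 10.0])
        assert a.elevation_phi == pytest.approx(90.0)

    def test_xy_diagonal(self, frame):
        a = orientation_angles(frame, [1.0, 1.0, 0.0])
        assert a.azimuth_theta == pytest.approx(45.0)
        assert a.elevation_phi == pytest.approx(0.0)

    def test_zero_vector_errors(self, frame):
        with pytest.raises(ValueError):
            orientation_angles(frame, [0.0, 0, 0])

    def test_circular_statistics_straddle_180(self):
        mean, sd = circular_mean_sd([178.0, -178.0])
        assert mean == pytest.approx(180.0, abs=1e-9) or \
            mean == pytest.approx(-180.0, abs=1e-9)
        assert sd < 5.0


def _identity_frame_fn(origin=np.zeros(3)):
    def fn(coords):
        return ForkFrame(origin, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                         np.array([0, 0, 1.0]))
    return fn


class TestSpatialDensity:
    def test_point_mass_integral_one(self):
        frames = np.zeros((10, 1, 3)) + 7.0
        g = spatial_density([_traj(frames)], _identity_frame_fn(),
                            lambda c: c, grid_spacing=5.0)
        assert g.integral() == pytest.approx(1.0, abs=1e-9)
        assert (g.density > 0).sum() == 1

    def test_uniform_box_density_level(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 40.0, size=(40000, 3))
        frames = pts.reshape(40, 1000, 3)
        g = spatial_density([_traj(frames)], _identity_frame_fn(),
                            lambda c: c, grid_spacing=5.0,
                            bounds=([0, 0, 0], [40.0, 40.0, 40.0]))
        inner = g.density[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(inner, 1.0 / 40.0**3, rtol=0.35)
        assert g.integral() == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_superlevel_volume_closed_form(self):
        rng = np.random.default_rng(1)
        s = 8.0
        pts = rng.normal(scale=s, size=(200000, 3))
        frames = pts.reshape(200, 1000, 3)
        g = spatial_density([_traj(frames)], _identity_frame_fn(),
                            lambda c: c, grid_spacing=3.0)
        level = 1e-5
        r2 = -2 * s * s * math.log(level * (2 * math.pi * s * s)**1.5)
        analytic = 4 / 3 * math.pi * r2**1.5
        assert g.superlevel_volume(level) == pytest.approx(analytic, rel=0.05)

    def test_overlap_fraction_symmetric_intersection(self):
        rng = np.random.default_rng(2)
        a = rng.normal(scale=5.0, size=(20000, 3)).reshape(20, 1000, 3)
        b = a + np.array([4.0, 0, 0])
        bounds = ([-30.0] * 3, [34.0] * 3)
        ga = spatial_density([_traj(a)], _identity_frame_fn(), lambda c: c,
                             grid_spacing=2.0, bounds=bounds)
        gb = spatial_density([_traj(b)], _identity_frame_fn(), lambda c: c,
                             grid_spacing=2.0, bounds=bounds)
        level = 1e-4
        fa = region_overlap_fraction(ga, gb, level, reference="a")
        fb = region_overlap_fraction(ga, gb, level, reference="b")
        assert 0.0 < fa <= 1.0
        # identical numerator: fractions differ only by reference volumes
        assert fa * ga.superlevel_volume(level) == pytest.approx(
            fb * gb.superlevel_volume(level), rel=1e-9)

    def test_isosurface_extraction(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=6.0, size=(50000, 3)).reshape(50, 1000, 3)
        g = spatial_density([_traj(pts)], _identity_frame_fn(), lambda c: c,
                            grid_spacing=3.0)
        verts, faces = g.isosurface(1e-4)
        assert len(verts) > 0 and faces.shape[1] == 3


class TestDistances:
    def test_junction_distance_is_euclidean(self, small_toy):
        top = small_toy.topology
        cargo = top.select("cargo")
        j = top.metadata["junction_bead"]
        coords = np.array(small_toy.coords)
        coords[cargo] = coords[j] + np.array([150.0, 0, 0]) \
            + (coords[cargo] - coords[cargo].mean(axis=0))
        assert junction_distance_3d(coords, cargo, j) == pytest.approx(
            150.0, abs=1e-6)
        moved = coords + np.array([3.0, -9.0, 1.0])
        assert junction_distance_3d(moved, cargo, j) == pytest.approx(
            150.0, abs=1e-6)

    def test_dyad_is_median_footprint_nucleotide(self, small_toy):
        top = small_toy.topology
        coords = np.array(small_toy.coords)
        cargo = top.select("cargo")
        strand = top.select("leading_duplex")
        nt_map = top.metadata["nt_from_junction"]
        # park the cargo on nucleotides k−2..k+2 of the leading arm
        k_target = 10
        sel = strand[np.isin(nt_map[strand], np.arange(k_target - 2,
                                                       k_target + 3))]
        for i, b in enumerate(cargo):
            coords[b] = coords[sel[i % len(sel)]] + 0.3
        d = dyad_distance_nt(coords, top, "leading", 0, cargo, cutoff=1.5)
        assert d == k_target


class TestRecyclingClassifier:
    @pytest.mark.parametrize("cutoff", [8.0, 10.0, 12.0])
    def test_full_label_recovery_on_scripted_suite(self, small_toy, cutoff):
        pairs = forkcg.generate_labeled_trajectories(
            n_per_scenario=1, seed=5, toy=small_toy)
        th = ClassifierThresholds(contact_cutoff=cutoff)
        for tr, label in pairs:
            out = classify_recycling(tr, small_toy.topology, th)
            assert out.destination == label.destination, tr.metadata
            if label.destination != "none":
                assert out.carrier_mediated == label.carrier_mediated
                assert out.deposition_step is not None

    def test_cargo_held_on_tail_is_none(self, small_toy):
        pairs = forkcg.generate_labeled_trajectories(
            scenario_set=("none",), n_per_scenario=1, seed=2, toy=small_toy)
        out = classify_recycling(pairs[0][0], small_toy.topology)
        assert out.destination == "none"
        assert out.carrier_mediated is None
        assert out.deposition_step is None

    def test_deposited_outcome_reports_dyad_and_distance(self, small_toy):
        pairs = forkcg.generate_labeled_trajectories(
            scenario_set=("lagging-unmediated",), n_per_scenario=1, seed=3,
            toy=small_toy)
        out = classify_recycling(pairs[0][0], small_toy.topology)
        assert out.destination == "lagging"
        assert out.dyad_nt_from_junction is not None
        assert out.junction_distance_at_deposition > 0
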