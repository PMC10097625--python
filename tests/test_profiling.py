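"""Super-fiber estimation, Gaussian-weighted profiles, trunk clipping, CSV."""

from __future__ import annotations

import numpy as np
import pytest

from tractoprof import (
    BinaryROI,
    ScalarMap,
    Tract,
    ValidationError,
    align_orientations,
    clip_to_roi,
    core_fiber,
    gaussian_weights,
    profiles_to_csv,
    read_profiles_csv,
    resample_streamline,
    tract_profile,
)
from tractoprof.profiling import N_NODES, TractProfile, bundle_node_matrix
from tractoprof.synthetic_phantom import PhantomSpec, default_grid, make_bundle


def straight(p0, p1, n=11):
    return np.linspace(p0, p1, n).astype(np.float32)


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        out = resample_streamline(straight([0, 0, 0], [0, 0, 2], 2), 5)
        assert np.allclose(out[:, 2], [0, 0.5, 1, 1.5, 2])
        assert np.allclose(out[:, :2], 0)

    def test_uniform_polyline_fixed_point(self):
        s = straight([0, 0, 0], [10, 0, 0], 6)  # already equally spaced
        assert np.allclose(resample_streamline(s, 6), s)

    def test_equal_arc_gaps_random_polyline(self, rng):
        """Resampled points sit at equal arc-length positions on the original."""
        s = np.cumsum(rng.normal(0, 1, (30, 3)), axis=0)
        out = resample_streamline(s, 100)
        seg = np.diff(s, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        arcs = np.concatenate([[0.0], np.cumsum(seg_len)])

        def arc_of(p):
            best = np.inf
            best_arc = None
            for i in range(len(s) - 1):
                t = np.clip(np.dot(p - s[i], seg[i]) / seg_len[i] ** 2, 0, 1)
                d = np.linalg.norm(p - (s[i] + t * seg[i]))
                if d < best:
                    best, best_arc = d, arcs[i] + t * seg_len[i]
            assert best < 1e-9  # resampled point lies on the polyline
            return best_arc

        positions = np.array([arc_of(p) for p in out])
        assert np.allclose(np.diff(positions), arcs[-1] / 99, rtol=1e-9)

    def test_zero_length_rejected(self):
        s = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            resample_streamline(s, 5)


class TestAlignment:
    def test_streamline_and_reverse_get_common_start(self):
        s = straight([0, 0, 0], [10, 0, 0])
        out = align_orientations([s, s[::-1].copy()])
        assert np.allclose(out[0][0], out[1][0])
        assert np.allclose(out[0][-1], out[1][-1])

    def test_aligned_bundle_unchanged(self):
        bundle = [straight([0, y, 0], [10, y, 0]) for y in range(3)]
        out = align_orientations(bundle)
        for a, b in zip(bundle, out):
            assert np.array_equal(a, b)

    def test_planted_flips_corrected(self, rng):
        base = [straight([0, y, 0], [20, y, 0.3 * y]) for y in range(10)]
        flipped = [s[::-1].copy() if rng.random() < 0.3 else s for s in base]
        out = align_orientations(flipped)
        starts = np.array([s[0] for s in out])
        assert np.all(starts[:, 0] < 1.0)  # everyone starts at the x~0 end


class TestCoreFiber:
    def test_two_parallel_lines_core_midway(self):
        a = straight([0, 0, 0], [10, 0, 0])
        b = straight([2, 0, 0], [12, 0, 0])
        # same direction, offset along x only: midpoints average to x+1
        core = core_fiber([a, b], n=11)
        assert np.allclose(core.nodes[:, 0], np.linspace(1, 11, 11), atol=1e-6)

    def test_single_streamline_core_is_itself(self):
        s = straight([0, 0, 0], [10, 5, 2])
        core = core_fiber([s], n=11)
        assert np.allclose(core.nodes, resample_streamline(s, 11), atol=1e-6)
        assert np.allclose(core.node_dispersion, 0.0)

    def test_jittered_arc_core_near_truth_clt(self):
        """50 streamlines with 1 mm jitter: the core is within 3*sigma/sqrt(50)
        of the planted centerline at every node (CLT bound)."""
        spec = PhantomSpec(seed=42, n_streamlines=50, jitter_sd=1.0)
        tract, centerline = make_bundle(spec)
        core = core_fiber(tract)
        truth = resample_streamline(centerline, N_NODES)
        err = np.linalg.norm(core.nodes - truth, axis=1)
        assert err.max() < 3.0 * 1.0 / np.sqrt(50)


class TestGaussianWeights:
    def test_equal_distances_uniform(self):
        w, flagged = gaussian_weights(np.array([2.0, 2.0, 2.0, 2.0]), sigma=1.5)
        assert np.allclose(w, 0.25)
        assert not flagged

    def test_distance_ratio_exp_half(self):
        sigma = 2.0
        w, _ = gaussian_weights(np.array([0.0, sigma]), sigma=sigma)
        assert np.isclose(w[1] / w[0], np.exp(-0.5))
        assert np.isclose(w.sum(), 1.0)

    def test_single_streamline_weight_one(self):
        w, _ = gaussian_weights(np.array([3.7]), sigma=1.0)
        assert np.allclose(w, [1.0])

    def test_underflow_falls_back_to_uniform(self):
        w, flagged = gaussian_weights(np.array([1e4, 1e4]), sigma=0.1)
        assert flagged
        assert np.allclose(w, 0.5)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            gaussian_weights(np.array([1.0]), sigma=0.0)


def bundle_along_z(n=9, z0=2.0, z1=18.0):
    return [straight([10 + 0.2 * k, 10, z0], [10 + 0.2 * k, 10, z1], 25) for k in range(n)]


class TestTractProfile:
    def test_constant_field_constant_profile(self, unit_grid):
        smap = ScalarMap(unit_grid, np.full(unit_grid.shape, 0.42), "FA")
        prof = tract_profile(Tract("t", bundle_along_z()), smap)
        assert np.allclose(prof.values, 0.42)
        assert np.isclose(prof.mean_value, 0.42)
        assert len(prof.values) == N_NODES

    def test_linear_field_linear_profile(self, unit_grid):
        z = np.arange(unit_grid.shape[2], dtype=float)
        values = np.broadcast_to(z, unit_grid.shape).copy()
        smap = ScalarMap(unit_grid, values, "ramp")
        prof = tract_profile(Tract("t", bundle_along_z(z0=2.0, z1=18.0)), smap)
        vals = prof.values if prof.values[0] < prof.values[-1] else prof.values[::-1]
        assert np.allclose(vals, np.linspace(2.0, 18.0, N_NODES), atol=1e-6)

    def test_antisymmetric_field_cancels(self, unit_grid):
        """A bundle symmetric about x=10 in a field odd about x=10 profiles to ~field(10)."""
        x = np.arange(unit_grid.shape[0], dtype=float)
        values = np.broadcast_to((x - 10.0)[:, None, None], unit_grid.shape).copy()
        smap = ScalarMap(unit_grid, values, "odd")
        bundle = [
            straight([10 + dx, 10, 2], [10 + dx, 10, 18], 25) for dx in (-2, -1, 1, 2)
        ]
        prof = tract_profile(Tract("t", bundle), smap, sigma=5.0)
        assert np.max(np.abs(prof.values)) < 1e-9

    def test_profile_within_sample_range(self, unit_grid, rng):
        smap = ScalarMap(unit_grid, rng.random(unit_grid.shape), "noise")
        bundle = [s + rng.normal(0, 0.3, s.shape).astype(np.float32) for s in bundle_along_z()]
        tract = Tract("t", bundle)
        prof = tract_profile(tract, smap)
        from scipy import ndimage

        nodes = bundle_node_matrix(bundle)
        samples = ndimage.map_coordinates(
            smap.values, unit_grid.world_to_voxel(nodes.reshape(-1, 3)).T, order=1
        ).reshape(nodes.shape[:2])
        assert np.all(prof.values >= samples.min(axis=0) - 1e-12)
        assert np.all(prof.values <= samples.max(axis=0) + 1e-12)

    def test_mean_is_arithmetic_mean(self, unit_grid, rng):
        smap = ScalarMap(unit_grid, rng.random(unit_grid.shape), "m")
        prof = tract_profile(Tract("t", bundle_along_z()), smap)
        assert prof.mean_value == pytest.approx(float(prof.values.mean()))

    def test_outside_map_is_error_when_total(self):
        tiny = default_grid(4)
        smap = ScalarMap(tiny, np.zeros(tiny.shape), "FA")
        far = [straight([100, 100, 100], [120, 100, 100])]
        with pytest.raises(ValidationError):
            tract_profile(Tract("t", far), smap)

    def test_reversing_bundle_reverses_profile(self, unit_grid):
        z = np.arange(unit_grid.shape[2], dtype=float)
        smap = ScalarMap(unit_grid, np.broadcast_to(z, unit_grid.shape).copy(), "ramp")
        bundle = bundle_along_z()
        fwd = tract_profile(Tract("t", bundle), smap)
        rev = tract_profile(Tract("t", [s[::-1].copy() for s in bundle]), smap)
        assert np.allclose(fwd.values, rev.values[::-1], atol=1e-9) or np.allclose(
            fwd.values, rev.values, atol=1e-9
        )


class TestClipToRoi:
    def _roi_at(self, grid, center, radius=1.6, name="r"):
        idx = np.indices(grid.shape).reshape(3, -1).T
        centers = grid.voxel_to_world(idx)
        mask = (np.linalg.norm(centers - np.asarray(center), axis=1) <= radius).reshape(grid.shape)
        return BinaryROI(grid, mask, name)

    def test_clip_arc_interval(self, unit_grid):
        """A streamline crossing ROI1 then ROI2 keeps [last-in-1, first-in-2]."""
        s = straight([10, 10, 1], [10, 10, 19], 37)  # z every 0.5 mm
        roi1 = self._roi_at(unit_grid, [10, 10, 4], radius=1.2, name="a")
        roi2 = self._roi_at(unit_grid, [10, 10, 15], radius=1.2, name="b")
        out = clip_to_roi(Tract("t", [s]), roi1, roi2)
        assert out.n_streamlines == 1
        z = out.streamlines[0][:, 2]
        # ROI membership (radius 1.2 around z=4/15, voxel-centre rounding)
        # spans z in [2.5, 5.5) and [13.5, 16.5): clip = last point <= 5.4 .. first >= 13.5
        assert z[0] == pytest.approx(5.0, abs=0.26)
        assert z[-1] == pytest.approx(13.5, abs=0.26)
        assert np.all(np.diff(z) > 0)

    def test_streamline_missing_a_roi_dropped(self, unit_grid):
        s_between = straight([10, 10, 7], [10, 10, 12], 11)
        roi1 = self._roi_at(unit_grid, [10, 10, 3], name="a")
        roi2 = self._roi_at(unit_grid, [10, 10, 17], name="b")
        out = clip_to_roi(Tract("t", [s_between]), roi1, roi2)
        assert out.n_streamlines == 0

    def test_clip_idempotent(self, unit_grid):
        bundle = [straight([10 + 0.1 * k, 10, 1], [10 + 0.1 * k, 10, 19], 37) for k in range(5)]
        roi1 = self._roi_at(unit_grid, [10, 10, 4], name="a")
        roi2 = self._roi_at(unit_grid, [10, 10, 15], name="b")
        once = clip_to_roi(Tract("t", bundle), roi1, roi2)
        twice = clip_to_roi(once, roi1, roi2)
        assert twice.n_streamlines == once.n_streamlines
        for a, b in zip(once.streamlines, twice.streamlines):
            assert np.allclose(a, b)

    def test_c2roi_flag_set(self, unit_grid):
        bundle = [straight([10, 10, 1], [10, 10, 19], 37)]
        roi1 = self._roi_at(unit_grid, [10, 10, 4], name="a")
        roi2 = self._roi_at(unit_grid, [10, 10, 15], name="b")
        out = clip_to_roi(Tract("t", bundle), roi1, roi2)
        assert out.params["c2roi"] is True


class TestProfileCsv:
    def _profile(self, name, values, metric="FA"):
        return TractProfile(tract_name=name, metric_name=metric, values=np.asarray(values, float),
                            n_streamlines=5)

    def test_geometry_100_rows_one_column_per_tract(self):
        profs = [self._profile("L_AF", np.linspace(0, 1, 100)),
                 self._profile("R_AF", np.linspace(1, 0, 100))]
        text = profiles_to_csv(profs)
        lines = text.strip().splitlines()
        assert lines[0] == "L_AF,R_AF"
        assert len(lines) == 1 + 100

    def test_zero_tracts_header_only(self):
        text = profiles_to_csv([])
        assert text.strip() in ("", ",")  # header-only, no data rows

    def test_round_trip_values(self, tmp_path):
        values = np.linspace(0.2, 0.8, 100)
        profiles_to_csv([self._profile("t", values)], tmp_path / "FA_profiles.csv")
        back = read_profiles_csv(tmp_path / "FA_profiles.csv")
        assert list(back.columns) == ["t"]
        assert np.allclose(back["t"].to_numpy(), values)

    def test_duplicate_names_rejected(self):
        p = self._profile("x", np.zeros(100))
        with pytest.raises(ValidationError):
            profiles_to_csv([p, p])

    def test_mixed_metrics_rejected(self):
        with pytest.raises(ValidationError):
            profiles_to_csv([self._profile("a", np.zeros(100), "FA"),
                             self._profile("b", np.zeros(100), "MD")])
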