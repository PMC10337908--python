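"""Ring profiles, clustering/polarization statistics, tracking, volumes,
collapse dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemech import imaging, synthetic
from nemech.imaging import (
    RingProfile,
    align_collapse_series,
    clustering_index,
    collapse_rates,
    fit_piecewise_rates,
    link_tracks,
    mean_speeds,
    normalized_mean_intensity,
    peak_region_stat,
    polarization_profile,
    sample_ring_profile,
    segment_nucleus_volume,
    track_mean_speed,
)
from nemech.synthetic import CollapseSpec, RingSpec, simulate_collapse_series, simulate_ring_image


def _profile(intensity, step=1.0, **kw):
    return RingProfile(np.arange(0.0, 360.0, step), np.asarray(intensity, float), **kw)


class TestRingSampling:
    def test_synthetic_ring_matches_truth_everywhere(self):
        spec = RingSpec(radius_px=20, n_patches=0, cap_amplitude=200.0,
                        cap_concentration=3.0, noise_sd=0.0)
        image, truth, _ = simulate_ring_image(spec, image_size=64, seed=0)
        prof = sample_ring_profile(image, (31.5, 31.5), 20.0, ring_width=1.0,
                                   background=0.0)
        # ring_width 1 px samples close to the crest; compare shape-wise
        assert np.all(np.abs(prof.intensity / truth - np.mean(prof.intensity / truth)) < 0.03)

    def test_rotated_image_gives_shifted_profile(self):
        spec = RingSpec(radius_px=15, n_patches=0, cap_amplitude=300.0,
                        cap_angle_deg=0.0, cap_concentration=10.0, noise_sd=0.0)
        img0, _, _ = simulate_ring_image(spec, image_size=64, seed=0)
        spec90 = RingSpec(radius_px=15, n_patches=0, cap_amplitude=300.0,
                          cap_angle_deg=90.0, cap_concentration=10.0, noise_sd=0.0)
        img90, _, _ = simulate_ring_image(spec90, image_size=64, seed=0)
        p0 = sample_ring_profile(img0, (31.5, 31.5), 15.0, background=0.0)
        p90 = sample_ring_profile(img90, (31.5, 31.5), 15.0, background=0.0)
        assert np.allclose(np.roll(p0.intensity, 90), p90.intensity, atol=0.5)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            sample_ring_profile(np.zeros((32, 32)), (40.0, 16.0), 5.0)

    def test_background_subtraction_floors_at_zero(self):
        image = np.full((64, 64), 10.0)
        prof = sample_ring_profile(image, (31.5, 31.5), 10.0)
        assert np.allclose(prof.intensity, 0.0)


class TestClusteringIndex:
    def test_constant_profile_zero(self):
        assert clustering_index(_profile(np.full(360, 5.0))) == 0.0

    def test_hand_computed_four_point_cv(self):
        # mean 1.5, sample SD 1.0 -> CV = 0.6667
        prof = RingProfile(np.array([0.0, 90.0, 180.0, 270.0]),
                           np.array([1.0, 1.0, 1.0, 3.0]))
        assert clustering_index(prof) == pytest.approx(1.0 / 1.5, abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(0, 359))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_scale_and_rotation_invariant(self, k, shift):
        rng = np.random.default_rng(7)
        base = rng.uniform(1.0, 10.0, 360)
        cv = clustering_index(_profile(base))
        assert clustering_index(_profile(k * np.roll(base, shift))) == pytest.approx(cv)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            clustering_index(_profile(np.zeros(360)))


class TestNormalizedMeanIntensity:
    def test_reference_group_averages_one(self):
        out = normalized_mean_intensity({"TZ": [2.0, 4.0], "MP": [3.0]})
        assert np.mean(out["TZ"]) == pytest.approx(1.0)

    def test_double_brightness_normalizes_to_two(self):
        out = normalized_mean_intensity({"TZ": [1.0, 1.0], "LP": [2.0, 2.0]})
        assert np.allclose(out["LP"], 2.0)

    def test_all_equal_gives_ones(self):
        out = normalized_mean_intensity({"TZ": [5.0], "Dip": [5.0, 5.0]})
        assert np.allclose(out["Dip"], 1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_mean_intensity({"TZ": [], "MP": [1.0]})


class TestPolarization:
    def test_constant_profile_all_ones(self):
        pol = polarization_profile(_profile(np.full(360, 3.0)))
        assert np.allclose(pol.intensity, 1.0)

    def test_cap_lands_at_180_and_zero_is_one(self):
        spec = RingSpec(radius_px=20, n_patches=0, cap_amplitude=400.0,
                        cap_angle_deg=30.0, cap_concentration=6.0, noise_sd=0.0)
        _, truth, _ = simulate_ring_image(spec, seed=0)
        pol = polarization_profile(_profile(truth))
        assert pol.intensity[0] == 1.0
        assert abs(int(np.argmax(pol.intensity)) - 180) <= 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        prof = _profile(rng.uniform(1, 5, 360) + 10 * np.exp(-((np.arange(360) - 77) % 360 - 0) ** 2 / 200))
        once = polarization_profile(prof)
        twice = polarization_profile(RingProfile(once.angles_deg, once.intensity))
        assert np.allclose(once.intensity, twice.intensity)

    def test_equivariant_to_input_rotation(self):
        spec = RingSpec(radius_px=20, n_patches=0, cap_amplitude=400.0,
                        cap_angle_deg=0.0, cap_concentration=6.0, noise_sd=0.0)
        _, truth, _ = simulate_ring_image(spec, seed=0)
        a = polarization_profile(_profile(truth))
        b = polarization_profile(_profile(np.roll(truth, 123)))
        assert np.allclose(a.intensity, b.intensity)

    def test_fold_averages_symmetric_halves(self):
        spec = RingSpec(radius_px=20, n_patches=0, cap_amplitude=400.0,
                        cap_angle_deg=180.0, cap_concentration=6.0, noise_sd=0.0)
        _, truth, _ = simulate_ring_image(spec, seed=0)
        folded = polarization_profile(_profile(truth), fold=True)
        unfolded = polarization_profile(_profile(truth))
        assert folded.angles_deg[-1] == 180.0
        # symmetric profile: folding reproduces either half exactly
        assert np.allclose(folded.intensity, unfolded.intensity[:181])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            polarization_profile(_profile(np.zeros(360)))


class TestPeakRegionStat:
    def test_constant_profile_gives_one(self):
        pol = polarization_profile(_profile(np.full(360, 2.0)))
        assert peak_region_stat([pol])[0] == pytest.approx(1.0)

    def test_monotone_in_cap_amplitude(self):
        stats = []
        for amp in (0.0, 100.0, 300.0, 600.0):
            spec = RingSpec(radius_px=20, n_patches=0, cap_amplitude=amp,
                            cap_angle_deg=90.0, cap_concentration=6.0, noise_sd=0.0)
            _, truth, _ = simulate_ring_image(spec, seed=0)
            pol = polarization_profile(_profile(truth))
            stats.append(peak_region_stat([pol])[0])
        assert np.all(np.diff(stats) > 0)

    def test_two_groups_distinguished_by_t_test(self):
        from nemech.stats import standard_tests

        rng_seeds = range(20)
        groups = {}
        for amp, key in ((0.0, "flat"), (200.0, "capped")):
            vals = []
            for s in rng_seeds:
                spec = RingSpec(radius_px=20, n_patches=3, patch_amplitude=30.0,
                                cap_amplitude=amp, cap_angle_deg=45.0,
                                cap_concentration=6.0, noise_sd=2.0)
                image, _, _ = simulate_ring_image(spec, seed=s)
                prof = sample_ring_profile(image, (31.5, 31.5), 20.0, background=0.0)
                pol = polarization_profile(prof)
                vals.append(peak_region_stat([pol])[0])
            groups[key] = np.asarray(vals)
        res = standard_tests("pairwise-t-bh", groups["flat"], groups["capped"])
        assert groups["capped"].mean() > groups["flat"].mean()
        assert res["table"]["p"].iloc[0] < 0.01


class TestTracking:
    def test_single_stationary_particle_one_full_track(self):
        det, _ = synthetic.simulate_tracks(1, {"model": "stationary"}, n_frames=6, seed=0)
        tracks = link_tracks(det, max_displacement_um=1.0)
        assert len(tracks) == 1 and len(tracks[0]) == 6

    def test_well_separated_particles_no_identity_swap(self):
        det, truth = synthetic.simulate_tracks(
            2, {"model": "directed", "speed_um_per_frame": 0.5},
            n_frames=8, box_um=50.0, seed=5,
        )
        tracks = link_tracks(det, max_displacement_um=1.5)
        assert len(tracks) == 2
        for t in tracks:
            start = t.positions_um[0]
            match = truth[(truth["frame"] == 0)]
            d = np.linalg.norm(
                match[["x_um", "y_um", "z_um"]].to_numpy() - start, axis=1
            )
            pid = match.iloc[int(np.argmin(d))]["particle"]
            expected = truth[truth["particle"] == pid].sort_values("frame")
            assert np.allclose(
                t.positions_um, expected[["x_um", "y_um", "z_um"]].to_numpy()
            )

    def test_drift_removal_restores_drift_free_tracks(self):
        det0, _ = synthetic.simulate_tracks(3, {"model": "stationary"}, n_frames=5, seed=9)
        detd, _ = synthetic.simulate_tracks(
            3, {"model": "stationary"}, drift_um_per_frame=(2.0, 0.0, 0.0),
            n_frames=5, seed=9,
        )
        t0 = link_tracks(det0, 1.0)
        td = link_tracks(detd, 1.0, reference_drift_um_per_frame=(2.0, 0.0, 0.0))
        pos0 = sorted(tuple(np.round(t.positions_um[0], 6)) for t in t0)
        posd = sorted(tuple(np.round(t.positions_um[0], 6)) for t in td)
        assert pos0 == posd

    def test_link_accuracy_on_directed_motion(self):
        # spacing >> per-frame displacement: >= 95% of links correct
        det, truth = synthetic.simulate_tracks(
            10, {"model": "directed", "speed_um_per_frame": 0.5},
            n_frames=10, box_um=60.0, seed=13,
        )
        tracks = link_tracks(det, max_displacement_um=1.5)
        n_links = sum(len(t) - 1 for t in tracks)
        expected_links = 10 * 9
        full = [t for t in tracks if len(t) == 10]
        assert n_links >= 0.95 * expected_links
        assert len(full) >= 9


class TestSpeeds:
    def test_stationary_zero_speed(self):
        track = imaging.Track(0, [0, 1, 2], np.zeros((3, 3)), frame_interval_s=5.0)
        assert track_mean_speed(track) == 0.0

    def test_one_um_per_frame_at_5s(self):
        pos = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        track = imaging.Track(0, np.arange(4), pos, frame_interval_s=5.0)
        assert track_mean_speed(track) == pytest.approx(0.2)

    def test_random_walk_speed_matches_monte_carlo_expectation(self):
        sigma, dt, n_frames, n_particles = 0.4, 5.0, 40, 60
        det, truth = synthetic.simulate_tracks(
            n_particles, {"model": "random-walk", "speed_um_per_frame": sigma},
            n_frames=n_frames, box_um=1000.0, seed=17,
        )
        tracks = link_tracks(det, max_displacement_um=5.0, frame_interval_s=dt)
        speeds = mean_speeds(tracks)
        # E|step| for 3D isotropic Gaussian steps: sigma * sqrt(2) * gamma(2)/gamma(3/2)
        import math
        e_step = sigma * math.sqrt(2) * math.gamma(2.0) / math.gamma(1.5)
        se = np.std(speeds, ddof=1) / np.sqrt(speeds.size)
        assert abs(speeds.mean() - e_step / dt) < 3 * max(se, 1e-6) + 0.01 * e_step / dt

    def test_singleton_excluded(self):
        track = imaging.Track(0, [3], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            track_mean_speed(track)
        assert mean_speeds([track]).size == 0


class TestVolume:
    @staticmethod
    def _sphere_stack(r, shape=(40, 40, 40), center=None):
        center = center or tuple(s / 2 - 0.5 for s in shape)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        dist = np.sqrt(
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        return (dist <= r).astype(np.uint16) * 1000

    def test_sphere_volume_within_5pct(self):
        r = 8.0
        stack = self._sphere_stack(r)
        out = segment_nucleus_volume(stack, voxel_size_um=(1.0, 1.0, 1.0))
        assert len(out) == 1
        assert out.loc[0, "volume_um3"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_empty_stack_no_nuclei(self):
        assert segment_nucleus_volume(np.zeros((10, 10, 10))).empty

    def test_two_disjoint_spheres(self):
        a = self._sphere_stack(5.0, shape=(40, 40, 80), center=(20, 20, 20))
        b = self._sphere_stack(7.0, shape=(40, 40, 80), center=(20, 20, 60))
        out = segment_nucleus_volume(a + b, voxel_size_um=(1.0, 1.0, 1.0))
        vols = sorted(out["volume_um3"])
        assert len(out) == 2
        assert vols[0] == pytest.approx(4 / 3 * np.pi * 125, rel=0.06)
        assert vols[1] == pytest.approx(4 / 3 * np.pi * 343, rel=0.06)

    def test_resolution_refinement_shrinks_error(self):
        # error roughly halves when the voxel edge halves
        truth = 4 / 3 * np.pi * 6.0**3
        errs = []
        for scale in (1, 2):
            r_vox = 6.0 * scale
            stack = self._sphere_stack(r_vox, shape=(int(16 * scale),) * 3,
                                       center=None)
            voxel = 1.0 / scale
            out = segment_nucleus_volume(stack, voxel_size_um=(voxel,) * 3)
            errs.append(abs(out["volume_um3"].sum() - truth) / truth)
        assert errs[1] < errs[0]

    def test_boundary_touching_flagged(self):
        stack = self._sphere_stack(6.0, shape=(10, 40, 40), center=(0, 20, 20))
        out = segment_nucleus_volume(stack)
        assert out.loc[0, "touches_boundary"]


class TestCollapse:
    def test_contact_frame_recovered_from_generator(self):
        spec = CollapseSpec(noise_sd=0.0)
        df = simulate_collapse_series(spec, seed=0)
        cs = align_collapse_series(df["ne_size_um"].to_numpy(), df["sc_size_um"].to_numpy())
        assert cs.contact_index == spec.contact_frame

    def test_final_frame_normalized_to_one(self):
        df = simulate_collapse_series(CollapseSpec(noise_sd=0.01), seed=1)
        cs = align_collapse_series(df["ne_size_um"].to_numpy(), df["sc_size_um"].to_numpy(),
                                   contact_tol=0.1)
        assert cs.ne_norm[-1] == 1.0 and cs.sc_norm[-1] == 1.0

    def test_sc_flat_before_contact(self):
        df = simulate_collapse_series(CollapseSpec(noise_sd=0.0), seed=0)
        cs = align_collapse_series(df["ne_size_um"].to_numpy(), df["sc_size_um"].to_numpy())
        pre = cs.sc_norm[cs.frames < 0]
        assert np.allclose(pre, pre[0])

    def test_noise_free_rates_exact(self):
        values = 4.0 - 0.05 * np.arange(30)
        pre, post = fit_piecewise_rates(values, np.arange(30), 15)
        assert pre == pytest.approx(-0.05, abs=1e-12)
        assert post == pytest.approx(-0.05, abs=1e-12)

    def test_zero_pre_rate(self):
        df = simulate_collapse_series(CollapseSpec(ne_size0_um=3.05, sc_size0_um=3.0,
                                                   contact_frame=10, rate_pre=0.0,
                                                   noise_sd=0.0), seed=0)
        pre, _ = fit_piecewise_rates(df["ne_size_um"].to_numpy(), df["frame"].to_numpy(), 10)
        assert pre == pytest.approx(0.0, abs=1e-12)

    def test_post_faster_than_pre(self):
        spec = CollapseSpec(rate_pre=-0.02, rate_post=-0.1, sc_rate_post=-0.05,
                            ne_size0_um=3.4, contact_frame=20, noise_sd=0.0)
        df = simulate_collapse_series(spec, seed=0)
        cs = align_collapse_series(df["ne_size_um"].to_numpy(), df["sc_size_um"].to_numpy())
        pre, post = collapse_rates(cs)
        assert abs(post) > abs(pre)

    def test_rate_recovery_within_5pct_at_2pct_noise(self):
        spec = CollapseSpec(noise_sd=0.02 * 4.0)
        recovered_pre, recovered_post = [], []
        for s in range(12):
            df = simulate_collapse_series(spec, seed=s)
            cs = align_collapse_series(
                df["ne_size_um"].to_numpy(), df["sc_size_um"].to_numpy(),
                contact_tol=2 * np.sqrt(2) * spec.noise_sd,
            )
            pre, post = collapse_rates(cs)
            recovered_pre.append(pre * cs.ne_final_um)
            recovered_post.append(post * cs.ne_final_um)
        assert np.mean(recovered_pre) == pytest.approx(spec.rate_pre, rel=0.05)
        assert np.mean(recovered_post) == pytest.approx(spec.rate_post, rel=0.05)

    def test_no_contact_raises_with_diagnostic(self):
        ne = np.full(10, 5.0)
        sc = np.full(10, 3.0)
        with pytest.raises(ValueError, match="no NE-SC contact"):
            align_collapse_series(ne, sc)
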