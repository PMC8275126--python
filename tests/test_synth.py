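import numpy as np
import pytest
from scipy import stats as sps

from orgakit.config import CohortConfig, ImageConfig, SimConfig, TrackConfig
from orgakit.quantify import count_domains
from orgakit.synth import (
    PlacementError,
    render_track_movie,
    simulate_intensity_cohort,
    simulate_organoid_image,
    simulate_tracks,
)


def cohort_cfg(**kw):
    base = dict(n_traces=1, onset_mean_h=10.0, onset_sd_h=0.0, frame_interval_min=30.0,
                duration_h=20.0, rise_time_h=2.0, noise_sd=0.0, baseline=0.05)
    seed = kw.pop("seed", 0)
    base.update(kw)
    return SimConfig(seed=seed, cohort=CohortConfig(**base))


class TestIntensityCohort:
    def test_noiseless_steepest_rise_at_onset(self):
        traces, gt = simulate_intensity_cohort(cohort_cfg())
        (trace,) = traces
        diffs = np.diff(trace.intensity_raw)
        k = int(np.argmax(diffs))
        # steepest frame-to-frame rise straddles the 10 h inflection
        assert trace.times_h[k] <= 10.0 <= trace.times_h[k + 1] + 1e-9
        assert gt.true_onsets_h[0] == 10.0

    def test_determinism(self):
        cfg = cohort_cfg(n_traces=5, onset_sd_h=0.5, noise_sd=0.02)
        t1, g1 = simulate_intensity_cohort(cfg)
        t2, g2 = simulate_intensity_cohort(cfg)
        np.testing.assert_array_equal(g1.true_onsets_h, g2.true_onsets_h)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.intensity_raw, b.intensity_raw)

    def test_seed_changes_output(self):
        t1, _ = simulate_intensity_cohort(cohort_cfg(noise_sd=0.02, seed=1))
        t2, _ = simulate_intensity_cohort(cohort_cfg(noise_sd=0.02, seed=2))
        assert not np.array_equal(t1[0].intensity_raw, t2[0].intensity_raw)

    def test_censored_duration_refused(self):
        with pytest.raises(ValueError, match="censored"):
            simulate_intensity_cohort(cohort_cfg(onset_mean_h=18.0, duration_h=20.0))

    def test_frame_grid(self):
        traces, _ = simulate_intensity_cohort(cohort_cfg())
        t = traces[0].times_h
        assert t[0] == 0.0
        assert t[-1] == pytest.approx(20.0)
        np.testing.assert_allclose(np.diff(t), 0.5)

    def test_missing_block_refused(self):
        with pytest.raises(ValueError, match="cohort"):
            simulate_intensity_cohort(SimConfig())


def image_cfg(**kw):
    base = dict(size_px=256, pixel_size_um=1.0, organoid_radius_um=100.0, n_domains=1,
                domain_radius_um=30.0, fg_intensity=200.0, bg_intensity=40.0,
                noise_sd=0.0, min_domain_gap_um=10.0)
    seed = kw.pop("seed", 0)
    base.update(kw)
    return SimConfig(seed=seed, image=ImageConfig(**base))


class TestOrganoidImage:
    def test_single_domain_label(self):
        _, _, gt = simulate_organoid_image(image_cfg())
        labels = gt.domain_labels
        assert set(np.unique(labels)) == {0, 1}

    def test_four_domains_counted_downstream(self):
        cfg = image_cfg(size_px=512, organoid_radius_um=200.0, n_domains=4, seed=3)
        _, fluor, gt = simulate_organoid_image(cfg)
        regions = count_domains(gt.domain_labels > 0, 1.0)
        assert regions.n_regions == 4

    def test_analytic_area_matches_raster(self):
        # generated domain areas match pi r^2 within 2% for radii >= 20 px
        for r in (20.0, 30.0, 45.0):
            cfg = image_cfg(domain_radius_um=r, seed=1)
            _, _, gt = simulate_organoid_image(cfg)
            raster = float((gt.domain_labels == 1).sum())
            assert raster == pytest.approx(np.pi * r**2, rel=0.02)

    def test_bright_field_polarity(self):
        bf, fluor, _ = simulate_organoid_image(image_cfg())
        center = bf.pixels[128, 128]
        corner = bf.pixels[2, 2]
        assert center < corner  # organoid dark on bright background
        assert fluor.pixels[2, 2] < fluor.pixels.max()

    def test_determinism(self):
        cfg = image_cfg(noise_sd=5.0, n_domains=3, organoid_radius_um=120.0, seed=9)
        a = simulate_organoid_image(cfg)
        b = simulate_organoid_image(cfg)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)
        np.testing.assert_array_equal(a[2].domain_labels, b[2].domain_labels)

    def test_placement_refused_when_impossible(self):
        cfg = image_cfg(n_domains=4, domain_radius_um=60.0, organoid_radius_um=100.0)
        with pytest.raises(PlacementError):
            simulate_organoid_image(cfg)

    def test_domain_covering_whole_organoid(self):
        cfg = image_cfg(domain_radius_um=100.0, organoid_radius_um=100.0)
        _, _, gt = simulate_organoid_image(cfg)
        org = float((gt.domain_labels > 0).sum())
        assert org == pytest.approx(np.pi * 100.0**2, rel=0.02)

    def test_pairwise_gap_respected(self):
        cfg = image_cfg(size_px=512, organoid_radius_um=200.0, n_domains=3, seed=5)
        _, _, gt = simulate_organoid_image(cfg)
        c = gt.domain_centers_um
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(c[i] - c[j]) >= 2 * 30.0 + 10.0 - 1e-9


def track_cfg(**kw):
    base = dict(n_cells=50, aggregate_radius_um=100.0, D_um2_per_min=0.5,
                v_um_per_min=0.45, p_outward=0.51, t_switch_h=4.0, duration_h=8.0,
                dt_min=15.0, loc_noise_um=0.0, miss_rate=0.0)
    seed = kw.pop("seed", 0)
    base.update(kw)
    return SimConfig(seed=seed, tracks=TrackConfig(**base))


class TestTracks:
    def test_pure_outward_radial_increase(self):
        cfg = track_cfg(D_um2_per_min=0.0, v_um_per_min=1.0, p_outward=1.0, n_cells=5)
        tracks, gt = simulate_tracks(cfg)
        for tr in tracks:
            r = np.linalg.norm(tr.positions(), axis=1)
            f = tr.frames
            post = f >= cfg.tracks.switch_frame
            dr = np.diff(r[post])
            np.testing.assert_allclose(dr, 15.0, atol=1e-9)  # v*dt per frame
            pre = r[~post]
            np.testing.assert_allclose(np.diff(pre), 0.0, atol=1e-12)  # D=0

    def test_class_counts_binomial(self):
        cfg = track_cfg(n_cells=4600, p_outward=0.5, duration_h=2.0, t_switch_h=1.0, seed=11)
        _, gt = simulate_tracks(cfg)
        n_out = sum(1 for c in gt.track_classes.values() if c == "outward")
        lo, hi = sps.binom.ppf([0.005, 0.995], 4600, 0.5)
        assert lo <= n_out <= hi

    def test_directed_sign_matches_class_noiseless(self):
        cfg = track_cfg(n_cells=100, seed=2)
        tracks, gt = simulate_tracks(cfg)
        sf = cfg.tracks.switch_frame
        for tr in tracks:
            r = np.linalg.norm(tr.positions(), axis=1)
            f = tr.frames
            i0 = int(np.searchsorted(f, sf))
            net = r[-1] - r[i0]
            cls = gt.track_classes[tr.id]
            # inward cells that hit the centre may rebound; only check clear movers
            if abs(net) > 5.0:
                assert (net > 0) == (cls == "outward")

    def test_brownian_msd_matches_6Dt(self):
        from orgakit.motility import ensemble_msd

        cfg = track_cfg(n_cells=500, t_switch_h=7.75, duration_h=8.0,
                        v_um_per_min=0.0, aggregate_radius_um=1000.0, seed=4)
        tracks, _ = simulate_tracks(cfg)
        pre = ensemble_msd(tracks, max_lag_fraction=0.25)
        tau = pre.lags_min[1:]
        expected = 6.0 * 0.5 * tau
        np.testing.assert_allclose(pre.msd_um2[1:], expected, rtol=0.10)

    def test_msd_linear_then_superlinear(self):
        from orgakit.motility import crop_track, ensemble_msd, fit_motion_model

        cfg = track_cfg(n_cells=400, aggregate_radius_um=300.0, seed=6)
        tracks, _ = simulate_tracks(cfg)
        pre = [t for t in (crop_track(t, t_max_h=4.0) for t in tracks) if t]
        post = [t for t in (crop_track(t, t_min_h=4.0) for t in tracks) if t]
        assert fit_motion_model(ensemble_msd(pre)).regime == "diffusive"
        assert fit_motion_model(ensemble_msd(post)).regime == "directed"

    def test_determinism(self):
        cfg = track_cfg(loc_noise_um=0.5, miss_rate=0.02, seed=13)
        a, ga = simulate_tracks(cfg)
        b, gb = simulate_tracks(cfg)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions(), tb.positions())
            np.testing.assert_array_equal(ta.frames, tb.frames)
        assert ga.track_classes == gb.track_classes

    def test_miss_rate_drops_frames(self):
        full, _ = simulate_tracks(track_cfg(seed=7))
        dropped, _ = simulate_tracks(track_cfg(miss_rate=0.1, seed=7))
        n_full = sum(len(t) for t in full)
        n_drop = sum(len(t) for t in dropped)
        assert n_drop < n_full

    def test_start_positions_inside_sphere(self):
        tracks, _ = simulate_tracks(track_cfg(n_cells=200, seed=8))
        starts = np.array([t.positions()[0] for t in tracks if t.frames[0] == 0])
        assert np.all(np.linalg.norm(starts, axis=1) <= 100.0 + 1e-9)


class TestRenderMovie:
    def _cfg(self, **track_kw):
        return SimConfig(
            seed=0,
            image=ImageConfig(size_px=64, pixel_size_um=1.0, organoid_radius_um=20.0,
                              domain_radius_um=5.0),
            tracks=TrackConfig(n_cells=1, aggregate_radius_um=20.0, t_switch_h=1.0,
                               duration_h=2.0, dt_min=15.0, loc_noise_um=0.0, **track_kw),
        )

    def test_static_cell_brightest_at_position(self):
        from helpers import static_track

        tr = static_track((5.0, -3.0, 2.0), n_frames=4)
        stack = render_track_movie([tr], self._cfg())
        for f in range(4):
            z, y, x = np.unravel_index(np.argmax(stack.data[f]), stack.data[f].shape)
            pos_um = np.array([x, y, z]) * stack.pixel_size_um + np.array(stack.origin_um)
            np.testing.assert_allclose(pos_um, [5.0, -3.0, 2.0], atol=0.51)

    def test_empty_tracks_background_only(self):
        stack = render_track_movie([], self._cfg())
        assert stack.data.max() == 0.0

    def test_small_sigma_refused(self):
        with pytest.raises(ValueError, match="sigma"):
            render_track_movie([], self._cfg(), spot_sigma_um=0.5)

    def test_detection_linking_recovers_links(self):
        from orgakit.synth import simulate_tracks
        from orgakit.tracking import detect_movie, link_tracks

        cfg = SimConfig(
            seed=3,
            image=ImageConfig(size_px=64, pixel_size_um=1.0, organoid_radius_um=40.0,
                              domain_radius_um=5.0),
            tracks=TrackConfig(n_cells=12, aggregate_radius_um=40.0, D_um2_per_min=0.05,
                               v_um_per_min=0.1, t_switch_h=1.0, duration_h=1.5,
                               dt_min=15.0, loc_noise_um=0.0),
        )
        tracks, _ = simulate_tracks(cfg)
        stack = render_track_movie(tracks, cfg, spot_sigma_um=2.0)
        frames = detect_movie(stack, sigma_um=2.0, quality_min=5.0)
        linked = link_tracks(frames, max_disp_um=6.0)
        # ground-truth link count vs recovered (separation condition holds
        # for most of these random layouts; require >= 95% of links)
        true_links = sum(len(t) - 1 for t in tracks)
        correct = 0
        for lt in linked:
            pos = lt.positions()
            for a in range(len(pos) - 1):
                # a link is correct if both endpoints are within 1 um of the
                # same ground-truth track at the right frames
                fa, fb = lt.frames[a], lt.frames[a + 1]
                for gt_tr in tracks:
                    f = gt_tr.frames
                    if fa in f and fb in f:
                        ia = int(np.where(f == fa)[0][0])
                        ib = int(np.where(f == fb)[0][0])
                        gp = gt_tr.positions()
                        if (np.linalg.norm(gp[ia] - pos[a]) < 1.0
                                and np.linalg.norm(gp[ib] - pos[a + 1]) < 1.0):
                            correct += 1
                            break
        assert correct / true_links >= 0.95
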