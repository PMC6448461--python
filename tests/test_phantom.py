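"""Synthetic phantom: rendering, decay sampling, forward pit model, truth."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_phantom
from trackdose.phantom import (
    Ellipse,
    PhantomConfig,
    forward_pit_model,
    generate_phantom,
    sample_dip_angles,
    simulate_decays,
    simulate_phantom,
    truth_dose_map,
    write_truth_bundle,
)
from trackdose.pit_geometry import EtchConfig, detector_response
from trackdose.segmentation import read_rgb_image, segment_regions
from trackdose.spectra import DecayModel, decay_correction_factor, local_dose_map


class TestRendering:
    def test_segmentation_recovers_truth_masks_exactly(self):
        cfg = small_phantom()
        image, truth = generate_phantom(cfg)
        tissue, pink, purple = segment_regions(image, pixel_size_um=cfg.pixel_size_um)
        np.testing.assert_array_equal(tissue.mask, truth.tissue.mask)
        np.testing.assert_array_equal(pink.mask, truth.pink.mask)
        np.testing.assert_array_equal(purple.mask, truth.purple.mask)

    def test_zero_size_tumor_gives_empty_pink(self):
        cfg = small_phantom(tumor_ellipses=())
        _, truth = generate_phantom(cfg)
        assert not truth.pink.mask.any()
        assert truth.purple.mask.sum() == truth.tissue.mask.sum()

    def test_geometry_outside_image_rejected(self):
        cfg = small_phantom(tissue_ellipse=Ellipse(250.0, 250.0, 400.0, 200.0))
        with pytest.raises(ValueError, match="outside"):
            generate_phantom(cfg)

    def test_fill_colors_checked_against_thresholds(self):
        cfg = small_phantom(pink_rgb=(200, 200, 200))  # outside the band-pass
        with pytest.raises(ValueError, match="band-pass"):
            generate_phantom(cfg)


class TestDecaySampling:
    def test_zero_activity_no_events(self, curve):
        cfg = small_phantom(activity_normal_per_mm2=0.0, activity_tumor_per_mm2=0.0)
        _, truth = generate_phantom(cfg)
        events = simulate_decays(cfg, truth, curve)
        assert len(events) == 0

    def test_window_fraction_matches_decay_curve(self, curve):
        """Among decays drawn over [0, t2], the fraction landing in the
        recording window is (e^-lt1 - e^-lt2)/(1 - e^-lt2) ~ 0.304."""
        cfg = small_phantom(seed=5, activity_normal_per_mm2=60000.0)
        _, truth = generate_phantom(cfg)
        events = simulate_decays(cfg, truth, curve)
        n = len(events)
        assert n > 10_000
        m = cfg.decay
        lam = m.lambda_per_h
        p = (np.exp(-lam * m.t1_h) - np.exp(-lam * m.t2_h)) / (1 - np.exp(-lam * m.t2_h))
        frac = ((events.decay_time_h >= m.t1_h) & (events.decay_time_h < m.t2_h)).mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_registration_fraction_is_detection_efficiency(self, curve):
        """At fixed S = 1 (LET 100 with the default curve) the fraction of
        isotropic-flux dip angles above critical is eta = 0.75."""
        cfg = small_phantom(
            seed=9, let_mean_keV_um=100.0, let_sd_keV_um=1e-6,
            activity_normal_per_mm2=90000.0, activity_tumor_per_mm2=0.0,
        )
        _, truth = generate_phantom(cfg)
        events = simulate_decays(cfg, truth, curve)
        n = len(events)
        assert n > 10_000
        frac = events.registered.mean()
        assert abs(frac - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)

    def test_dip_angle_distribution(self):
        rng = np.random.default_rng(61)
        theta = sample_dip_angles(50_000, rng)
        # sin^2(theta) should be uniform on (0, 1)
        u = np.sin(theta) ** 2
        assert abs(u.mean() - 0.5) < 3 * np.sqrt(1 / 12 / 50_000)
        assert theta.min() > 0 and theta.max() <= np.pi / 2

    def test_positions_stay_inside_region(self, curve):
        cfg = small_phantom(seed=13)
        _, truth = generate_phantom(cfg)
        events = simulate_decays(cfg, truth, curve)
        pink = events[events.region == "pink"]
        ell = cfg.tumor_ellipses[0]
        # jitter is sub-pixel, so allow one pixel of slack at the rim
        r = ((pink.x_um - ell.cx_um) / (ell.rx_um + cfg.pixel_size_um)) ** 2 + (
            (pink.y_um - ell.cy_um) / (ell.ry_um + cfg.pixel_size_um)
        ) ** 2
        assert (r <= 1.0).all()


class TestForwardPitModel:
    def test_vertical_incidence_circular_pit(self, curve):
        """At normal incidence the pit is circular with d = 2B sqrt(S/(S+2))."""
        etch = EtchConfig()
        let = curve.let_from_response(2.0 / 3.0)
        da, db = forward_pit_model(let, np.pi / 2, etch, curve)
        assert da == pytest.approx(3.3, rel=1e-9)
        assert db == pytest.approx(3.3, rel=1e-9)

    def test_round_trip_recovers_response(self, curve):
        rng = np.random.default_rng(67)
        etch = EtchConfig()
        let = rng.uniform(10.0, 590.0, 100)
        s = curve.response_from_let(let)
        theta_c = np.arcsin(1.0 / (s + 1.0))
        theta = theta_c + rng.uniform(0.01, 1.0, 100) * (np.pi / 2 - theta_c)
        da, db = forward_pit_model(let, theta, etch, curve)
        np.testing.assert_allclose(detector_response(da, db, etch), s, rtol=1e-9)

    def test_grazing_angle_minor_axis_vanishes(self, curve):
        etch = EtchConfig()
        s = curve.response_from_let(130.0)
        theta_c = np.arcsin(1.0 / (s + 1.0))
        _, db = forward_pit_model(130.0, theta_c + 1e-9, etch, curve)
        assert db < 1e-3

    def test_sub_critical_angle_rejected(self, curve):
        s = curve.response_from_let(130.0)
        theta_c = np.arcsin(1.0 / (s + 1.0))
        with pytest.raises(ValueError, match="critical"):
            forward_pit_model(130.0, theta_c - 0.05, EtchConfig(), curve)

    def test_major_never_smaller_than_minor(self, curve):
        rng = np.random.default_rng(71)
        let = rng.uniform(50.0, 400.0, 500)
        s = curve.response_from_let(let)
        theta_c = np.arcsin(1.0 / (s + 1.0))
        theta = theta_c + rng.uniform(0.0, 1.0, 500) * (np.pi / 2 - theta_c)
        da, db = forward_pit_model(let, theta, EtchConfig(), curve)
        assert np.all(da >= db - 1e-12)


class TestTruthConsistency:
    def test_truth_dose_map_matches_direct_scoring(self, curve):
        cfg = small_phantom(seed=17)
        _, _, events = simulate_phantom(cfg, curve)
        truth_map = truth_dose_map(events, cfg)
        m = cfg.decay
        window = events[(events.decay_time_h >= m.t1_h) & (events.decay_time_h < m.t2_h)]
        frame = pd.DataFrame(
            {
                "x_um": window.x_um,
                "y_um": window.y_um,
                "let_keV_um": window.let_keV_um,
                "weight": 1.0,
                "eta": 1.0,
            }
        )
        direct = local_dose_map(frame, truth_map.origin_um, truth_map.dose_Gy.shape, 10.0)
        np.testing.assert_allclose(direct.dose_Gy, truth_map.dose_Gy, rtol=1e-12)

    def test_efficiency_weighting_recovers_true_fluence(self, curve):
        """Summing 1/eta over registered window events reproduces the true
        traversal count per LET bin within 3 sigma of the thinning noise."""
        cfg = PhantomConfig(seed=19)
        _, _, events = simulate_phantom(cfg, curve)
        m = cfg.decay
        window = events[(events.decay_time_h >= m.t1_h) & (events.decay_time_h < m.t2_h)]
        eta = 1.0 - 1.0 / (window.response_S + 1.0) ** 2
        edges = np.array([3.5, 110.0, 150.0, 600.0])
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (window.let_keV_um >= lo) & (window.let_keV_um < hi)
            truth_n = sel.sum()
            est = (1.0 / eta[sel & window.registered]).sum()
            sigma = np.sqrt(((1.0 - eta[sel]) / eta[sel] ** 2).sum())
            assert abs(est - truth_n) < 3 * sigma + 1

    def test_decay_recovery(self, curve):
        """Scaling the recording-window decay count by 1 + D0/D recovers the
        pre-window count within 3 sigma of counting statistics."""
        cfg = PhantomConfig(seed=23)
        _, truth, events = simulate_phantom(cfg, curve)
        m = cfg.decay
        n_pre = sum(c["pre_window"] for c in truth.decay_counts.values())
        n_win = sum(c["window"] for c in truth.decay_counts.values())
        f = decay_correction_factor(m)
        sigma = np.sqrt(f**2 * n_win + n_pre)
        assert abs(f * n_win - n_pre) < 3 * sigma


class TestBundle:
    def test_same_seed_byte_identical(self, tmp_path, curve):
        outs = []
        for sub in ("a", "b"):
            cfg = small_phantom(seed=29)
            image, truth, events = simulate_phantom(cfg, curve)
            paths = write_truth_bundle(tmp_path / sub, cfg, image, truth, events, curve)
            outs.append(paths)
        for key in ("pits", "events", "markers", "manifest"):
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()

    def test_pit_rows_match_registered_window_events(self, tmp_path, curve):
        cfg = small_phantom(seed=31)
        image, truth, events = simulate_phantom(cfg, curve)
        paths = write_truth_bundle(tmp_path, cfg, image, truth, events, curve)
        pits = pd.read_csv(paths["pits"])
        m = cfg.decay
        expected = (
            events.registered
            & (events.decay_time_h >= m.t1_h)
            & (events.decay_time_h < m.t2_h)
        ).sum()
        assert len(pits) == expected
        assert (pits.minor_axis_um <= pits.major_axis_um).all()

    def test_micrograph_readable_and_segmentable(self, tmp_path, curve):
        cfg = small_phantom(seed=37)
        image, truth, events = simulate_phantom(cfg, curve)
        paths = write_truth_bundle(tmp_path, cfg, image, truth, events, curve)
        rgb = read_rgb_image(paths["micrograph"])
        _, pink, _ = segment_regions(rgb, pixel_size_um=cfg.pixel_size_um)
        np.testing.assert_array_equal(pink.mask, truth.pink.mask)
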