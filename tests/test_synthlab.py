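"""Synthetic generators: profiles, kinematics, footprints, microvilli, shear."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rollmap import synthlab as sl

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# adhesion profile
# --------------------------------------------------------------------------

class TestAdhesionProfile:
    def test_flat_profile_is_constant(self):
        p = sl.make_adhesion_profile([], baseline_dwell=0.1)
        th = np.linspace(0, TWO_PI, 100)
        assert np.allclose(p.dwell(th), 0.1)

    def test_patch_arithmetic(self):
        p = sl.make_adhesion_profile([(np.pi, np.pi / 2, 9.0)], baseline_dwell=0.1)
        assert p.dwell(np.pi) == pytest.approx(1.0)
        assert p.dwell(0.0) == pytest.approx(0.1)

    def test_two_patches_give_secondary_autocorrelation_peak_near_pi(self):
        # independent numeric autocorrelation of the constructed profile
        p = sl.make_adhesion_profile(
            [(0.5 * np.pi, 0.4 * np.pi, 6.0), (1.5 * np.pi, 0.4 * np.pi, 6.0)], 0.1
        )
        th = np.arange(0, 8 * TWO_PI, TWO_PI / 200)
        tau = p.dwell(th)
        a = tau - tau.mean()
        acf = np.correlate(a, a, "full")[len(a) - 1 :] / (len(a) * np.mean(a**2))
        k_pi = int(np.pi / (TWO_PI / 200))
        peak_pi = acf[k_pi - 10 : k_pi + 10].max()
        assert peak_pi > 0.5  # strong secondary peak at half-period

    def test_rejects_nonpositive_baseline_naming_field(self):
        with pytest.raises(ValueError, match="baseline_dwell"):
            sl.make_adhesion_profile([], baseline_dwell=0.0)

    @given(
        center=st.floats(0, TWO_PI),
        width=st.floats(0.01, TWO_PI - 0.01),
        mult=st.floats(1.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_dwell_positive_and_periodic(self, center, width, mult):
        p = sl.make_adhesion_profile([(center, width, mult)], 0.05)
        th = np.linspace(0, TWO_PI, 257)
        assert np.all(p.dwell(th) > 0)
        assert np.allclose(p.dwell(th), p.dwell(th + TWO_PI))


# --------------------------------------------------------------------------
# rolling kinematics / movie
# --------------------------------------------------------------------------

class TestRollingKinematics:
    def test_distance_per_cycle_is_circumference(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        tr = sl.simulate_rolling_kinematics(flat_profile, geom, n_cycles=1)
        # x advances by r*theta -> one full cycle covers pi*d ~ 44.0 um
        d_per_cycle = tr.x_um[-1] / tr.theta[-1] * TWO_PI
        assert d_per_cycle == pytest.approx(np.pi * 14.0, rel=1e-6)

    def test_spot_trace_is_cosine_with_amplitude_R(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0, spot_positions=((5.0, 0.0, 0.0),))
        tr = sl.simulate_rolling_kinematics(flat_profile, geom, n_cycles=1)
        x, y = tr.spot_xy_cm(0)
        assert np.allclose(x, 5.0 * np.cos(tr.theta), atol=1e-12)
        assert np.allclose(y, 0.0)
        assert np.max(np.abs(x)) <= 5.0 + 1e-9

    def test_detachment_lowers_rotation_per_distance(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        ct = flat_profile.cycle_time()
        tr = sl.simulate_rolling_kinematics(
            flat_profile, geom, n_cycles=3, detachment_intervals=((ct, 2 * ct),)
        )
        r = 7.0
        dth = np.gradient(tr.theta, tr.x_um) * r
        inside = tr.detached
        # skip boundary frames where the window straddles the transition
        core = inside & np.roll(inside, 2) & np.roll(inside, -2)
        outside = ~inside & np.roll(~inside, 2) & np.roll(~inside, -2)
        assert np.all(dth[core] <= 0.5)
        assert np.allclose(dth[outside], 1.0, atol=0.05)

    def test_rotation_conservation(self, patchy_profile):
        # mean angular speed over a period times rolling time ~ angle traversed
        geom = sl.CellGeometry(diameter=14.0)
        tr = sl.simulate_rolling_kinematics(patchy_profile, geom, n_cycles=4)
        rolling_time = tr.t[-1]
        mean_omega = TWO_PI / patchy_profile.cycle_time()
        assert tr.theta[-1] == pytest.approx(mean_omega * rolling_time, rel=0.01)

    def test_spot_outside_sphere_rejected(self):
        with pytest.raises(ValueError, match="outside the sphere"):
            sl.CellGeometry(diameter=14.0, spot_positions=((8.0, 0.0, 0.0),))

    def test_too_small_image_rejected_with_required_size(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        imaging = sl.ImagingParams(image_shape=(20, 20))
        with pytest.raises(ValueError, match="requires at least"):
            sl.simulate_rolling_movie(flat_profile, geom, imaging, n_cycles=1)

    def test_identical_seed_bit_identical_movie(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        imaging = sl.ImagingParams(noise_model=(2.0, 0.0))
        m1, _ = sl.simulate_rolling_movie(flat_profile, geom, imaging, n_cycles=1, seed=5)
        m2, _ = sl.simulate_rolling_movie(flat_profile, geom, imaging, n_cycles=1, seed=5)
        assert np.array_equal(m1, m2)


# --------------------------------------------------------------------------
# footprint tiles
# --------------------------------------------------------------------------

class TestFootprintSimulator:
    def test_flat_profile_events_uniform_along_x(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams(rupture_density_scale=3.0)
        _, truth = sl.simulate_footprint_tiles(
            flat_profile, geom, params, track_length_cycles=4, seed=1
        )
        x = truth.event_xy_um[:, 0]
        hist, _ = np.histogram(x, bins=20, range=(x.min(), x.max()))
        chi2, p = stats.chisquare(hist)
        assert p > 0.01

    def test_patch_density_peaks_repeat_at_circumference(self):
        profile = sl.make_adhesion_profile([(np.pi, 0.4 * np.pi, 20.0)], 0.3)
        geom = sl.CellGeometry(diameter=14.0)
        _, truth = sl.simulate_footprint_tiles(
            profile, geom, sl.FootprintSimParams(), track_length_cycles=4, seed=2
        )
        x = truth.event_xy_um[:, 0]
        hist, edges = np.histogram(x, bins=int(x.max() - x.min()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        # autocorrelation peak spacing of the density profile
        a = hist - hist.mean()
        acf = np.correlate(a, a, "full")[len(a) - 1 :]
        circ_px = int(round(np.pi * 14.0 / (centers[1] - centers[0])))
        peak = np.argmax(acf[circ_px - 5 : circ_px + 5]) + circ_px - 5
        assert abs(peak * (centers[1] - centers[0]) - np.pi * 14.0) < 2.0

    def test_tiles_concatenate_to_clean_image_when_uncorrupted(self, patchy_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams(background_level=0.0)
        tiles, truth = sl.simulate_footprint_tiles(
            patchy_profile, geom, params, track_length_cycles=2, seed=3
        )
        rebuilt = np.zeros_like(truth.clean_image)
        for tile, off in zip(tiles, truth.tile_offsets_px):
            rebuilt[:, off : off + tile.shape[1]] = tile
        assert np.array_equal(rebuilt, truth.clean_image)

    def test_event_count_scales_linearly_with_density(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        counts = []
        scales = [2.0, 4.0, 8.0]
        for s in scales:
            params = sl.FootprintSimParams(rupture_density_scale=s)
            _, truth = sl.simulate_footprint_tiles(
                flat_profile, geom, params, track_length_cycles=3, seed=9
            )
            counts.append(len(truth.event_xy_um))
        ratios = np.array(counts) / np.array(scales)
        assert np.all(np.abs(ratios / ratios.mean() - 1) < 0.05)

    def test_zero_rate_rejected(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams(rupture_density_scale=0.0)
        with pytest.raises(ValueError, match="zero event rate"):
            sl.simulate_footprint_tiles(flat_profile, geom, params, 2, seed=0)

    def test_band_wider_than_image_rejected(self, flat_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams(track_band_width=20.0, tile_shape=(64, 256))
        with pytest.raises(ValueError, match="wider than"):
            sl.simulate_footprint_tiles(flat_profile, geom, params, 2, seed=0)

    def test_events_inside_band(self, patchy_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams()
        _, truth = sl.simulate_footprint_tiles(
            patchy_profile, geom, params, track_length_cycles=2, seed=4
        )
        y = truth.event_xy_um[:, 1]
        center = truth.band_center_row  # px row; convert to um via pixel size
        center_um = truth.clean_image.shape[0] * truth.pixel_size / 2.0
        assert np.all(np.abs(y - center_um) <= truth.band_width_um / 2 + 1e-9)

    def test_identical_seed_bit_identical_tiles(self, patchy_profile):
        geom = sl.CellGeometry(diameter=14.0)
        params = sl.FootprintSimParams(noise_sd=0.5, tile_jitter_px=3)
        t1, g1 = sl.simulate_footprint_tiles(patchy_profile, geom, params, 2, seed=6)
        t2, g2 = sl.simulate_footprint_tiles(patchy_profile, geom, params, 2, seed=6)
        assert all(np.array_equal(a, b) for a, b in zip(t1, t2))
        assert np.array_equal(g1.tile_offsets_px, g2.tile_offsets_px)


# --------------------------------------------------------------------------
# microvilli Monte-Carlo
# --------------------------------------------------------------------------

class TestMicrovilli:
    def test_mean_instantaneous_contacts_match_area_fraction(self):
        # brute-force count over seeds vs the spherical-cap area fraction
        geom = sl.CellGeometry(diameter=14.1)
        r = 14.1 / 2
        cap_frac = (1 - np.cos((5.7 / 2) / r)) / 2  # cap area / sphere area
        expected = 730 * cap_frac
        means = []
        for seed in range(30):
            census = sl.simulate_microvilli_contacts(geom, seed=seed)
            means.append(np.mean(sl.instantaneous_contact_counts(census)))
        assert np.mean(means) == pytest.approx(expected, rel=0.05)
        # and consistent with the flat-cap approximation 730*26/(pi*14.1^2) ~ 30
        assert np.mean(means) == pytest.approx(30.0, rel=0.10)

    def test_bin_counts_poisson_cv(self):
        # coefficient of variation across bins ~ 1/sqrt(mean per bin)
        geom = sl.CellGeometry(diameter=14.1)
        cvs, expected_cvs = [], []
        for seed in range(100):
            census = sl.simulate_microvilli_contacts(geom, seed=seed)
            counts = census.tether_counts[0]
            cvs.append(np.std(counts) / np.mean(counts))
            expected_cvs.append(1.0 / np.sqrt(np.mean(counts)))
        assert np.mean(cvs) == pytest.approx(np.mean(expected_cvs), rel=0.15)

    def test_cycles_identical_and_bounded(self):
        census = sl.simulate_microvilli_contacts(
            sl.CellGeometry(diameter=14.1), n_cycles=4, seed=3
        )
        assert np.all(census.tether_counts == census.tether_counts[0])
        assert census.tether_counts[0].sum() <= census.n_villi

    def test_no_order_of_magnitude_patches(self):
        # random placement cannot produce 10x max/min bin contrast
        geom = sl.CellGeometry(diameter=14.1)
        n_bad = 0
        for seed in range(100):
            counts = sl.simulate_microvilli_contacts(geom, seed=seed).tether_counts[0]
            if counts.max() / max(counts.min(), 1) > 10:
                n_bad += 1
        assert n_bad == 0

    def test_truncated_bin_flagged(self):
        census = sl.simulate_microvilli_contacts(
            sl.CellGeometry(diameter=14.1), bin_width=0.7, seed=0
        )
        assert census.truncated_last_bin


# --------------------------------------------------------------------------
# wall shear stress
# --------------------------------------------------------------------------

class TestWallShearStress:
    def test_reference_value(self):
        # hand-evaluated 6*mu*Q/(w0*h0^2) with unit conversion
        ch = sl.FlowChannel(h0=80.0, w0=2000.0, mu=1e-3, Q=100.0)
        assert sl.wall_shear_stress(ch) == pytest.approx(0.013, abs=5e-4)

    def test_linearity_in_flow_rate(self):
        s1 = sl.wall_shear_stress(sl.FlowChannel(Q=100.0))
        s2 = sl.wall_shear_stress(sl.FlowChannel(Q=200.0))
        assert s2 == pytest.approx(2 * s1)

    def test_zero_flow(self):
        assert sl.wall_shear_stress(sl.FlowChannel(Q=0.0)) == 0.0

    @pytest.mark.parametrize("field", ["h0", "w0", "mu"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            sl.FlowChannel(**{field: 0.0})
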