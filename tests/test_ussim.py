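import numpy as np
import pytest
from scipy import signal, stats

from usimgen import scatterers as sc
from usimgen import ussim
from usimgen.errors import GeometryError, RangeError, SamplingError
from usimgen.preprocess import TemplateImage


def _single_scatterer(x, z, coeff=1.0):
    return sc.ScattererMap(np.array([[x, z]]), np.array([coeff]), "background")


class TestProbeSpec:
    def test_default_geometry_matches_c3(self):
        p = ussim.ProbeSpec()
        assert p.n_elements == 192
        assert p.fov == 73.0
        # full aperture arc subtends the field of view -> radius ~69 mm
        assert p.curvature_radius * 1e3 == pytest.approx(69.3, abs=0.5)
        elems = p.element_positions()
        assert elems.shape == (192, 2)
        # center of the arc touches the surface, edges curve backwards
        assert abs(elems[:, 1].max()) < 1e-6
        assert elems[0, 1] < 0 and elems[-1, 1] < 0

    def test_nyquist_guard(self):
        with pytest.raises(SamplingError):
            ussim.ProbeSpec(sampling_freq=5e6)

    def test_yaml_round_trip(self, tmp_path, fast_probe):
        fast_probe.to_yaml(tmp_path / "probe.yaml")
        back = ussim.ProbeSpec.from_yaml(tmp_path / "probe.yaml")
        assert back == fast_probe


class TestSimulateRF:
    def test_empty_map_zero_traces(self, fast_probe):
        rf = ussim.simulate_rf(sc.ScattererMap.empty(), fast_probe)
        assert rf.samples.shape[0] == fast_probe.n_elements
        assert np.all(rf.samples == 0)

    def test_round_trip_echo_time(self, fast_probe):
        """Echo from 20 mm straight ahead arrives at t = 2r/c = 25.97 us."""
        rf = ussim.simulate_rf(_single_scatterer(0.0, 20e-3), fast_probe)
        center = fast_probe.n_elements // 2
        env = np.abs(signal.hilbert(rf.samples[center]))
        t_peak = rf.times[np.argmax(env)]
        t_expected = 2 * 20e-3 / fast_probe.sound_speed
        assert t_expected == pytest.approx(25.97e-6, abs=0.01e-6)
        assert abs(t_peak - t_expected) < ussim.pulse_halfwidth(fast_probe)

    def test_linearity_in_coefficients(self, fast_probe):
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(-10e-3, 10e-3, 30), rng.uniform(5e-3, 40e-3, 30)]
        )
        coeffs = rng.uniform(0.1, 1.0, 30)
        a = ussim.simulate_rf(sc.ScattererMap(pos, coeffs), fast_probe)
        b = ussim.simulate_rf(sc.ScattererMap(pos, 2 * coeffs), fast_probe)
        np.testing.assert_allclose(b.samples, 2 * a.samples, rtol=1e-9, atol=1e-30)

    def test_superposition(self, fast_probe):
        rng = np.random.default_rng(1)
        pos = np.column_stack(
            [rng.uniform(-10e-3, 10e-3, 20), rng.uniform(5e-3, 40e-3, 20)]
        )
        coeffs = rng.uniform(0.1, 1.0, 20)
        whole = ussim.simulate_rf(sc.ScattererMap(pos, coeffs), fast_probe)
        part1 = ussim.simulate_rf(sc.ScattererMap(pos[:10], coeffs[:10]), fast_probe)
        part2 = ussim.simulate_rf(sc.ScattererMap(pos[10:], coeffs[10:]), fast_probe)
        scale = np.abs(whole.samples).max()
        np.testing.assert_allclose(
            whole.samples, part1.samples + part2.samples, atol=1e-6 * scale
        )

    def test_scatterer_beyond_depth_rejected(self, fast_probe):
        with pytest.raises(RangeError):
            ussim.simulate_rf(_single_scatterer(0.0, 0.2), fast_probe)


class TestDemodulateIQ:
    def test_pure_tone_constant_magnitude(self, fast_probe):
        fs = fast_probe.sampling_freq
        t = np.arange(4096) / fs
        tone = np.cos(2 * np.pi * fast_probe.center_freq * t)
        rf = ussim.RFFrame(tone[None, :], 0.0, fs)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        mag = np.abs(iq.samples[0, 500:-500])
        assert mag.std() / mag.mean() < 0.01
        assert mag.mean() == pytest.approx(1.0, rel=0.02)

    def test_zero_rf_zero_iq(self, fast_probe):
        rf = ussim.RFFrame(np.zeros((4, 512)), 0.0, fast_probe.sampling_freq)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        assert np.all(iq.samples == 0)

    def test_envelope_peak_matches_hilbert_oracle(self, fast_probe):
        rf = ussim.simulate_rf(_single_scatterer(2e-3, 25e-3), fast_probe)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        for e in [0, fast_probe.n_elements // 2, fast_probe.n_elements - 1]:
            ref = np.argmax(np.abs(signal.hilbert(rf.samples[e])))
            got = np.argmax(np.abs(iq.samples[e]))
            assert abs(int(got) - int(ref)) <= 1

    def test_invalid_demod_freq(self, fast_probe):
        rf = ussim.RFFrame(np.zeros((2, 64)), 0.0, fast_probe.sampling_freq)
        with pytest.raises(ValueError):
            ussim.demodulate_iq(rf, -1.0)


def _beamform_point(probe, x, z, half_mm=3.0, step_mm=0.1):
    scat = _single_scatterer(x, z)
    rf = ussim.simulate_rf(scat, probe)
    iq = ussim.demodulate_iq(rf, probe.center_freq)
    n = int(2 * half_mm / step_mm) + 1
    grid = ussim.CartesianGrid(
        origin=(x - half_mm * 1e-3, z - half_mm * 1e-3),
        spacing=(step_mm * 1e-3, step_mm * 1e-3),
        shape=(n, n),
    )
    img = ussim.das_beamform(iq, probe, grid)
    r, c = np.unravel_index(np.argmax(np.abs(img)), img.shape)
    gx, gz = grid.points()
    return gx[r, c], gz[r, c], img, grid


class TestDASBeamform:
    def test_point_scatterer_localized(self, fast_probe):
        px, pz, _, _ = _beamform_point(fast_probe, 0.0, 30e-3)
        err = np.hypot(px - 0.0, pz - 30e-3)
        assert err < fast_probe.wavelength

    def test_zero_iq_zero_image(self, fast_probe):
        iq = ussim.IQFrame(
            np.zeros((fast_probe.n_elements, 1024), dtype=complex),
            0.0,
            fast_probe.sampling_freq,
            fast_probe.center_freq,
        )
        grid = ussim.SectorGrid(fast_probe, 0.04, 32, 32)
        img = ussim.das_beamform(iq, fast_probe, grid)
        assert np.all(img == 0)

    def test_two_separated_scatterers(self, fast_probe):
        pts = [(-8e-3, 25e-3), (8e-3, 35e-3)]
        scat = sc.ScattererMap(np.array(pts), np.array([1.0, 1.0]))
        rf = ussim.simulate_rf(scat, fast_probe)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        for x, z in pts:
            n = 61
            grid = ussim.CartesianGrid(
                (x - 3e-3, z - 3e-3), (0.1e-3, 0.1e-3), (n, n)
            )
            img = np.abs(ussim.das_beamform(iq, fast_probe, grid))
            r, c = np.unravel_index(np.argmax(img), img.shape)
            gx, gz = grid.points()
            err = np.hypot(gx[r, c] - x, gz[r, c] - z)
            assert err < fast_probe.wavelength

    def test_grid_outside_sector_rejected(self, fast_probe):
        iq = ussim.IQFrame(
            np.zeros((fast_probe.n_elements, 128), dtype=complex),
            0.0,
            fast_probe.sampling_freq,
            fast_probe.center_freq,
        )
        grid = ussim.CartesianGrid((-60e-3, 10e-3), (1e-3, 1e-3), (4, 4))
        with pytest.raises(GeometryError):
            ussim.das_beamform(iq, fast_probe, grid)


class TestBMode:
    def test_peak_maps_to_255_and_floor_to_zero(self):
        img = np.array([[1.0, 10 ** (-30 / 20), 10 ** (-15 / 20), 0.0]])
        bm = ussim.bmode(img, dynamic_range=30.0)
        assert bm.pixels[0, 0] == pytest.approx(255.0)
        assert bm.pixels[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert bm.pixels[0, 3] == 0.0
        assert 0 < bm.pixels[0, 2] < 255

    def test_monotone_in_envelope(self):
        env = np.linspace(0, 1, 50)[None, :]
        bm = ussim.bmode(env, 25.0)
        assert np.all(np.diff(bm.pixels[0]) >= 0)

    def test_wider_dynamic_range_keeps_more_pixels(self, fast_probe):
        rng = np.random.default_rng(2)
        img = rng.rayleigh(size=(40, 40))
        n25 = (ussim.bmode(img, 25.0).pixels > 0).sum()
        n35 = (ussim.bmode(img, 35.0).pixels > 0).sum()
        assert n35 >= n25

    def test_all_zero_is_black(self):
        bm = ussim.bmode(np.zeros((8, 8)), 30.0)
        assert np.all(bm.pixels == 0)


class TestScanConvert:
    def test_cartesian_identity(self, fast_probe):
        rng = np.random.default_rng(3)
        grid = ussim.CartesianGrid((-5e-3, 10e-3), (0.5e-3, 0.5e-3), (16, 16))
        bm = ussim.BModeImage(rng.uniform(0, 255, (16, 16)), 30.0, grid)
        out = ussim.scan_convert(bm, fast_probe, (16, 16))
        np.testing.assert_array_equal(out.pixels, bm.pixels)

    def test_constant_sector(self, fast_probe):
        sector = ussim.SectorGrid(fast_probe, 0.045, 64, 64)
        bm = ussim.BModeImage(np.full(sector.shape, 200.0), 30.0, sector)
        out = ussim.scan_convert(bm, fast_probe, (128, 128))
        inside = out.pixels > 0
        assert 0.2 < inside.mean() < 0.9
        assert np.all(out.pixels[inside] == pytest.approx(200.0))
        # corners are outside the sector
        assert out.pixels[0, 0] == 0 and out.pixels[0, -1] == 0

    def test_point_target_position_after_conversion(self, fast_probe):
        x0, z0 = 5e-3, 30e-3
        scat = _single_scatterer(x0, z0)
        rf = ussim.simulate_rf(scat, fast_probe)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        sector = ussim.SectorGrid(fast_probe, 0.045, 192, 192)
        bf = ussim.das_beamform(iq, fast_probe, sector)
        bm = ussim.bmode(bf, 30.0, sector)
        out = ussim.scan_convert(bm, fast_probe, (256, 256))
        # oracle: forward-map the polar-grid peak into display pixels
        pr, pc = np.unravel_index(np.argmax(bm.pixels), bm.pixels.shape)
        sx, sz = sector.points()
        peak_x, peak_z = sx[pr, pc], sz[pr, pc]
        col, row = out.grid.physical_to_pixel(peak_x, peak_z)
        orow, ocol = np.unravel_index(np.argmax(out.pixels), out.pixels.shape)
        assert max(abs(orow - row), abs(ocol - col)) <= 1.0

    def test_degenerate_shape_rejected(self, fast_probe):
        sector = ussim.SectorGrid(fast_probe, 0.045, 16, 16)
        bm = ussim.BModeImage(np.zeros(sector.shape), 30.0, sector)
        with pytest.raises(ValueError):
            ussim.scan_convert(bm, fast_probe, (1, 5))


class TestStatisticalProperties:
    def test_point_spread_median_under_wavelength(self, fast_probe):
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(20):
            ang = rng.uniform(-0.4, 0.4)
            r = rng.uniform(15e-3, 45e-3)
            x, z = r * np.sin(ang), r * np.cos(ang)
            px, pz, _, _ = _beamform_point(fast_probe, x, z)
            errors.append(np.hypot(px - x, pz - z))
        assert np.median(errors) < fast_probe.wavelength

    def test_speckle_envelope_closer_to_rayleigh_than_gaussian(self, fast_probe):
        rng = np.random.default_rng(8)
        n = 6000
        pos = np.column_stack(
            [rng.uniform(-8e-3, 8e-3, n), rng.uniform(20e-3, 36e-3, n)]
        )
        scat = sc.ScattererMap(pos, np.full(n, 1.0))
        rf = ussim.simulate_rf(scat, fast_probe)
        iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
        grid = ussim.CartesianGrid((-6e-3, 24e-3), (0.25e-3, 0.25e-3), (32, 48))
        env = np.abs(ussim.das_beamform(iq, fast_probe, grid)).ravel()
        env = env / env.mean()
        ks_rayleigh = stats.kstest(
            env, "rayleigh", args=(0, env.mean() / np.sqrt(np.pi / 2))
        ).statistic
        ks_gauss = stats.kstest(env, "norm", args=(env.mean(), env.std())).statistic
        assert ks_rayleigh < ks_gauss

    def test_end_to_end_determinism(self, fast_probe, cropped_heart_templates):
        def render():
            t = cropped_heart_templates[0]
            bg = sc.sample_background(t, 0.1, fast_probe.wavelength, seed=99)
            rf = ussim.simulate_rf(bg, fast_probe)
            iq = ussim.demodulate_iq(rf, fast_probe.center_freq)
            sector = ussim.SectorGrid(fast_probe, 0.045, 48, 48)
            bf = ussim.das_beamform(iq, fast_probe, sector)
            return ussim.scan_convert(
                ussim.bmode(bf, 30.0, sector), fast_probe, (64, 64)
            ).pixels

        np.testing.assert_array_equal(render(), render())
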