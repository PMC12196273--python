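"""Synthetic-study generator: kinetics, rendering, PK link, determinism."""

import math

import numpy as np
import pytest

from ivivr import simulate as sim


@pytest.fixture(scope="module")
def media():
    return sim.default_media()


@pytest.fixture(scope="module")
def forms():
    return sim.default_formulations()


class TestFractionDissolved:
    def test_zero_at_t0(self, forms, media):
        for f in forms.values():
            assert sim.fraction_dissolved(f, media["Wa"], 0.0) == 0.0

    def test_first_order_closed_form(self, media):
        # k * m = 0.1 / min at t = 10 min -> 1 - e^-1
        f = sim.FormulationSpec("t", "IR", 1.0, 8, 8, {"k": 0.1})
        got = sim.fraction_dissolved(f, sim.MediumSpec("Wa", 1.0), 10.0)
        assert got == pytest.approx(1.0 - math.exp(-1.0), abs=1e-12)

    def test_weibull_at_scale(self):
        f = sim.FormulationSpec("t", "XR", 1.0, 8, 8, {"tau": 240.0, "beta": 1.2})
        got = sim.fraction_dissolved(f, sim.MediumSpec("Wa", 1.0), 240.0)
        assert got == pytest.approx(1.0 - math.exp(-1.0), abs=1e-12)

    def test_nondecreasing_and_bounded(self, forms, media):
        t = np.linspace(0.0, 2000.0, 400)
        for f in forms.values():
            for m in media.values():
                frac = sim.fraction_dissolved(f, m, t)
                assert np.all(np.diff(frac) >= 0)
                assert frac.min() >= 0 and frac.max() <= 1
                assert sim.fraction_dissolved(f, m, 1e7) == pytest.approx(1.0)

    def test_negative_time_rejected(self, forms, media):
        with pytest.raises(ValueError):
            sim.fraction_dissolved(forms["IR500"], media["Wa"], -1.0)

    def test_rate_matches_numerical_derivative(self, forms, media):
        # absolute floor needed where the release has plateaued and the
        # finite difference of 1 - exp(-kt) loses all significant digits
        t = np.linspace(1.0, 300.0, 40)
        h = 1e-4
        for f in forms.values():
            num = (sim.fraction_dissolved(f, media["6_8"], t + h)
                   - sim.fraction_dissolved(f, media["6_8"], t - h)) / (2 * h)
            np.testing.assert_allclose(
                sim.release_rate(f, media["6_8"], t), num,
                rtol=1e-5, atol=1e-9)


class TestRendering:
    def test_t0_frame_blank_plume_full_tablet(self, forms, media):
        f = forms["IR500"]
        acq = sim.default_acquisitions(0.0)[255]
        img, frac, core, outer = sim.render_frame(f, media["Wa"], acq, 0.0)
        assert frac == 0.0
        n_rows = int(math.floor(outer[0]))
        assert img[:n_rows].sum() == 0.0
        area = img.sum() / acq.tablet_opacity
        assert area == pytest.approx(f.tablet_height_px * f.tablet_width_px,
                                     rel=1e-9)

    @pytest.mark.parametrize("fid", ["IR500", "XR750"])
    @pytest.mark.parametrize("t", [5.0, 30.0, 75.0, 300.0])
    def test_plume_integral_equals_dissolved_mass(self, forms, media, fid, t):
        f = forms[fid]
        acq = sim.default_acquisitions(0.0)[255]
        img, frac, core, outer = sim.render_frame(f, media["6_8"], acq, t)
        n_rows = int(math.floor(outer[0]))
        got = img[:n_rows].sum() / (acq.drug_absorptivity * f.dose)
        assert got == pytest.approx(frac, abs=1e-6)

    @pytest.mark.parametrize("fid", ["IR500", "XR750"])
    def test_mass_conservation_noise_free(self, forms, media, fid):
        """Tablet-mask opacity (in dose units) + plume integral /
        absorptivity stays equal to the dose on every frame."""
        f = forms[fid]
        acq = sim.default_acquisitions(0.0)[255]
        a0 = f.tablet_height_px * f.tablet_width_px
        for t in [0.0, 10.0, 60.0, 240.0, 700.0]:
            img, frac, core, outer = sim.render_frame(f, media["Wa"], acq, t)
            n_rows = int(math.floor(outer[0]))
            dissolved = img[:n_rows].sum() / acq.drug_absorptivity
            if fid == "XR750":  # exclude the gel annulus from the core sum
                gel = sim.GEL_OPACITY_FACTOR * acq.tablet_opacity * (
                    (outer[1] - outer[0]) * (outer[3] - outer[2])
                    - (core[1] - core[0]) * (core[3] - core[2]))
                core_sum = img[n_rows:].sum() - gel
            else:
                core_sum = img[n_rows:].sum()
            remaining = core_sum / (acq.tablet_opacity * a0) * f.dose
            assert dissolved + remaining == pytest.approx(f.dose, rel=1e-6)

    def test_video_determinism(self, media):
        f = sim.FormulationSpec("s", "IR", 100.0, 16, 24, {"k": 0.05})
        acq = sim.default_acquisitions()[520]
        kw = dict(duration=20.0, frame_interval=5.0, seed=42, shape=(56, 48))
        v1 = sim.simulate_dissolution_video(f, media["Wa"], acq, **kw)
        v2 = sim.simulate_dissolution_video(f, media["Wa"], acq, **kw)
        assert np.array_equal(v1.frames, v2.frames)

    def test_noise_is_seed_and_channel_specific(self, media):
        f = sim.FormulationSpec("s", "IR", 100.0, 16, 24, {"k": 0.05})
        acq = sim.default_acquisitions()[520]
        kw = dict(duration=20.0, frame_interval=5.0, shape=(56, 48))
        v1 = sim.simulate_dissolution_video(f, media["Wa"], acq, seed=1, **kw)
        v2 = sim.simulate_dissolution_video(f, media["Wa"], acq, seed=2, **kw)
        v3 = sim.simulate_dissolution_video(f, media["6_8"], acq, seed=1, **kw)
        assert not np.array_equal(v1.frames, v2.frames)
        assert not np.array_equal(v1.frames, v3.frames)

    def test_margin_violation_rejected(self, media):
        fat = sim.FormulationSpec("fat", "IR", 1.0, 54, 46, {"k": 0.1})
        with pytest.raises(ValueError, match="margin"):
            sim.simulate_dissolution_video(fat, media["Wa"],
                                           sim.default_acquisitions()[255],
                                           10.0, 5.0, 0, shape=(56, 48))


class TestPlasmaProfile:
    def test_zero_at_zero_and_nonnegative(self, forms):
        prof = sim.simulate_plasma_profile(
            forms["IR500"], sim.default_pk_params()["IR500"],
            np.arange(0.0, 1441.0, 10.0))
        assert prof.concentrations[0] == 0.0
        assert np.all(prof.concentrations >= 0)

    def test_ir_tmax_matches_bateman(self, forms):
        pk = sim.default_pk_params()["IR500"]
        grid = np.arange(0.0, 1441.0, 2.0)
        prof = sim.simulate_plasma_profile(forms["IR500"], pk, grid)
        ka = forms["IR500"].dissolution_params["k"] * 0.5  # pH 1.2 multiplier
        expected = sim.bateman_tmax(ka, pk.ke)
        got = grid[prof.concentrations.argmax()]
        assert abs(got - expected) <= 2.0  # within one grid step

    def test_matches_fine_quadrature_oracle(self, forms):
        """ka = 0.05, ke = 0.005, F dose/V = 1000 at t = 120 against an
        independent step-0.01 trapezoid of the Bateman integrand."""
        f = sim.FormulationSpec("o", "IR", 1.0, 8, 8, {"k": 0.05})
        pk = sim.PKParams(ke=0.005, V=1e-3, F=1.0, reference_medium="Wa")
        prof = sim.simulate_plasma_profile(f, pk, [0.0, 120.0])
        u = np.arange(0.0, 120.0 + 1e-9, 0.01)
        integrand = 0.05 * np.exp(-0.05 * u) * np.exp(-0.005 * (120.0 - u))
        oracle = 1000.0 * np.trapezoid(integrand, u)
        assert prof.concentrations[-1] == pytest.approx(oracle, rel=5e-3)

    def test_ir_unimodal_and_exponential_tail(self, forms):
        """Past release completion the profile decays log-linearly at ke."""
        pk = sim.default_pk_params()["IR500"]
        grid = np.arange(0.0, 1441.0, 5.0)
        prof = sim.simulate_plasma_profile(forms["IR500"], pk, grid)
        c = prof.concentrations
        peak = c.argmax()
        assert np.all(np.diff(c[:peak + 1]) >= 0)
        assert np.all(np.diff(c[peak:]) <= 0)
        tail = grid >= 1000.0
        slope = np.polyfit(grid[tail], np.log(c[tail]), 1)[0]
        assert slope == pytest.approx(-pk.ke, rel=0.01)

    def test_unsorted_grid_rejected(self, forms):
        with pytest.raises(ValueError):
            sim.simulate_plasma_profile(forms["IR500"],
                                        sim.default_pk_params()["IR500"],
                                        [0.0, 10.0, 5.0])


class TestGenerateStudy:
    def test_ir_frames_cover_sampling_plan(self, ir_study):
        for video in ir_study.videos.values():
            for t in (0, 5, 10, 15, 30, 45, 60, 75):
                video.frame_at(float(t))  # raises if missing

    def test_xr_frames_cover_17_point_plan(self, xr_study):
        assert len(xr_study.sampling_times) == 18  # t=0 plus 17 samples
        assert xr_study.sampling_times[-1] == 720.0
        for video in xr_study.videos.values():
            for t in xr_study.sampling_times:
                video.frame_at(t)

    def test_same_seed_same_grid_different_content(self, ir_study, xr_study):
        v_ir = ir_study.video("Wa", 255)
        v_xr = xr_study.video("Wa", 255)
        ir_sub = np.intersect1d(v_ir.times, v_xr.times)
        assert ir_sub.size > 0  # shared early grid
        assert not np.array_equal(v_ir.frame_at(30.0), v_xr.frame_at(30.0))

    def test_six_videos_share_frame_grid(self, ir_study):
        grids = [v.times for v in ir_study.videos.values()]
        for g in grids[1:]:
            np.testing.assert_array_equal(grids[0], g)

    def test_mismatched_plan_rejected(self):
        forms = sim.default_formulations()
        with pytest.raises(ValueError, match="capture window"):
            sim.generate_study(forms["IR500"], sim.default_media(),
                               sim.default_acquisitions(),
                               sim.default_pk_params()["IR500"],
                               sim.XR_SAMPLING_TIMES, seed=0)

    def test_study_reproducible_bit_for_bit(self, small_shape):
        a = sim.generate_default_study("IR500", seed=3, shape=small_shape)
        b = sim.generate_default_study("IR500", seed=3, shape=small_shape)
        np.testing.assert_array_equal(a.plasma_profile.concentrations,
                                      b.plasma_profile.concentrations)
        for key in a.videos:
            assert np.array_equal(a.videos[key].frames, b.videos[key].frames)

    def test_metformin_like_scale(self, ir_study):
        c = ir_study.plasma_profile.concentrations
        t = ir_study.plasma_profile.times
        assert 1000.0 <= c.max() <= 1150.0
        assert 90.0 <= t[c.argmax()] <= 150.0


class TestStudyIO:
    def test_png_roundtrip(self, tmp_path, ir_study_noisefree):
        root = sim.write_study(ir_study_noisefree, tmp_path)
        videos = sim.read_study_frames(root)
        assert set(videos) == set(ir_study_noisefree.videos)
        for key, video in videos.items():
            orig = ir_study_noisefree.videos[key]
            np.testing.assert_array_equal(video.times, orig.times)
            scale = orig.frames.max() / 65535.0
            np.testing.assert_allclose(video.frames, orig.frames,
                                       atol=scale * 0.51)
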