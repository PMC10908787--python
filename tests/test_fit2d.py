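import numpy as np
import pandas as pd
import pytest

from smlfm3d import fit2d, pipeline
from smlfm3d.optics import default_spec, gaussian_spot, render_psf
from smlfm3d.simulate import CameraModel, FrameRenderer, SimConfig, simulate_frame


def _spot_image(size, x, y, sigma_px, photons, background=0.0):
    return gaussian_spot(size, x, y, sigma_px, sigma_px, photons) + background


class TestDetection:
    def test_blank_image_has_no_seeds(self):
        img = np.zeros((64, 64))
        assert len(fit2d.detect_candidates(img, noise_std=1.0)) == 0

    def test_two_separated_spots_two_seeds(self):
        img = _spot_image(64, 20.3, 20.6, 1.3, 2000.0)
        img += _spot_image(64, 30.4, 20.6, 1.3, 2000.0)
        seeds = fit2d.detect_candidates(img, min_snr=5, psf_sigma_px=1.3, noise_std=1.0)
        assert len(seeds) == 2

    def test_isolated_emitter_detection_rate(self, lf_ctx, sparse_lf_dataset,
                                             sparse_lf_locs):
        """Nearly every isolated ground-truth emitter is recovered at the
        sparse benchmark density."""
        gt = sparse_lf_dataset.ground_truth
        locs = sparse_lf_locs
        hits = 0
        for r in gt.itertuples():
            p = locs[locs["frame"] == r.frame]
            if len(p) and np.min(np.hypot(p["x_nm"] - r.x_nm,
                                          p["y_nm"] - r.y_nm)) < 250:
                hits += 1
        assert hits / len(gt) >= 0.97


class TestGaussianFit:
    def test_noiseless_fit_recovers_center_exactly(self):
        img = _spot_image(15, 7.3, 6.8, 1.4, 5000.0, background=2.0)
        loc = fit2d.fit_gaussian2d(img, (7, 7), pixel_nm=1.0, window=11,
                                   sigma0_nm=1.2)
        assert loc["x_nm"] == pytest.approx(7.3, abs=1e-4)
        assert loc["y_nm"] == pytest.approx(6.8, abs=1e-4)
        assert loc["sigma_x"] == pytest.approx(1.4, abs=1e-3)
        assert loc["photons"] == pytest.approx(5000.0, rel=1e-3)

    def test_elliptical_fit_recovers_both_widths(self):
        img = gaussian_spot(15, 7.5, 7.5, 1.1, 2.0, 5000.0) + 3.0
        params, ok, _, _ = fit2d.fit_gaussian_batch(img[None], 1.5, circular=False)
        assert ok[0]
        assert params[0, 2] == pytest.approx(1.1, abs=0.01)
        assert params[0, 3] == pytest.approx(2.0, abs=0.01)

    def test_photon_estimate_at_zero_background(self):
        rng = np.random.default_rng(0)
        wins = rng.poisson(gaussian_spot(11, 5.5, 5.5, 1.3, 1.3, 4000.0)[None].repeat(200, 0))
        params, ok, _, _ = fit2d.fit_gaussian_batch(wins.astype(float), 1.3)
        assert np.mean(params[ok, 4]) == pytest.approx(4000.0, rel=0.05)

    def test_precision_scales_with_photons_as_mortensen_predicts(self):
        """Monte-Carlo localization spread follows the Mortensen formula
        (sigma/sqrt(N) with a background correction) at every tier."""
        rng = np.random.default_rng(1)
        bg = 5.0
        for n in (1000.0, 4000.0, 10000.0):
            wins = rng.poisson(
                gaussian_spot(11, 5.5, 5.5, 1.3, 1.3, n)[None].repeat(400, 0) + bg
            )
            params, ok, _, _ = fit2d.fit_gaussian_batch(wins.astype(float), 1.3)
            spread = params[ok, 0].std()
            predicted = fit2d.mortensen_precision(1.3, 1.3, n, bg, 1.0)
            assert spread == pytest.approx(float(predicted), rel=0.10)

    def test_bias_below_a_third_of_precision(self):
        """Localization bias for isolated emitters stays well below the
        reported precision at every photon tier."""
        rng = np.random.default_rng(2)
        for n in (1000.0, 4000.0, 10000.0):
            truth = gaussian_spot(11, 5.72, 5.31, 1.3, 1.3, n) + 5.0
            wins = rng.poisson(truth[None].repeat(400, 0)).astype(float)
            params, ok, _, _ = fit2d.fit_gaussian_batch(wins, 1.3)
            bias = abs(np.mean(params[ok, 0]) - 5.72)
            precision = params[ok, 0].std()
            assert bias < precision / 3

    def test_nonconverged_fit_raises(self):
        img = np.zeros((15, 15))
        with pytest.raises(RuntimeError):
            fit2d.fit_gaussian2d(img, (7, 7), pixel_nm=1.0, window=11)


class TestAstigZLookup:
    def test_focus_maps_to_zero(self, astig_ctx):
        cal = astig_ctx.astig_cal
        s = float(np.interp(0.0, cal.z_nm, cal.sigma_x_nm))
        z, sz, ok = fit2d.astig_z_lookup([s], [s], cal)
        assert ok[0]
        assert z[0] == pytest.approx(0.0, abs=5.0)

    def test_round_trip_within_30nm(self, astig_ctx):
        """render(z) -> elliptical fit -> lookup recovers z at 4000 photons."""
        rng = np.random.default_rng(3)
        cal = astig_ctx.astig_cal
        errors = []
        for z_true in (-400, -250, -100, 0, 150, 300, 400):
            img = render_psf(default_spec("astigmatic"), z_true, 4000.0,
                             astig_ctx.optics_cfg, size_px=15,
                             warn_out_of_dof=False)
            wins = rng.poisson(img[None].repeat(30, 0) + 10.0).astype(float)
            params, ok, _, _ = fit2d.fit_gaussian_batch(wins, 1.5, circular=False)
            z_est, _, zok = fit2d.astig_z_lookup(params[ok, 2] * 110,
                                                 params[ok, 3] * 110, cal)
            errors.append(abs(np.median(z_est[zok]) - z_true))
        assert np.median(errors) < 30.0

    def test_out_of_range_rejected_not_extrapolated(self, astig_ctx):
        cal = astig_ctx.astig_cal
        big = cal.s.max() + 200.0
        z, sz, ok = fit2d.astig_z_lookup([200.0 + big], [200.0], cal)
        assert not ok[0]

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            fit2d.AstigCalibration(np.array([-100.0, 0.0, 100.0]),
                                   np.array([150.0, 160.0, 150.0]),
                                   np.array([160.0, 160.0, 160.0]))


class TestDhPairing:
    def _lobes(self, frame, x, y, z, spec, noise=0.0, rng=None):
        from smlfm3d.optics import dh_lobe_positions

        rows = []
        for lx, ly in dh_lobe_positions(spec, z):
            px, py = x + lx, y + ly
            if rng is not None and noise > 0:
                px += rng.normal(0, noise)
                py += rng.normal(0, noise)
            rows.append((frame, 0, px, py, 330.0, 330.0, 2000.0, 10.0, 10.0))
        return rows

    def test_angle_to_z_round_trip(self):
        spec = default_spec("double_helix")
        rows = []
        zs = np.arange(-1900.0, 1901.0, 100.0)
        for i, z in enumerate(zs):
            rows += self._lobes(i, 10000.0, 10000.0, z, spec)
        locs = pd.DataFrame(rows, columns=fit2d.LOC2D_COLUMNS)
        out = fit2d.dhpsf_pair_lobes(locs, spec)
        assert len(out) == len(zs)
        r = np.corrcoef(out["z_nm"], zs)[0, 1] ** 2
        assert r > 0.999
        assert np.abs(out["z_nm"].to_numpy() - zs).max() < 5.0

    def test_mid_range_angle_gives_dof_center(self):
        spec = default_spec("double_helix")
        locs = pd.DataFrame(self._lobes(0, 5000.0, 5000.0, 0.0, spec),
                            columns=fit2d.LOC2D_COLUMNS)
        out = fit2d.dhpsf_pair_lobes(locs, spec)
        assert out["z_nm"].iloc[0] == pytest.approx(0.0, abs=1.0)
        assert out["x_nm"].iloc[0] == pytest.approx(5000.0, abs=1.0)

    def test_single_lobe_emits_nothing(self):
        spec = default_spec("double_helix")
        locs = pd.DataFrame([(0, 0, 1000.0, 1000.0, 330.0, 330.0, 2000.0, 10.0, 10.0)],
                            columns=fit2d.LOC2D_COLUMNS)
        assert len(fit2d.dhpsf_pair_lobes(locs, spec)) == 0

    def test_ambiguous_pairing_resolved_by_separation_consistency(self):
        spec = default_spec("double_helix")
        rows = self._lobes(0, 4000.0, 4000.0, 500.0, spec)
        rows += self._lobes(0, 4000.0 + 1.8 * spec.dh_separation_nm, 4000.0,
                            -500.0, spec)
        locs = pd.DataFrame(rows, columns=fit2d.LOC2D_COLUMNS)
        out = fit2d.dhpsf_pair_lobes(locs, spec)
        assert len(out) == 2
        assert sorted(np.round(out["z_nm"]).tolist()) == [-500.0, 500.0]


class TestTetrapodFit:
    def test_noiseless_z_recovery_within_one_step(self, optics_cfg):
        ctx = pipeline.PipelineContext.create("tetrapod")
        lib = ctx.tetrapod_lib
        cfg = SimConfig(density_per_um2=0.0, fov_um=10.0, modality="tetrapod",
                        background=0.0)
        ren = FrameRenderer(cfg, ctx.optics_cfg, ctx.spec)
        step = lib.z_values[1] - lib.z_values[0]
        for z in (-2500.0, -500.0, 1000.0, 3000.0):
            em = pd.DataFrame({"frame": [0], "id": [0], "x_nm": [5000.0],
                               "y_nm": [5000.0], "z_nm": [z], "photons": [4000.0]})
            img = ren.expectation(em)[0]
            half = img.shape[0] // 2
            rec = fit2d.tetrapod_fit(img, (half, half), lib, max_shift_px=12,
                                     min_corr=0.5)
            assert rec is not None
            assert abs(rec["z_nm"] - z) <= step

    def test_symmetric_focus_has_small_z_bias(self, optics_cfg):
        ctx = pipeline.PipelineContext.create("tetrapod")
        lib = ctx.tetrapod_lib
        cfg = SimConfig(density_per_um2=0.0, fov_um=10.0, modality="tetrapod",
                        background=10.0)
        ren = FrameRenderer(cfg, ctx.optics_cfg, ctx.spec)
        cam = CameraModel()
        em = pd.DataFrame({"frame": [0], "id": [0], "x_nm": [5000.0],
                           "y_nm": [5000.0], "z_nm": [0.0], "photons": [4000.0]})
        rng = np.random.default_rng(4)
        zs = []
        half = ren.shape[1] // 2
        for _ in range(60):
            img = cam.to_photons(simulate_frame(em, ren, cam, rng)[0])
            rec = fit2d.tetrapod_fit(img, (half, half), lib, max_shift_px=12,
                                     noise_std=cam.noise_std_photons(10.0))
            if rec is not None:
                zs.append(rec["z_nm"])
        step = lib.z_values[1] - lib.z_values[0]
        assert len(zs) > 30
        assert abs(np.mean(zs)) < step

    def test_overlapping_emitters_yield_at_most_one_fit_per_window(self, optics_cfg):
        """Single-emitter contract: one detection window never produces two
        accepted localizations."""
        ctx = pipeline.PipelineContext.create("tetrapod")
        cfg = SimConfig(density_per_um2=0.0, fov_um=10.0, modality="tetrapod",
                        background=0.0)
        ren = FrameRenderer(cfg, ctx.optics_cfg, ctx.spec)
        em = pd.DataFrame({"frame": [0, 0], "id": [0, 1],
                           "x_nm": [4800.0, 5400.0], "y_nm": [5000.0, 5100.0],
                           "z_nm": [1200.0, -800.0], "photons": [4000.0, 4000.0]})
        img = ren.expectation(em)[0]
        half = img.shape[0] // 2
        rec = fit2d.tetrapod_fit(img, (half, half), ctx.tetrapod_lib,
                                 max_shift_px=12, min_corr=0.0)
        assert rec is None or isinstance(rec, pd.Series)
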