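import itertools

import numpy as np
import pandas as pd
import pytest

from smlfm3d import lightfield as lf
from smlfm3d.fit2d import LOC2D_COLUMNS

from conftest import synthetic_view_table


def make_group(geometry, optics_cfg, x, y, z, views=range(7), noise=0.0, rng=None):
    """Per-view positions of one emitter straight from the parallax model."""
    W = lf.shift_vectors(geometry, optics_cfg)
    pos = []
    for v in views:
        p = np.array([x, y]) + z * W[v]
        if rng is not None and noise > 0:
            p = p + rng.normal(0, noise, 2)
        pos.append(p)
    return np.asarray(pos), np.asarray(list(views))


def table_from_emitters(geometry, optics_cfg, emitters, noise=0.0, seed=0,
                        frame=0, views=range(7)):
    rng = np.random.default_rng(seed)
    rows = []
    for (x, y, z) in emitters:
        pos, vs = make_group(geometry, optics_cfg, x, y, z, views, noise, rng)
        for p, v in zip(pos, vs):
            rows.append((frame, v, p[0], p[1], 343.0, 343.0, 571.0, 10.0,
                         max(noise, 1.0)))
    return pd.DataFrame(rows, columns=LOC2D_COLUMNS)


@pytest.fixture()
def recon_cfg():
    return lf.ReconstructConfig(max_defocus_nm=4000.0)


class TestFitParallax:
    def test_perfect_group_recovered_exactly(self, geometry, optics_cfg, recon_cfg):
        W = lf.shift_vectors(geometry, optics_cfg)
        pos, views = make_group(geometry, optics_cfg, 5000.0, 6000.0, 1500.0)
        fit = lf.fit_parallax(pos, views, W, recon_cfg)
        assert fit["z_nm"] == pytest.approx(1500.0, abs=1.0)
        assert fit["x_nm"] == pytest.approx(5000.0, abs=0.1)
        assert fit["residual_nm"] == pytest.approx(0.0, abs=1e-6)

    def test_perturbed_view_fails_residual_gate(self, geometry, optics_cfg, recon_cfg):
        """A view displaced by 600 nm perpendicular to its epipolar
        direction pushes the RMS residual above the 200 nm threshold."""
        W = lf.shift_vectors(geometry, optics_cfg)
        pos, views = make_group(geometry, optics_cfg, 5000.0, 6000.0, 1000.0)
        u = geometry.centers[1] / np.linalg.norm(geometry.centers[1])
        perp = np.array([-u[1], u[0]])
        pos[1] = pos[1] + 600.0 * perp
        fit = lf.fit_parallax(pos, views, W, recon_cfg)
        assert fit["residual_nm"] >= recon_cfg.residual_threshold_nm

    def test_fewer_views_have_larger_covariance(self, geometry, optics_cfg, recon_cfg):
        rng = np.random.default_rng(0)
        W = lf.shift_vectors(geometry, optics_cfg)
        s3, s7 = [], []
        for _ in range(200):
            pos, views = make_group(geometry, optics_cfg, 5000.0, 6000.0, 2000.0,
                                    noise=15.0, rng=rng)
            full = lf.fit_parallax(pos, views, W, recon_cfg)
            sub = lf.fit_parallax(pos[:3], views[:3], W, recon_cfg)
            s7.append((full["sigma_xy_nm"], full["sigma_z_nm"]))
            s3.append((sub["sigma_xy_nm"], sub["sigma_z_nm"]))
        s3, s7 = np.median(s3, axis=0), np.median(s7, axis=0)
        assert s3[0] > s7[0]
        assert s3[1] > s7[1]

    def test_degenerate_single_view_rejected(self, geometry, optics_cfg, recon_cfg):
        """One view cannot constrain (x, y, z): the normal equations are
        singular and the fit is refused."""
        W = lf.shift_vectors(geometry, optics_cfg)
        pos, views = make_group(geometry, optics_cfg, 5000.0, 6000.0, 1000.0,
                                views=[1])
        fit = lf.fit_parallax(pos, views, W, recon_cfg)
        assert fit is None


class TestGrouping:
    def test_in_focus_emitter_groups_all_views(self, geometry, optics_cfg, recon_cfg):
        locs = table_from_emitters(geometry, optics_cfg, [(5000.0, 5000.0, 0.0)])
        groups = lf.group_candidates(locs, geometry, recon_cfg, optics_cfg)
        assert any(len(g) == 7 for g in groups)

    def test_laterally_overlapping_emitters_split_by_parallax(self, geometry,
                                                              optics_cfg, recon_cfg):
        """Two emitters at the same (x, y) but z = +-2 um are displaced
        oppositely in off-axis views and reconstruct as two emitters."""
        locs = table_from_emitters(
            geometry, optics_cfg,
            [(8000.0, 8000.0, 2000.0), (8000.0, 8000.0, -2000.0)], noise=5.0)
        out = lf.reconstruct_frame(locs, geometry, recon_cfg, optics_cfg)
        assert len(out) == 2
        zs = sorted(out["z_nm"])
        assert zs[0] == pytest.approx(-2000.0, abs=30.0)
        assert zs[1] == pytest.approx(2000.0, abs=30.0)

    def test_too_few_views_yield_no_group(self, geometry, optics_cfg, recon_cfg):
        locs = table_from_emitters(geometry, optics_cfg, [(5000.0, 5000.0, 500.0)],
                                   views=[0, 1])
        groups = lf.group_candidates(locs, geometry, recon_cfg, optics_cfg)
        assert groups == []
        out = lf.reconstruct_frame(locs, geometry, recon_cfg, optics_cfg)
        assert len(out) == 0


class TestReconstructFrame:
    def test_empty_input(self, geometry, optics_cfg, recon_cfg):
        out = lf.reconstruct_frame(pd.DataFrame(columns=LOC2D_COLUMNS),
                                   geometry, recon_cfg, optics_cfg)
        assert len(out) == 0

    def test_well_separated_emitters_all_recovered(self, geometry, optics_cfg,
                                                   recon_cfg):
        emitters = [(3000.0, 3000.0, -3000.0), (10000.0, 4000.0, 0.0),
                    (5000.0, 15000.0, 2500.0), (16000.0, 16000.0, 1000.0)]
        locs = table_from_emitters(geometry, optics_cfg, emitters, noise=10.0)
        out = lf.reconstruct_frame(locs, geometry, recon_cfg, optics_cfg)
        assert len(out) == len(emitters)
        for (x, y, z) in emitters:
            d = np.sqrt((out["x_nm"] - x) ** 2 + (out["y_nm"] - y) ** 2
                        + (out["z_nm"] - z) ** 2)
            assert d.min() < 60.0

    def test_accepted_fits_respect_gates_and_uniqueness(self, lf_ctx, sparse_lf_dataset):
        """Every accepted fit passes the residual and view-count gates and
        no 2D localization is used twice."""
        from smlfm3d import pipeline

        locs2d = pipeline.localize_lightfield_2d(sparse_lf_dataset.frames, lf_ctx)
        out = lf.reconstruct(locs2d, lf_ctx.geometry, lf_ctx.recon_cfg,
                             lf_ctx.optics_cfg)
        assert (out["residual_nm"] < lf_ctx.recon_cfg.residual_threshold_nm).all()
        assert (out["n_views"] >= lf_ctx.recon_cfg.min_views).all()
        members = list(itertools.chain.from_iterable(out["members"]))
        assert len(members) == len(set(members))

    def test_greedy_matches_exhaustive_on_small_frames(self, geometry, optics_cfg,
                                                       recon_cfg):
        """Brute-force enumeration over all view assignments agrees with
        the greedy reconstruction on frames with <= 3 emitters."""
        rng = np.random.default_rng(7)
        W = lf.shift_vectors(geometry, optics_cfg)
        agree = 0
        trials = 12
        for t in range(trials):
            n_emitters = rng.integers(1, 4)
            emitters = [(rng.uniform(4000, 16000), rng.uniform(4000, 16000),
                         rng.uniform(-3500, 3500)) for _ in range(n_emitters)]
            locs = table_from_emitters(geometry, optics_cfg, emitters, noise=10.0,
                                       seed=int(t))
            greedy = lf.reconstruct_frame(locs, geometry, recon_cfg, optics_cfg)
            # oracle: enumerate every subset with <=1 loc per view, fit all,
            # then greedily take best-residual disjoint subsets
            xy = locs[["x_nm", "y_nm"]].to_numpy()
            by_view = {v: g.index.tolist() for v, g in locs.groupby("view")}
            options = [([None] + by_view.get(v, [])) for v in range(7)]
            cands = []
            for combo in itertools.product(*options):
                chosen = [(v, i) for v, i in enumerate(combo) if i is not None]
                if len(chosen) < recon_cfg.min_views:
                    continue
                views = np.array([v for v, _ in chosen])
                pos = xy[[i for _, i in chosen]]
                fit = lf.fit_parallax(pos, views, W, recon_cfg)
                if fit and fit["residual_nm"] < recon_cfg.residual_threshold_nm \
                        and abs(fit["z_nm"]) <= recon_cfg.max_defocus_nm:
                    cands.append((fit["residual_nm"], [i for _, i in chosen], fit))
            cands.sort(key=lambda c: c[0])
            used, oracle = set(), []
            for res, rows, fit in cands:
                if not used.intersection(rows):
                    used.update(rows)
                    oracle.append(fit)
            if len(oracle) == len(greedy):
                oz = sorted(f["z_nm"] for f in oracle)
                gz = sorted(greedy["z_nm"])
                if np.allclose(oz, gz, atol=25.0):
                    agree += 1
        assert agree / trials >= 0.9


class TestAberration:
    def test_unaberrated_data_give_null_map(self, geometry, optics_cfg, recon_cfg):
        locs2d, _ = synthetic_view_table(geometry, optics_cfg, n_frames=25,
                                         noise_nm=2.0, seed=1)
        amap = lf.estimate_aberration_map(locs2d, geometry, recon_cfg, optics_cfg)
        assert np.abs(amap.offsets_nm).max() < 2.0

    def test_injected_tangential_offset_recovered(self, geometry, optics_cfg,
                                                  recon_cfg):
        """An offset perpendicular to a view's parallax direction is fully
        observable and is recovered to a few nm.  (The radial component is
        gauge-equivalent to a global defocus shift and is absorbed by the
        fit, so it cannot -- and need not -- be recovered.)"""
        u = geometry.centers[3] / np.linalg.norm(geometry.centers[3])
        tangent = np.array([-u[1], u[0]])
        offsets = np.zeros((7, 2))
        offsets[3] = 58.0 * tangent
        locs2d, _ = synthetic_view_table(geometry, optics_cfg, n_frames=40,
                                         noise_nm=5.0, seed=2,
                                         view_offsets=offsets)
        amap = lf.estimate_aberration_map(locs2d, geometry, recon_cfg, optics_cfg)
        assert amap.offsets_nm[3] == pytest.approx(offsets[3], abs=5.0)

    def test_correction_reduces_mean_residual(self, geometry, optics_cfg, recon_cfg):
        offsets = np.zeros((7, 2))
        offsets[3] = (50.0, -30.0)
        offsets[5] = (-20.0, 40.0)
        locs2d, _ = synthetic_view_table(geometry, optics_cfg, n_frames=40,
                                         noise_nm=5.0, seed=2,
                                         view_offsets=offsets)
        amap = lf.estimate_aberration_map(locs2d, geometry, recon_cfg, optics_cfg)
        corrected = lf.apply_aberration_map(locs2d, amap)
        before = lf.reconstruct(locs2d, geometry, recon_cfg, optics_cfg)
        after = lf.reconstruct(corrected, geometry, recon_cfg, optics_cfg)
        assert after["residual_nm"].mean() < before["residual_nm"].mean()

    def test_too_few_fits_fall_back_to_identity(self, geometry, optics_cfg, recon_cfg):
        locs2d, _ = synthetic_view_table(geometry, optics_cfg, n_frames=1,
                                         emitters_per_frame=1, seed=3)
        with pytest.warns(UserWarning):
            amap = lf.estimate_aberration_map(locs2d, geometry, recon_cfg,
                                              optics_cfg, min_fits=10)
        assert np.all(amap.offsets_nm == 0.0)


class TestDriftCorrection:
    def _locs(self, n_frames=20):
        return pd.DataFrame({
            "frame": np.arange(n_frames), "x_nm": 5000.0, "y_nm": 5000.0,
            "z_nm": 100.0, "sigma_xy_nm": 10.0, "sigma_z_nm": 15.0,
            "residual_nm": 50.0, "n_views": 7, "photons": 4000.0,
        })

    def test_static_fiducial_changes_nothing(self):
        locs = self._locs()
        fid = pd.DataFrame({"frame": np.arange(20), "x_nm": 100.0,
                            "y_nm": 200.0, "z_nm": 0.0})
        out = lf.correct_drift(locs, fid)
        pd.testing.assert_frame_equal(out, locs)

    def test_linear_drift_removed(self):
        locs = self._locs()
        drift = locs["frame"].to_numpy() * 1.0
        drifted = locs.copy()
        drifted["x_nm"] = drifted["x_nm"] + drift
        fid = pd.DataFrame({"frame": np.arange(20), "x_nm": 100.0 + drift,
                            "y_nm": 200.0, "z_nm": 0.0})
        out = lf.correct_drift(drifted, fid)
        rms = np.sqrt(((out["x_nm"] - 5000.0) ** 2).mean())
        assert rms < 2.0

    def test_fiducial_gaps_interpolated(self):
        locs = self._locs()
        frames = np.array([0, 1, 2, 8, 9, 10, 15, 19])
        fid = pd.DataFrame({"frame": frames, "x_nm": 100.0 + frames * 2.0,
                            "y_nm": 200.0, "z_nm": 0.0})
        out = lf.correct_drift(locs, fid)
        assert len(out) == len(locs)
        assert out["x_nm"].iloc[5] == pytest.approx(5000.0 - 5 * 2.0, abs=1e-6)

    def test_missing_fiducial_is_an_error(self):
        with pytest.raises(ValueError, match="fiducial"):
            lf.correct_drift(self._locs(), pd.DataFrame(columns=["frame", "x_nm",
                                                                 "y_nm", "z_nm"]))


class TestAxialCalibration:
    def test_unit_optics_give_unit_factor(self):
        rng = np.random.default_rng(4)
        piezo = np.arange(-4000.0, 4000.0, 60.0)
        recon = piezo + rng.normal(0, 15.0, piezo.shape)
        cal = lf.axial_calibration(recon, piezo)
        assert cal.correction_factor == pytest.approx(1.0, abs=0.02)

    def test_compressed_scale_recovered(self):
        rng = np.random.default_rng(5)
        piezo = np.arange(-4000.0, 4000.0, 60.0)
        recon = 0.9 * piezo + rng.normal(0, 15.0, piezo.shape)
        cal = lf.axial_calibration(recon, piezo)
        assert cal.correction_factor == pytest.approx(1.0 / 0.9, rel=0.02)
        assert np.mean(cal.apply(recon) - piezo) == pytest.approx(0.0, abs=10.0)

    def test_scan_step_count(self):
        # 8 um range at 60 nm increments
        piezo = np.arange(-4000.0, 4000.0 + 30.0, 60.0)
        assert len(piezo) == pytest.approx(134, abs=1)

    def test_nonlinear_curve_fails(self):
        piezo = np.linspace(-4000, 4000, 100)
        recon = np.sign(piezo) * np.sqrt(np.abs(piezo)) * 40 + piezo * 0.05
        rng = np.random.default_rng(6)
        with pytest.raises(lf.CalibrationError):
            lf.axial_calibration(rng.permutation(recon), piezo, min_r2=0.99)


class TestTemporalGrouping:
    def _loc(self, frame, x=0.0, y=0.0, z=0.0, photons=100.0, sxy=10.0, sz=15.0):
        return dict(frame=frame, x_nm=x, y_nm=y, z_nm=z, sigma_xy_nm=sxy,
                    sigma_z_nm=sz, residual_nm=50.0, n_views=7, photons=photons)

    def test_consecutive_frames_merge_keeping_brightest(self):
        df = pd.DataFrame([self._loc(1, photons=100), self._loc(2, x=5, photons=300),
                           self._loc(3, x=2, photons=200)])
        out = lf.temporal_group(df)
        assert len(out) == 1
        assert out["photons"].iloc[0] == 300
        assert out["x_nm"].iloc[0] == 5

    def test_gap_beyond_four_frames_splits(self):
        df = pd.DataFrame([self._loc(0), self._loc(5)])
        out = lf.temporal_group(df)
        assert len(out) == 2
        df2 = pd.DataFrame([self._loc(0), self._loc(4)])
        assert len(lf.temporal_group(df2)) == 1

    def test_distant_emitters_never_merge(self):
        df = pd.DataFrame([self._loc(0), self._loc(1, x=5000.0)])
        out = lf.temporal_group(df)
        assert len(out) == 2

    def test_precision_gate_scales_with_k(self):
        df = pd.DataFrame([self._loc(0), self._loc(1, x=50.0)])
        tight = lf.ReconstructConfig(precision_gate_multiplier=1.0)
        loose = lf.ReconstructConfig(precision_gate_multiplier=5.0)
        assert len(lf.temporal_group(df, tight)) == 2
        assert len(lf.temporal_group(df, loose)) == 1
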