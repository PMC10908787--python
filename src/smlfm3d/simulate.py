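"""Synthetic ground truth, raw camera frames and Brownian trajectories.

The generator emulates the density benchmark's study conditions: emitters
drawn with per-frame Poisson counts at density ``rho_loc`` over a
20 um x 20 um field of view, z uniform over the modality's depth of field,
a fixed detected-photon budget per emitter (1000 / 4000 / 10000 photon
tiers), uniform background, and an EMCCD noise chain (Poisson shot noise,
gamma-distributed electron multiplication, Gaussian read noise, offset and
a clamp at zero ADU).  Frames for every modality are rendered through the
PSF models of :mod:`smlfm3d.optics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import optics
from .optics import (
    LensletGeometry,
    OpticalConfig,
    PSFModelSpec,
    default_spec,
    gaussian_spot,
    make_lenslet_geometry,
)

__all__ = [
    "SimConfig",
    "CameraModel",
    "SimDataset",
    "sample_emitters",
    "simulate_frame",
    "simulate_dataset",
    "simulate_from_ground_truth",
    "simulate_tracks",
    "GT_COLUMNS",
]

GT_COLUMNS = ["frame", "id", "x_nm", "y_nm", "z_nm", "photons"]


@dataclass(frozen=True)
class CameraModel:
    """EMCCD noise chain.

    Electron multiplication is modelled as a gamma distribution with shape
    equal to the photoelectron count and scale equal to the gain, which
    reproduces the sqrt(2) excess-noise factor of real EM registers.
    ``read_noise_e`` is input-referred (e- rms).  With ``em_gain=1`` the
    chain collapses to pure Poisson statistics.
    """

    em_gain: float = 100.0
    read_noise_e: float = 1.0
    quantum_efficiency: float = 0.9
    #: offset is several post-gain read-noise sigmas so the zero-ADU clamp
    #: never truncates the noise distribution
    offset_adu: float = 1000.0
    adu_per_electron: float = 1.0

    def __post_init__(self) -> None:
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must lie in (0, 1]")

    def apply(self, expectation_photons: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy integer-ADU image from a photon-expectation image."""
        counts = rng.poisson(expectation_photons * self.quantum_efficiency)
        if self.em_gain > 1:
            electrons = rng.standard_gamma(counts.astype(float)) * self.em_gain
        else:
            electrons = counts.astype(float)
        if self.read_noise_e > 0:
            electrons = electrons + rng.normal(
                0.0, self.read_noise_e * self.em_gain, size=electrons.shape
            )
        adu = electrons * self.adu_per_electron + self.offset_adu
        return np.clip(np.rint(adu), 0.0, None).astype(np.float32)

    def noise_std_photons(self, background_photons: float) -> float:
        """Per-pixel noise (photon units) at a given background level:
        shot noise with the EM excess-noise factor plus input-referred
        read noise."""
        excess = 2.0 if self.em_gain > 1 else 1.0
        read = self.read_noise_e / self.quantum_efficiency
        return float(np.sqrt(excess * max(background_photons, 0.0) + read**2))

    def to_photons(self, image_adu: np.ndarray) -> np.ndarray:
        """Invert the mean camera chain: offset-subtracted ADU back to
        expected detected photons."""
        scale = self.em_gain * self.quantum_efficiency * self.adu_per_electron
        return (np.asarray(image_adu, dtype=float) - self.offset_adu) / scale


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    density_per_um2: float = 0.1
    fov_um: float = 20.0
    n_frames: int = 100
    n_repeats: int = 3
    photons: float = 4000.0
    background: float = 10.0  # photons / pixel / frame
    modality: str = "lightfield"
    seed: int = 0
    #: when True, molecules persist across frames with geometric on-times
    #: (dSTORM-like blinking); benchmark mode keeps frames independent.
    blinking: bool = False
    mean_on_frames: float = 2.0

    def __post_init__(self) -> None:
        if self.density_per_um2 < 0:
            raise ValueError("density must be >= 0")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if self.photons <= 0:
            raise ValueError("photons must be positive")

    @property
    def fov_nm(self) -> float:
        return self.fov_um * 1e3

    @property
    def area_um2(self) -> float:
        return self.fov_um**2


def frame_shape(cfg: SimConfig, optics_cfg: OpticalConfig,
                spec: PSFModelSpec | None = None,
                geometry: LensletGeometry | None = None) -> tuple[int, int, int]:
    """(views, height, width) of one simulated frame, including the
    sensor margin around the analysis FoV (see
    :func:`smlfm3d.optics.psf_margin_nm`)."""
    px = optics_cfg.pixel_size_nm(cfg.modality)
    spec = spec or default_spec(cfg.modality)
    margin = int(np.ceil(optics.psf_margin_nm(spec, optics_cfg, geometry) / px))
    n = int(np.ceil(cfg.fov_nm / px)) + 2 * margin
    views = 7 if cfg.modality == "lightfield" else 1
    return views, n, n


def sample_emitters(
    cfg: SimConfig,
    frame: int,
    rng: np.random.Generator,
    spec: PSFModelSpec | None = None,
    start_id: int = 0,
) -> pd.DataFrame:
    """Ground-truth emitters for one frame.

    The count is Poisson(rho * area); x, y are uniform over the FoV and z
    uniform over the modality's depth of field.
    """
    spec = spec or default_spec(cfg.modality)
    n = rng.poisson(cfg.density_per_um2 * cfg.area_um2)
    half_dof = spec.dof_nm / 2.0
    return pd.DataFrame(
        {
            "frame": np.full(n, frame, dtype=int),
            "id": start_id + np.arange(n),
            "x_nm": rng.uniform(0.0, cfg.fov_nm, n),
            "y_nm": rng.uniform(0.0, cfg.fov_nm, n),
            "z_nm": rng.uniform(-half_dof, half_dof, n),
            "photons": np.full(n, float(cfg.photons)),
        }
    )


# ---------------------------------------------------------------------------
# expectation-image rendering


class TemplateLibrary:
    """Cache of Fourier-rendered PSF templates on a z grid.

    Used to place standard / astigmatic / tetrapod PSFs into frames without
    re-running the Fourier propagation per emitter.  Templates are unit
    normalized (pre-crop); stamps are interpolated linearly between the two
    bracketing z slices and shifted to sub-pixel positions in Fourier space.
    """

    def __init__(self, spec: PSFModelSpec, optics_cfg: OpticalConfig,
                 z_step_nm: float | None = None, size_px: int | None = None):
        self.spec = spec
        self.cfg = optics_cfg
        if z_step_nm is None:
            z_step_nm = 20.0 if spec.dof_um <= 2 else 100.0
        half = spec.dof_nm / 2.0
        self.z_values = np.arange(-half, half + z_step_nm / 2, z_step_nm)
        self.templates = np.stack(
            [
                optics.render_psf(
                    spec, z, 1.0, optics_cfg, size_px=size_px,
                    warn_out_of_dof=False,
                )
                for z in self.z_values
            ]
        )
        self.size_px = self.templates.shape[-1]

    def stamp(self, z_nm: float, frac_dx_px: float, frac_dy_px: float,
              photons: float) -> np.ndarray:
        z = np.clip(z_nm, self.z_values[0], self.z_values[-1])
        i = int(np.clip(np.searchsorted(self.z_values, z) - 1, 0, len(self.z_values) - 2))
        w = (z - self.z_values[i]) / (self.z_values[i + 1] - self.z_values[i])
        t = (1.0 - w) * self.templates[i] + w * self.templates[i + 1]
        if abs(frac_dx_px) > 1e-9 or abs(frac_dy_px) > 1e-9:
            from scipy.ndimage import fourier_shift

            t = np.fft.ifft2(
                fourier_shift(np.fft.fft2(t), (frac_dy_px, frac_dx_px))
            ).real
            t = np.clip(t, 0.0, None)
        return photons * t


def _add_patch(img: np.ndarray, patch: np.ndarray, ix: int, iy: int) -> None:
    """Add ``patch`` to ``img`` with its top-left at (iy, ix), clipping."""
    h, w = patch.shape
    H, W = img.shape
    y0, y1 = max(iy, 0), min(iy + h, H)
    x0, x1 = max(ix, 0), min(ix + w, W)
    if y0 >= y1 or x0 >= x1:
        return
    img[y0:y1, x0:x1] += patch[y0 - iy : y1 - iy, x0 - ix : x1 - ix]


def _add_gaussian(img: np.ndarray, x_px: float, y_px: float, sx_px: float,
                  sy_px: float, photons: float) -> None:
    half = int(np.ceil(4.0 * max(sx_px, sy_px))) + 1
    ix, iy = int(np.floor(x_px)) - half, int(np.floor(y_px)) - half
    size = 2 * half + 1
    patch = gaussian_spot(size, x_px - ix, y_px - iy, sx_px, sy_px, photons)
    _add_patch(img, patch, ix, iy)


class FrameRenderer:
    """Renders photon-expectation frames for one modality.

    Gaussian-shaped modalities (light field views, double-helix lobes) use
    exact pixel-integrated Gaussians; Fourier-rendered modalities place
    interpolated templates from a :class:`TemplateLibrary`.
    """

    def __init__(self, cfg: SimConfig, optics_cfg: OpticalConfig | None = None,
                 spec: PSFModelSpec | None = None,
                 geometry: LensletGeometry | None = None):
        self.sim = cfg
        self.cfg = optics_cfg or OpticalConfig()
        self.spec = spec or default_spec(cfg.modality)
        self.pixel = self.cfg.pixel_size_nm(cfg.modality)
        self.geometry = geometry
        self.library: TemplateLibrary | None = None
        if cfg.modality == "lightfield":
            self.geometry = geometry or make_lenslet_geometry(self.cfg)
            self.view_sigma_px = (
                optics.lightfield_view_sigma_nm(self.cfg, self.geometry) / self.pixel
            )
        elif cfg.modality in ("standard", "astigmatic"):
            self.library = TemplateLibrary(self.spec, self.cfg)
        self.margin_nm = optics.psf_margin_nm(self.spec, self.cfg, self.geometry)
        self.shape = frame_shape(cfg, self.cfg, self.spec, self.geometry)

    def expectation(self, emitters: pd.DataFrame) -> np.ndarray:
        """Noise-free photon-expectation planes (views, H, W) incl. background."""
        v, h, w = self.shape
        out = np.full((v, h, w), float(self.sim.background))
        px = self.pixel
        mod = self.sim.modality
        for row in emitters.itertuples(index=False):
            x = row.x_nm + self.margin_nm
            y = row.y_nm + self.margin_nm
            z, photons = row.z_nm, row.photons
            if mod == "lightfield":
                share = photons / self.geometry.count
                for k, uv in enumerate(self.geometry.centers):
                    shift = optics.parallax_shift(z, uv, self.cfg)
                    _add_gaussian(
                        out[k], (x + shift[0]) / px, (y + shift[1]) / px,
                        self.view_sigma_px, self.view_sigma_px, share,
                    )
            elif mod == "double_helix":
                s = self.spec.dh_lobe_sigma_nm / px
                for lx, ly in optics.dh_lobe_positions(self.spec, z):
                    _add_gaussian(out[0], (x + lx) / px, (y + ly) / px, s, s,
                                  photons / 2.0)
            elif mod == "tetrapod":
                s = self.spec.tetrapod_lobe_sigma_nm / px
                for lx, ly in optics.tetrapod_lobe_positions(self.spec, z):
                    _add_gaussian(out[0], (x + lx) / px, (y + ly) / px, s, s,
                                  photons / 2.0)
            else:
                lib = self.library
                x_px, y_px = x / px, y / px
                # template peak sits at the center of the middle pixel,
                # i.e. at edge-coordinate cx + 0.5 within the patch
                cx = (lib.size_px - 1) / 2.0 + 0.5
                ix = int(np.floor(x_px - cx))
                iy = int(np.floor(y_px - cx))
                patch = lib.stamp(z, x_px - cx - ix, y_px - cx - iy, photons)
                _add_patch(out[0], patch, ix, iy)
        return out


def simulate_frame(
    emitters: pd.DataFrame,
    renderer: FrameRenderer,
    camera: CameraModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy camera frame (views, H, W) in ADU."""
    if len(emitters) and emitters["frame"].nunique() > 1:
        raise ValueError("emitters must share one frame index")
    return camera.apply(renderer.expectation(emitters), rng)


@dataclass
class SimDataset:
    """A simulated image stack with its ground truth."""

    frames: np.ndarray  # (n_frames, views, H, W) float32 ADU
    ground_truth: pd.DataFrame
    config: SimConfig
    camera: CameraModel
    optics_config: OpticalConfig
    spec: PSFModelSpec

    def save(self, tiff_path=None, gt_csv_path=None, config_yaml_path=None) -> None:
        if tiff_path is not None:
            import tifffile

            f, v, h, w = self.frames.shape
            data = np.clip(self.frames, 0, 65535).astype(np.uint16)
            tifffile.imwrite(tiff_path, data.reshape(f * v, h, w),
                             metadata={"axes": "QYX", "views": v})
        if gt_csv_path is not None:
            self.ground_truth.to_csv(gt_csv_path, index=False)
        if config_yaml_path is not None:
            import yaml
            from dataclasses import asdict

            blob = {
                "sim": asdict(self.config),
                "camera": asdict(self.camera),
                "optics": asdict(self.optics_config),
                "psf": asdict(self.spec),
            }
            with open(config_yaml_path, "w") as fh:
                yaml.safe_dump(blob, fh)


def _blinking_ground_truth(cfg: SimConfig, spec: PSFModelSpec,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Ground truth with geometric on-time persistence across frames."""
    half_dof = spec.dof_nm / 2.0
    activation_rate = cfg.density_per_um2 * cfg.area_um2 / cfg.mean_on_frames
    rows = []
    next_id = 0
    for f in range(cfg.n_frames):
        n_new = rng.poisson(activation_rate)
        for _ in range(n_new):
            on = rng.geometric(1.0 / cfg.mean_on_frames)
            x = rng.uniform(0.0, cfg.fov_nm)
            y = rng.uniform(0.0, cfg.fov_nm)
            z = rng.uniform(-half_dof, half_dof)
            for df in range(on):
                if f + df >= cfg.n_frames:
                    break
                rows.append((f + df, next_id, x, y, z, float(cfg.photons)))
            next_id += 1
    gt = pd.DataFrame(rows, columns=GT_COLUMNS)
    return gt.sort_values(["frame", "id"], ignore_index=True)


def simulate_dataset(
    cfg: SimConfig,
    *,
    camera: CameraModel | None = None,
    optics_cfg: OpticalConfig | None = None,
    spec: PSFModelSpec | None = None,
    geometry: LensletGeometry | None = None,
    renderer: FrameRenderer | None = None,
) -> SimDataset:
    """Simulate a full image stack plus ground-truth table.

    Fully reproducible from ``cfg.seed``: identical configs yield
    bit-identical frames and tables.
    """
    camera = camera or CameraModel()
    optics_cfg = optics_cfg or OpticalConfig()
    spec = spec or default_spec(cfg.modality)
    if renderer is None:
        renderer = FrameRenderer(cfg, optics_cfg, spec, geometry)
    rng = np.random.default_rng(cfg.seed)
    if cfg.blinking:
        gt = _blinking_ground_truth(cfg, spec, rng)
        per_frame = [gt[gt["frame"] == f] for f in range(cfg.n_frames)]
    else:
        per_frame = []
        start = 0
        for f in range(cfg.n_frames):
            em = sample_emitters(cfg, f, rng, spec, start_id=start)
            start += len(em)
            per_frame.append(em)
        gt = (
            pd.concat(per_frame, ignore_index=True)
            if per_frame
            else pd.DataFrame(columns=GT_COLUMNS)
        )
    v, h, w = renderer.shape
    frames = np.zeros((cfg.n_frames, v, h, w), dtype=np.float32)
    for f, em in enumerate(per_frame):
        frames[f] = simulate_frame(em, renderer, camera, rng)
    return SimDataset(frames, gt, cfg, camera, optics_cfg, spec)


def simulate_from_ground_truth(
    gt: pd.DataFrame,
    cfg: SimConfig,
    *,
    camera: CameraModel | None = None,
    optics_cfg: OpticalConfig | None = None,
    spec: PSFModelSpec | None = None,
    geometry: LensletGeometry | None = None,
    renderer: FrameRenderer | None = None,
    seed: int | None = None,
) -> SimDataset:
    """Render frames for a caller-supplied ground-truth table (used for
    bead scans, isolated-emitter calibration and injection tests)."""
    camera = camera or CameraModel()
    optics_cfg = optics_cfg or OpticalConfig()
    spec = spec or default_spec(cfg.modality)
    if renderer is None:
        renderer = FrameRenderer(cfg, optics_cfg, spec, geometry)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_frames = int(gt["frame"].max()) + 1 if len(gt) else cfg.n_frames
    v, h, w = renderer.shape
    frames = np.zeros((n_frames, v, h, w), dtype=np.float32)
    for f in range(n_frames):
        frames[f] = simulate_frame(gt[gt["frame"] == f], renderer, camera, rng)
    return SimDataset(frames, gt.reset_index(drop=True), cfg, camera, optics_cfg, spec)


# ---------------------------------------------------------------------------
# Brownian trajectories for tracking tests


def simulate_tracks(
    d_um2_s: float,
    n_tracks: int,
    dt_s: float,
    loc_precision_nm=(0.0, 0.0, 0.0),
    track_length=50,
    seed: int = 0,
    box_um=(10.0, 10.0, 4.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isotropic Brownian trajectories plus noisy observations.

    Per-axis steps are Normal(0, 2 D dt); observed positions add
    independent Gaussian localization noise per axis.  ``track_length`` is
    either a fixed integer or a callable ``rng -> int``.  Returns
    ``(ground_truth, observed)`` tables with columns
    ``track_id, frame, x_nm, y_nm, z_nm``.
    """
    if d_um2_s < 0:
        raise ValueError("D must be >= 0")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    step_nm = np.sqrt(2.0 * d_um2_s * dt_s) * 1e3
    sigma = np.asarray(loc_precision_nm, dtype=float)
    gt_rows, obs_rows = [], []
    for tid in range(n_tracks):
        n = track_length(rng) if callable(track_length) else int(track_length)
        start = rng.uniform(0.0, np.asarray(box_um) * 1e3)
        steps = rng.normal(0.0, step_nm, size=(n - 1, 3)) if n > 1 else np.zeros((0, 3))
        pos = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        noise = rng.normal(0.0, 1.0, size=(n, 3)) * sigma
        for f in range(n):
            gt_rows.append((tid, f, *pos[f]))
            obs_rows.append((tid, f, *(pos[f] + noise[f])))
    cols = ["track_id", "frame", "x_nm", "y_nm", "z_nm"]
    return pd.DataFrame(gt_rows, columns=cols), pd.DataFrame(obs_rows, columns=cols)
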