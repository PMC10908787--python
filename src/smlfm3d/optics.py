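"""Optical models for 3D single-molecule localization modalities.

This module holds the geometric-optics description of a hexagonal
microlens-array (MLA) light-field microscope -- the normalized pupil
positions of the seven lenslets and the parallax model that maps emitter
defocus to per-view image shifts -- together with point-spread-function
(PSF) models for the five modalities compared in the density benchmark:

* ``standard``     -- unmodified widefield PSF (scalar Fourier optics),
* ``astigmatic``   -- cylindrical-lens PSF (vertical-astigmatism Zernike
  phase in the pupil),
* ``double_helix`` -- parametric two-Gaussian-lobe model whose lobe pair
  rotates linearly with defocus,
* ``tetrapod``     -- polynomial (primary + secondary astigmatism) phase
  mask rendered by Fourier optics,
* ``lightfield``   -- seven diffraction-limited sub-aperture spots, each
  displaced by the parallax shift and carrying 1/7 of the photons.

All positions and shifts are expressed in sample-space nanometres; pupil
coordinates are normalized to the objective pupil radius.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "LensletGeometry",
    "PSFModelSpec",
    "PSFStack",
    "ConfigurationError",
    "EvanescentAngleError",
    "MODALITIES",
    "PIXEL_SIZE_NM",
    "default_spec",
    "make_lenslet_geometry",
    "parallax_shift",
    "shift_coefficient",
    "render_psf",
    "render_psf_stack",
    "psf_footprint_area",
    "gaussian_sigma_nm",
]

MODALITIES = ("standard", "astigmatic", "double_helix", "tetrapod", "lightfield")

#: Camera pixel size (sample space, nm) per modality.  The compact PSFs are
#: sampled at 110 nm; the large-footprint double-helix and light-field PSFs
#: use 266 nm pixels, matching typical experimental magnifications.
PIXEL_SIZE_NM = {
    "standard": 110.0,
    "astigmatic": 110.0,
    "tetrapod": 110.0,
    "double_helix": 266.0,
    "lightfield": 266.0,
}


class ConfigurationError(ValueError):
    """Raised for physically impossible optical configurations."""


class EvanescentAngleError(ValueError):
    """Raised when a pupil position maps to an evanescent ray angle."""


@dataclass(frozen=True)
class OpticalConfig:
    """Physical parameters of the microscope and the light-field relay.

    Defaults describe a 60x / 1.27 NA water-immersion objective with a
    200 mm tube lens, a 175 mm Fourier lens relaying the back focal plane
    onto a hexagonal MLA of 2.39 mm pitch and 175 mm focal length.
    """

    numerical_aperture: float = 1.27
    medium_index: float = 1.33
    wavelength_nm: float = 670.0
    magnification: float = 60.0
    tube_lens_f_mm: float = 200.0
    fourier_lens_f_mm: float = 175.0
    mla_focal_length_mm: float = 175.0
    mla_pitch_mm: float = 2.39

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < self.medium_index:
            raise ConfigurationError(
                "numerical aperture must satisfy 0 < NA < medium index "
                f"(got NA={self.numerical_aperture}, n={self.medium_index})"
            )
        for name in (
            "wavelength_nm",
            "magnification",
            "tube_lens_f_mm",
            "fourier_lens_f_mm",
            "mla_focal_length_mm",
            "mla_pitch_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def objective_focal_length_mm(self) -> float:
        return self.tube_lens_f_mm / self.magnification

    @property
    def relayed_pupil_radius_mm(self) -> float:
        """Radius of the objective pupil image at the MLA plane.

        The 4f relay (tube lens -> Fourier lens) demagnifies the pupil by
        f_fourier / f_tube; the physical pupil radius is NA * f_objective.
        """
        return (
            self.numerical_aperture
            * self.objective_focal_length_mm
            * (self.fourier_lens_f_mm / self.tube_lens_f_mm)
        )

    def pixel_size_nm(self, modality: str) -> float:
        return PIXEL_SIZE_NM[modality]


@dataclass(frozen=True)
class LensletGeometry:
    """Normalized pupil-plane centers of the hexagonal lenslets.

    ``centers`` is a (7, 2) array of (u, v) coordinates with the pupil
    radius normalized to 1.  Index 0 is the central lenslet at the origin;
    indices 1-6 are the hexagonal neighbors at equal radius and 60 degree
    spacing.
    """

    centers: np.ndarray
    lenslet_radius_normalized: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.shape != (7, 2):
            raise ConfigurationError("expected 7 lenslet centers")
        if not np.allclose(c[0], 0.0):
            raise ConfigurationError("central lenslet must sit at (0, 0)")

    @property
    def count(self) -> int:
        return len(self.centers)


def make_lenslet_geometry(cfg: OpticalConfig, angle_offset_deg: float = 0.0) -> LensletGeometry:
    """Hexagonal 7-lenslet geometry in normalized pupil coordinates.

    The neighbor radius is the MLA pitch divided by the relayed pupil
    radius.  Raises :class:`ConfigurationError` when the pitch exceeds the
    pupil diameter (no off-axis lenslet would collect light).
    """
    r = cfg.mla_pitch_mm / cfg.relayed_pupil_radius_mm
    if r >= 2.0:
        raise ConfigurationError(
            "MLA pitch larger than relayed pupil diameter: no off-axis views"
        )
    ang = np.deg2rad(angle_offset_deg + 60.0 * np.arange(6))
    centers = np.zeros((7, 2))
    centers[1:, 0] = r * np.cos(ang)
    centers[1:, 1] = r * np.sin(ang)
    return LensletGeometry(centers=centers, lenslet_radius_normalized=r / 2.0)


def shift_coefficient(lenslet_uv, cfg: OpticalConfig) -> float:
    """tan(theta) of the chief ray for a lenslet center: nm of lateral
    image shift per nm of defocus, along the radial pupil direction."""
    u = np.asarray(lenslet_uv, dtype=float)
    rho = float(np.hypot(u[0], u[1]))
    if rho == 0.0:
        return 0.0
    sin_t = rho * cfg.numerical_aperture / cfg.medium_index
    if sin_t >= 1.0:
        raise EvanescentAngleError(
            f"|u| * NA / n = {sin_t:.3f} >= 1: evanescent ray angle"
        )
    return sin_t / np.sqrt(1.0 - sin_t * sin_t)


def parallax_shift(z_nm, lenslet_uv, cfg: OpticalConfig) -> np.ndarray:
    """Lateral image shift (dx, dy) in nm of an emitter at defocus ``z_nm``
    seen through the lenslet at normalized pupil position ``lenslet_uv``.

    The chief ray through a lenslet at pupil radius rho travels at
    sin(theta) = rho * NA / n in the sample medium, so the view is
    displaced by z * tan(theta) along the radial pupil direction.  The
    central lenslet has no parallax.  ``z_nm`` may be a scalar or array;
    the result has shape ``z.shape + (2,)``.
    """
    z = np.asarray(z_nm, dtype=float)
    u = np.asarray(lenslet_uv, dtype=float)
    rho = float(np.hypot(u[0], u[1]))
    if rho == 0.0:
        return np.zeros(z.shape + (2,)) if z.shape else np.zeros(2)
    c = shift_coefficient(u, cfg)
    direction = u / rho
    out = z[..., None] * c * direction
    return out


# ---------------------------------------------------------------------------
# PSF model specifications


@dataclass(frozen=True)
class PSFModelSpec:
    """Parameters of one modality's PSF model.

    ``dof_um`` is the axial range over which the modality encodes z; the
    benchmark draws ground-truth z uniformly over [-dof/2, +dof/2].
    """

    modality: str
    dof_um: float
    #: Zernike vertical-astigmatism coefficient (radians at the pupil edge).
    astig_strength_rad: float = 2.3
    #: Double-helix lobe-pair separation and lobe width (nm, sample space).
    dh_separation_nm: float = 1160.0
    dh_lobe_sigma_nm: float = 330.0
    #: Lobe-axis rotation rate (degrees per micrometre of defocus); the
    #: angle spans +-(rate * dof/2) and must stay within (-90, 90] to keep
    #: the angle -> z map single-valued.
    dh_rotation_deg_per_um: float = 37.5
    #: Parametric tetrapod model: two Gaussian lobes that separate along x
    #: for z > 0 and along y for z < 0 (the four "legs" of the tetrapod),
    #: with separation growing linearly with |z|.
    tetrapod_lobe_sigma_nm: float = 350.0
    tetrapod_sep_per_um: float = 1000.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.dof_um <= 0:
            raise ConfigurationError("dof_um must be positive")

    @property
    def dof_nm(self) -> float:
        return self.dof_um * 1e3


_DEFAULT_DOF_UM = {
    "standard": 1.0,
    "astigmatic": 1.0,
    "double_helix": 4.0,
    "tetrapod": 8.0,
    "lightfield": 8.0,
}


def default_spec(modality: str, **overrides) -> PSFModelSpec:
    """Default :class:`PSFModelSpec` for a modality (DoF ~1 um astigmatic,
    ~4 um double helix, 8 um tetrapod [configurable 6-20] and light field)."""
    kwargs = {"modality": modality, "dof_um": _DEFAULT_DOF_UM[modality]}
    kwargs.update(overrides)
    return PSFModelSpec(**kwargs)


def gaussian_sigma_nm(cfg: OpticalConfig, na: float | None = None) -> float:
    """Gaussian-equivalent width of a diffraction-limited spot,
    sigma ~ 0.21 * lambda / NA (Airy-to-Gaussian approximation)."""
    na = cfg.numerical_aperture if na is None else na
    return 0.21 * cfg.wavelength_nm / na


def lightfield_view_sigma_nm(cfg: OpticalConfig, geometry: LensletGeometry) -> float:
    """Width of a single perspective-view spot.  Each lenslet samples a
    sub-aperture of the pupil, so the effective NA is reduced by the
    normalized lenslet radius and the per-view spot is correspondingly
    wider than the full-NA diffraction limit."""
    na_eff = cfg.numerical_aperture * geometry.lenslet_radius_normalized
    return gaussian_sigma_nm(cfg, na=na_eff)


# ---------------------------------------------------------------------------
# Fourier-optics rendering


def _pupil_grid(n: int, half_extent: float):
    ax = (np.arange(n) - n / 2) * (2.0 * half_extent / n)
    ux, uy = np.meshgrid(ax, ax)
    rho2 = ux * ux + uy * uy
    return ux, uy, rho2


def _fourier_psf(cfg: OpticalConfig, z_nm: float, phase_extra, pixel_nm: float,
                 size_px: int, oversample: int, grid_n: int) -> np.ndarray:
    """Scalar Fourier-optics intensity PSF on the camera pixel grid.

    The pupil is sampled on a square grid whose half extent (in normalized
    pupil units) sets the fine image pixel pitch via
    ``dx = lambda / (2 * L * NA)``; the fine image is then binned by
    ``oversample`` to the camera pitch.  Defocus inside the immersion
    medium contributes the phase (2 pi / lambda) * z * sqrt(n^2 - NA^2 rho^2).
    """
    fine_px = pixel_nm / oversample
    half_extent = cfg.wavelength_nm / (2.0 * cfg.numerical_aperture * fine_px)
    if half_extent < 1.0:
        raise ConfigurationError(
            "camera pixel too coarse for this NA; increase oversample"
        )
    ux, uy, rho2 = _pupil_grid(grid_n, half_extent)
    aperture = rho2 <= 1.0
    na, nm_idx = cfg.numerical_aperture, cfg.medium_index
    kz = np.zeros_like(rho2)
    arg = nm_idx**2 - na**2 * rho2
    np.sqrt(np.clip(arg, 0.0, None), out=kz)
    phase = (2.0 * np.pi / cfg.wavelength_nm) * z_nm * kz
    if phase_extra is not None:
        phase = phase + phase_extra(ux, uy, rho2)
    field = np.where(aperture, np.exp(1j * phase), 0.0)
    img = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field)))) ** 2
    # bin fine pixels down to camera pixels, centered on the grid center
    m = size_px * oversample
    c = grid_n // 2
    half = m // 2
    sub = img[c - half : c - half + m, c - half : c - half + m]
    binned = sub.reshape(size_px, oversample, size_px, oversample).sum(axis=(1, 3))
    total = img.sum()
    return binned / total if total > 0 else binned


def _zernike_astig(strength_rad: float):
    def phase(ux, uy, rho2):
        return strength_rad * (ux * ux - uy * uy)

    return phase


def tetrapod_lobe_positions(spec: PSFModelSpec, z_nm: float) -> np.ndarray:
    """Centers (2, 2) of the two tetrapod lobes relative to the emitter
    (nm): they separate along x above focus and along y below."""
    half = 0.5 * spec.tetrapod_sep_per_um * abs(z_nm) / 1e3
    if z_nm >= 0:
        d = np.array([half, 0.0])
    else:
        d = np.array([0.0, half])
    return np.stack([d, -d])


def _integrated_gaussian_1d(edges_px: np.ndarray, center_px, sigma_px) -> np.ndarray:
    from scipy.special import erf

    s = np.sqrt(2.0) * np.asarray(sigma_px, dtype=float)
    z = (edges_px - np.asarray(center_px, dtype=float)) / s
    e = erf(z)
    return 0.5 * (e[..., 1:] - e[..., :-1])


def gaussian_spot(size_px: int, x_px: float, y_px: float, sigma_x_px: float,
                  sigma_y_px: float, photons: float) -> np.ndarray:
    """Pixel-integrated elliptical Gaussian spot (photons sum to budget on
    an infinite detector; edges clip whatever falls outside)."""
    edges = np.arange(size_px + 1, dtype=float)
    gx = _integrated_gaussian_1d(edges, x_px, sigma_x_px)
    gy = _integrated_gaussian_1d(edges, y_px, sigma_y_px)
    return photons * np.outer(gy, gx)


def dh_lobe_positions(spec: PSFModelSpec, z_nm: float) -> np.ndarray:
    """Centers (2, 2) of the two double-helix lobes, relative to the
    emitter position (nm).  The lobe axis rotates linearly with z."""
    ang = np.deg2rad(spec.dh_rotation_deg_per_um * z_nm / 1e3)
    half = 0.5 * spec.dh_separation_nm
    d = np.array([np.cos(ang), np.sin(ang)]) * half
    return np.stack([d, -d])


def render_psf(
    spec: PSFModelSpec,
    z_nm: float,
    photons: float,
    cfg: OpticalConfig,
    *,
    size_px: int | None = None,
    geometry: LensletGeometry | None = None,
    grid_n: int = 256,
    warn_out_of_dof: bool = True,
) -> np.ndarray:
    """Expectation image (photons per pixel) of a single emitter at
    defocus ``z_nm``, centered in the window.

    For the ``lightfield`` modality the result has shape (7, size, size):
    one sub-image per perspective view, each a diffraction-limited spot at
    the parallax-shifted position carrying 1/7 of the photon budget.
    Other modalities return a single (size, size) image.
    """
    if photons <= 0:
        raise ValueError("photons must be positive")
    if warn_out_of_dof and abs(z_nm) > spec.dof_nm / 2:
        import warnings

        warnings.warn(
            f"z={z_nm:.0f} nm outside the {spec.modality} depth of field",
            stacklevel=2,
        )
    pixel = cfg.pixel_size_nm(spec.modality)
    if size_px is None:
        size_px = _default_window_px(spec, cfg)
    half = (size_px - 1) / 2.0

    if spec.modality == "lightfield":
        if geometry is None:
            geometry = make_lenslet_geometry(cfg)
        sigma_px = lightfield_view_sigma_nm(cfg, geometry) / pixel
        out = np.zeros((7, size_px, size_px))
        share = photons / geometry.count
        for k, uv in enumerate(geometry.centers):
            shift = parallax_shift(z_nm, uv, cfg)
            out[k] = gaussian_spot(
                size_px,
                half + 0.5 + shift[0] / pixel - 0.5,
                half + 0.5 + shift[1] / pixel - 0.5,
                sigma_px,
                sigma_px,
                share,
            )
        return out

    if spec.modality == "double_helix":
        sigma_px = spec.dh_lobe_sigma_nm / pixel
        out = np.zeros((size_px, size_px))
        for lx, ly in dh_lobe_positions(spec, z_nm):
            out += gaussian_spot(
                size_px, half + lx / pixel, half + ly / pixel,
                sigma_px, sigma_px, photons / 2.0,
            )
        return out

    if spec.modality == "tetrapod":
        sigma_px = spec.tetrapod_lobe_sigma_nm / pixel
        out = np.zeros((size_px, size_px))
        for lx, ly in tetrapod_lobe_positions(spec, z_nm):
            out += gaussian_spot(
                size_px, half + lx / pixel, half + ly / pixel,
                sigma_px, sigma_px, photons / 2.0,
            )
        return out

    if spec.modality == "standard":
        phase = None
    elif spec.modality == "astigmatic":
        phase = _zernike_astig(spec.astig_strength_rad)
    else:  # pragma: no cover
        raise ConfigurationError(spec.modality)
    # large defocus needs finer pupil sampling to keep the phase Nyquist-safe
    if abs(z_nm) > 1500.0:
        grid_n = max(grid_n, 512)
    if abs(z_nm) > 6000.0:
        grid_n = max(grid_n, 1024)
    img = _fourier_psf(cfg, z_nm, phase, pixel, size_px, oversample=3, grid_n=grid_n)
    return photons * img


def _default_window_px(spec: PSFModelSpec, cfg: OpticalConfig) -> int:
    pixel = cfg.pixel_size_nm(spec.modality)
    if spec.modality == "tetrapod":
        extent = (
            spec.tetrapod_sep_per_um * spec.dof_um / 2.0
            + 8.0 * spec.tetrapod_lobe_sigma_nm
        )
    elif spec.modality == "double_helix":
        extent = 2.0 * (spec.dh_separation_nm + 4 * spec.dh_lobe_sigma_nm)
    elif spec.modality == "lightfield":
        geom = make_lenslet_geometry(cfg)
        extent = 10 * lightfield_view_sigma_nm(cfg, geom)
    else:
        extent = 12 * gaussian_sigma_nm(cfg) + 2.0 * abs(spec.dof_nm) / 2
    n = int(np.ceil(extent / pixel))
    return n + 1 if n % 2 == 0 else n


def psf_margin_nm(spec: PSFModelSpec, cfg: OpticalConfig,
                  geometry: LensletGeometry | None = None) -> float:
    """Sensor margin around the analysis field of view so that the PSF of
    an emitter at the FoV edge is still fully imaged (real detectors are
    larger than the analyzed region)."""
    if spec.modality == "lightfield":
        geometry = geometry or make_lenslet_geometry(cfg)
        c = shift_coefficient(geometry.centers[1], cfg)
        return c * spec.dof_nm / 2.0 + 5.0 * lightfield_view_sigma_nm(cfg, geometry)
    window = _default_window_px(spec, cfg) * cfg.pixel_size_nm(spec.modality)
    return window / 2.0


@dataclass
class PSFStack:
    """A z-indexed stack of expectation images for one modality."""

    z_values_nm: np.ndarray
    images: np.ndarray  # (nz, h, w) photons per pixel
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.z_values_nm = np.asarray(self.z_values_nm, dtype=float)
        self.images = np.asarray(self.images, dtype=float)
        if len(self.images) != len(self.z_values_nm):
            raise ValueError("images and z_values length mismatch")

    def save_tiff(self, path, sidecar_yaml=None) -> None:
        """Write the stack as a multi-page float32 TIFF with z metadata in
        a YAML sidecar."""
        import tifffile
        import yaml

        tifffile.imwrite(path, self.images.astype(np.float32))
        if sidecar_yaml is not None:
            meta = {
                "z_values_nm": [float(z) for z in self.z_values_nm],
                "pixel_size_nm": float(self.pixel_size_nm),
            }
            with open(sidecar_yaml, "w") as fh:
                yaml.safe_dump(meta, fh)


def render_psf_stack(
    spec: PSFModelSpec,
    photons: float,
    cfg: OpticalConfig,
    *,
    z_step_nm: float = 100.0,
    size_px: int | None = None,
    geometry: LensletGeometry | None = None,
) -> PSFStack:
    """Render the PSF over the modality's full depth of field.

    For the light-field modality the central perspective view is stacked
    (per-view footprint); other modalities stack the full image.
    """
    half = spec.dof_nm / 2.0
    z_values = np.arange(-half, half + z_step_nm / 2, z_step_nm)
    images = []
    for z in z_values:
        img = render_psf(
            spec, z, photons, cfg, size_px=size_px, geometry=geometry,
            warn_out_of_dof=False,
        )
        if spec.modality == "lightfield":
            img = img[0]
        images.append(img)
    return PSFStack(
        z_values_nm=z_values,
        images=np.stack(images),
        pixel_size_nm=cfg.pixel_size_nm(spec.modality),
    )


def psf_footprint_area(stack: PSFStack, threshold_frac: float = 0.01):
    """Above-threshold pixel area per z slice (um^2) and its mean.

    A pixel counts toward the footprint of a slice when it exceeds
    ``threshold_frac`` of that slice's peak.  Returns ``(areas, mean)``.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    if len(stack.images) == 0:
        raise ValueError("empty PSF stack")
    px_area_um2 = (stack.pixel_size_nm / 1e3) ** 2
    peaks = stack.images.reshape(len(stack.images), -1).max(axis=1)
    areas = np.array(
        [
            np.count_nonzero(img > threshold_frac * peak) * px_area_um2
            for img, peak in zip(stack.images, peaks)
        ]
    )
    return areas, float(areas.mean())
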