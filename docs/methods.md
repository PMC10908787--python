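# Methods

## Optical model

A hexagonal microlens array (MLA) in a relayed back focal plane divides the
objective pupil into seven sub-apertures: one central lenslet and six
neighbors at equal pupil radius, 60° apart.  With the default optics (60×,
NA 1.27 water immersion, 200 mm tube lens, 175 mm Fourier lens, 2.39 mm MLA
pitch) the relayed pupil radius is NA·f_obj·(f_Fourier/f_tube) ≈ 3.70 mm,
so the neighbor lenslets sit at normalized pupil radius
ρ = 2.39/3.70 ≈ 0.645.

An emitter at defocus *z* appears displaced in the view of the lenslet at
normalized position **u** by the parallax

    s(z, u) = z · tan θ · û,    sin θ = |u| · NA / n,

which is linear in *z* for a fixed lenslet (θ depends only on the lenslet
radius).  For the hexagonal geometry the shift gradient is
tan θ ≈ 0.781 nm of image shift per nm of defocus for every off-axis view.
Pupil positions with |u|·NA/n ≥ 1 correspond to evanescent angles and are
rejected.

Each perspective view collects light through a sub-aperture of normalized
radius 0.323, so its effective NA is 0.41 and the per-view spot is modelled
as a diffraction-limited Gaussian of σ ≈ 0.21 λ/NA_eff ≈ 343 nm — much
wider than the full-NA spot but constant across the 8 µm depth of field
(the sub-aperture's own depth of focus spans the working range).

## PSF models

* **standard / astigmatic** — scalar Fourier optics: a uniformly filled
  pupil with defocus phase (2π/λ)·z·√(n² − NA²ρ²), plus a vertical
  astigmatism (Zernike Z₂²) term for the astigmatic PSF.  The default
  astigmatism coefficient (2.3 rad at the pupil edge) corresponds to a
  ±~400 nm focal split, giving a strictly monotone σx − σy curve over a
  1 µm depth of field.  Camera images are rendered 3× oversampled and
  binned to the camera pitch.
* **double helix** — a parametric two-Gaussian-lobe model: lobes of
  σ = 330 nm separated by 1160 nm, with the lobe axis rotating linearly at
  37.5°/µm (±75° over the 4 µm DoF, keeping the angle→z map single
  valued).  This matches how double-helix data are analyzed in practice
  (circular Gaussian fits per lobe).
* **tetrapod** — a parametric two-lobe model whose lobes separate along x
  above focus and along y below (the four "legs"), with separation growing
  at 1 µm per µm of |z| over an 8 µm DoF (configurable within 6–20 µm).
  A simple polynomial pupil mask cannot cancel defocus over many microns —
  the rendered energy density collapses far from focus, unlike real
  (numerically optimized) tetrapod masks — so the parametric model keeps
  the modality detectable at realistic photon budgets while preserving its
  defining footprint and axial encoding.
* **lightfield** — seven Gaussian spots (σ = 343 nm, 1/7 photon share
  each) at the parallax-shifted positions.

Pixel sizes are 110 nm (standard, astigmatic, tetrapod) and 266 nm (double
helix, light field) in sample-space units.  The *PSF footprint* of a slice
is its above-threshold pixel area (default threshold: 1% of the slice
peak); averaged over the depth of field, the per-view light-field
footprint is ~0.55× the double-helix footprint.

## Simulator

Ground truth: per-frame emitter counts are Poisson(ρ_loc · area) over a
20 µm × 20 µm field of view, with x, y uniform and z uniform over the
modality's DoF (the axial prior is a modelling choice; the benchmark
conditions do not state one).  Photon budgets follow the three labelling
tiers (1000 / 4000 / 10000 detected photons).  Background defaults to 10
photons/pixel/frame at every tier.

Frames include a **sensor margin** around the analysis FoV equal to the
modality's PSF half-extent (for the light field: the maximum parallax plus
5σ of the view spot), as a real 512×512 detector provides; emitters near
the FoV edge are therefore fully imaged.  Localizations are reported in
FoV-relative coordinates.

The EMCCD chain applies, in order: quantum efficiency (0.9), Poisson shot
noise, gamma-distributed electron multiplication (gain 100, reproducing the
√2 excess-noise factor), Gaussian read noise (1 e⁻ input-referred), offset
and a clamp at zero ADU.  The offset (1000 ADU at 1 ADU/e⁻) is several
post-gain read-noise sigmas so the clamp never truncates the noise
distribution.  With gain 1, QE 1 and no read noise the chain reduces to
pure Poisson counts.  Benchmark frames are statistically independent;
a separate blinking mode (geometric on-times) emulates dSTORM emitters for
temporal-grouping tests.

Brownian trajectories for tracking use per-axis steps N(0, 2D·Δt) plus
independent Gaussian localization noise.

## Detection and 2D fitting

Detection is a difference-of-Gaussians band-pass (σ and 2σ at the PSF
scale) with non-maximum suppression over about one PSF full width.  The
threshold is min_snr = 5 times the filtered noise level; the noise level
comes from the camera model at the robustly estimated background (a
median-absolute-deviation estimate is the fallback when no camera model is
available, but it overestimates noise badly on crowded frames).  The
threshold was chosen so that isolated-emitter sensitivity at the sparse
benchmark condition (0.005 µm⁻², 4000 photons) exceeds 99% while chance
noise localizations remain rare, and then frozen.

Fitting is least squares with a pixel-integrated Gaussian model (circular
or elliptical), run as a batched Levenberg–Marquardt over all windows of a
frame at once; windows are 5×5 px for the 266 nm modalities, 7×7 px for
the standard PSF and 11×11 px for the astigmatic PSF (whose σ_y reaches
~2.2 px at the DoF edge).  Localization precision uses the Mortensen
least-squares formula with background correction.  There is deliberately
no computational multi-emitter fitting anywhere: one detection window
yields at most one localization, so overlapping emitters produce biased or
rejected fits — that is the effect the density benchmark measures.

For modalities without a multi-view consensus (standard, astigmatic,
double helix) a post-fit filter removes the occasional heavy-tailed
EMCCD noise detections: fits whose peak amplitude falls below the
detection SNR multiple of the camera noise, or whose fitted width is
below half the PSF scale (single-pixel spikes), are rejected.  The
light-field path needs no such filter — chance 2D noise localizations do
not survive the multi-view grouping.

Per-modality 3D readout:

* **astigmatic** — monotone interpolation of σx − σy against a
  self-calibration generated by rendering and fitting the PSF over its DoF
  (mirroring an experimental bead scan).  Out-of-range widths are
  rejected, never extrapolated.  A width filter (geometric-mean σ inside
  the calibration-curve range) removes blended fits.
* **double helix** — lobes paired greedily by separation consistency
  (each lobe used once); xy is the midpoint and z the linear map of the
  lobe-axis angle.
* **tetrapod** — matched-filter search over a template library (250 nm z
  grid) with sub-pixel refinement; acceptance by matched-filter SNR
  against the camera-model noise (a whole-window Pearson correlation is
  diluted by background pixels and rejects valid fits at realistic SNR).

## 3D light-field reconstruction

For each frame, every 2D localization seeds a candidate: localizations in
other views lying within `search_radius` (250 nm) of the seed's epipolar
locus vote for an implied defocus, and the largest z-consistent subset
(at most one localization per view) forms the candidate group.  Groups are
fitted by linear least squares to `s_k = (x, y) + z·w_k`; the fit reports
the RMS per-view residual and per-axis precisions from the residual-scaled
parameter covariance.  A fit is accepted when the residual is below
200 nm and at least `min_views` views contribute; while the gate fails,
the worst-residual member is trimmed down to `min_views`.

Reconstruction is greedy with lazy re-evaluation: candidates sit in a
priority queue ordered by residual; accepting one consumes its 2D members
and stale candidates are re-formed from the remaining pool, so each 2D
localization contributes to at most one 3D fit.  On frames with up to
three emitters this matches exhaustive enumeration over view assignments.

`min_views` defaults to 4 ("more than 3" views).  Three-view fits are
geometrically valid and can be enabled (they are used for the
precision-versus-views analysis), but they admit noticeably more chance
groupings at high density.

Aberration (residual disparity) correction estimates per-view median
residual vectors from the first 1000 frames and subtracts them from all 2D
localizations before the final solve.  The estimate is iterated because
the defocus absorbs part of a radial view offset each pass.  One gauge
direction is fundamentally unobservable: offsets proportional to the
per-view parallax gradients are indistinguishable from a global defocus
shift, so only the tangential (observable) part of the disparity is
recovered — which is also the only part that affects reconstruction
quality.

Drift correction subtracts the interpolated per-frame displacement of a
fiducial track.  Axial calibration fits commanded piezo z against
reconstructed z over an 8 µm scan (60 nm steps, ~134 points); the gradient
is a multiplicative correction factor (calibration fails below R² = 0.95).
Temporal grouping merges sequential localizations within a 4-frame gap
whose per-axis distances fall inside k = 3 times the combined precision,
keeping the brightest member's record.

## Benchmark scoring

Matching is an optimal (Hungarian) one-to-one assignment on the per-frame
3D Euclidean distance matrix (2D for the standard PSF), gated by a
per-modality tolerance; unmatched fits are false positives and unmatched
ground truth false negatives.  PPV = TP/(TP+FP), sensitivity = TP/GT,
Jaccard = TP/(TP+FP+FN).

The tolerance is calibrated per modality and photon tier as **3× the
larger of** the isolated-emitter RMS 3D error and the median fit-reported
3D precision, measured on well-separated emitters rendered by the same
simulator.  For the light field the isolated reconstruction is restricted
to `min_views` views first: dense data legitimately produce minimum-view
fits whose precision class is coarser than a 7-view fit, and a tolerance
derived only from 7-view fits would score those correct detections as
errors.  The factor 3 covers the far tail of the isolated error
distribution, so the score measures detection rather than precision-class
membership.  Before scoring, localizations with lateral fit error above
60 nm are discarded (the fitting-error threshold conventionally applied
when summarizing light-field reconstructions).

The speed comparison defines the error rate E = 1 − sensitivity, builds a
monotone (PCHIP, log-density) interpolant of density as a function of
error rate per modality, and reports the maximum density ratio over the
shared error-rate range.  1 − Jaccard is available as an alternative error
definition.

Fourier shell correlation renders two random half-sets as 3D histograms
and reports 1/frequency at the first crossing below the 1/7 cutoff.

## Tracking

Frame-to-frame linking within a link distance (default 500 nm), tolerating
up to 2 dark frames, with per-frame-pair conflicts resolved by optimal
assignment (greedy mode available); tracks shorter than 5 points are
discarded.  The diffusion coefficient per track is the isotropic Brownian
MLE D̂ = Σ‖Δr‖²/(2·3·ΣΔt).  No localization-noise correction is applied;
static noise biases D̂ by σ²/Δt per axis, and that floor is characterized
empirically from immobilized-emitter data instead.  Link distance, dark
frames and minimum length are user choices, not derived quantities.
Diffusion histograms use Freedman–Diaconis bins (Sturges fallback when the
IQR collapses).

## Problem sizes and determinism

Dense conditions contribute many emitters per frame, so benchmark runs
scale the frame count inversely with density (e.g. 60 frames at
0.005 µm⁻² but 10 at 0.375 µm⁻² in the acceptance script, ~3 repeats);
the per-condition emitter counts stay in the thousands and the rate
metrics are stable to ~1 percentage point.  All randomness flows from a
single seed through `numpy.random.default_rng` / `SeedSequence`, and
identical configurations reproduce byte-identical ground truth and frames.

## Known limitations

* The per-view light-field spot, double-helix and tetrapod PSFs are
  parametric Gaussian-lobe models.  They reproduce footprint areas and
  axial encodings but not the diffraction side structure or the photon
  inefficiency of real phase masks; in particular the double helix remains
  easier to detect at 1000 photons than its experimental counterpart, so
  low-photon speed comparisons against it are conservative.
* Blended (overlapping) emitters produce biased single-emitter 2D fits by
  design; at extreme density this limits the positive predictive value of
  the 3D reconstruction even though the grouping itself is essentially
  error-free on clean input.
* No sample aberrations beyond per-view disparity offsets, no sCMOS noise
  maps, no photobleaching kinetics.
* Passing tests on this simulator demonstrate correctness of the
  algorithms under the stated noise model, not performance on real
  microscope data, which adds aberrations, drift, non-uniform background
  and photophysics.
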