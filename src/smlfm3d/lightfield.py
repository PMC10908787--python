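"""3D reconstruction of light-field localizations by parallax fitting.

Per-view 2D localizations of one frame are grouped into emitter candidates
along their epipolar loci (the 1-parameter family of positions an emitter
traces across views as its defocus varies), then each candidate group is
fitted by least squares to the parallax model

    s_k = (x, y) + z * w_k,      w_k = tan(theta_k) * u_hat_k,

where ``w_k`` is the per-view shift gradient from the lenslet geometry.
A fit is accepted when its RMS per-view residual is below the residual
threshold (200 nm by default) and it uses at least ``min_views`` views.
Reconstruction is greedy: the best-residual candidate is accepted first,
its 2D members leave the pool, and remaining candidates are re-formed from
what is left, so every 2D localization is used at most once.

The module also provides per-view aberration (residual-disparity)
estimation, fiducial drift correction, axial calibration against a piezo
bead scan, and temporal grouping of re-appearing molecules.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit2d import LOC3D_COLUMNS
from .optics import LensletGeometry, OpticalConfig, shift_coefficient

__all__ = [
    "ReconstructConfig",
    "AberrationMap",
    "AxialCalibration",
    "CalibrationError",
    "shift_vectors",
    "fit_parallax",
    "group_candidates",
    "reconstruct_frame",
    "reconstruct",
    "estimate_aberration_map",
    "apply_aberration_map",
    "correct_drift",
    "axial_calibration",
    "temporal_group",
]


class CalibrationError(RuntimeError):
    """Raised when the axial bead-scan calibration cannot be trusted."""


@dataclass(frozen=True)
class ReconstructConfig:
    """Tunable parameters of the 3D reconstruction."""

    residual_threshold_nm: float = 200.0
    #: minimum perspective views per accepted fit; the reconstruction
    #: requires a subset of more than 3 elements by default, and 3-view
    #: fits can be enabled for precision-vs-views analyses.
    min_views: int = 4
    search_radius_nm: float = 250.0
    max_defocus_nm: float = 4000.0
    aberration_window_frames: int = 1000
    temporal_gap_frames: int = 4
    precision_gate_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.residual_threshold_nm <= 0:
            raise ValueError("residual_threshold_nm must be positive")
        if not 3 <= self.min_views <= 7:
            raise ValueError("min_views must lie in [3, 7]")


def shift_vectors(geometry: LensletGeometry, cfg: OpticalConfig) -> np.ndarray:
    """Per-view parallax gradients w_k (7, 2): image shift (nm) per nm of
    defocus."""
    out = np.zeros_like(geometry.centers)
    for k, uv in enumerate(geometry.centers):
        rho = np.hypot(uv[0], uv[1])
        if rho > 0:
            out[k] = shift_coefficient(uv, cfg) * uv / rho
    return out


def fit_parallax(
    positions: np.ndarray,
    views: np.ndarray,
    W: np.ndarray,
    cfg: ReconstructConfig | None = None,
):
    """Least-squares parallax fit of one candidate group.

    ``positions``: (m, 2) per-view localizations (nm); ``views``: their
    view indices; ``W``: the (7, 2) shift-gradient matrix.  Returns a dict
    with the estimate, per-axis precisions from the residual-scaled
    parameter covariance, and the RMS residual; or None when the geometry
    is singular (all views collinear in the pupil).
    """
    m = len(positions)
    A = np.zeros((2 * m, 3))
    A[0::2, 0] = 1.0
    A[1::2, 1] = 1.0
    A[0::2, 2] = W[views, 0]
    A[1::2, 2] = W[views, 1]
    b = np.asarray(positions, dtype=float).reshape(-1)
    AtA = A.T @ A
    if np.linalg.cond(AtA) > 1e10:
        return None
    p = np.linalg.solve(AtA, A.T @ b)
    pred = A @ p
    r = (b - pred).reshape(m, 2)
    ss = float((r**2).sum())
    residual = np.sqrt(ss / m)
    dof = 2 * m - 3
    s2 = ss / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(AtA)
    sigma_xy = float(np.sqrt(0.5 * (cov[0, 0] + cov[1, 1])))
    sigma_z = float(np.sqrt(cov[2, 2]))
    return {
        "x_nm": p[0],
        "y_nm": p[1],
        "z_nm": p[2],
        "sigma_xy_nm": sigma_xy,
        "sigma_z_nm": sigma_z,
        "residual_nm": residual,
        "n_views": m,
        "per_view_residuals": r,
    }


class _FramePool:
    """Per-view position arrays of one frame with a shared `used` mask."""

    def __init__(self, frame_df: pd.DataFrame):
        self.rows = frame_df.index.to_numpy()
        self.view = frame_df["view"].to_numpy(dtype=int)
        self.pos = frame_df[["x_nm", "y_nm"]].to_numpy(dtype=float)
        self.photons = frame_df["photons"].to_numpy(dtype=float)
        self.used = np.zeros(len(frame_df), dtype=bool)
        self.by_view = {v: np.nonzero(self.view == v)[0] for v in range(7)}


def _members_for_seed(pool: _FramePool, seed: int, W: np.ndarray,
                      cfg: ReconstructConfig, dz_tol: float):
    """Collect, per other view, the unused localizations consistent with
    some defocus of the seed, then pick the largest z-consistent subset."""
    sv = pool.view[seed]
    sp = pool.pos[seed]
    cand_z, cand_idx, cand_view, cand_perp = [], [], [], []
    for v in range(7):
        if v == sv:
            continue
        idx = pool.by_view[v]
        idx = idx[~pool.used[idx]]
        if len(idx) == 0:
            continue
        w = W[v] - W[sv]
        wn2 = float(w @ w)
        if wn2 < 1e-12:
            continue
        d = pool.pos[idx] - sp
        t = (d @ w) / wn2
        perp = np.linalg.norm(d - t[:, None] * w, axis=1)
        keep = (perp <= cfg.search_radius_nm) & (np.abs(t) <= cfg.max_defocus_nm + dz_tol)
        if not keep.any():
            continue
        cand_z.append(t[keep])
        cand_idx.append(idx[keep])
        cand_view.append(np.full(keep.sum(), v))
        cand_perp.append(perp[keep])
    if not cand_z:
        return None
    z = np.concatenate(cand_z)
    idx = np.concatenate(cand_idx)
    view = np.concatenate(cand_view)
    perp = np.concatenate(cand_perp)
    order = np.argsort(z)
    z, idx, view, perp = z[order], idx[order], view[order], perp[order]
    # two-pointer scan for the window of width 2*dz_tol with most views
    best = (-1, 0.0, 0, 0)  # (n_views, -spread, lo, hi)
    lo = 0
    n = len(z)
    for hi in range(n):
        while z[hi] - z[lo] > 2.0 * dz_tol:
            lo += 1
        nv = len(set(view[lo : hi + 1]))
        spread = z[hi] - z[lo]
        cand = (nv, -spread, lo, hi)
        if cand[:2] > best[:2]:
            best = cand
    nv, _, lo, hi = best
    if nv < 1:
        return None
    z0 = float(np.median(z[lo : hi + 1]))
    members = [seed]
    for v in set(view[lo : hi + 1]):
        m = np.nonzero(view[lo : hi + 1] == v)[0] + lo
        pick = m[np.argmin(np.abs(z[m] - z0) + perp[m] / cfg.search_radius_nm * dz_tol * 0.1)]
        members.append(int(idx[pick]))
    return members


def _min_pair_gradient(W: np.ndarray) -> float:
    d = W[:, None, :] - W[None, :, :]
    n = np.linalg.norm(d, axis=2)
    n = n[n > 1e-9]
    return float(n.min())


def group_candidates(
    frame_df: pd.DataFrame,
    geometry: LensletGeometry,
    cfg: ReconstructConfig,
    optics_cfg: OpticalConfig,
) -> list[list]:
    """Candidate groups (lists of row labels) for one frame, seeded from
    every localization (central view first), without consuming the pool.
    Groups below ``min_views`` are omitted."""
    W = shift_vectors(geometry, optics_cfg)
    dz_tol = cfg.search_radius_nm / _min_pair_gradient(W)
    pool = _FramePool(frame_df)
    order = np.argsort(pool.view, kind="stable")
    groups = []
    for seed in order:
        members = _members_for_seed(pool, int(seed), W, cfg, dz_tol)
        if members is not None and len(members) >= cfg.min_views:
            groups.append([pool.rows[i] for i in members])
    return groups


def reconstruct_frame(
    frame_df: pd.DataFrame,
    geometry: LensletGeometry,
    cfg: ReconstructConfig,
    optics_cfg: OpticalConfig,
) -> pd.DataFrame:
    """Greedy parallax reconstruction of one frame of 2D localizations.

    Candidates from every seed are fitted and kept in a priority queue by
    residual; accepting a candidate consumes its 2D members, and stale
    candidates are lazily re-formed from the remaining pool.  The output
    table carries a ``members`` column with the row labels of the 2D
    localizations behind each accepted 3D fit.
    """
    if len(frame_df) == 0:
        return pd.DataFrame(columns=LOC3D_COLUMNS + ["members"])
    W = shift_vectors(geometry, optics_cfg)
    dz_tol = cfg.search_radius_nm / _min_pair_gradient(W)
    pool = _FramePool(frame_df)
    frame = int(frame_df["frame"].iloc[0])

    heap = []
    counter = 0

    def push_seed(seed: int):
        nonlocal counter
        if pool.used[seed]:
            return
        members = _members_for_seed(pool, seed, W, cfg, dz_tol)
        if members is None or len(members) < cfg.min_views:
            return
        fit = fit_parallax(pool.pos[members], pool.view[members], W, cfg)
        # trim the worst outlier view while the residual gate fails
        while (
            fit is not None
            and fit["residual_nm"] >= cfg.residual_threshold_nm
            and len(members) > cfg.min_views
        ):
            per_view = np.linalg.norm(fit["per_view_residuals"], axis=1)
            per_view[0] = -1.0  # never drop the seed (members[0])
            members.pop(int(np.argmax(per_view)))
            fit = fit_parallax(pool.pos[members], pool.view[members], W, cfg)
        if fit is None or fit["residual_nm"] >= cfg.residual_threshold_nm:
            return
        if abs(fit["z_nm"]) > cfg.max_defocus_nm:
            return
        heapq.heappush(heap, (fit["residual_nm"], counter, seed, members, fit))
        counter += 1

    order = np.argsort(pool.view, kind="stable")
    for seed in order:
        push_seed(int(seed))

    out = []
    while heap:
        _, _, seed, members, fit = heapq.heappop(heap)
        if pool.used[seed]:
            continue
        if any(pool.used[m] for m in members):
            push_seed(seed)  # re-form from the remaining pool
            continue
        for m in members:
            pool.used[m] = True
        out.append(
            {
                "frame": frame,
                "x_nm": fit["x_nm"],
                "y_nm": fit["y_nm"],
                "z_nm": fit["z_nm"],
                "sigma_xy_nm": fit["sigma_xy_nm"],
                "sigma_z_nm": fit["sigma_z_nm"],
                "residual_nm": fit["residual_nm"],
                "n_views": fit["n_views"],
                "photons": float(pool.photons[members].sum()),
                "members": tuple(pool.rows[m] for m in members),
            }
        )
    return pd.DataFrame(out, columns=LOC3D_COLUMNS + ["members"])


def reconstruct(
    locs2d: pd.DataFrame,
    geometry: LensletGeometry,
    cfg: ReconstructConfig | None = None,
    optics_cfg: OpticalConfig | None = None,
    correct_aberration: bool = False,
    axial_factor: float = 1.0,
) -> pd.DataFrame:
    """Reconstruct all frames of a per-view 2D localization table.

    With ``correct_aberration`` the per-view residual disparity is first
    estimated from the early frames and subtracted from all 2D
    localizations before the final solve.  ``axial_factor`` is the
    multiplicative axial-calibration correction applied to reported z.
    """
    cfg = cfg or ReconstructConfig()
    optics_cfg = optics_cfg or OpticalConfig()
    if correct_aberration and len(locs2d):
        amap = estimate_aberration_map(locs2d, geometry, cfg, optics_cfg)
        locs2d = apply_aberration_map(locs2d, amap)
    parts = [
        reconstruct_frame(g, geometry, cfg, optics_cfg)
        for _, g in locs2d.groupby("frame", sort=True)
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=LOC3D_COLUMNS + ["members"])
    out = pd.concat(parts, ignore_index=True)
    if axial_factor != 1.0:
        out["z_nm"] = out["z_nm"] * axial_factor
    return out


# ---------------------------------------------------------------------------
# aberration (residual disparity)


@dataclass
class AberrationMap:
    """Per-view systematic (dx, dy) localization offsets in nm; the central
    view is the reference and is identically zero."""

    offsets_nm: np.ndarray  # (7, 2)

    def __post_init__(self) -> None:
        self.offsets_nm = np.asarray(self.offsets_nm, dtype=float)
        if self.offsets_nm.shape != (7, 2):
            raise ValueError("expected (7, 2) offsets")
        if not np.allclose(self.offsets_nm[0], 0.0):
            raise ValueError("central view offset must be (0, 0)")

    @classmethod
    def identity(cls) -> "AberrationMap":
        return cls(np.zeros((7, 2)))


def estimate_aberration_map(
    locs2d: pd.DataFrame,
    geometry: LensletGeometry,
    cfg: ReconstructConfig,
    optics_cfg: OpticalConfig,
    min_fits: int = 10,
    n_iter: int = 4,
) -> AberrationMap:
    """Median per-view residual disparity of accepted fits over the first
    ``aberration_window_frames`` frames (all frames when fewer).

    Because the least-squares solve absorbs any common displacement, the
    per-view medians are reported relative to the central view; and because
    the radial component of a view offset is partially absorbed into the
    fitted defocus, the estimate is refined iteratively (subtract the
    current map, refit, re-estimate) until it converges on the true
    disparity.
    """
    window = locs2d[
        locs2d["frame"] < locs2d["frame"].min() + cfg.aberration_window_frames
    ].copy()
    W = shift_vectors(geometry, optics_cfg)
    total = np.zeros((7, 2))
    for it in range(n_iter):
        fitted = reconstruct(window, geometry, cfg, optics_cfg)
        if len(fitted) < min_fits:
            if it == 0:
                warnings.warn(
                    "too few accepted fits for aberration estimation; identity map"
                )
                return AberrationMap.identity()
            break
        view_of = window["view"]
        pos = window[["x_nm", "y_nm"]]
        res = {v: [] for v in range(7)}
        for row in fitted.itertuples(index=False):
            pred_xy = np.array([row.x_nm, row.y_nm])
            for label in row.members:
                v = int(view_of.loc[label])
                p = pos.loc[label].to_numpy(dtype=float)
                res[v].append(p - (pred_xy + row.z_nm * W[v]))
        med = np.zeros((7, 2))
        for v in range(7):
            if res[v]:
                med[v] = np.median(np.asarray(res[v]), axis=0)
        med -= med[0]
        med[0] = 0.0
        total += med
        window = apply_aberration_map(window, AberrationMap(med))
        if np.abs(med).max() < 0.5:
            break
    total[0] = 0.0
    return AberrationMap(total)


def apply_aberration_map(locs2d: pd.DataFrame, amap: AberrationMap) -> pd.DataFrame:
    """Subtract the per-view disparity offsets from a 2D table (copy)."""
    out = locs2d.copy()
    off = amap.offsets_nm[out["view"].to_numpy(dtype=int)]
    out["x_nm"] = out["x_nm"] - off[:, 0]
    out["y_nm"] = out["y_nm"] - off[:, 1]
    return out


# ---------------------------------------------------------------------------
# drift, axial calibration, temporal grouping


def correct_drift(locs3d: pd.DataFrame, fiducial: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-frame displacement of a fiducial marker.

    ``fiducial`` has columns frame, x_nm, y_nm, z_nm; gaps are linearly
    interpolated.  Raises ``ValueError`` when the fiducial table is empty.
    """
    if len(fiducial) == 0:
        raise ValueError(
            "no fiducial localizations: localize a fiducial marker first "
            "or skip drift correction"
        )
    fid = fiducial.sort_values("frame")
    frames = locs3d["frame"].to_numpy(dtype=float)
    out = locs3d.copy()
    for axis in ("x_nm", "y_nm", "z_nm"):
        track = np.interp(frames, fid["frame"].to_numpy(dtype=float),
                          fid[axis].to_numpy(dtype=float))
        first = fid[axis].iloc[0]
        out[axis] = out[axis] - (track - first)
    return out


@dataclass(frozen=True)
class AxialCalibration:
    """Linear correction mapping reconstructed z onto true (piezo) z.

    ``correction_factor`` is the gradient of the fit of commanded piezo
    position against reconstructed z; reported z values are multiplied by
    it.
    """

    correction_factor: float
    intercept_nm: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.correction_factor <= 0:
            raise CalibrationError("correction factor must be positive")

    def apply(self, z_nm):
        return np.asarray(z_nm, dtype=float) * self.correction_factor


def axial_calibration(recon_z_nm, piezo_z_nm, min_r2: float = 0.95) -> AxialCalibration:
    """Ordinary least-squares line through (reconstructed z, commanded z).

    Raises :class:`CalibrationError` when the linear fit explains less than
    ``min_r2`` of the variance.
    """
    from scipy.stats import linregress

    res = linregress(np.asarray(recon_z_nm, float), np.asarray(piezo_z_nm, float))
    r2 = res.rvalue**2
    if r2 < min_r2:
        raise CalibrationError(f"calibration R^2 = {r2:.3f} < {min_r2}")
    return AxialCalibration(float(res.slope), float(res.intercept), float(r2))


def temporal_group(locs3d: pd.DataFrame, cfg: ReconstructConfig | None = None) -> pd.DataFrame:
    """Merge re-appearances of one molecule across nearby frames.

    Sequential localizations within ``temporal_gap_frames`` of each other
    are chained when they fall within k times their combined precision per
    axis (k = ``precision_gate_multiplier``).  Each chain is reduced to its
    brightest member's record (position, precision, photons).
    """
    cfg = cfg or ReconstructConfig()
    if len(locs3d) == 0:
        return locs3d.copy()
    df = locs3d.sort_values(["frame"], kind="stable").reset_index(drop=True)
    k = cfg.precision_gate_multiplier
    chains: list[dict] = []  # each: {'last': row, 'rows': [indices]}
    frames = df["frame"].to_numpy()
    xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    sxy = df["sigma_xy_nm"].to_numpy(dtype=float)
    sz = df["sigma_z_nm"].to_numpy(dtype=float)
    open_chains: list[dict] = []
    all_chains: list[list[int]] = []
    for i in range(len(df)):
        f = frames[i]
        best = None
        for ch in open_chains:
            j = ch["last"]
            gap = f - frames[j]
            if gap <= 0 or gap > cfg.temporal_gap_frames:
                continue
            gate_xy = k * np.hypot(sxy[i], sxy[j])
            gate_z = k * np.hypot(sz[i], sz[j])
            dxy = xyz[i, :2] - xyz[j, :2]
            dz = abs(xyz[i, 2] - xyz[j, 2])
            if abs(dxy[0]) <= gate_xy and abs(dxy[1]) <= gate_xy and dz <= gate_z:
                d = np.hypot(dxy[0], dxy[1]) + dz
                if best is None or d < best[0]:
                    best = (d, ch)
        if best is None:
            ch = {"last": i, "rows": [i]}
            open_chains.append(ch)
            all_chains.append(ch["rows"])
        else:
            best[1]["last"] = i
            best[1]["rows"].append(i)
        open_chains = [c for c in open_chains if f - frames[c["last"]] <= cfg.temporal_gap_frames]
    out_rows = []
    for rows in all_chains:
        sub = df.iloc[rows]
        best = sub["photons"].idxmax()
        rec = df.loc[best].copy()
        rec["n_grouped"] = len(rows)
        out_rows.append(rec)
    return pd.DataFrame(out_rows).reset_index(drop=True)
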