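"""3D single-particle tracking and diffusion estimation.

Localizations are linked frame to frame by optimal assignment within a
linking distance, tolerating a configurable number of dark frames; each
trajectory's diffusion coefficient is the maximum-likelihood estimate for
isotropic Brownian motion,

    D_hat = sum_i ||r_{i+1} - r_i||^2 / (2 d sum_i dt_i),   d = 3.

No localization-noise correction is applied: static localization error
biases D_hat upward by sigma^2 / dt per axis, and that floor is
characterized empirically from immobilized-emitter data instead
(:func:`noise_floor`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TrackingConfig",
    "Track",
    "link_tracks",
    "mle_diffusion",
    "noise_floor",
    "diffusion_distribution",
]


@dataclass(frozen=True)
class TrackingConfig:
    max_dark_frames: int = 2
    link_distance_nm: float = 500.0
    min_track_length: int = 5
    dt_s: float = 0.02
    #: resolve per-frame linking conflicts by global minimal total
    #: displacement (optimal assignment); greedy nearest-neighbor mode is
    #: available for comparison.
    greedy: bool = False

    def __post_init__(self) -> None:
        if self.max_dark_frames < 0 or self.link_distance_nm <= 0:
            raise ValueError("linking parameters must be positive")
        if self.min_track_length < 2 or self.dt_s <= 0:
            raise ValueError("min_track_length >= 2 and dt > 0 required")


@dataclass
class Track:
    """A time-ordered 3D trajectory with its diffusion estimate."""

    track_id: int
    frames: np.ndarray
    xyz_nm: np.ndarray  # (n, 3)
    d_um2_s: float = np.nan

    @property
    def n_points(self) -> int:
        return len(self.frames)


def link_tracks(locs3d: pd.DataFrame, cfg: TrackingConfig) -> list[Track]:
    """Frame-to-frame nearest-neighbor linking with gap tolerance.

    Conflicts within a frame pair are resolved by minimizing the total
    displacement (Hungarian assignment); localizations that link nothing
    start new tracks; tracks shorter than ``min_track_length`` are
    discarded.  The result is invariant to input row order.
    """
    if len(locs3d) == 0:
        return []
    df = locs3d.sort_values(["frame", "x_nm", "y_nm", "z_nm"], kind="stable")
    frames_u = np.sort(df["frame"].unique())
    active: list[dict] = []
    done: list[dict] = []
    for f in frames_u:
        pts = df[df["frame"] == f][["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        still, expired = [], []
        for tr in active:
            (expired if f - tr["last_frame"] > cfg.max_dark_frames + 1 else still).append(tr)
        done.extend(expired)
        active = still
        assigned = np.full(len(pts), -1)
        if active and len(pts):
            last = np.array([tr["xyz"][-1] for tr in active])
            d = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            if cfg.greedy:
                order = np.argsort(d, axis=None)
                used_t = np.zeros(len(active), bool)
                for flat in order:
                    ti, pi = np.unravel_index(flat, d.shape)
                    if d[ti, pi] > cfg.link_distance_nm:
                        break
                    if used_t[ti] or assigned[pi] >= 0:
                        continue
                    used_t[ti] = True
                    assigned[pi] = ti
            else:
                big = 1e12
                cost = np.where(d <= cfg.link_distance_nm, d, big)
                ri, ci = linear_sum_assignment(cost)
                for ti, pi in zip(ri, ci):
                    if d[ti, pi] <= cfg.link_distance_nm:
                        assigned[pi] = ti
        for pi, ti in enumerate(assigned):
            if ti >= 0:
                active[ti]["frames"].append(int(f))
                active[ti]["xyz"].append(pts[pi])
        for pi in np.nonzero(assigned < 0)[0]:
            active.append({"frames": [int(f)], "xyz": [pts[pi]], "last_frame": int(f)})
        for tr in active:
            if tr["frames"][-1] == f:
                tr["last_frame"] = int(f)
    done.extend(active)
    tracks = []
    tid = 0
    for tr in done:
        if len(tr["frames"]) >= cfg.min_track_length:
            tracks.append(
                Track(tid, np.asarray(tr["frames"]), np.asarray(tr["xyz"]))
            )
            tid += 1
    return tracks


def mle_diffusion(track: Track, cfg: TrackingConfig) -> float:
    """Maximum-likelihood diffusion coefficient (um^2/s) of one track.

    Gap intervals are weighted by their elapsed time.  Raises
    ``ValueError`` for single-point tracks.
    """
    if track.n_points < 2:
        raise ValueError("cannot estimate diffusion from a single point")
    disp = np.diff(track.xyz_nm, axis=0) / 1e3  # um
    dts = np.diff(track.frames) * cfg.dt_s
    d = 3
    return float((disp**2).sum() / (2.0 * d * dts.sum()))


def noise_floor(static_locs3d: pd.DataFrame, cfg: TrackingConfig) -> float:
    """Smallest resolvable diffusion coefficient, from immobilized
    emitters: the median apparent D of linked static trajectories
    (analytically ~ sigma^2 / dt for per-axis localization noise sigma)."""
    tracks = link_tracks(static_locs3d, cfg)
    if not tracks:
        return 0.0
    ds = [mle_diffusion(t, cfg) for t in tracks]
    return float(np.median(ds))


def diffusion_distribution(d_values) -> dict:
    """Histogram of diffusion coefficients with Freedman-Diaconis bins.

    Bin width = 2 IQR n^(-1/3); when the IQR collapses to zero the
    histogram falls back to Sturges bins with a warning.  Returns the bin
    edges/counts plus median and quartiles.
    """
    import warnings

    d = np.asarray(list(d_values), dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one diffusion value")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    if iqr > 0:
        width = 2.0 * iqr * len(d) ** (-1.0 / 3.0)
        n_bins = max(1, int(np.ceil((d.max() - d.min()) / width))) if d.max() > d.min() else 1
        edges = d.min() + width * np.arange(n_bins + 1)
        rule = "freedman-diaconis"
    else:
        warnings.warn("IQR is zero; falling back to Sturges bins")
        n_bins = int(np.ceil(np.log2(len(d)))) + 1 if len(d) > 1 else 1
        edges = np.linspace(d.min(), d.max() + 1e-12, n_bins + 1)
        width = edges[1] - edges[0]
        rule = "sturges"
    counts, edges = np.histogram(d, bins=edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "bin_width": float(width),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "rule": rule,
    }
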