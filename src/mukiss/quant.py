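"""Image quantification: spot tracking velocimetry, kymographs,
colocalization, cluster dynamics and trajectory characterization.

All operations consume calibrated :class:`~mukiss.imaging.ImageSeries`
or localization/trajectory tables and return plain DataFrames or small
result dataclasses; nothing here depends on the synthetic generators,
so the same code paths apply to recorded data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops

from .imaging import ImageSeries
from .tracers import TrajectorySet

logger = logging.getLogger(__name__)


# -- detection and linking ------------------------------------------------

def detect_spots(
    frame: np.ndarray,
    expected_size: float = 3.0,
    threshold: float = 5.0,
    pixel_size: float = 1.0,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Band-pass + local-maxima spot detection with centroid refinement.

    `expected_size` is the spot diameter in pixels (≥ 2); `threshold` an
    absolute band-passed intensity cut.  Returns a table of sub-pixel
    localizations (x, y in μm via `pixel_size`) with intensity and
    detection score.
    """
    if expected_size < 2:
        raise ValueError("expected_size must be at least 2 pixels")
    img = np.asarray(frame, dtype=float)
    if img.size and (img == img.max()).mean() > 0.01 and img.max() > 0:
        warnings.warn("frame looks saturated: clipped highlights")
    bp = difference_of_gaussians(img, low_sigma=1.0, high_sigma=expected_size)
    peaks = peak_local_max(
        bp,
        min_distance=max(int(round(expected_size)), 1),
        threshold_abs=threshold,
        exclude_border=False,
    )
    rows = []
    w = max(int(round(expected_size)), 2)
    bp_pos = np.maximum(bp, 0.0)
    for py, px in peaks:
        y0, y1 = max(py - w, 0), min(py + w + 1, img.shape[0])
        x0, x1 = max(px - w, 0), min(px + w + 1, img.shape[1])
        win = bp_pos[y0:y1, x0:x1]
        tot = win.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = (win * yy).sum() / tot
        cx = (win * xx).sum() / tot
        rows.append(
            {
                "frame": frame_index,
                "x": (cx + 0.5) * pixel_size,
                "y": (cy + 0.5) * pixel_size,
                "intensity": img[y0:y1, x0:x1].sum(),
                "score": bp[py, px],
            }
        )
    return pd.DataFrame(rows, columns=["frame", "x", "y", "intensity", "score"])


def detect_spots_series(series: ImageSeries, expected_size=3.0, threshold=5.0):
    """Run :func:`detect_spots` on every frame of a series."""
    tables = [
        detect_spots(
            series.frames[k],
            expected_size=expected_size,
            threshold=threshold,
            pixel_size=series.pixel_size,
            frame_index=k,
        )
        for k in range(series.n_frames)
    ]
    return pd.concat(tables, ignore_index=True)


def link_trajectories(
    localizations: pd.DataFrame,
    max_displacement: float,
    memory: int = 0,
    frame_interval: float = 1.0,
) -> TrajectorySet:
    """Gated nearest-neighbor frame-to-frame linking.

    Candidate (track, localization) pairs within the displacement gate
    are assigned greedily by increasing distance, which breaks ties by
    minimal total displacement; an exactly ambiguous assignment rejects
    both candidates.  `memory` is the number of frames a lost particle
    may skip and still be reconnected.
    """
    if max_displacement < 0:
        raise ValueError("max_displacement must be ≥ 0")
    locs = localizations.sort_values("frame").reset_index(drop=True)
    next_id = 0
    tracks: dict[int, list] = {}
    heads: dict[int, tuple[int, float, float]] = {}  # id -> (frame, x, y)
    for f, grp in locs.groupby("frame"):
        pts = grp[["x", "y"]].to_numpy()
        cand = []
        ids = list(heads.keys())
        for tid in ids:
            hf, hx, hy = heads[tid]
            if f - hf > memory + 1:
                continue
            d = np.hypot(pts[:, 0] - hx, pts[:, 1] - hy)
            for j in np.nonzero(d <= max_displacement)[0]:
                cand.append((d[j], tid, int(j)))
        cand.sort(key=lambda c: c[0])
        used_t, used_p = set(), set()
        blocked_p = set()  # ambiguous localizations: no link, new track
        i = 0
        while i < len(cand):
            d, tid, j = cand[i]
            twins = [c for c in cand[i + 1 :] if abs(c[0] - d) < 1e-12 and
                     (c[1] == tid or c[2] == j) and (c[1], c[2]) != (tid, j)]
            if twins and tid not in used_t and j not in used_p:
                # exactly ambiguous: reject every party; the orphaned
                # localizations start fresh trajectories below
                used_t.add(tid)
                blocked_p.add(j)
                for c in twins:
                    used_t.add(c[1])
                    blocked_p.add(c[2])
                logger.warning(
                    "ambiguous assignment at frame %s rejected (tie)", f
                )
                i += 1
                continue
            if tid not in used_t and j not in used_p and j not in blocked_p:
                tracks[tid].append((f, pts[j, 0], pts[j, 1]))
                heads[tid] = (f, pts[j, 0], pts[j, 1])
                used_t.add(tid)
                used_p.add(j)
            i += 1
        for j in range(len(pts)):
            if j not in used_p:
                tracks[next_id] = [(f, pts[j, 0], pts[j, 1])]
                heads[next_id] = (f, pts[j, 0], pts[j, 1])
                next_id += 1
        # drop stale heads
        for tid in [t for t, (hf, _, _) in heads.items() if f - hf > memory]:
            del heads[tid]
    rows = []
    for tid, pts in tracks.items():
        for f, x, y in pts:
            rows.append((tid, f * frame_interval, x, y, 0.0))
    data = pd.DataFrame(rows, columns=["particle_id", "t", "x", "y", "z"])
    return TrajectorySet(data=data, frame_interval=frame_interval)


def velocity_map(
    trajectories: TrajectorySet,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    min_count: int = 1,
) -> dict:
    """Binned step velocimetry: per-bin vector-mean velocity and speed.

    Each frame-to-frame step contributes its displacement/interval
    velocity at the step midpoint.  Bins with fewer than `min_count`
    steps are masked (NaN), not zeroed.
    """
    steps = trajectories.steps()
    x_edges = np.asarray(x_edges)
    y_edges = np.asarray(y_edges)
    ix = np.digitize(steps["x"], x_edges) - 1
    iy = np.digitize(steps["y"], y_edges) - 1
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    shape = (ny, nx)
    count = np.zeros(shape)
    vx = np.zeros(shape)
    vy = np.zeros(shape)
    np.add.at(count, (iy[ok], ix[ok]), 1)
    np.add.at(vx, (iy[ok], ix[ok]), steps["vx"][ok])
    np.add.at(vy, (iy[ok], ix[ok]), steps["vy"][ok])
    with np.errstate(invalid="ignore"):
        vx = np.where(count >= min_count, vx / np.maximum(count, 1), np.nan)
        vy = np.where(count >= min_count, vy / np.maximum(count, 1), np.nan)
    return {
        "vx": vx,
        "vy": vy,
        "speed": np.hypot(vx, vy),
        "count": count,
        "x_edges": x_edges,
        "y_edges": y_edges,
    }


# -- kymographs -----------------------------------------------------------

@dataclass
class Kymograph:
    """Intensity along a sampling path vs time.

    data has shape (n_positions, n_frames); positions are arc-length μm
    along the path; times in s.
    """

    data: np.ndarray
    positions: np.ndarray
    times: np.ndarray
    path: np.ndarray = field(repr=False, default=None)
    line_width: float = 1.0

    def plot(self, ax=None, cmap="magma"):
        """Position-vs-time intensity map with calibrated axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(
            self.data, aspect="auto", origin="lower", cmap=cmap,
            extent=[self.times[0], self.times[-1],
                    self.positions[0], self.positions[-1]],
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position along path (μm)")
        return ax

    def time_reversed(self) -> "Kymograph":
        return Kymograph(
            data=self.data[:, ::-1].copy(),
            positions=self.positions,
            times=self.times,
            path=self.path,
            line_width=self.line_width,
        )


def build_kymograph(
    series: ImageSeries, path: np.ndarray, line_width: float = 1.0
) -> Kymograph:
    """Average intensity across `line_width` perpendicular to `path`.

    `path` is a polyline in μm; samples are taken at pixel pitch along
    it, with bilinear interpolation.
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if len(path) < 2:
        raise ValueError("path needs at least two points")
    px = series.pixel_size
    ny, nx = series.frames.shape[1:]
    if (path[:, 0].min() < 0 or path[:, 1].min() < 0
            or path[:, 0].max() > nx * px or path[:, 1].max() > ny * px):
        raise ValueError("path exits the frame bounds")
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    if total <= 0:
        raise ValueError("path has zero length")
    n_samples = max(int(np.floor(total / px)) + 1, 2)
    s = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    k = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[k]) / np.maximum(seg_len[k], 1e-300)
    pts = path[k] + frac[:, None] * seg[k]
    tang = seg[k] / np.maximum(seg_len[k], 1e-300)[:, None]
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    n_off = max(int(round(line_width / px)), 1)
    offsets = (np.arange(n_off) - (n_off - 1) / 2.0) * px
    sample_pts = pts[:, None, :] + offsets[None, :, None] * norm[:, None, :]
    # map to pixel-index coordinates (pixel centers at (i + 0.5) * px)
    rows = sample_pts[..., 1] / px - 0.5
    cols = sample_pts[..., 0] / px - 0.5
    data = np.empty((n_samples, series.n_frames))
    for t in range(series.n_frames):
        vals = ndimage.map_coordinates(
            series.frames[t], [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
        data[:, t] = vals.mean(axis=1)
    return Kymograph(
        data=data,
        positions=s,
        times=series.timestamps,
        path=path,
        line_width=line_width,
    )


def kymograph_feature_speed(
    kymo: Kymograph,
    feature_window: tuple[float, float],
    min_snr: float = 2.0,
) -> tuple[float, int]:
    """Speed of a linear ridge, nm/s, from centroid tracking + regression.

    `feature_window` is the (lo, hi) arc-length range containing the
    ridge at the first time sample; the window tracks the ridge centroid
    across columns.  Returns (speed in nm/s, frames used); the trace is
    truncated when the centroid SNR drops below `min_snr`.
    """
    lo, hi = feature_window
    half = 0.5 * (hi - lo)
    center = 0.5 * (hi + lo)
    pos = kymo.positions
    centroids = []
    times = []
    weights = []
    for j in range(kymo.data.shape[1]):
        col = kymo.data[:, j]
        baseline = np.median(col)
        noise = 1.4826 * np.median(np.abs(col - baseline)) + 1e-12
        sel = (pos >= center - half) & (pos <= center + half)
        prof = np.maximum(col[sel] - baseline, 0.0)
        if prof.size == 0 or prof.max() / noise < min_snr:
            break
        c = float((prof * pos[sel]).sum() / prof.sum())
        centroids.append(c)
        times.append(kymo.times[j])
        weights.append(prof.sum())
        center = c
    if len(centroids) < 10:
        raise ValueError("ridge visible for fewer than 10 time samples")
    t = np.asarray(times)
    c = np.asarray(centroids)
    w = np.asarray(weights)
    W = w.sum()
    tbar = (w * t).sum() / W
    cbar = (w * c).sum() / W
    slope = (w * (t - tbar) * (c - cbar)).sum() / (w * (t - tbar) ** 2).sum()
    return slope * 1.0e3, len(centroids)  # μm/s → nm/s


# -- colocalization -------------------------------------------------------

@dataclass
class ColocResult:
    M1: float  # fraction of A intensity inside the B mask
    M2: float  # fraction of B intensity inside the A mask
    threshold_a: float
    threshold_b: float
    threshold_method: str
    roi: tuple | None = None


def manders_coefficients(
    img_a: np.ndarray,
    img_b: np.ndarray,
    roi=None,
    thresholds: tuple[float, float] | None = None,
    background: tuple[float, float] = (0.0, 0.0),
) -> ColocResult:
    """Mander's overlap coefficients M1 (A-in-B) and M2 (B-in-A).

    Intensities are background-subtracted and floored at zero; the mask
    of the other channel uses fixed `thresholds` when given, otherwise
    per-channel Otsu within the ROI (the convention is recorded in the
    result).
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel images must share a shape")
    if roi is not None:
        a = a[roi]
        b = b[roi]
    a_eff = np.maximum(a - background[0], 0.0)
    b_eff = np.maximum(b - background[1], 0.0)
    if thresholds is None:
        t_a = float(threshold_otsu(a))
        t_b = float(threshold_otsu(b))
        method = "otsu"
    else:
        t_a, t_b = (float(t) for t in thresholds)
        method = "fixed"
    sum_a = a_eff.sum()
    sum_b = b_eff.sum()
    if sum_a == 0 or sum_b == 0:
        raise ValueError("Mander's coefficients undefined: a channel is empty")
    m1 = float(a_eff[b > t_b].sum() / sum_a)
    m2 = float(b_eff[a > t_a].sum() / sum_b)
    return ColocResult(
        M1=m1, M2=m2, threshold_a=t_a, threshold_b=t_b,
        threshold_method=method, roi=roi,
    )


# -- cluster time course --------------------------------------------------

def cluster_timecourse(
    series: ImageSeries,
    threshold_method="otsu",
    min_area: float = 0.0,
    unit_intensity: float | None = None,
    background: float = 0.0,
) -> pd.DataFrame:
    """Per-frame segmentation of bright clusters.

    Thresholds each frame (Otsu or a fixed value), labels 8-connected
    components, and tabulates centroid (μm), area (μm²) and integrated
    background-subtracted intensity; when `unit_intensity` is given, a
    rounded copy number (intensity / unit_intensity) is added.  An
    all-background frame contributes no rows (not an error).
    """
    if series.n_frames < 1:
        raise ValueError("need at least one frame")
    px = series.pixel_size
    rows = []
    for k in range(series.n_frames):
        img = series.frames[k]
        if threshold_method == "otsu":
            if img.max() <= img.min():
                continue
            thr = float(threshold_otsu(img))
        else:
            thr = float(threshold_method)
        mask = img > thr
        if not mask.any():
            continue
        labels = cc_label(mask, connectivity=2)
        for rp in regionprops(labels, intensity_image=img):
            area = rp.area * px**2
            if area < min_area:
                continue
            inten = float(rp.image_intensity[rp.image].sum()) - background * rp.area
            row = {
                "frame": k,
                "t": series.timestamps[k],
                "cluster_id": rp.label,
                "x": (rp.centroid[1] + 0.5) * px,
                "y": (rp.centroid[0] + 0.5) * px,
                "area_um2": area,
                "intensity": inten,
            }
            if unit_intensity is not None:
                row["copy_number"] = int(round(inten / unit_intensity))
            rows.append(row)
    cols = ["frame", "t", "cluster_id", "x", "y", "area_um2", "intensity"]
    if unit_intensity is not None:
        cols.append("copy_number")
    return pd.DataFrame(rows, columns=cols)


# -- mean-squared displacement --------------------------------------------

@dataclass
class MSDResult:
    lags: np.ndarray  # s
    msd: np.ndarray  # μm²
    alpha: float  # anomalous exponent (1 diffusive, 2 directed)
    D_fit: float  # μm²/s from the 2D intercept msd = 4 D τ^α
    n_tracks: int = 1


def msd_exponent(
    traj: TrajectorySet,
    max_lag_fraction: float = 0.25,
    min_track_length: int = 20,
) -> MSDResult:
    """Time-averaged in-plane MSD and anomalous exponent.

    Averages the time-averaged MSD over all tracks of length ≥ 20
    samples, then fits log MSD vs log τ; α ≈ 1 for Brownian motion and
    α → 2 for directed transport.  In-plane (x, y) displacements only.
    """
    groups = [g for _, g in traj.data.groupby("particle_id")
              if len(g) >= min_track_length]
    if not groups:
        raise ValueError(f"no track with at least {min_track_length} samples")
    n_min = min(len(g) for g in groups)
    max_lag = max(int(np.floor(n_min * max_lag_fraction)), 2)
    lags = np.arange(1, max_lag + 1)
    msd = np.zeros(len(lags))
    for g in groups:
        p = g[["x", "y"]].to_numpy()
        for i, lag in enumerate(lags):
            d = p[lag:] - p[:-lag]
            msd[i] += np.mean((d**2).sum(axis=1))
    msd /= len(groups)
    tau = lags * traj.frame_interval
    if np.all(msd < 1e-18):
        return MSDResult(lags=tau, msd=msd, alpha=np.nan, D_fit=0.0,
                         n_tracks=len(groups))
    coef = np.polyfit(np.log(tau), np.log(np.maximum(msd, 1e-300)), 1)
    alpha = float(coef[0])
    d_fit = float(np.exp(coef[1]) / 4.0)
    return MSDResult(lags=tau, msd=msd, alpha=alpha, D_fit=d_fit,
                     n_tracks=len(groups))
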