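"""Synthetic fluorescence image series generator.

Emulates the statistical structure of the confocal recordings every
quantification stage consumes: diffraction-limited labeled spots
spreading by 2D membrane diffusion, Gaussian bleach/recovery, a
peripheral extended-labeling band with slowly drifting bright clusters,
two-channel partially colocalized punctate images, and coalescing
cluster timelapses — all with Poisson shot noise, Gaussian read noise
and a Gaussian point-spread function.

Width convention: σ² always denotes per-axis Gaussian variance, which
grows as σ²(t) = σ0² + 2·D·t for free 2D diffusion (equivalently the
width² ≡ 2σ² bookkeeping grows as 4·D·t).  Gaussian ⊛ Gaussian is
evaluated analytically, so PSF convolution adds σ_psf² to the variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ImageSeries:
    """Calibrated fluorescence frame stack (photon counts).

    frames has shape (t, y, x); pixel_size in μm; frame_interval in s.
    ``time_offset`` is the elapsed time of the first frame relative to
    the event that defines t = 0 (end of the labeling pulse / bleach).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (t, y, x)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return self.time_offset + self.frame_interval * np.arange(self.n_frames)

    @property
    def shape(self):
        return self.frames.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) μm coordinate grids of pixel centers (0-based, y down)."""
        ny, nx = self.frames.shape[1:]
        x = (np.arange(nx) + 0.5) * self.pixel_size
        y = (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class PSFModel:
    """Gaussian PSF approximation, σ_psf in μm."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("σ_psf must be > 0")

    @classmethod
    def from_optics(cls, wavelength_nm: float = 488.0, na: float = 1.0) -> "PSFModel":
        """σ_psf = 0.21·λ/NA (standard Gaussian approximation)."""
        return cls(sigma=0.21 * wavelength_nm * 1e-3 / na)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise + zero-mean Gaussian read noise + background.

    ``background`` is expected counts per pixel (participates in shot
    noise); ``read_sd`` in counts.  ``shot_noise=False`` renders the
    noiseless expectation (used by oracle tests).
    """

    read_sd: float = 2.0
    background: float = 5.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.read_sd < 0 or self.background < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        expected = np.maximum(expected + self.background, 0.0)
        if self.shot_noise:
            out = rng.poisson(expected).astype(float)
        else:
            out = expected.astype(float)
        if self.read_sd > 0:
            out = out + self.read_sd * rng.standard_normal(size=out.shape)
        return np.maximum(out, 0.0)


QUIET = NoiseModel(read_sd=0.0, background=0.0, shot_noise=False)


@dataclass(frozen=True)
class SpotModel:
    """A labeled (sign +1) or bleached (sign −1) diffusing Gaussian spot.

    amplitude in counts at t = 0, sigma0 in μm (per-axis), center in μm,
    D in μm² s⁻¹.
    """

    amplitude: float
    sigma0: float
    center: tuple[float, float]
    D: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sigma0 <= 0:
            raise ValueError("amplitude and σ0 must be > 0")
        if self.D < 0:
            raise ValueError("D must be ≥ 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be ±1")

    def variance_at(self, t: float) -> float:
        return self.sigma0**2 + 2.0 * self.D * t

    def amplitude_at(self, t: float, psf_sigma: float = 0.0) -> float:
        """Peak amplitude of the PSF-convolved spot at elapsed time t."""
        return self.amplitude * self.sigma0**2 / (self.variance_at(t) + psf_sigma**2)


def _gaussian_frame(xx, yy, center, amplitude, variance):
    dx = xx - center[0]
    dy = yy - center[1]
    return amplitude * np.exp(-(dx**2 + dy**2) / (2.0 * variance))


def _grids(n_pixels, pixel_size):
    ny, nx = n_pixels if np.iterable(n_pixels) else (n_pixels, n_pixels)
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)


def generate_punctual_series(
    spot: SpotModel,
    psf: PSFModel,
    noise: NoiseModel,
    pixel_size: float = 0.1,
    frame_interval: float = 0.13,
    n_frames: int = 30,
    n_pixels: int = 96,
    seed: int = 0,
    time_offset: float | None = None,
) -> ImageSeries:
    """Punctual-labeling series: a spot deposited in one frame spreads.

    Noiseless frame at elapsed time t is a 2D Gaussian of per-axis
    variance σ0² + 2Dt and peak A0·σ0²/(σ0² + 2Dt), convolved with the
    PSF (variance + σ_psf²); the spatial integral is conserved.  The
    first frame is recorded half a frame after the pulse ends by
    default.
    """
    if time_offset is None:
        time_offset = 0.5 * frame_interval
    rng = np.random.default_rng(seed)
    xx, yy = _grids(n_pixels, pixel_size)
    t_end = time_offset + frame_interval * (n_frames - 1)
    sig_end = np.sqrt(spot.variance_at(t_end) + psf.sigma**2)
    for c, extent in zip(spot.center, (xx.max(), yy.max())):
        if c - 3 * sig_end < 0 or c + 3 * sig_end > extent:
            raise ValueError("spot spreads off the field of view")
    frames = np.empty((n_frames, *xx.shape))
    for k in range(n_frames):
        t = time_offset + k * frame_interval
        frames[k] = noise.apply(
            noiseless_punctual_frame(spot, psf, xx, yy, t), rng
        )
    return ImageSeries(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel="punctual",
        time_offset=time_offset,
    )


def noiseless_punctual_frame(
    spot: SpotModel, psf: PSFModel, xx, yy, t: float
) -> np.ndarray:
    """Analytic noiseless frame (shared by generator and oracle tests)."""
    var = spot.variance_at(t) + psf.sigma**2
    amp = spot.amplitude * spot.sigma0**2 / var
    return _gaussian_frame(xx, yy, spot.center, amp, var)


def generate_frap_series(
    prebleach_level: float,
    bleach: SpotModel,
    psf: PSFModel,
    noise: NoiseModel,
    pixel_size: float = 0.1,
    frame_interval: float = 0.13,
    n_frames: int = 30,
    n_prebleach: int = 5,
    n_pixels: int = 96,
    seed: int = 0,
    time_offset: float | None = None,
) -> ImageSeries:
    """Bleach-recovery series: uniform plateau minus a diffusing hole.

    The hole evolves exactly like the punctual spot with inverted sign,
    so recovery at the hole center follows the same closed form.  The
    first `n_prebleach` frames show the undisturbed plateau.
    """
    if bleach.amplitude > prebleach_level:
        raise ValueError("bleach depth exceeds prebleach level")
    if bleach.sign != -1:
        bleach = replace(bleach, sign=-1)
    if time_offset is None:
        time_offset = 0.5 * frame_interval
    rng = np.random.default_rng(seed)
    xx, yy = _grids(n_pixels, pixel_size)
    frames = np.empty((n_prebleach + n_frames, *xx.shape))
    for k in range(n_prebleach):
        frames[k] = noise.apply(np.full(xx.shape, prebleach_level), rng)
    for k in range(n_frames):
        t = time_offset + k * frame_interval
        hole = noiseless_punctual_frame(replace(bleach, sign=1), psf, xx, yy, t)
        frames[n_prebleach + k] = noise.apply(
            np.maximum(prebleach_level - hole, 0.0), rng
        )
    return ImageSeries(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel="frap",
        time_offset=time_offset - n_prebleach * frame_interval,
    )


# -- extended labeling ----------------------------------------------------

@dataclass(frozen=True)
class DriftingCluster:
    """Bright cluster translating at constant speed along a direction."""

    position: tuple[float, float]  # μm at t = 0
    speed: float  # μm/s (≥ 0)
    direction: tuple[float, float] = (1.0, 0.0)
    amplitude: float = 100.0
    sigma: float = 0.25  # μm

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("cluster speed must be ≥ 0")

    def center_at(self, t: float) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        d /= max(np.linalg.norm(d), 1e-300)
        return np.asarray(self.position) + self.speed * t * d


@dataclass(frozen=True)
class LabelingBand:
    """Static labeled band: Gaussian cross-section around a horizontal line."""

    y_center: float  # μm
    sigma: float  # μm, cross-section width
    intensity: float  # counts at band center


def generate_extended_series(
    band: LabelingBand,
    clusters: list[DriftingCluster],
    psf: PSFModel,
    noise: NoiseModel,
    pixel_size: float = 0.1,
    frame_interval: float = 5.0,
    n_frames: int = 190,
    n_pixels=(40, 128),
    seed: int = 0,
) -> ImageSeries:
    """Extended peripheral labeling: static band plus drifting clusters.

    Default duration ≥ 900 s (190 frames × 5 s) to cover the slow
    (~nm/s) cluster drift the kymograph analysis targets.
    """
    rng = np.random.default_rng(seed)
    xx, yy = _grids(n_pixels, pixel_size)
    band_img = band.intensity * np.exp(
        -((yy - band.y_center) ** 2) / (2.0 * (band.sigma**2 + psf.sigma**2))
    )
    frames = np.empty((n_frames, *xx.shape))
    clipped = 0
    for k in range(n_frames):
        t = k * frame_interval
        img = band_img.copy()
        for cl in clusters:
            c = cl.center_at(t)
            if not (0 <= c[0] <= xx.max() and 0 <= c[1] <= yy.max()):
                clipped += 1
                continue
            img += _gaussian_frame(
                xx, yy, c, cl.amplitude, cl.sigma**2 + psf.sigma**2
            )
        frames[k] = noise.apply(img, rng)
    if clipped:
        warnings.warn(f"{clipped} cluster renderings clipped at the field edge")
    return ImageSeries(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel="extended",
    )


def render_trajectory_frames(
    trajectories,
    pixel_size: float = 0.15,
    n_pixels: int = 128,
    origin=(0.0, 0.0),
    amplitude: float = 150.0,
    sigma: float = 0.2,
    noise: NoiseModel = QUIET,
    seed: int = 0,
) -> ImageSeries:
    """Render particle trajectories as a widefield-style frame stack.

    Each particle contributes an in-plane Gaussian spot at its (x, y)
    position per time sample (the axial coordinate is projected out, as
    in high-speed interferometric tracking).  ``origin`` is the μm
    coordinate of the image's lower-left corner in the trajectory frame.
    """
    rng = np.random.default_rng(seed)
    xx, yy = _grids(n_pixels, pixel_size)
    times = np.sort(trajectories.data["t"].unique())
    ox, oy = origin
    extent_x, extent_y = xx.max(), yy.max()
    frames = np.empty((len(times), *xx.shape))
    for k, t in enumerate(times):
        sub = trajectories.data[trajectories.data["t"] == t]
        img = np.zeros_like(xx)
        for cx, cy in sub[["x", "y"]].to_numpy():
            cx, cy = cx - ox, cy - oy
            if -1.0 < cx < extent_x + 1.0 and -1.0 < cy < extent_y + 1.0:
                img += _gaussian_frame(xx, yy, (cx, cy), amplitude, sigma**2)
        frames[k] = noise.apply(img, rng)
    return ImageSeries(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=trajectories.frame_interval,
        channel="tracking",
    )


# -- two-channel colocalization -------------------------------------------

@dataclass
class ColocDesign:
    """Placement solving for target Mander's overlap fractions.

    Spots are punctate Gaussians on a jittered grid; sites are common
    (both channels), A-only or B-only.  The amplitudes of the A-only
    (resp. B-only) spots are solved so that the fraction of A intensity
    inside the thresholded B mask equals M1 (and symmetrically M2) under
    the stated measurement convention.
    """

    target_m1: float
    target_m2: float
    n_common: int = 24
    n_a_only: int = 10
    n_b_only: int = 14
    spot_sigma: float = 0.15  # μm, pre-PSF
    amplitude: float = 300.0
    threshold: float = 30.0  # counts, fixed absolute threshold convention
    background_subtraction: float = 0.0  # set from the noise model when rendering
    a_only_amplitude: float = field(default=None)  # solved
    b_only_amplitude: float = field(default=None)  # solved

    def __post_init__(self) -> None:
        for m in (self.target_m1, self.target_m2):
            if not 0.0 <= m <= 1.0:
                raise ValueError("designed fractions must lie in [0, 1]")
        if self.target_m1 == 1.0 and (self.n_a_only or not self.n_common):
            raise ValueError("infeasible design: M1 = 1 needs every A spot in B")
        if self.target_m2 == 1.0 and (self.n_b_only or not self.n_common):
            raise ValueError("infeasible design: M2 = 1 needs every B spot in A")


def _site_layout(design: ColocDesign, fov: float, rng: np.random.Generator):
    n_sites = design.n_common + design.n_a_only + design.n_b_only
    grid = int(np.ceil(np.sqrt(n_sites)))
    pitch = fov / (grid + 1)
    pts = []
    for i in range(grid):
        for j in range(grid):
            pts.append([(i + 1) * pitch, (j + 1) * pitch])
    pts = np.asarray(pts)
    rng.shuffle(pts)
    pts = pts[:n_sites] + rng.uniform(-0.15, 0.15, size=(n_sites, 2)) * pitch
    return (
        pts[: design.n_common],
        pts[design.n_common : design.n_common + design.n_a_only],
        pts[design.n_common + design.n_a_only :],
    )


def generate_two_channel(
    design: ColocDesign,
    psf: PSFModel,
    noise: NoiseModel,
    pixel_size: float = 0.1,
    n_pixels: int = 128,
    seed: int = 0,
) -> tuple[ImageSeries, ImageSeries]:
    """Render a partially colocalized two-channel image pair.

    The A-only and B-only amplitudes are solved on the noiseless render
    so the measured Mander's coefficients (fixed-threshold convention,
    background-subtracted, floored at zero) equal the designed fractions
    by construction; the solved amplitudes are stored on the design.
    """
    rng = np.random.default_rng(seed)
    xx, yy = _grids(n_pixels, pixel_size)
    common, a_only, b_only = _site_layout(design, xx.max(), rng)
    var = design.spot_sigma**2 + psf.sigma**2
    b_sub = design.background_subtraction

    def render(sites_amp):
        img = np.zeros_like(xx)
        for (cx, cy), amp in sites_amp:
            img += _gaussian_frame(xx, yy, (cx, cy), amp, var)
        return img

    amp = design.amplitude
    a_out_amp = amp * 0.8
    b_out_amp = amp * 0.8
    solver_rng = np.random.default_rng(rng.integers(2**31))

    def measure(img_x, img_y):
        x_eff = np.maximum(img_x - b_sub, 0.0)
        mask_y = img_y > design.threshold
        s_in = x_eff[mask_y].sum()
        s_out = x_eff[~mask_y].sum()
        return s_in, s_out

    # fixed-point solve for the outside-spot amplitudes: first on the
    # noiseless render, then against noisy renders so the systematic
    # effect of shot noise, flooring and mask-edge flips is absorbed
    for it in range(8):
        img_a = render([(tuple(p), amp) for p in common] +
                       [(tuple(p), a_out_amp) for p in a_only])
        img_b = render([(tuple(p), amp) for p in common] +
                       [(tuple(p), b_out_amp) for p in b_only])
        if it >= 4:
            img_a = noise.apply(img_a, solver_rng)
            img_b = noise.apply(img_b, solver_rng)
        s_in_a, s_out_a = measure(img_a, img_b)
        s_in_b, s_out_b = measure(img_b, img_a)
        if design.target_m1 > 0 and s_out_a > 0:
            want_out_a = s_in_a * (1.0 - design.target_m1) / design.target_m1
            a_out_amp *= (want_out_a / s_out_a) ** (0.7 if it >= 4 else 1.0)
        if design.target_m2 > 0 and s_out_b > 0:
            want_out_b = s_in_b * (1.0 - design.target_m2) / design.target_m2
            b_out_amp *= (want_out_b / s_out_b) ** (0.7 if it >= 4 else 1.0)
    design.a_only_amplitude = float(a_out_amp)
    design.b_only_amplitude = float(b_out_amp)
    img_a = render([(tuple(p), amp) for p in common] +
                   [(tuple(p), a_out_amp) for p in a_only])
    img_b = render([(tuple(p), amp) for p in common] +
                   [(tuple(p), b_out_amp) for p in b_only])
    series_a = ImageSeries(
        frames=noise.apply(img_a, rng)[None, :, :],
        pixel_size=pixel_size,
        frame_interval=1.0,
        channel="A",
    )
    series_b = ImageSeries(
        frames=noise.apply(img_b, rng)[None, :, :],
        pixel_size=pixel_size,
        frame_interval=1.0,
        channel="B",
    )
    return series_a, series_b


# -- coalescing cluster timelapse ----------------------------------------

@dataclass
class ClusterState:
    positions: np.ndarray  # (K, 2) μm
    intensities: np.ndarray  # integrated counts per cluster
    sigmas: np.ndarray  # μm (area ∝ σ²)


def generate_cluster_timelapse(
    n0: int = 40,
    D_cluster: float = 0.01,
    coalescence_radius: float = 0.4,
    field_size: float = 15.0,
    duration: float = 300.0,
    frame_interval: float = 5.0,
    psf: PSFModel | None = None,
    noise: NoiseModel = QUIET,
    pixel_size: float = 0.15,
    seed: int = 0,
    initial_intensity: float = 2000.0,
    initial_sigma: float = 0.2,
    return_truth: bool = False,
):
    """Coalescing membrane clusters in a square region (default 15×15 μm²).

    Clusters perform 2D Brownian motion with reflecting boundaries; any
    pair closer than `coalescence_radius` merges, summing integrated
    intensity and area (σ² adds), so the count is non-increasing and the
    total intensity conserved.
    """
    if n0 < 2:
        raise ValueError("need at least two clusters")
    if psf is None:
        psf = PSFModel.from_optics()
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval)) + 1
    n_px = int(round(field_size / pixel_size))
    xx, yy = _grids(n_px, pixel_size)
    pos = rng.uniform(0.0, field_size, size=(n0, 2))
    inten = np.full(n0, initial_intensity)
    sig = np.full(n0, initial_sigma)
    step_sd = np.sqrt(2.0 * D_cluster * frame_interval)
    frames = np.empty((n_frames, n_px, n_px))
    truth = []

    def render():
        img = np.zeros_like(xx)
        for p, a, s in zip(pos, inten, sig):
            v = s**2 + psf.sigma**2
            img += _gaussian_frame(xx, yy, p, a / (2 * np.pi * v) * pixel_size**2, v)
        return img

    for k in range(n_frames):
        if k > 0:
            pos = pos + step_sd * rng.standard_normal(size=pos.shape)
            pos = np.abs(pos)
            pos = field_size - np.abs(field_size - pos)
            if coalescence_radius > 0:
                merged = True
                while merged and len(pos) > 1:
                    merged = False
                    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
                    np.fill_diagonal(d, np.inf)
                    i, j = np.unravel_index(np.argmin(d), d.shape)
                    if d[i, j] < coalescence_radius:
                        w = inten[[i, j]] / inten[[i, j]].sum()
                        pos[i] = w @ pos[[i, j]]
                        inten[i] += inten[j]
                        sig[i] = np.sqrt(sig[i] ** 2 + sig[j] ** 2)
                        keep = np.ones(len(pos), dtype=bool)
                        keep[j] = False
                        pos, inten, sig = pos[keep], inten[keep], sig[keep]
                        merged = True
        frames[k] = noise.apply(render(), rng)
        truth.append(
            ClusterState(pos.copy(), inten.copy(), sig.copy())
        )
    series = ImageSeries(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel="clusters",
    )
    if return_truth:
        return series, truth
    return series
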