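"""Diffusion-coefficient estimation from punctual labeling and FRAP.

Both measurement modalities reduce to the same inference problem: a
Gaussian intensity feature (a deposited label spot, or a bleached hole
with inverted sign) whose per-axis variance grows linearly in time,
σ²(t) = σ0² + 2·D·t.  Each frame is fitted with a symmetric 2D Gaussian
plus constant background; the diffusion coefficient is then the slope
of a weighted linear regression of fitted variance against elapsed
time, divided by two (``punctual_width``), or alternatively from the
hyperbolic decay of the fitted peak amplitude (``punctual_amplitude``).
Using one estimator for both modalities makes their agreement testable
by construction; the method used is recorded in every fit.

Exposed in a statsmodels-like shape: ``PunctualDiffusionModel(series)``
/ ``FrapDiffusionModel(series)`` are built from data and ``.fit()``
returns a :class:`DiffusionResults` with the estimate, its standard
error, per-frame diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging import ImageSeries

VALID_METHODS = ("punctual_width", "punctual_amplitude", "frap_recovery")


class FitError(RuntimeError):
    pass


def _gauss2d(coords, amplitude, cx, cy, variance, background):
    x, y = coords
    # |variance| keeps the model defined (with gradient) when the
    # optimizer steps through zero; fits report variance > 0 or fail
    arg = ((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * max(abs(variance), 1e-12))
    return amplitude * np.exp(-np.clip(arg, 0.0, 700.0)) + background


def fit_gaussian_frames(series: ImageSeries, roi=None) -> pd.DataFrame:
    """Per-frame weighted 2D-Gaussian + background fits.

    roi is a (y_slice, x_slice) pair or None for the full frame.
    Returns a table with per-frame amplitude, center, per-axis variance,
    background, their standard errors, and an ``ok`` flag; aborts if
    more than half the frames fail to converge.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames")
    ys = roi[0] if roi is not None else slice(None)
    xs = roi[1] if roi is not None else slice(None)
    xx, yy = series.pixel_centers()
    xx, yy = xx[ys, xs], yy[ys, xs]
    if xx.size == 0:
        raise ValueError("roi outside frame bounds")
    rows = []
    for k in range(series.n_frames):
        img = series.frames[k][ys, xs]
        rows.append(_fit_one(img, xx, yy, k, series.timestamps[k]))
    table = pd.DataFrame(rows)
    # flat frames (feature below the noise floor) are flagged but are not
    # convergence failures; only the latter abort the analysis
    if (table["status"] == "failed").mean() > 0.5:
        raise FitError("Gaussian fit failed to converge on more than half the frames")
    return table


def _fit_one(img, xx, yy, k, t):
    bg0 = float(np.median(img))
    resid = img - bg0
    # robust noise scale; moments restricted to significant pixels so a
    # noise pedestal over the full field cannot corrupt the initializer
    noise_sd = 1.4826 * float(np.median(np.abs(resid))) + 1e-12
    mask = resid > 4.0 * noise_sd
    flat = {"frame": k, "t": t, "amplitude": 0.0, "cx": np.nan, "cy": np.nan,
            "variance": np.nan, "background": bg0, "amplitude_err": np.nan,
            "variance_err": np.nan, "ok": False, "status": "flat"}
    if mask.sum() < 4:
        return flat  # flat frame: amplitude ≈ 0, variance unconstrained
    sub = np.where(mask, resid, 0.0)
    total = sub.sum()
    cx0 = float((sub * xx).sum() / total)
    cy0 = float((sub * yy).sum() / total)
    var0 = float(
        (sub * ((xx - cx0) ** 2 + (yy - cy0) ** 2)).sum() / (2.0 * total)
    )
    var0 = max(var0, (xx[0, 1] - xx[0, 0]) ** 2)
    p0 = [float(resid.max()), cx0, cy0, var0, bg0]
    coords = (xx.ravel(), yy.ravel())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss2d, coords, img.ravel(), p0=p0, maxfev=8000
            )
            # reweight from the fitted model (not the data) so shot-noise
            # weighting does not bias the width estimate
            sigma = np.sqrt(np.maximum(_gauss2d(coords, *popt), 1.0))
            popt, pcov = optimize.curve_fit(
                _gauss2d,
                coords,
                img.ravel(),
                p0=popt,
                sigma=sigma,
                absolute_sigma=True,
                maxfev=8000,
            )
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(popt)) or popt[3] <= 0:
            return {**flat, "status": "failed"}
        return {
            "frame": k,
            "t": t,
            "amplitude": popt[0],
            "cx": popt[1],
            "cy": popt[2],
            "variance": popt[3],
            "background": popt[4],
            "amplitude_err": perr[0],
            "variance_err": perr[3],
            "ok": True,
            "status": "converged",
        }
    except RuntimeError:
        return {**flat, "status": "failed"}


@dataclass
class DiffusionResults:
    """Result of a diffusion fit: D̂ ± SE plus per-frame diagnostics."""

    D_hat: float  # μm²/s
    stderr: float  # μm²/s
    method: str
    frame_table: pd.DataFrame = field(repr=False)
    frames_used: int = 0
    residuals: np.ndarray = field(repr=False, default=None)
    flags: list = field(default_factory=list)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        dof = max(self.frames_used - 2, 1)
        q = stats.t.ppf(1 - alpha / 2, dof)
        return self.D_hat - q * self.stderr, self.D_hat + q * self.stderr

    def plot(self, ax=None):
        """Fitted per-frame variance vs time with the regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        good = self.frame_table[self.frame_table["ok"]]
        ax.errorbar(good["t"], good["variance"], yerr=good["variance_err"],
                    fmt="o", ms=4, label="per-frame fits")
        t = np.linspace(good["t"].min(), good["t"].max(), 50)
        v0 = good["variance"].iloc[0] - 2 * self.D_hat * good["t"].iloc[0]
        ax.plot(t, v0 + 2 * self.D_hat * t, "-",
                label=f"D̂ = {self.D_hat:.3g} μm²/s")
        ax.set_xlabel("time since pulse end (s)")
        ax.set_ylabel("per-axis variance (μm²)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Diffusion fit",
            "=" * 40,
            f"method:        {self.method}",
            f"D_hat:         {self.D_hat:.4g} μm²/s",
            f"stderr:        {self.stderr:.3g} μm²/s",
            f"95% CI:        [{lo:.4g}, {hi:.4g}]",
            f"frames used:   {self.frames_used}",
        ]
        if self.flags:
            lines.append("flags:         " + "; ".join(self.flags))
        return "\n".join(lines)


class PunctualDiffusionModel:
    """Diffusion model for a punctual-labeling decay series.

    Parameters
    ----------
    series : ImageSeries
        Frames recorded after the labeling pulse ended (the series'
        ``time_offset`` carries the half-frame correction).
    roi : (slice, slice), optional
        Region containing the spot.
    """

    inverted = False

    def __init__(self, series: ImageSeries, roi=None):
        self.series = series
        self.roi = roi
        self.frame_table: pd.DataFrame | None = None

    def _prepare_table(self) -> pd.DataFrame:
        series = self.series
        if self.inverted:
            series = self._invert(series)
        self.frame_table = fit_gaussian_frames(series, roi=self.roi)
        return self.frame_table

    def _invert(self, series):  # overridden by the FRAP subclass
        return series

    def fit(self, method: str = "punctual_width") -> DiffusionResults:
        if method not in ("punctual_width", "punctual_amplitude"):
            raise ValueError(f"unknown method {method!r}")
        table = self._prepare_table()
        good = table[table["ok"]]
        if len(good) < 3:
            raise FitError("fewer than 3 usable frames")
        t = good["t"].to_numpy()
        flags = []
        if method == "punctual_width":
            v = good["variance"].to_numpy()
            verr = good["variance_err"].to_numpy()
            w = 1.0 / np.maximum(verr, 1e-12) ** 2
            slope, slope_se, resid = _wls_line(t, v, w)
            d_hat = slope / 2.0
            d_se = slope_se / 2.0
            if d_hat < 0:
                flags.append("variance series non-increasing; D̂ clipped to 0")
                warnings.warn("no spreading detected: D̂ = 0")
                d_hat = 0.0
        else:
            a = good["amplitude"].to_numpy()
            aerr = np.maximum(good["amplitude_err"].to_numpy(), 1e-12)
            # hyperbolic amplitude decay referenced to the first usable
            # frame, whose fitted variance provides σ0² + σ_psf²
            s0sq = good["variance"].iloc[0]
            t_rel = t - t[0]

            def model(tt, a0, d):
                return a0 * s0sq / (s0sq + 2.0 * d * tt)

            popt, pcov = optimize.curve_fit(
                model, t_rel, a, p0=[a[0], 0.05], sigma=aerr,
                absolute_sigma=True, maxfev=4000,
            )
            d_hat = float(popt[1])
            d_se = float(np.sqrt(pcov[1, 1]))
            resid = a - model(t_rel, *popt)
            if d_hat < 0:
                flags.append("amplitude non-decaying; D̂ clipped to 0")
                d_hat = 0.0
        method_name = self._result_method(method)
        return DiffusionResults(
            D_hat=float(d_hat),
            stderr=float(d_se),
            method=method_name,
            frame_table=table,
            frames_used=int(len(good)),
            residuals=resid,
            flags=flags,
        )

    def _result_method(self, method: str) -> str:
        return method


class FrapDiffusionModel(PunctualDiffusionModel):
    """Diffusion model for a bleach-recovery series.

    The prebleach plateau (first ``n_prebleach`` frames) is averaged and
    the evolving hole (plateau − frame) is fitted exactly like the
    punctual spot; the recovery of the hole center follows the same
    closed form with inverted sign.
    """

    inverted = True

    def __init__(self, series: ImageSeries, roi=None, n_prebleach: int = 5):
        super().__init__(series, roi=roi)
        if n_prebleach < 1:
            raise ValueError("need at least one prebleach frame")
        if n_prebleach >= series.n_frames - 2:
            raise ValueError("too few post-bleach frames")
        self.n_prebleach = n_prebleach

    def _invert(self, series: ImageSeries) -> ImageSeries:
        plateau = series.frames[: self.n_prebleach].mean(axis=0)
        post = series.frames[self.n_prebleach :]
        hole = plateau[None, :, :] - post
        noise_sd = float(series.frames[: self.n_prebleach].std())
        # the plateau subtraction inflates the noise by (1 + 1/n_pre)^0.5
        hole_sd = noise_sd * np.sqrt(1.0 + 1.0 / self.n_prebleach)
        if hole.max() < 5.0 * max(hole_sd, 1e-12):
            raise FitError("no detectable bleach hole")
        # shift so the noise floor is not clipped: the fitted constant
        # background absorbs the pedestal
        pedestal = 6.0 * noise_sd - min(hole.min(), 0.0)
        t0 = series.timestamps[self.n_prebleach]
        return ImageSeries(
            frames=np.maximum(hole + pedestal, 0.0),
            pixel_size=series.pixel_size,
            frame_interval=series.frame_interval,
            channel=series.channel,
            time_offset=t0,
        )

    def fit(self, method: str = "punctual_width") -> DiffusionResults:
        res = super().fit(method=method)
        table = res.frame_table
        good = table[table["ok"]]
        if len(good) >= 2:
            a = good["amplitude"].to_numpy()
            if a[0] < 3.0 * good["amplitude_err"].iloc[0]:
                res.flags.append(
                    "hole filled within the first interval: D̂ is a lower bound"
                )
        return res

    def _result_method(self, method: str) -> str:
        return "frap_recovery"


def estimate_diffusivity_punctual(
    series: ImageSeries, roi=None, method: str = "punctual_width"
) -> DiffusionResults:
    """Functional wrapper around :class:`PunctualDiffusionModel`."""
    return PunctualDiffusionModel(series, roi=roi).fit(method=method)


def estimate_diffusivity_frap(
    series: ImageSeries, roi=None, n_prebleach: int = 5
) -> DiffusionResults:
    """Functional wrapper around :class:`FrapDiffusionModel`."""
    return FrapDiffusionModel(series, roi=roi, n_prebleach=n_prebleach).fit()


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns (slope, slope SE, residuals)."""
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    slope_se = np.sqrt(s2 / sxx)
    return slope, slope_se, resid


@dataclass
class EnsembleStats:
    """Sample mean ± sd of replicate diffusion fits."""

    n: int
    mean_D: float
    sd_D: float
    method: str = ""


def ensemble_stats(fits: list[DiffusionResults]) -> EnsembleStats:
    """Mean and sample standard deviation over replicate fits.

    Mirrors the reporting convention of replicate measurements as
    sample mean ± sd; warns when methods are mixed in one ensemble.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits for ensemble statistics")
    methods = {f.method for f in fits}
    if len(methods) > 1:
        warnings.warn(f"mixed methods in one ensemble: {sorted(methods)}")
    d = np.array([f.D_hat for f in fits])
    return EnsembleStats(
        n=len(fits),
        mean_D=float(d.mean()),
        sd_D=float(d.std(ddof=1)),
        method=",".join(sorted(methods)),
    )
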