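"""Brownian-advective tracer simulation in the envelope flow.

Overdamped point particles follow the analytic flow field with additive
Brownian noise (Euler–Maruyama): x ← x + v(x)·dt + √(2D·dt)·ξ.  Inertia
is neglected (Re ≪ 1) and there are no hydrodynamic wall corrections.
Used to build velocimetry fixtures (high-speed tracking of 80 nm gold
probes) and to simulate bead deposition strokes on the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import FlowField, build_field
from .geometry import DeviceGeometry, FlowConfig
from .units import UM2_PER_S_TO_M2_PER_S

#: default step, s — matches a 10 kHz localization cadence
DEFAULT_DT = 1.0e-5


@dataclass
class TrajectorySet:
    """Per-particle ordered (t, x, y, z) samples in μm.

    Backed by a long-format DataFrame with columns
    ``particle_id, t, x, y, z``; all particles share one frame interval.
    """

    data: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        for pid, grp in self.data.groupby("particle_id"):
            if not np.all(np.diff(grp["t"].to_numpy()) > 0):
                raise ValueError(f"non-increasing timestamps for particle {pid}")

    @property
    def particle_ids(self) -> np.ndarray:
        return self.data["particle_id"].unique()

    def positions(self, pid) -> np.ndarray:
        grp = self.data[self.data["particle_id"] == pid]
        return grp[["x", "y", "z"]].to_numpy()

    def steps(self) -> pd.DataFrame:
        """Frame-to-frame displacement steps with midpoint coordinates.

        Columns: particle_id, t, x, y, z (midpoints), vx, vy, vz (μm/s).
        """
        rows = []
        for pid, grp in self.data.groupby("particle_id"):
            p = grp[["x", "y", "z"]].to_numpy()
            t = grp["t"].to_numpy()
            if len(p) < 2:
                continue
            dp = np.diff(p, axis=0)
            dt = np.diff(t)[:, None]
            mid = 0.5 * (p[1:] + p[:-1])
            v = dp / dt
            df = pd.DataFrame(
                {
                    "particle_id": pid,
                    "t": 0.5 * (t[1:] + t[:-1]),
                    "x": mid[:, 0],
                    "y": mid[:, 1],
                    "z": mid[:, 2],
                    "vx": v[:, 0],
                    "vy": v[:, 1],
                    "vz": v[:, 2],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# frame_interval={self.frame_interval!r}\n")
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# frame_interval="):
                raise ValueError("missing frame_interval header in trajectory CSV")
            interval = float(header.split("=", 1)[1])
            data = pd.read_csv(fh)
        return cls(data=data, frame_interval=interval)


def _seed_positions(
    fld: FlowField, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic seeds on the injection-opening sphere."""
    r = 0.5 * fld.geometry.aperture_inner_diameter_inj
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = fld.geometry.injection_position[None, :] + r * u
    if fld.geometry.substrate_present:
        pts[:, 2] = np.abs(pts[:, 2])
    return pts


def _check_dt(fld: FlowField, dt: float) -> None:
    """Reject dt if the advective step at the seeding radius is too long."""
    r_in = 0.5 * fld.geometry.aperture_inner_diameter_inj
    probe = fld.geometry.injection_position + np.array([0.0, 0.0, r_in])
    vmax = np.linalg.norm(fld.velocity(probe))
    if vmax * dt > 0.5 * r_in:
        raise ValueError(
            f"dt={dt:g} s too coarse: advective step {vmax * dt:.3g} μm exceeds "
            f"half the aperture radius ({0.5 * r_in:g} μm)"
        )


def simulate_tracers(
    n: int,
    fld: FlowField,
    D: float,
    dt: float = DEFAULT_DT,
    duration: float = 0.1,
    seed: int = 0,
) -> TrajectorySet:
    """Simulate `n` tracers released at the injection opening.

    D in m² s⁻¹ (SI, as produced by the Stokes–Einstein relation).
    Particles are absorbed at the aspiration capture radius; with a
    substrate they reflect specularly at z = 0.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_dt(fld, dt)
    rng = np.random.default_rng(seed)
    d_um = D / UM2_PER_S_TO_M2_PER_S  # μm²/s
    sigma = np.sqrt(2.0 * d_um * dt)
    n_steps = int(round(duration / dt))
    pos = _seed_positions(fld, n, rng)
    sink = fld.geometry.aspiration_position
    cap = fld.capture_radius
    has_sink = fld.config.Q_asp > 0
    active = np.ones(n, dtype=bool)
    traj = np.full((n, n_steps + 1, 3), np.nan)
    traj[:, 0] = pos
    last = np.zeros(n, dtype=int)
    for k in range(n_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        p = pos[idx]
        v = fld.velocity(p)
        p = p + v * dt
        if sigma > 0:
            p = p + sigma * rng.standard_normal(size=p.shape)
        if fld.geometry.substrate_present:
            below = p[:, 2] < 0
            p[below, 2] *= -1.0
        pos[idx] = p
        traj[idx, k + 1] = p
        last[idx] = k + 1
        if has_sink:
            captured = np.linalg.norm(p - sink[None, :], axis=1) < cap
            active[idx[captured]] = False
        escaped = np.linalg.norm(p, axis=1) > fld.r_max
        active[idx[escaped]] = False
    frames = []
    for i in range(n):
        m = last[i] + 1
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": i,
                    "t": dt * np.arange(m),
                    "x": traj[i, :m, 0],
                    "y": traj[i, :m, 1],
                    "z": traj[i, :m, 2],
                }
            )
        )
    return TrajectorySet(data=pd.concat(frames, ignore_index=True), frame_interval=dt)


# -- deposition -----------------------------------------------------------

@dataclass
class TipPath:
    """Straight-segment tip path traversed at constant speed."""

    waypoints: np.ndarray  # (K, 2) in-plane μm displacements of the device
    speed: float  # μm/s

    def __post_init__(self) -> None:
        self.waypoints = np.atleast_2d(np.asarray(self.waypoints, dtype=float))
        seg = np.diff(self.waypoints, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        self._cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    @property
    def total_time(self) -> float:
        if self.speed == 0:
            return 0.0
        return self._cum[-1] / self.speed

    def offset(self, t) -> np.ndarray:
        """In-plane device displacement at time(s) t, shape (..., 2)."""
        t = np.asarray(t, dtype=float)
        s = np.clip(t * self.speed, 0.0, self._cum[-1])
        k = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0,
                    len(self._cum) - 2)
        seg = self.waypoints[k + 1] - self.waypoints[k]
        seg_len = np.maximum(np.linalg.norm(seg, axis=-1, keepdims=True), 1e-300)
        frac = ((s - self._cum[k]) / seg_len[..., 0])[..., None]
        return self.waypoints[k] + frac * seg


@dataclass
class DepositionResult:
    positions: np.ndarray  # (M, 2) adsorbed (x, y) on z=0, μm
    arrival_times: np.ndarray  # (M,) s
    tip_path: TipPath
    n_released: int = 0
    n_captured: int = 0

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "t_arrival": self.arrival_times,
            }
        ).to_csv(path, index=False)


def simulate_deposition(
    geometry: DeviceGeometry,
    config: FlowConfig,
    n: int,
    D: float,
    sticking_probability: float = 1.0,
    tip_path: TipPath | None = None,
    dt: float = 2.0e-5,
    seed: int = 0,
    particle_radius: float = 0.1,
    max_transit_steps: int = 40000,
) -> DepositionResult:
    """Deposit particles on the substrate while the device translates.

    Particles are released continuously from the injection opening over
    the traversal of `tip_path`; a particle whose height drops below the
    particle radius contacts the substrate and adsorbs with
    `sticking_probability` per contact, otherwise it is reflected
    specularly.  The quasi-static approximation evaluates the device
    field at the instantaneous tip offset.
    """
    if not geometry.substrate_present:
        raise ValueError("deposition requires substrate_present geometry")
    if not 0.0 <= sticking_probability <= 1.0:
        raise ValueError("sticking_probability must lie in [0, 1]")
    if tip_path is None:
        tip_path = TipPath(waypoints=np.zeros((1, 2)), speed=0.0)
    fld = build_field(geometry, config)
    if np.any(np.abs(tip_path.waypoints) > fld.r_max):
        raise ValueError("tip path leaves the simulation box")
    _check_dt(fld, dt)
    rng = np.random.default_rng(seed)
    d_um = D / UM2_PER_S_TO_M2_PER_S
    sigma = np.sqrt(2.0 * d_um * dt)
    horizon = max(tip_path.total_time, dt)
    release_t = np.sort(rng.uniform(0.0, horizon, size=n))
    seeds_local = _seed_positions(fld, n, rng)  # device frame
    pos = seeds_local.copy()
    off0 = tip_path.offset(release_t)
    pos[:, 0] += off0[:, 0]
    pos[:, 1] += off0[:, 1]
    sink_local = fld.geometry.aspiration_position
    cap = fld.capture_radius
    deposited = []
    arrivals = []
    active = np.ones(n, dtype=bool)
    n_captured = 0
    for k in range(max_transit_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        t_now = release_t[idx] + k * dt
        off = tip_path.offset(t_now)
        local = pos[idx].copy()
        local[:, 0] -= off[:, 0]
        local[:, 1] -= off[:, 1]
        v = fld.velocity(local)
        p = pos[idx] + v * dt
        if sigma > 0:
            p += sigma * rng.standard_normal(size=p.shape)
        # substrate contact at one particle radius
        contact = p[:, 2] < particle_radius
        if contact.any():
            stick = rng.uniform(size=int(contact.sum())) < sticking_probability
            ci = idx[contact]
            stick_ids = ci[stick]
            for pi, pp in zip(stick_ids, p[contact][stick]):
                deposited.append([pp[0], pp[1]])
                arrivals.append(release_t[pi] + (k + 1) * dt)
            active[stick_ids] = False
            refl = contact.copy()
            refl[contact] = ~stick
            p[refl, 2] = 2.0 * particle_radius - p[refl, 2]
        pos[idx] = p
        # capture by aspiration (device frame)
        local_new = p.copy()
        off_new = tip_path.offset(release_t[idx] + (k + 1) * dt)
        local_new[:, 0] -= off_new[:, 0]
        local_new[:, 1] -= off_new[:, 1]
        captured = np.linalg.norm(local_new - sink_local[None, :], axis=1) < cap
        captured &= active[idx]
        n_captured += int(captured.sum())
        active[idx[captured]] = False
        gone = np.linalg.norm(local_new, axis=1) > fld.r_max
        active[idx[gone & active[idx]]] = False
    return DepositionResult(
        positions=np.asarray(deposited).reshape(-1, 2),
        arrival_times=np.asarray(arrivals),
        tip_path=tip_path,
        n_released=n,
        n_captured=n_captured,
    )


def stroke_width(
    result: DepositionResult,
    n_cross_sections: int = 10,
    bin_width: float = 0.5,
    min_deposits: int = 5,
) -> float:
    """Mean transverse FWHM of a deposition stroke, μm.

    Deposits are assigned to equally spaced stations along the tip path,
    binned transverse to the local path direction, and the FWHM of each
    station histogram is interpolated at half maximum; stations with
    fewer than `min_deposits` deposits are skipped.
    """
    if len(result.positions) < 50:
        raise ValueError("need at least 50 adsorbed particles")
    path = result.tip_path
    wp = path.waypoints
    seg = np.diff(wp, axis=0)
    if len(seg) == 0 or np.allclose(seg, 0):
        raise ValueError("stroke_width requires a translating tip path")
    cum = path._cum
    total = cum[-1]
    pts = result.positions
    # project each deposit onto the path (per segment, pick closest)
    best_s = np.zeros(len(pts))
    best_d = np.full(len(pts), np.inf)
    best_sign = np.zeros(len(pts))
    for i in range(len(seg)):
        a, b = wp[i], wp[i + 1]
        u = (b - a) / np.linalg.norm(b - a)
        rel = pts - a
        s_loc = np.clip(rel @ u, 0.0, np.linalg.norm(b - a))
        foot = a + s_loc[:, None] * u
        d = pts - foot
        dist = np.linalg.norm(d, axis=1)
        better = dist < best_d
        cross = u[0] * d[:, 1] - u[1] * d[:, 0]
        best_d[better] = dist[better]
        best_s[better] = cum[i] + s_loc[better]
        best_sign[better] = np.sign(cross[better])
    trans = best_d * np.where(best_sign == 0, 1.0, best_sign)
    stations = np.linspace(0.0, total, n_cross_sections + 1)
    widths = []
    for lo, hi in zip(stations[:-1], stations[1:]):
        sel = (best_s >= lo) & (best_s < hi)
        if sel.sum() < min_deposits:
            continue
        w = _histogram_fwhm(trans[sel], bin_width)
        if np.isfinite(w):
            widths.append(w)
    if not widths:
        raise ValueError("no station had enough deposits for a width estimate")
    return float(np.mean(widths))


def _histogram_fwhm(values: np.ndarray, bin_width: float) -> float:
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        return bin_width
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = counts.max()
    half = 0.5 * peak
    above = np.nonzero(counts >= half)[0]
    i0, i1 = above[0], above[-1]

    def cross(i_out, i_in):
        c0, c1 = counts[i_out], counts[i_in]
        if c1 == c0:
            return centers[i_in]
        frac = (half - c0) / (c1 - c0)
        return centers[i_out] + frac * (centers[i_in] - centers[i_out])

    left = centers[i0] if i0 == 0 else cross(i0 - 1, i0)
    right = centers[i1] if i1 == len(counts) - 1 else cross(i1 + 1, i1)
    return float(right - left)
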