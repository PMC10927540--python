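"""Reduced-order model of the confined perfusion flow.

The flow between the injection and aspiration openings is modelled as
the Stokes superposition of a point source (strength ``Q_inj``) and a
point sink (``Q_asp``); each contributes radially with
``|v| = Q / (4 π r²)``.  When a substrate is present, an image source
and sink mirrored across z = 0 cancel the normal velocity on the
substrate (no-penetration; the model does not impose no-slip).

This replaces a finite-element solution with an analytic field: it keeps
the mass budget and the far-field structure exactly, at the cost of
ignoring the collimation by the pipette walls, which is why the envelope
volume is only an order-of-magnitude quantity here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.spatial import ConvexHull

from .geometry import DeviceGeometry, FlowConfig
from .units import MPAS_TO_PAS, NL_PER_S_TO_UM3_PER_S

logger = logging.getLogger(__name__)

#: fraction of the inner radius excluded around each opening
EXCLUSION_FRACTION = 0.1
#: escape radius in units of the largest aperture diameter
R_MAX_FACTOR = 50.0
#: relative tolerance of the streamline integrator
RK_RTOL = 1.0e-6


class ConfinementError(RuntimeError):
    """Raised when streamlines escape a flow that should be confined."""

    def __init__(self, escaping_fraction: float):
        self.escaping_fraction = escaping_fraction
        super().__init__(
            f"confinement violated: {escaping_fraction:.1%} of streamlines escaped"
        )


class FlowField:
    """Analytic source–sink velocity field.

    Callable on points of shape (3,) or (N, 3) in μm; returns velocities
    in μm/s.  Also provides the analytic velocity gradient used for
    shear-stress evaluation.
    """

    def __init__(self, geometry: DeviceGeometry, config: FlowConfig):
        if config.Q_asp > 0 and config.Q_inj >= config.Q_asp:
            raise ValueError("no confinement possible: requires Q_inj < Q_asp")
        self.geometry = geometry
        self.config = config
        q_inj = config.Q_inj * NL_PER_S_TO_UM3_PER_S  # μm³/s
        q_asp = config.Q_asp * NL_PER_S_TO_UM3_PER_S
        centers = [geometry.injection_position, geometry.aspiration_position]
        strengths = [q_inj, -q_asp]
        if geometry.substrate_present:
            mirror = np.array([1.0, 1.0, -1.0])
            centers += [c * mirror for c in centers[:2]]
            strengths += strengths[:2]
        self._centers = np.asarray(centers)  # (M, 3)
        self._strengths = np.asarray(strengths)  # μm³/s

    # -- geometry helpers -------------------------------------------------
    @property
    def exclusion_radii(self) -> np.ndarray:
        g = self.geometry
        return EXCLUSION_FRACTION * 0.5 * np.array(
            [g.aperture_inner_diameter_inj, g.aperture_inner_diameter_asp]
        )

    @property
    def capture_radius(self) -> float:
        return 0.5 * self.geometry.aperture_inner_diameter_asp

    @property
    def r_max(self) -> float:
        return R_MAX_FACTOR * self.geometry.largest_diameter

    @property
    def speed_scale(self) -> float:
        """Characteristic speed at the tip-separation scale, μm/s."""
        q = max(self.config.Q_inj, self.config.Q_asp) * NL_PER_S_TO_UM3_PER_S
        return q / (4.0 * np.pi * self.geometry.tip_separation**2)

    def near_singular(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: points inside an exclusion sphere of an opening."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        real = self._centers[:2]
        d = np.linalg.norm(pts[:, None, :] - real[None, :, :], axis=-1)
        return np.any(d < self.exclusion_radii[None, :], axis=1)

    # -- field evaluation -------------------------------------------------
    def velocity(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        dx = pts[:, None, :] - self._centers[None, :, :]  # (N, M, 3)
        r2 = np.einsum("nmi,nmi->nm", dx, dx)
        r2 = np.maximum(r2, 1.0e-300)
        coeff = self._strengths[None, :] / (4.0 * np.pi * r2**1.5)
        v = np.einsum("nm,nmi->ni", coeff, dx)
        return v[0] if single else v

    __call__ = velocity

    def velocity_gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic ∇v, shape (N, 3, 3) with units 1/s; G[n, i, j] = ∂v_i/∂x_j."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        single = np.asarray(points).ndim == 1
        dx = pts[:, None, :] - self._centers[None, :, :]
        r2 = np.einsum("nmi,nmi->nm", dx, dx)
        r2 = np.maximum(r2, 1.0e-300)
        r3 = r2**1.5
        r5 = r2**2.5
        eye = np.eye(3)
        g = (
            self._strengths[None, :, None, None]
            / (4.0 * np.pi)
            * (
                eye[None, None, :, :] / r3[:, :, None, None]
                - 3.0
                * dx[:, :, :, None]
                * dx[:, :, None, :]
                / r5[:, :, None, None]
            )
        ).sum(axis=1)
        return g[0] if single else g


def build_field(geometry: DeviceGeometry, config: FlowConfig) -> FlowField:
    """Construct the analytic source–sink field for a device.

    Rejects configurations with ``Q_inj >= Q_asp > 0`` ("no confinement
    possible").  Degenerate pure-source (``Q_asp = 0``) and no-flow
    fields are permitted so that escape behaviour can be studied.
    """
    return FlowField(geometry, config)


# -- streamlines ----------------------------------------------------------

@dataclass
class Streamline:
    path: np.ndarray  # (N, 3) μm
    terminus: str  # captured_by_aspiration | escaped | exhausted
    arc_length: float
    dense = None  # scipy OdeSolution, arc-length parameterized


def trace_streamline(
    start: np.ndarray,
    field: FlowField,
    max_arc_length: float | None = None,
) -> Streamline:
    """Integrate the unit-speed streamline ODE dx/ds = v/|v|.

    Arc-length parameterization makes the path independent of the
    absolute flow magnitude, which is what makes the envelope a function
    of Q_ratio and geometry only.
    """
    start = np.asarray(start, dtype=float)
    if field.near_singular(start)[0]:
        raise ValueError("streamline start lies inside an exclusion sphere")
    if max_arc_length is None:
        max_arc_length = 10.0 * field.r_max

    v_tol = 1.0e-9 * max(field.speed_scale, 1.0e-30)
    sink = field.geometry.aspiration_position
    src = field.geometry.injection_position
    has_sink = field.config.Q_asp > 0

    def rhs(_s, x):
        v = field.velocity(x)
        speed = np.linalg.norm(v)
        if speed < v_tol:
            return np.zeros(3)
        return v / speed

    def ev_capture(_s, x):
        return np.linalg.norm(x - sink) - field.capture_radius

    def ev_escape(_s, x):
        return np.linalg.norm(x - src) - field.r_max

    def ev_stagnation(_s, x):
        return np.linalg.norm(field.velocity(x)) - v_tol

    events = [ev_escape, ev_stagnation]
    if has_sink:
        events.insert(0, ev_capture)
    for ev in events:
        ev.terminal = True
    ev_stagnation.direction = -1

    if np.linalg.norm(field.velocity(start)) < v_tol:
        return Streamline(path=start[None, :], terminus="exhausted", arc_length=0.0)

    sol = solve_ivp(
        rhs,
        (0.0, max_arc_length),
        start,
        method="RK45",
        rtol=RK_RTOL,
        atol=1.0e-9 * field.geometry.tip_separation,
        events=events,
        dense_output=True,
        max_step=0.25 * field.geometry.tip_separation,
    )
    terminus = "exhausted"
    if has_sink and sol.t_events[0].size:
        terminus = "captured_by_aspiration"
    elif sol.t_events[-2].size:
        terminus = "escaped"
    out = Streamline(
        path=sol.y.T.copy(),
        terminus=terminus,
        arc_length=float(sol.t[-1]),
    )
    out.dense = sol.sol
    return out


# -- envelope -------------------------------------------------------------

@dataclass
class Envelope:
    """Rasterized region visited by injected-fluid streamlines."""

    boundary_points: np.ndarray  # (B, 3) surface-voxel centers, μm
    extent: float  # max in-plane caliper width, μm
    volume: float  # fl (1 fl = 1 μm³)
    raster_resolution: float  # voxel edge, μm
    occupancy_indices: np.ndarray = field(repr=False, default=None)  # (K, 3) int
    origin: np.ndarray = field(repr=False, default=None)  # voxel (0,0,0) corner, μm

    @property
    def n_voxels(self) -> int:
        return len(self.occupancy_indices)

    def occupancy_grid(self) -> np.ndarray:
        """Dense boolean voxel grid (z, y, x) of the occupied region."""
        idx = self.occupancy_indices
        lo = idx.min(axis=0)
        shape = idx.max(axis=0) - lo + 1
        grid = np.zeros(shape[::-1], dtype=bool)
        rel = idx - lo
        grid[rel[:, 2], rel[:, 1], rel[:, 0]] = True
        return grid


def _launch_points(field: FlowField, n: int, rng: np.random.Generator) -> np.ndarray:
    """Seed-controlled isotropic points on the ε-sphere around the source."""
    eps = field.exclusion_radii[0]
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = field.geometry.injection_position[None, :] + 1.001 * eps * u
    if field.geometry.substrate_present:
        pts[:, 2] = np.abs(pts[:, 2])  # keep launches above the substrate
    return pts


def _voxelize(paths, resolution: float) -> np.ndarray:
    """Unique voxel indices visited by a collection of polyline paths."""
    chunks = []
    for pts in paths:
        chunks.append(np.floor(pts / resolution).astype(np.int64))
    idx = np.concatenate(chunks, axis=0)
    return np.unique(idx, axis=0)


def _surface_voxels(idx: np.ndarray) -> np.ndarray:
    """Voxels with fewer than 6 occupied face neighbors."""
    lo = idx.min(axis=0) - 1
    span = idx.max(axis=0) - lo + 2
    key = ((idx[:, 0] - lo[0]) * span[1] + (idx[:, 1] - lo[1])) * span[2] + (
        idx[:, 2] - lo[2]
    )
    key = np.sort(key)
    n_nb = np.zeros(len(idx), dtype=np.int8)
    for axis, stride in enumerate(
        [span[1] * span[2], span[2], 1]
    ):
        for sign in (-1, 1):
            shifted = (
                ((idx[:, 0] - lo[0]) * span[1] + (idx[:, 1] - lo[1])) * span[2]
                + (idx[:, 2] - lo[2])
                + sign * stride
            )
            pos = np.searchsorted(key, shifted)
            pos = np.clip(pos, 0, len(key) - 1)
            n_nb += (key[pos] == shifted).astype(np.int8)
    return idx[n_nb < 6]


def compute_envelope(
    geometry: DeviceGeometry,
    config: FlowConfig,
    n_streamlines: int = 2000,
    raster_resolution: float | None = None,
    seed: int = 0,
) -> Envelope:
    """Rasterize the injected-fluid region from seeded streamlines.

    Streamlines are launched isotropically from the exclusion sphere of
    the source and the points visited by the adaptive integrator are
    accumulated onto the voxel grid.  The volume is therefore an
    operational, streamline-sampled estimate of the perfused region (the
    sampling density is fixed by the integrator tolerance), suited to
    order-of-magnitude comparisons.  Any escaping streamline violates
    the confinement premise and raises :class:`ConfinementError`.
    """
    if not config.confined:
        raise ValueError("envelope requires Q_ratio < 1")
    if raster_resolution is None:
        raster_resolution = geometry.aperture_inner_diameter_inj / 50.0
    fld = build_field(geometry, config)
    rng = np.random.default_rng(seed)
    starts = _launch_points(fld, n_streamlines, rng)
    paths = []
    n_escaped = 0
    for s in starts:
        line = trace_streamline(s, fld)
        if line.terminus == "escaped":
            n_escaped += 1
        paths.append(line.path)
    if n_escaped:
        raise ConfinementError(n_escaped / n_streamlines)
    idx = _voxelize(paths, raster_resolution)
    centers = (idx + 0.5) * raster_resolution
    hull = ConvexHull(centers[:, :2])
    hp = centers[hull.vertices, :2]
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(-1)
    extent = float(np.sqrt(d2.max()))
    surf = _surface_voxels(idx)
    return Envelope(
        boundary_points=(surf + 0.5) * raster_resolution,
        extent=extent,
        volume=float(len(idx)) * raster_resolution**3,
        raster_resolution=raster_resolution,
        occupancy_indices=idx,
        origin=np.zeros(3),
    )


# -- profiles and shear ---------------------------------------------------

def axial_velocity_profile(
    line: tuple[np.ndarray, np.ndarray],
    geometry: DeviceGeometry,
    config: FlowConfig,
    n_samples: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample |v| along a segment; returns (positions μm, speeds μm/s).

    Positions are arc-length coordinates along the segment from its
    first endpoint.
    """
    fld = build_field(geometry, config)
    a, b = (np.asarray(p, dtype=float) for p in line)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    if np.any(fld.near_singular(pts)):
        raise ValueError("profile line passes through an exclusion sphere")
    speeds = np.linalg.norm(fld.velocity(pts), axis=1)
    return t * np.linalg.norm(b - a), speeds


@dataclass
class ShearReport:
    sample_points: np.ndarray  # (N, 3) μm
    shear_stress: np.ndarray  # Pa
    max_abs_shear: float  # Pa
    max_location: np.ndarray  # (3,) μm
    n_excluded: int = 0


def shear_report(
    points: np.ndarray,
    geometry: DeviceGeometry,
    config: FlowConfig,
) -> ShearReport:
    """Viscous shear stress μ‖(∇v + ∇vᵀ)/2‖_F at the given points, Pa.

    Points inside an exclusion sphere are dropped from the report and
    logged rather than evaluated against the singular field.
    """
    fld = build_field(geometry, config)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    bad = fld.near_singular(pts)
    if bad.any():
        logger.warning("shear_report: excluded %d near-singular points", bad.sum())
    pts = pts[~bad]
    if len(pts) == 0:
        raise ValueError("no points outside the exclusion spheres")
    grad = fld.velocity_gradient(pts)  # 1/s
    strain = 0.5 * (grad + np.swapaxes(grad, 1, 2))
    norm = np.sqrt((strain**2).sum(axis=(1, 2)))
    shear = config.viscosity * MPAS_TO_PAS * norm  # Pa
    imax = int(np.argmax(shear))
    return ShearReport(
        sample_points=pts,
        shear_stress=shear,
        max_abs_shear=float(shear[imax]),
        max_location=pts[imax],
        n_excluded=int(bad.sum()),
    )
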