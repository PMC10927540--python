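"""Device geometry and flow configuration for the two-aperture brush.

Coordinate convention: the substrate (coverslip / membrane) lies in the
plane z = 0 with z pointing up; the injection opening sits at the origin
shifted to height ``tip_height`` and the aspiration opening at distance
``tip_separation`` along +x at the same height.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import numpy as np
import yaml


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of an injection/aspiration micropipette aperture pair.

    Parameters
    ----------
    aperture_inner_diameter_inj, aperture_inner_diameter_asp : float
        Inner diameters of the two openings, μm.
    wall_thickness : float
        Glass wall thickness at the tip, μm.
    tip_separation : float or None
        Center-to-center distance of the two openings, μm.  ``None``
        selects the rim-touching default
        ``(⌀_inj + ⌀_asp)/2 + 2·wall_thickness``.
    in_plane_angle : float
        Angle between the two pipette axes, degrees, in (0, 90].
    tip_height : float or None
        Height of the opening centers above the substrate plane z = 0, μm.
        ``None`` defaults to the injection inner radius (tip resting at
        the surface).
    substrate_present : bool
        If True the velocity field includes an image system across z = 0
        so that no fluid penetrates the substrate.
    """

    aperture_inner_diameter_inj: float = 6.0
    aperture_inner_diameter_asp: float = 6.0
    wall_thickness: float = 1.0
    tip_separation: float | None = None
    in_plane_angle: float = 35.0
    tip_height: float | None = None
    substrate_present: bool = False

    def __post_init__(self) -> None:
        if self.aperture_inner_diameter_inj <= 0:
            raise ValueError("injection aperture diameter must be > 0")
        if self.aperture_inner_diameter_asp <= 0:
            raise ValueError("aspiration aperture diameter must be > 0")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be > 0")
        if not 0.0 < self.in_plane_angle <= 90.0:
            raise ValueError("in-plane angle must lie in (0, 90] degrees")
        if self.tip_separation is None:
            object.__setattr__(self, "tip_separation", self.default_separation())
        if self.tip_separation < self.default_separation() - 1e-12:
            raise ValueError(
                "tip_separation smaller than touching outer rims "
                f"({self.default_separation():g} μm)"
            )
        if self.tip_height is None:
            object.__setattr__(
                self, "tip_height", 0.5 * self.aperture_inner_diameter_inj
            )
        if self.tip_height <= 0:
            raise ValueError("tip_height must be > 0")

    def default_separation(self) -> float:
        """Rim-touching center-to-center distance, μm."""
        return (
            0.5 * (self.aperture_inner_diameter_inj + self.aperture_inner_diameter_asp)
            + 2.0 * self.wall_thickness
        )

    @property
    def injection_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.tip_height])

    @property
    def aspiration_position(self) -> np.ndarray:
        return np.array([self.tip_separation, 0.0, self.tip_height])

    @property
    def largest_diameter(self) -> float:
        return max(self.aperture_inner_diameter_inj, self.aperture_inner_diameter_asp)


@dataclass(frozen=True)
class FlowConfig:
    """Volumetric flow rates and fluid properties.

    Flows in nl/s, viscosity in mPa·s, temperature in °C, density in
    kg/m³.  Defaults are water at 22 °C.
    """

    Q_inj: float
    Q_asp: float
    viscosity: float = 0.9544
    temperature: float = 22.0
    density: float = 997.8

    def __post_init__(self) -> None:
        if self.Q_inj < 0 or self.Q_asp < 0:
            raise ValueError("flow rates must be non-negative")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def Q_ratio(self) -> float:
        """Injection-to-aspiration flow ratio; < 1 required for confinement."""
        if self.Q_asp == 0:
            return float("inf") if self.Q_inj > 0 else float("nan")
        return self.Q_inj / self.Q_asp

    @property
    def confined(self) -> bool:
        return self.Q_asp > 0 and self.Q_inj < self.Q_asp

    @property
    def reliably_confined(self) -> bool:
        """Empirical reliability criterion Q_ratio < 0.8."""
        return self.Q_asp > 0 and self.Q_ratio < 0.8


def _asdict(obj) -> dict:
    return dataclasses.asdict(obj)


def save_yaml(path, geometry: DeviceGeometry, config: FlowConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"geometry": _asdict(geometry), "flow": _asdict(config)},
            fh,
            sort_keys=False,
        )


def load_yaml(path) -> tuple[DeviceGeometry, FlowConfig]:
    if isinstance(path, io.IOBase):
        data = yaml.safe_load(path)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return DeviceGeometry(**data["geometry"]), FlowConfig(**data["flow"])
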