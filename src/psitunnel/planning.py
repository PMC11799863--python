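"""Tunnel trajectory planning from per-ligament angle prescriptions.

Each femoral tunnel is prescribed by two clinical angles read off CT planes:
an *axial* angle (degrees anterior of the medio-lateral direction, measured in
the axial plane) and a *coronal* angle (degrees proximal, measured in the
coronal plane).  The default prescriptions are the ones used for combined
collateral-ligament reconstruction: LCL 30°/0°, PT 30°/30°, MCL 30°/30°,
POL 30°/30°, with 8 mm tunnels laterally, 7 mm medially, all 25 mm deep.

Two conventions exist for composing the two angles into a 3D direction; both
are implemented:

``projection`` (default)
    The unique direction whose projection onto the axial plane makes the
    axial angle with ML *and* whose projection onto the coronal plane makes
    the coronal angle with ML: ``normalize(ml + tan(ax)·ap + tan(co)·si)``.
    This matches reading each angle off its own CT slice simultaneously.
``sequential``
    Rotate ML anteriorly by the axial angle within the axial plane, then
    elevate by the coronal angle: ``cos(co)·(cos(ax)·ml + sin(ax)·ap) +
    sin(co)·si``.  Differs from ``projection`` by a few degrees at 30°/30°.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .frames import AnatomicalFrame, Side

__all__ = [
    "Ligament",
    "TunnelSpec",
    "Tunnel",
    "PsiGuideParams",
    "DEFAULT_SPECS",
    "PRESETS",
    "LIGAMENT_SIDE",
    "direction_from_angles",
    "angles_from_direction",
    "plan_knee",
]


class Ligament(str, Enum):
    LCL = "LCL"  # lateral collateral ligament
    PT = "PT"  # popliteal tendon
    MCL = "MCL"  # medial collateral ligament
    POL = "POL"  # posterior oblique ligament


LIGAMENT_SIDE: Mapping[Ligament, Side] = {
    Ligament.LCL: Side.LATERAL,
    Ligament.PT: Side.LATERAL,
    Ligament.MCL: Side.MEDIAL,
    Ligament.POL: Side.MEDIAL,
}


@dataclass(frozen=True)
class TunnelSpec:
    """Per-ligament prescription: angles (deg), diameter and depth (mm)."""

    ligament: Ligament
    axial_angle_deg: float
    coronal_angle_deg: float
    diameter_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligament", Ligament(self.ligament))
        if not (abs(self.axial_angle_deg) < 90 and abs(self.coronal_angle_deg) < 90):
            raise ValueError("tunnel angles must lie in (-90, 90) degrees")
        if self.diameter_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("diameter and depth must be positive")


# Standard prescriptions: 30° anterior everywhere; 30° proximal except the LCL;
# 8 mm ∅ × 25 mm laterally, 7 mm ∅ × 25 mm medially.
DEFAULT_SPECS: tuple[TunnelSpec, ...] = (
    TunnelSpec(Ligament.LCL, 30.0, 0.0, 8.0, 25.0),
    TunnelSpec(Ligament.PT, 30.0, 30.0, 8.0, 25.0),
    TunnelSpec(Ligament.MCL, 30.0, 30.0, 7.0, 25.0),
    TunnelSpec(Ligament.POL, 30.0, 30.0, 7.0, 25.0),
)

# Literature alternatives for the lateral tunnels, selectable by name.
PRESETS: Mapping[str, tuple[TunnelSpec, ...]] = {
    "standard": DEFAULT_SPECS,
    # lateral tunnels 35° anterior to clear a cruciate tunnel
    "anterior-35": tuple(
        replace(s, axial_angle_deg=35.0) if LIGAMENT_SIDE[s.ligament] is Side.LATERAL else s
        for s in DEFAULT_SPECS
    ),
    # lateral tunnels ~20° anterior / 10° proximal to the transepicondylar axis
    "anterior-20-proximal-10": tuple(
        replace(s, axial_angle_deg=20.0, coronal_angle_deg=10.0)
        if LIGAMENT_SIDE[s.ligament] is Side.LATERAL
        else s
        for s in DEFAULT_SPECS
    ),
}


@dataclass(frozen=True)
class Tunnel:
    """A capped cylinder in 3D: entry point, unit direction into bone, ∅, depth."""

    entry: np.ndarray
    direction: np.ndarray
    diameter_mm: float
    depth_mm: float
    ligament: Ligament

    def __post_init__(self) -> None:
        entry = np.asarray(self.entry, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if entry.shape != (3,) or direction.shape != (3,):
            raise ValueError("entry and direction must be 3-vectors")
        n = np.linalg.norm(direction)
        if n == 0 or not np.isfinite(n):
            raise ValueError("tunnel direction must be nonzero and finite")
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "direction", direction / n)
        object.__setattr__(self, "ligament", Ligament(self.ligament))
        if self.diameter_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("diameter and depth must be positive")

    @property
    def exit_point(self) -> np.ndarray:
        return self.entry + self.depth_mm * self.direction

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def to_dict(self) -> dict:
        return {
            "ligament": self.ligament.value,
            "entry": self.entry.tolist(),
            "direction": self.direction.tolist(),
            "diameter_mm": self.diameter_mm,
            "depth_mm": self.depth_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tunnel":
        return cls(
            entry=d["entry"],
            direction=d["direction"],
            diameter_mm=d["diameter_mm"],
            depth_mm=d["depth_mm"],
            ligament=d["ligament"],
        )


@dataclass(frozen=True)
class PsiGuideParams:
    """Descriptive parameters of the 3D-printed drill guide.

    The guide's computational content is the cannula direction, which equals
    the planned tunnel direction; these parameters describe its physical
    realization (K-wire bore, bone standoff, shell thickness).
    """

    kwire_diameter_mm: float = 2.5
    cannula_clearance_mm: float = 0.6
    bone_offset_mm: float = 0.4
    mean_thickness_mm: float = 3.3

    @property
    def cannula_inner_diameter_mm(self) -> float:
        return self.kwire_diameter_mm + self.cannula_clearance_mm


def direction_from_angles(
    frame: AnatomicalFrame,
    axial_deg: float,
    coronal_deg: float,
    convention: str = "projection",
) -> np.ndarray:
    """Unit tunnel direction for the given axial/coronal prescription."""
    if not (abs(axial_deg) < 90 and abs(coronal_deg) < 90):
        raise ValueError("angles must lie in (-90, 90) degrees")
    ax = np.radians(axial_deg)
    co = np.radians(coronal_deg)
    if convention == "projection":
        d = frame.ml_axis + np.tan(ax) * frame.ap_axis + np.tan(co) * frame.si_axis
        return d / np.linalg.norm(d)
    if convention == "sequential":
        return (
            np.cos(co) * (np.cos(ax) * frame.ml_axis + np.sin(ax) * frame.ap_axis)
            + np.sin(co) * frame.si_axis
        )
    raise ValueError(f"unknown angle convention {convention!r}")


def angles_from_direction(
    frame: AnatomicalFrame, direction, convention: str = "projection"
) -> tuple[float, float]:
    """Axial/coronal angles (degrees) of a direction; inverse of
    :func:`direction_from_angles`.

    Raises
    ------
    ValueError
        If the direction's ML component is not positive (tunnel not directed
        into the bone).
    """
    ml_c, ap_c, si_c = frame.coords(direction)
    if ml_c <= 0:
        raise ValueError("direction is not into the bone (ML component <= 0)")
    if convention == "projection":
        return (
            float(np.degrees(np.arctan(ap_c / ml_c))),
            float(np.degrees(np.arctan(si_c / ml_c))),
        )
    if convention == "sequential":
        n = float(np.linalg.norm([ml_c, ap_c, si_c]))
        return (
            float(np.degrees(np.arctan2(ap_c, ml_c))),
            float(np.degrees(np.arcsin(np.clip(si_c / n, -1.0, 1.0)))),
        )
    raise ValueError(f"unknown angle convention {convention!r}")


def plan_knee(
    model,
    specs: Sequence[TunnelSpec] = DEFAULT_SPECS,
    frames: Mapping[Side, AnatomicalFrame] | None = None,
    convention: str = "projection",
) -> list[Tunnel]:
    """Plan one tunnel per spec, anchored at the ligament footprints.

    ``model`` is a :class:`~psitunnel.synthetic_femur.FemurModel` (or any
    object with ``footprints`` and ``landmarks``).  ``frames`` maps each entry
    side to its anatomical frame; when omitted, frames are built from the
    model's landmarks.
    """
    from .frames import build_frame  # local import to avoid cycle noise

    if frames is None:
        knee_side = getattr(model, "knee_side", "right")
        frames = {
            side: build_frame(model.landmarks, side, knee_side)
            for side in (Side.LATERAL, Side.MEDIAL)
        }
    tunnels = []
    for spec in specs:
        if spec.ligament not in model.footprints:
            raise KeyError(f"model has no footprint for ligament {spec.ligament.value}")
        frame = frames[LIGAMENT_SIDE[spec.ligament]]
        tunnels.append(
            Tunnel(
                entry=model.footprints[spec.ligament],
                direction=direction_from_angles(
                    frame, spec.axial_angle_deg, spec.coronal_angle_deg, convention
                ),
                diameter_mm=spec.diameter_mm,
                depth_mm=spec.depth_mm,
                ligament=spec.ligament,
            )
        )
    return tunnels
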