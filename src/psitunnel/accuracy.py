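"""Accuracy endpoints: angular deviation and entry-point distance.

After the post-operative bone has been rigidly overlaid onto the
pre-operative one, each achieved tunnel is compared with its plan on two
endpoints:

* **angular deviation** — the 3D angle between the planned and achieved
  direction vectors.  Clinically it is described as the angle "in the plane
  where the deviation is greatest"; that plane is exactly the plane spanned
  by the two vectors (any other projection can only shrink the angle), so
  the plain arccos of the dot product is the correct implementation.
* **entry-point distance** — Euclidean distance (mm) between the planned and
  achieved entry points.

Directions are compared *signed*: a drill reversed 180° is maximal error,
not zero — tunnels are oriented into the bone, not undirected lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .planning import Ligament, Tunnel
from .registration import RegistrationResult, RigidTransform, apply

__all__ = [
    "Group",
    "AccuracyRecord",
    "angular_deviation",
    "entry_distance",
    "evaluate_knee",
    "records_to_frame",
]


class Group(str, Enum):
    FREEHAND = "freehand"  # control: surgeon drills guided by the plan only
    PSI = "psi"  # drilled through the patient-specific guide


@dataclass(frozen=True)
class AccuracyRecord:
    ligament: Ligament
    group: Group
    angular_deviation_deg: float
    entry_distance_mm: float
    knee_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligament", Ligament(self.ligament))
        object.__setattr__(self, "group", Group(self.group))
        if not 0.0 <= self.angular_deviation_deg <= 180.0:
            raise ValueError("angular deviation must lie in [0, 180] degrees")
        if self.entry_distance_mm < 0:
            raise ValueError("entry distance cannot be negative")


def angular_deviation(planned: Tunnel, achieved: Tunnel) -> float:
    """3D angle (degrees) between planned and achieved directions."""
    u = np.asarray(planned.direction, dtype=float)
    v = np.asarray(achieved.direction, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length tunnel direction")
    return float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0))))


def entry_distance(planned: Tunnel, achieved: Tunnel) -> float:
    """Euclidean distance (mm) between entry points."""
    return float(np.linalg.norm(planned.entry - achieved.entry))


def evaluate_knee(
    planned: Sequence[Tunnel],
    achieved: Sequence[Tunnel],
    reg: RegistrationResult | RigidTransform,
    group: Group | str,
    knee_id: str,
) -> list[AccuracyRecord]:
    """One record per tunnel, with achieved tunnels mapped into the pre-op
    frame through the registration transform before metrics are computed.

    ``planned`` and ``achieved`` must be aligned by ligament.
    """
    transform = reg.transform if isinstance(reg, RegistrationResult) else reg
    group = Group(group)
    if len(planned) != len(achieved):
        raise ValueError("planned and achieved tunnel lists differ in length")
    records = []
    for p, a in zip(planned, achieved):
        if p.ligament != a.ligament:
            raise ValueError(
                f"ligament mismatch: planned {p.ligament.value} vs "
                f"achieved {a.ligament.value}"
            )
        a_pre = apply(transform, a)
        records.append(
            AccuracyRecord(
                ligament=p.ligament,
                group=group,
                angular_deviation_deg=angular_deviation(p, a_pre),
                entry_distance_mm=entry_distance(p, a_pre),
                knee_id=knee_id,
            )
        )
    return records


def records_to_frame(records: Iterable[AccuracyRecord]) -> pd.DataFrame:
    """Tidy table: knee_id, group, ligament, angular_deviation_deg, entry_distance_mm."""
    return pd.DataFrame(
        [
            {
                "knee_id": r.knee_id,
                "group": r.group.value,
                "ligament": r.ligament.value,
                "angular_deviation_deg": r.angular_deviation_deg,
                "entry_distance_mm": r.entry_distance_mm,
            }
            for r in records
        ]
    )
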