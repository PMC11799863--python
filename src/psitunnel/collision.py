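"""Tunnel convergence (collision) detection.

Two bone tunnels drilled toward each other can confluence inside the bone,
compromising fixation — the complication the angle prescriptions exist to
avoid.  Tunnels are modeled as capped cylinders (finite axis segments with a
radius), so the check reduces to an exact closed-form minimum distance
between two 3D segments; the residual bone wall between a pair is that axis
distance minus both radii.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .planning import Ligament, Tunnel

__all__ = ["CollisionReport", "segment_distance", "check_convergence"]


@dataclass(frozen=True)
class CollisionReport:
    """Convergence check for one unordered tunnel pair.

    ``wall_thickness_mm`` = axis distance − r1 − r2 (negative if the
    cylinders overlap); ``breach_depth_pair`` gives the arc length along each
    tunnel at the closest approach.
    """

    pair: tuple[Ligament, Ligament]
    min_axis_distance_mm: float
    wall_thickness_mm: float
    collides: bool
    breach_depth_pair: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "ligament_a": self.pair[0].value,
            "ligament_b": self.pair[1].value,
            "min_axis_distance_mm": self.min_axis_distance_mm,
            "wall_thickness_mm": self.wall_thickness_mm,
            "collides": self.collides,
            "depth_a_mm": self.breach_depth_pair[0],
            "depth_b_mm": self.breach_depth_pair[1],
        }


def segment_distance(
    p1, d1, L1: float, p2, d2, L2: float
) -> tuple[float, float, float]:
    """Exact minimum distance between segments [p1, p1+L1·d1] and
    [p2, p2+L2·d2], with the closest-approach parameters (mm along each).

    ``d1``/``d2`` must be unit vectors; standard clamped closed-form solution.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    u = np.asarray(d1, dtype=float) * L1
    v = np.asarray(d2, dtype=float) * L2
    w0 = p1 - p2

    a = u @ u
    b = u @ v
    c = v @ v
    d = u @ w0
    e = v @ w0
    denom = a * c - b * b

    # closest approach of the infinite lines, in [0,1] segment parameters;
    # (near-)parallel lines start from s=0 and let the clamped coordinate
    # sweep below find a minimizer
    s = (b * e - c * d) / denom if denom > 1e-12 * a * c else 0.0
    s = float(np.clip(s, 0.0, 1.0))
    t = (b * s + e) / c if c > 0 else 0.0
    # clamp t, then re-optimize s for the clamped t (and once more for s)
    t = float(np.clip(t, 0.0, 1.0))
    s = float(np.clip((b * t - d) / a if a > 0 else 0.0, 0.0, 1.0))
    t = float(np.clip((b * s + e) / c if c > 0 else 0.0, 0.0, 1.0))

    diff = (p1 + s * u) - (p2 + t * v)
    return float(np.linalg.norm(diff)), s * L1, t * L2


def check_convergence(
    tunnels: Sequence[Tunnel], min_wall_mm: float = 0.0
) -> list[CollisionReport]:
    """One report per unordered tunnel pair.

    A pair collides when the bone wall between the two cylinders is thinner
    than ``min_wall_mm`` (default 0: touching counts as collision).  Pairs on
    opposite sides of the femur are checked too — cross-femur convergence is
    the clinically relevant failure mode.
    """
    if len(tunnels) < 2:
        raise ValueError("need at least two tunnels to check convergence")
    reports = []
    for ta, tb in combinations(tunnels, 2):
        dist, sa, sb = segment_distance(
            ta.entry, ta.direction, ta.depth_mm, tb.entry, tb.direction, tb.depth_mm
        )
        wall = dist - ta.radius_mm - tb.radius_mm
        reports.append(
            CollisionReport(
                pair=(ta.ligament, tb.ligament),
                min_axis_distance_mm=dist,
                wall_thickness_mm=wall,
                collides=wall < min_wall_mm,
                breach_depth_pair=(sa, sb),
            )
        )
    return reports
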