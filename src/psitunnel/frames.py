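"""Per-knee anatomical coordinate frames.

A tunnel angle prescription ("30° anterior in the axial plane, 30° proximal in
the coronal plane") only has meaning relative to an anatomical frame.  This
module builds that frame from five palpable/identifiable landmarks:

* the shaft axis (two points on the diaphysis) fixes the superior-inferior
  (SI) axis, hence the axial plane;
* the transepicondylar direction, orthogonalized against SI, fixes the
  medio-lateral (ML) axis;
* the most anterior point of the trochlea disambiguates the anterior
  direction of the AP axis.

Frames are built per entry side: the ML axis always points from the entry
epicondyle *into* the bone (medially for a lateral-side frame, laterally for
a medial-side frame), and the origin sits at the entry epicondyle.  With
"anterior" and "proximal" meaning the same thing on both sides, a single
angle convention serves lateral (LCL/PT) and medial (MCL/POL) tunnels.

Chirality note: because ml, ap and si signs are each pinned by anatomy, the
triad's handedness alternates with the entry side (the lateral frame is the
sagittal mirror of the medial one).  Nothing downstream depends on it; all
angle math uses coordinates, not cross products of frame axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Side",
    "KneeSide",
    "LandmarkSet",
    "AnatomicalFrame",
    "build_frame",
    "DegenerateGeometryError",
]

_ORTHO_TOL = 1e-9
_PARALLEL_TOL = 1e-6


class Side(str, Enum):
    """Entry side of the femur for a tunnel or frame."""

    LATERAL = "lateral"
    MEDIAL = "medial"


class KneeSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class DegenerateGeometryError(ValueError):
    """Raised when landmarks do not span a usable frame."""


def _as_point(x, name: str) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} contains non-finite values")
    return p


@dataclass(frozen=True)
class LandmarkSet:
    """Frame-defining landmarks, all in mm, in the mesh coordinate system."""

    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    shaft_axis_point_distal: np.ndarray
    shaft_axis_point_proximal: np.ndarray
    most_anterior_trochlea: np.ndarray

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        if np.linalg.norm(self.lateral_epicondyle - self.medial_epicondyle) <= 0:
            raise ValueError("epicondyles coincide")
        if np.linalg.norm(
            self.shaft_axis_point_proximal - self.shaft_axis_point_distal
        ) <= 0:
            raise ValueError("shaft axis points coincide")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform ``x -> R x + t`` to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return LandmarkSet(
            **{
                name: R @ getattr(self, name) + t
                for name in self.__dataclass_fields__
            }
        )

    def mirrored_x(self) -> "LandmarkSet":
        """Mirror across the x=0 sagittal plane (left/right conversion)."""
        M = np.diag([-1.0, 1.0, 1.0])
        return LandmarkSet(
            **{name: M @ getattr(self, name) for name in self.__dataclass_fields__}
        )

    def to_dict(self) -> dict:
        return {name: getattr(self, name).tolist() for name in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(**{name: d[name] for name in cls.__dataclass_fields__})

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        """Read landmarks from a JSON sidecar (``{"medial_epicondyle": [x,y,z], ...}``)."""
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal ML/AP/SI axes + origin for one knee and one entry side.

    The axial plane is spanned by (ml, ap); the coronal plane by (ml, si).
    ``ml_axis`` points from the entry epicondyle across the femur (into the
    bone), ``ap_axis`` anteriorly, ``si_axis`` proximally.  Origin is the
    entry-side epicondyle (mm).
    """

    origin: np.ndarray
    ml_axis: np.ndarray
    ap_axis: np.ndarray
    si_axis: np.ndarray
    side: Side
    knee_side: KneeSide

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_point(self.origin, "origin"))
        for name in ("ml_axis", "ap_axis", "si_axis"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        A = self.axes
        if not np.allclose(A @ A.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("frame axes are not orthonormal")
        if abs(abs(np.linalg.det(A)) - 1.0) > _ORTHO_TOL:
            raise ValueError("frame axes are not a unit triad")
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "knee_side", KneeSide(self.knee_side))

    @property
    def axes(self) -> np.ndarray:
        """Rows are ml, ap, si."""
        return np.vstack([self.ml_axis, self.ap_axis, self.si_axis])

    def coords(self, vector) -> np.ndarray:
        """(ml, ap, si) components of a free vector."""
        return self.axes @ np.asarray(vector, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnatomicalFrame":
        R = np.asarray(rotation, dtype=float)
        return AnatomicalFrame(
            origin=R @ self.origin + np.asarray(translation, dtype=float),
            ml_axis=R @ self.ml_axis,
            ap_axis=R @ self.ap_axis,
            si_axis=R @ self.si_axis,
            side=self.side,
            knee_side=self.knee_side,
        )


def build_frame(
    landmarks: LandmarkSet, side: Side | str, knee_side: KneeSide | str
) -> AnatomicalFrame:
    """Construct the per-side anatomical frame from landmarks.

    SI is the normalized shaft direction (proximal − distal).  ML is the
    inter-epicondylar direction Gram–Schmidt-orthogonalized against SI and
    oriented away from the entry side.  AP completes the triad, signed so the
    anterior trochlear landmark has a positive AP coordinate.

    Raises
    ------
    DegenerateGeometryError
        If the epicondylar axis is parallel to the shaft axis (within 1e-6).
    """
    side = Side(side)
    knee_side = KneeSide(knee_side)
    lm = landmarks

    si = lm.shaft_axis_point_proximal - lm.shaft_axis_point_distal
    si = si / np.linalg.norm(si)

    if side is Side.LATERAL:
        entry_epi, far_epi = lm.lateral_epicondyle, lm.medial_epicondyle
    else:
        entry_epi, far_epi = lm.medial_epicondyle, lm.lateral_epicondyle

    e = far_epi - entry_epi  # points into the bone across the femur
    e_norm = np.linalg.norm(e)
    ml = e - (e @ si) * si
    ml_norm = np.linalg.norm(ml)
    if ml_norm < _PARALLEL_TOL * e_norm:
        raise DegenerateGeometryError(
            "epicondylar axis is (near-)parallel to the shaft axis; "
            f"residual fraction {ml_norm / e_norm:.2e}"
        )
    ml = ml / ml_norm

    ap = np.cross(si, ml)
    if ap @ (lm.most_anterior_trochlea - entry_epi) < 0:
        ap = -ap

    return AnatomicalFrame(
        origin=entry_epi,
        ml_axis=ml,
        ap_axis=ap,
        si_axis=si,
        side=side,
        knee_side=knee_side,
    )
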