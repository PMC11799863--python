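"""Rigid overlay of post-operative onto pre-operative bone.

Accuracy metrics only make sense once both scans live in one coordinate
system.  This module provides the least-squares rigid fit for paired points
(Kabsch/Umeyama, SVD with reflection correction) and an iterative closest
point (ICP) loop over it: source vertices are matched to their nearest point
*on the target surface* (not nearest vertex), the rigid fit is re-solved,
and iteration stops when the mean closest-point distance stops improving.

The reported ``mean_distance_mm`` is the average source-vertex-to-target-
surface distance at convergence — the analog of the overlay quality figure a
commercial ICP reports after superimposing two scans of the same bone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from ._surface import SurfaceDistance
from .planning import Tunnel

__all__ = ["RigidTransform", "RegistrationResult", "best_rigid", "icp", "apply"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3])


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    mean_distance_mm: float
    iterations: int
    converged: bool
    history: tuple[float, ...] = ()  # mean distance per iteration

    def __post_init__(self) -> None:
        if self.mean_distance_mm < 0:
            raise ValueError("mean distance cannot be negative")


class RegistrationError(RuntimeError):
    """Raised when ICP fails to converge within the iteration budget."""


def best_rigid(points_a, points_b) -> RigidTransform:
    """Least-squares rigid transform mapping paired ``points_a`` onto
    ``points_b`` (minimizes sum ||R a + t - b||^2).

    SVD (Kabsch) solution with reflection correction.  Requires >= 3
    non-collinear pairs.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need matched (n>=3, 3) point arrays")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the common axis undetermined
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point sets")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cb - R @ ca)


def _subsample(vertices: np.ndarray, n: int, seed: int) -> np.ndarray:
    if len(vertices) <= n:
        return vertices
    rng = np.random.default_rng(seed)
    return vertices[rng.choice(len(vertices), size=n, replace=False)]


def icp(
    source_mesh,
    target_mesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol_mm: float = 1e-4,
    sample_size: int = 5000,
    seed: int = 0,
) -> RegistrationResult:
    """Register ``source_mesh`` onto ``target_mesh``.

    A fixed random subsample of source vertices (<= ``sample_size``, for
    desk-scale runtime) is matched each iteration to the nearest point on the
    target surface; the rigid fit is re-solved from scratch against the
    original sample so the correspondence objective is non-increasing.
    ``init`` defaults to centroid alignment.  Convergence: change in mean
    closest-point distance < ``tol_mm``.

    Raises
    ------
    RegistrationError
        If the loop exhausts ``max_iter`` without meeting ``tol_mm``.
    """
    src = np.asarray(source_mesh.vertices, dtype=float)
    if len(src) == 0 or len(np.asarray(target_mesh.vertices)) == 0:
        raise ValueError("meshes must be non-empty")
    samples = _subsample(src, sample_size, seed)
    surface = SurfaceDistance(target_mesh)

    if init is None:
        init = RigidTransform(
            np.eye(3),
            np.asarray(target_mesh.vertices).mean(axis=0) - src.mean(axis=0),
        )

    T = init
    history: list[float] = []
    prev = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = T.apply_points(samples)
        dist, closest, _ = surface.query(moved)
        mean_d = float(dist.mean())
        history.append(mean_d)
        if mean_d < tol_mm or prev - mean_d < tol_mm:
            converged = True
            break
        prev = mean_d
        T = best_rigid(samples, closest)
    if not converged:
        raise RegistrationError(
            f"ICP did not converge in {max_iter} iterations "
            f"(last mean distance {history[-1]:.4f} mm)"
        )
    return RegistrationResult(
        transform=T,
        mean_distance_mm=history[-1],
        iterations=iterations,
        converged=converged,
        history=tuple(history),
    )


def apply(transform: RigidTransform, obj):
    """Rigidly transform a point array, a Tunnel, or a mesh-bearing model.

    Tunnel directions are rotated; diameters and depths are unchanged.
    """
    if isinstance(obj, Tunnel):
        return Tunnel(
            entry=transform.apply_points(obj.entry),
            direction=transform.rotation @ obj.direction,
            diameter_mm=obj.diameter_mm,
            depth_mm=obj.depth_mm,
            ligament=obj.ligament,
        )
    if hasattr(obj, "mesh"):  # FemurModel-like: defer to its own rigid action
        return obj.transformed(transform)
    return transform.apply_points(obj)
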