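"""Parametric synthetic distal femurs with ligament footprints.

No imaging data ship with this package; instead, every downstream stage
(planning, registration, accuracy, statistics) is exercised on synthetic
distal femurs.  The generator blends a small set of implicit primitives —
two condylar ellipsoids, a trochlear/metaphyseal bulge and a diaphyseal
cylinder — with a smooth-minimum field, polygonizes the zero level set by
marching cubes, and tags the mesh with:

* the four collateral-ligament footprints (LCL and popliteal tendon on the
  lateral epicondyle, MCL and POL on the medial epicondyle), placed at
  parametric epicondylar offsets and projected exactly onto the surface;
* the frame landmarks (epicondyles, shaft-axis points, anterior trochlea).

The default geometry is an adult-sized knee (epicondylar width 80 mm, shaft
radius 15 mm); per-specimen variability enters through ``size_scale`` and a
small seeded jitter of condylar geometry.  Anatomy is canonical-right
(+x lateral, +y anterior, +z proximal); left knees are represented by
mirroring.

``make_postop`` manufactures the "post-operative scan": the same bone
rigidly repositioned and optionally perturbed by isotropic Gaussian surface
noise, together with the achieved tunnels expressed in the displaced
coordinates — exactly what the registration stage must undo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from ._surface import SurfaceDistance
from .frames import KneeSide, LandmarkSet
from .planning import Ligament, Tunnel
from .registration import RigidTransform

__all__ = ["FemurParams", "FemurModel", "generate_femur", "make_postop"]

_FOOTPRINT_SURFACE_TOL = 1.0  # mm


class MeshGenerationError(RuntimeError):
    """Polygonization produced a non-watertight or non-manifold mesh."""


@dataclass(frozen=True)
class FemurParams:
    """Geometry of the primitive-blend femur, mm at size_scale=1."""

    size_scale: float = 1.0
    condyle_center_x: float = 21.0  # +/- lateral/medial condyle centers
    condyle_semi_axes: tuple[float, float, float] = (19.0, 24.0, 21.0)
    condyle_center_y: float = -4.0
    condyle_center_z: float = 4.0
    trochlea_center: tuple[float, float, float] = (0.0, 6.0, 8.0)
    trochlea_semi_axes: tuple[float, float, float] = (16.0, 20.0, 16.0)
    shaft_radius: float = 15.0
    shaft_z_range: tuple[float, float] = (18.0, 95.0)
    blend_mm: float = 6.0  # smooth-union radius
    pitch_mm: float = 1.25  # marching-cubes grid spacing
    shape_jitter: float = 0.03  # relative sd of seeded condylar jitter

    def __post_init__(self) -> None:
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")
        if self.pitch_mm <= 0 or self.blend_mm <= 0:
            raise ValueError("pitch and blend must be positive")


@dataclass
class FemurModel:
    """Triangle mesh + named ligament footprints + frame landmarks."""

    mesh: trimesh.Trimesh
    footprints: dict[Ligament, np.ndarray]
    landmarks: LandmarkSet
    size_scale: float
    knee_side: KneeSide = KneeSide.RIGHT

    def __post_init__(self) -> None:
        self.knee_side = KneeSide(self.knee_side)
        self.footprints = {
            Ligament(k): np.asarray(v, dtype=float) for k, v in self.footprints.items()
        }
        if not self.mesh.is_watertight:
            raise MeshGenerationError(
                f"mesh is not watertight ({len(self.mesh.vertices)} vertices, "
                f"{len(self.mesh.faces)} faces)"
            )
        surf = SurfaceDistance(self.mesh)
        for lig, p in self.footprints.items():
            d = float(surf.query(p[None, :])[0][0])
            if d > _FOOTPRINT_SURFACE_TOL:
                raise ValueError(
                    f"{lig.value} footprint lies {d:.2f} mm off the surface "
                    f"(limit {_FOOTPRINT_SURFACE_TOL} mm)"
                )

    def surface(self) -> SurfaceDistance:
        return SurfaceDistance(self.mesh)

    def transformed(self, transform: RigidTransform) -> "FemurModel":
        return FemurModel(
            mesh=trimesh.Trimesh(
                vertices=transform.apply_points(self.mesh.vertices),
                faces=self.mesh.faces.copy(),
                process=False,
            ),
            footprints={
                lig: transform.apply_points(p) for lig, p in self.footprints.items()
            },
            landmarks=self.landmarks.transformed(
                transform.rotation, transform.translation
            ),
            size_scale=self.size_scale,
            knee_side=self.knee_side,
        )

    # ---- file IO: binary STL + JSON sidecar -------------------------------
    def save(self, stl_path: str | Path) -> None:
        stl_path = Path(stl_path)
        self.mesh.export(stl_path)
        sidecar = {
            **self.landmarks.to_dict(),
            "footprints": {lig.value: p.tolist() for lig, p in self.footprints.items()},
            "size_scale": self.size_scale,
            "knee_side": self.knee_side.value,
        }
        stl_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stl_path: str | Path) -> "FemurModel":
        stl_path = Path(stl_path)
        # STL stores a triangle soup; merging duplicate vertices restores the
        # shared-vertex manifold the watertightness check needs
        mesh = trimesh.load_mesh(stl_path, process=True)
        d = json.loads(stl_path.with_suffix(".json").read_text())
        return cls(
            mesh=mesh,
            footprints={Ligament(k): v for k, v in d["footprints"].items()},
            landmarks=LandmarkSet.from_dict(d),
            size_scale=d.get("size_scale", 1.0),
            knee_side=d.get("knee_side", "right"),
        )


def _ellipsoid_sdf(pts: np.ndarray, center, semi) -> np.ndarray:
    # scaled-radial approximation; exact enough for blending at these scales
    q = (pts - np.asarray(center)) / np.asarray(semi)
    return (np.linalg.norm(q, axis=1) - 1.0) * float(min(semi))


def _capped_cylinder_sdf(pts: np.ndarray, radius, z0, z1) -> np.ndarray:
    radial = np.linalg.norm(pts[:, :2], axis=1) - radius
    zc = 0.5 * (z0 + z1)
    axial = np.abs(pts[:, 2] - zc) - 0.5 * (z1 - z0)
    outside = np.sqrt(np.maximum(radial, 0.0) ** 2 + np.maximum(axial, 0.0) ** 2)
    inside = np.minimum(np.maximum(radial, axial), 0.0)
    return outside + inside


def _smooth_min(fields: list[np.ndarray], k: float) -> np.ndarray:
    F = np.stack(fields, axis=0) / k
    m = F.min(axis=0)
    return (m - np.log(np.exp(-(F - m)).sum(axis=0))) * k


def generate_femur(params: FemurParams = FemurParams(), seed: int = 0) -> FemurModel:
    """Deterministically generate one synthetic distal femur.

    The seed drives only the per-specimen condylar jitter; the same
    (params, seed) pair reproduces bit-identical vertex arrays.  Scaling
    ``size_scale`` rescales the finished model exactly (similarity), so
    landmark distances scale linearly.

    Raises
    ------
    MeshGenerationError
        If polygonization does not yield a watertight manifold.
    """
    p = params
    rng = np.random.default_rng(seed)
    jit = 1.0 + p.shape_jitter * rng.standard_normal(8)

    lat_center = np.array(
        [p.condyle_center_x * jit[0], p.condyle_center_y * jit[1], p.condyle_center_z]
    )
    med_center = np.array(
        [-p.condyle_center_x * jit[2], p.condyle_center_y * jit[3], p.condyle_center_z]
    )
    lat_semi = np.asarray(p.condyle_semi_axes) * jit[4]
    med_semi = np.asarray(p.condyle_semi_axes) * jit[5]
    tro_center = np.asarray(p.trochlea_center, dtype=float)
    tro_semi = np.asarray(p.trochlea_semi_axes) * jit[6]
    shaft_r = p.shaft_radius * jit[7]
    z0, z1 = p.shaft_z_range

    margin = 3.0 * p.blend_mm + 2.0 * p.pitch_mm
    lo = np.array(
        [
            med_center[0] - med_semi[0],
            min(p.condyle_center_y - lat_semi[1], -shaft_r),
            p.condyle_center_z - lat_semi[2],
        ]
    ) - margin
    hi = np.array(
        [
            lat_center[0] + lat_semi[0],
            max(tro_center[1] + tro_semi[1], shaft_r),
            z1,
        ]
    ) + margin

    xs = np.arange(lo[0], hi[0] + p.pitch_mm, p.pitch_mm)
    ys = np.arange(lo[1], hi[1] + p.pitch_mm, p.pitch_mm)
    zs = np.arange(lo[2], hi[2] + p.pitch_mm, p.pitch_mm)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)

    sdf = _smooth_min(
        [
            _ellipsoid_sdf(pts, lat_center, lat_semi),
            _ellipsoid_sdf(pts, med_center, med_semi),
            _ellipsoid_sdf(pts, tro_center, tro_semi),
            _capped_cylinder_sdf(pts, shaft_r, z0, z1),
        ],
        p.blend_mm,
    ).reshape(grid.shape[:3])

    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=(p.pitch_mm,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not mesh.is_watertight:
        raise MeshGenerationError(
            "marching cubes produced a non-watertight surface: "
            f"{len(mesh.vertices)} vertices, {len(mesh.faces)} faces, "
            f"euler={mesh.euler_number}"
        )

    surf = SurfaceDistance(mesh)
    lat_tip = lat_center + np.array([lat_semi[0], 0.0, 0.0])
    med_tip = med_center - np.array([med_semi[0], 0.0, 0.0])
    # footprint seeds at epicondylar offsets; the PT footprint lies
    # anterior-distal to the LCL footprint at the ~18.5 mm separation anatomic
    # studies report (projection shrinks the raw offset, hence the overshoot);
    # the POL sits posterior-proximal to the MCL
    seeds = {
        Ligament.LCL: lat_tip,
        Ligament.PT: lat_tip + np.array([-2.0, 15.5, -15.5]),
        Ligament.MCL: med_tip,
        Ligament.POL: med_tip + np.array([1.0, -10.0, 7.0]),
    }
    footprints = {lig: surf.project(seed_pt) for lig, seed_pt in seeds.items()}

    landmarks = LandmarkSet(
        medial_epicondyle=med_tip,
        lateral_epicondyle=lat_tip,
        shaft_axis_point_distal=np.array([0.0, 0.0, z0 + 10.0]),
        shaft_axis_point_proximal=np.array([0.0, 0.0, z1 - 5.0]),
        most_anterior_trochlea=tro_center + np.array([0.0, tro_semi[1], 0.0]),
    )

    s = p.size_scale
    if s != 1.0:
        mesh = trimesh.Trimesh(vertices=mesh.vertices * s, faces=faces, process=False)
        footprints = {lig: fp * s for lig, fp in footprints.items()}
        landmarks = LandmarkSet(
            **{name: getattr(landmarks, name) * s for name in landmarks.__dataclass_fields__}
        )

    return FemurModel(
        mesh=mesh, footprints=footprints, landmarks=landmarks, size_scale=s
    )


def make_postop(
    model: FemurModel,
    achieved: list[Tunnel],
    transform: RigidTransform,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FemurModel, list[Tunnel]]:
    """Simulate the post-operative scan of a drilled femur.

    Mesh vertices are rigidly transformed and then perturbed by isotropic
    Gaussian noise of sd ``noise_sd`` (mm); footprints, landmarks and the
    achieved tunnels are carried through the rigid transform only (tunnels
    are geometric annotations, not re-measured surface points).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    moved = model.transformed(transform)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = moved.mesh.vertices + rng.normal(0.0, noise_sd, moved.mesh.vertices.shape)
        moved = FemurModel(
            mesh=trimesh.Trimesh(vertices=noisy, faces=moved.mesh.faces, process=False),
            footprints=moved.footprints,
            landmarks=moved.landmarks,
            size_scale=moved.size_scale,
            knee_side=moved.knee_side,
        )
    from .registration import apply as _apply

    return moved, [_apply(transform, t) for t in achieved]
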