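"""Quartile-calibrated simulation of surgical execution error.

The study design being emulated reports, per ligament and per technique
(freehand control vs. PSI-guided), the median and interquartile range of two
error magnitudes: angular deviation (degrees) and entry-point distance (mm).
This module turns those summaries into a generative model:

* each (group, ligament, outcome) cell is a **log-normal** magnitude
  distribution — strictly positive and exactly identified by (median, Q1,
  Q3): ``mu = ln(median)``, ``sigma = ln(Q3/Q1) / (2 z_0.75)``;
* a drawn angular magnitude tilts the planned direction away from its axis
  at a uniformly random azimuth (cone model); a drawn entry magnitude slides
  the entry point along a uniformly random surface-tangent direction and
  re-projects it onto the bone.

Angular and entry errors are drawn independently, and independently across
the four tunnels of a knee (no correlation structure is known for the
emulated protocol).  ``simulate_study`` runs the whole pipeline — generate
femur, plan, perturb, displace the "post-operative" bone, register it back
by ICP, measure — and keeps the injected ground-truth errors alongside the
measured ones so recovery can be asserted end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .accuracy import Group, angular_deviation, entry_distance, evaluate_knee, records_to_frame
from .frames import Side, build_frame
from .planning import DEFAULT_SPECS, Ligament, Tunnel, plan_knee
from .registration import RigidTransform, icp
from .synthetic_femur import FemurModel, FemurParams, generate_femur, make_postop

__all__ = [
    "QuartileSpec",
    "ErrorModel",
    "calibrate_lognormal",
    "sample_magnitudes",
    "perturb_tunnel",
    "simulate_study",
]

_Z75 = float(norm.ppf(0.75))  # 0.674490


@dataclass(frozen=True)
class QuartileSpec:
    """Median and quartiles of a sample or distribution.

    Also the summary container returned by descriptive statistics; only the
    log-normal calibration below additionally requires positive quartiles.
    """

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("need q1 <= median <= q3")


def calibrate_lognormal(spec: QuartileSpec) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with exactly the spec's median and IQR.

    ``mu = ln(median)``; ``sigma = ln(q3/q1) / (2 z_0.75)``.  A degenerate
    spec (q1 == q3) yields sigma = 0, i.e. a point mass at the median.
    """
    if spec.q1 == spec.q3:  # point mass at the median
        return (float(np.log(spec.median)) if spec.median > 0 else -np.inf, 0.0)
    if spec.q1 <= 0:
        raise ValueError("log-normal calibration needs q1 > 0")
    return float(np.log(spec.median)), float(np.log(spec.q3 / spec.q1) / (2.0 * _Z75))


def sample_magnitudes(spec: QuartileSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Draw magnitudes from the calibrated distribution for ``spec``."""
    if spec.q1 == spec.q3:
        return np.full(size, spec.median, dtype=float)
    mu, sigma = calibrate_lognormal(spec)
    return np.exp(mu + sigma * rng.standard_normal(size))


class ErrorModel:
    """Per-(group, ligament) quartile specs for angular and entry error."""

    def __init__(
        self,
        table: Mapping[tuple[Group, Ligament], Mapping[str, QuartileSpec]],
    ):
        self._table = {
            (Group(g), Ligament(l)): {
                "angular": cell["angular"],
                "entry": cell["entry"],
            }
            for (g, l), cell in table.items()
        }

    def spec(self, group: Group | str, ligament: Ligament | str, outcome: str) -> QuartileSpec:
        if outcome not in ("angular", "entry"):
            raise KeyError(f"unknown outcome {outcome!r}")
        return self._table[(Group(group), Ligament(ligament))][outcome]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ErrorModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "ErrorModel":
        table = {}
        for g, ligs in raw.items():
            for l, cell in ligs.items():
                table[(Group(g), Ligament(l))] = {
                    k: QuartileSpec(cell[k]["median"], cell[k]["q1"], cell[k]["q3"])
                    for k in ("angular", "entry")
                }
        return cls(table)

    @classmethod
    def default(cls) -> "ErrorModel":
        """The packaged study-default quartiles."""
        raw = yaml.safe_load(
            resources.files("psitunnel.data")
            .joinpath("error_model_defaults.yaml")
            .read_text()
        )
        return cls._from_raw(raw)


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing d to an orthonormal triad."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def perturb_tunnel(
    planned: Tunnel,
    model: ErrorModel,
    group: Group | str,
    rng: np.random.Generator,
    surface=None,
) -> Tunnel:
    """Draw one executed tunnel from the error model.

    The direction is tilted off the planned axis by a drawn angular magnitude
    at a uniform azimuth; the entry point is displaced by a drawn magnitude
    along a uniform tangent direction and, when a surface is supplied,
    re-projected onto the bone.  Diameter and depth are untouched.
    """
    group = Group(group)
    ang_spec = model.spec(group, planned.ligament, "angular")
    ent_spec = model.spec(group, planned.ligament, "entry")

    theta = np.radians(float(sample_magnitudes(ang_spec, (), rng)))
    u, v = _orthonormal_basis(planned.direction)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    direction = (
        np.cos(theta) * planned.direction
        + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
    )

    m = float(sample_magnitudes(ent_spec, (), rng))
    if surface is not None:
        _, _, tri = surface.query(planned.entry[None, :])
        # tangent plane from the nearest face normal
        tri_pts = surface._tri[tri[0]]
        n = np.cross(tri_pts[1] - tri_pts[0], tri_pts[2] - tri_pts[0])
        n /= np.linalg.norm(n)
        tu, tv = _orthonormal_basis(n)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        tangent = np.cos(psi) * tu + np.sin(psi) * tv
        entry = surface.project(planned.entry + m * tangent)
    else:
        tu, tv = _orthonormal_basis(planned.direction)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        entry = planned.entry + m * (np.cos(psi) * tu + np.sin(psi) * tv)

    return Tunnel(
        entry=entry,
        direction=direction,
        diameter_mm=planned.diameter_mm,
        depth_mm=planned.depth_mm,
        ligament=planned.ligament,
    )


def _random_repositioning(rng: np.random.Generator) -> RigidTransform:
    """Rigid displacement between the two scans: rotation <=15 deg, shift <=10 mm."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(5.0, 15.0)
    shift = rng.uniform(-10.0, 10.0, 3)
    return RigidTransform.from_axis_angle(axis, angle, shift)


def simulate_study(
    n_knees_per_group: int = 5,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    femur_params: FemurParams | None = None,
    noise_sd: float = 0.0,
    icp_sample_size: int = 2000,
    icp_max_iter: int = 200,
    icp_tol_mm: float = 1e-4,
) -> pd.DataFrame:
    """Run the full in-silico study and return the tidy record table.

    Per knee: generate a femur (seeded shape jitter), plan the four default
    tunnels, draw executed tunnels from the error model, manufacture the
    displaced (optionally noised) post-operative mesh, register it back onto
    the pre-operative mesh by ICP, and measure angular deviation and
    entry-point distance of the re-mapped achieved tunnels against the plan.

    The returned frame carries the measured metrics plus the injected
    ground-truth errors (``injected_angular_deg``, ``injected_entry_mm``)
    and the registration residual per knee.  Deterministic given ``seed``.
    """
    if n_knees_per_group < 1:
        raise ValueError("need at least one knee per group")
    error_model = error_model or ErrorModel.default()
    femur_params = femur_params or FemurParams()

    master = np.random.default_rng(seed)
    knee_seeds = master.integers(0, 2**31 - 1, size=2 * n_knees_per_group)

    rows = []
    knee_index = 0
    for group in (Group.FREEHAND, Group.PSI):
        for i in range(n_knees_per_group):
            knee_seed = int(knee_seeds[knee_index])
            knee_id = f"{group.value}-{i + 1:02d}"
            rng = np.random.default_rng(knee_seed)

            model = generate_femur(femur_params, seed=knee_seed)
            frames = {
                side: build_frame(model.landmarks, side, model.knee_side)
                for side in (Side.LATERAL, Side.MEDIAL)
            }
            planned = plan_knee(model, DEFAULT_SPECS, frames)

            surface = model.surface()
            achieved = [
                perturb_tunnel(t, error_model, group, rng, surface) for t in planned
            ]
            injected = [
                (angular_deviation(p, a), entry_distance(p, a))
                for p, a in zip(planned, achieved)
            ]

            reposition = _random_repositioning(rng)
            postop, achieved_displaced = make_postop(
                model, achieved, reposition, noise_sd=noise_sd, seed=knee_seed
            )
            reg = icp(
                postop.mesh,
                model.mesh,
                sample_size=icp_sample_size,
                max_iter=icp_max_iter,
                tol_mm=icp_tol_mm,
                seed=knee_seed,
            )
            records = evaluate_knee(planned, achieved_displaced, reg, group, knee_id)

            for rec, (inj_ang, inj_ent) in zip(records, injected):
                rows.append(
                    {
                        "knee_id": rec.knee_id,
                        "group": rec.group.value,
                        "ligament": rec.ligament.value,
                        "angular_deviation_deg": rec.angular_deviation_deg,
                        "entry_distance_mm": rec.entry_distance_mm,
                        "injected_angular_deg": inj_ang,
                        "injected_entry_mm": inj_ent,
                        "registration_mean_distance_mm": reg.mean_distance_mm,
                        "registration_iterations": reg.iterations,
                    }
                )
            knee_index += 1
    return pd.DataFrame(rows)
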