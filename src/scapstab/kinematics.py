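"""Bone coordinate systems and glenohumeral pose generation.

Conventions (right shoulder): the x-axis points laterally, y superiorly,
z posteriorly; anterior is -z. Glenohumeral orientation uses a Y-Z-Y Euler
sequence -- elevation plane, abduction, axial rotation -- where a positive
elevation plane is anterior to the scapular plane and positive axial
rotation is *internal*; the customary 50 degrees of external rotation in
a "full-can" abduction is therefore encoded as axial = -50.

The humeral placement here is deliberately simple: the head centre sits on
the glenoid-centre normal at ``head_radius + gap`` so the joint stays
congruent at every pose, and feasibility over the rotational range of
motion is judged with an analytic impingement model (glenoid slab plus
acromial/coracoid obstacle spheres against humeral test points). The
kinematic neutral pose is the centroid of the feasible Euler grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .landmarks import LandmarkConfiguration
from .synthgen import BoneSet

__all__ = [
    "BodyFrame",
    "Pose",
    "KinematicPath",
    "scapula_frame",
    "humerus_frame",
    "yzy_to_matrix",
    "matrix_to_yzy",
    "base_path",
    "perturb_path",
    "place_humerus",
    "neutral_pose",
    "GimbalLockWarning",
]

_RIM_NAMES = [
    "glenoid_rim_superior", "glenoid_rim_posterosuperior", "glenoid_rim_posterior",
    "glenoid_rim_posteroinferior", "glenoid_rim_inferior",
    "glenoid_rim_anteroinferior", "glenoid_rim_anterior", "glenoid_rim_anterosuperior",
]
_BLADE_NAMES = [
    "medial_border_superior", "medial_border_mid", "medial_border_inferior",
    "inferior_angle", "blade_center",
]


class GimbalLockWarning(UserWarning):
    """Raised to the user when a YZY decomposition is not unique."""


@dataclass
class BodyFrame:
    """Right-handed orthonormal body frame (columns: x lateral, y superior, z posterior)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns x, y, z

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if np.max(np.abs(self.axes.T @ self.axes - np.eye(3))) > 1e-10:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed (mirrored input?)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


def _get(landmarks, name: str) -> np.ndarray:
    try:
        if isinstance(landmarks, LandmarkConfiguration):
            return landmarks[name]
        return np.asarray(landmarks[name], dtype=float)
    except (KeyError, ValueError):
        raise KeyError(f"missing required landmark: {name!r}") from None


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane; raises if points are collinear."""
    c = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane normal undefined")
    return vt[-1]


def scapula_frame(landmarks) -> BodyFrame:
    """Scapular body frame from named landmarks.

    y runs along the medial border (inferior to superior), z is the blade
    plane normal oriented posteriorly (using the scapular spine, which lies
    posterior to the blade), and x = y cross z points laterally. The origin
    is the glenoid rim centroid. Mirrored (left-handed) input is rejected.
    """
    y = _get(landmarks, "medial_border_superior") - _get(landmarks, "medial_border_inferior")
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("medial border landmarks are coincident")
    y = y / ny
    blade = np.array([_get(landmarks, n) for n in _BLADE_NAMES])
    n = _fit_plane_normal(blade)
    if np.dot(_get(landmarks, "spine_lateral") - _get(landmarks, "blade_center"), n) < 0:
        n = -n
    z = n - np.dot(n, y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("blade normal is parallel to the medial border")
    z = z / nz
    x = np.cross(y, z)
    origin = np.mean([_get(landmarks, nm) for nm in _RIM_NAMES], axis=0)
    if np.dot(origin - _get(landmarks, "blade_center"), x) < 0:
        raise ValueError("glenoid lies medial to the blade: mirrored (left-handed) input")
    return BodyFrame(origin=origin, axes=np.column_stack([x, y, z]))


def humerus_frame(landmarks) -> BodyFrame:
    """ISB-style humeral frame: y along the shaft (elbow to head), plane by the epicondylar axis."""
    head = _get(landmarks, "head_center")
    lat = _get(landmarks, "lateral_epicondyle")
    med = _get(landmarks, "medial_epicondyle")
    mid = 0.5 * (lat + med)
    y = head - mid
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("head centre coincides with the epicondyle midpoint")
    y = y / ny
    e = lat - med
    x = e - np.dot(e, y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("epicondylar axis is parallel to the shaft")
    x = x / nx
    z = np.cross(x, y)
    return BodyFrame(origin=head, axes=np.column_stack([x, y, z]))


def yzy_to_matrix(plane: float, abduction: float, axial: float) -> np.ndarray:
    """Rotation matrix R = Ry(plane) Rz(abduction) Ry(axial), angles in degrees."""
    return Rotation.from_euler("YZY", [plane, abduction, axial], degrees=True).as_matrix()


def matrix_to_yzy(R: np.ndarray, gimbal_tol_deg: float = 1e-6) -> np.ndarray:
    """Recover (plane, abduction, axial) degrees in the canonical branch.

    Abduction is returned in (0, 180); poses with abduction within
    ``gimbal_tol_deg`` of 0 or 180 are degenerate (only plane+axial or
    plane-axial is determined) and raise :class:`GimbalLockWarning`.
    """
    R = np.asarray(R, dtype=float)
    angles = Rotation.from_matrix(R).as_euler("YZY", degrees=True)
    if min(abs(angles[1]), abs(180.0 - abs(angles[1]))) < gimbal_tol_deg:
        warnings.warn(
            "YZY decomposition is not unique at abduction ~ 0 or 180 degrees",
            GimbalLockWarning, stacklevel=2,
        )
    return angles


@dataclass
class Pose:
    """One glenohumeral rotational pose (degrees) with optional placement."""

    elevation_plane: float
    abduction: float
    axial_rotation: float
    humerus_transform: np.ndarray | None = None  # 4x4 scapula <- humerus

    def rotation(self) -> np.ndarray:
        return yzy_to_matrix(self.elevation_plane, self.abduction, self.axial_rotation)


@dataclass
class KinematicPath:
    """Ordered sequence of poses with strictly increasing abduction."""

    poses: list[Pose]
    label: str = "base"

    def __post_init__(self) -> None:
        abd = [p.abduction for p in self.poses]
        if any(b <= a for a, b in zip(abd, abd[1:])):
            raise ValueError("abduction must be strictly increasing along a path")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


def base_path(scapular_plane_offset: float = 5.0, external_rotation: float = 50.0) -> KinematicPath:
    """Standardized abduction path: 10-100 degrees at 5-degree increments.

    The elevation plane sits ``scapular_plane_offset`` degrees anterior to
    the scapular plane and the humerus is externally rotated by
    ``external_rotation`` degrees (axial = -external_rotation under the
    internal-positive convention), at every pose.
    """
    poses = [
        Pose(elevation_plane=scapular_plane_offset, abduction=float(a),
             axial_rotation=-external_rotation)
        for a in range(10, 101, 5)
    ]
    return KinematicPath(poses=poses, label="base")


def perturb_path(path: KinematicPath, d_plane: float = 0.0, d_axial: float = 0.0) -> KinematicPath:
    """Add constant elevation-plane / axial-rotation offsets to every pose.

    Positive ``d_plane`` shifts the path anteriorly; positive ``d_axial``
    adds internal rotation. Abduction is untouched, so perturbations
    compose additively and invert exactly.
    """
    poses = [
        Pose(elevation_plane=p.elevation_plane + d_plane, abduction=p.abduction,
             axial_rotation=p.axial_rotation + d_axial)
        for p in path
    ]
    label = "base" if d_plane == 0.0 and d_axial == 0.0 and path.label == "base" \
        else f"perturbed(dplane={d_plane:+g}, daxial={d_axial:+g})"
    return KinematicPath(poses=poses, label=label)


# ---------------------------------------------------------------------------
# humeral placement and range-of-motion feasibility

_SLAB_CLEARANCE = 2.0
_SLAB_MARGIN = 4.0
_TEST_POINT_RADIUS = 1.5
_SHAFT_SAMPLE_T = np.array([30.0, 45.0, 60.0, 75.0, 90.0])
_SHAFT_POINT_RADIUS = 11.0


def _humerus_test_points(bones: BoneSet) -> tuple[np.ndarray, np.ndarray]:
    """Humerus-local collision test points and their effective radii."""
    r = bones.head_radius
    pts = [1.05 * r * d for d in bones.humerus_collision_dirs]
    radii = [_TEST_POINT_RADIUS] * len(pts)
    for t in _SHAFT_SAMPLE_T:
        pts.append(np.array([0.0, -t, 0.0]))
        radii.append(_SHAFT_POINT_RADIUS)
    return np.array(pts), np.array(radii)


def _head_position(bones: BoneSet, gap: float) -> np.ndarray:
    return bones.glenoid_center + (bones.head_radius + gap) * bones.glenoid_normal


def _infeasible_mask(bones: BoneSet, rotations: np.ndarray, gap: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized impingement test. Returns (infeasible mask, max penetration)."""
    pts, radii = _humerus_test_points(bones)
    pos = _head_position(bones, gap)
    world = np.einsum("mij,pj->mpi", rotations, pts) + pos  # (M, P, 3)

    c, n = bones.glenoid_center, bones.glenoid_normal
    rel = world - c
    s = rel @ n
    inplane = np.linalg.norm(rel - s[..., None] * n, axis=-1)
    slab_radius = max(bones.params.glenoid_semi_axes) + _SLAB_MARGIN
    slab_pen = (_SLAB_CLEARANCE + radii) - s
    slab_hit = (slab_pen > 0) & (inplane < slab_radius + radii)
    pen = np.where(slab_hit, slab_pen, 0.0).max(axis=1)

    for oc, orad in bones.obstacle_spheres:
        d = np.linalg.norm(world - oc, axis=-1)
        sph_pen = (orad + radii) - d
        pen = np.maximum(pen, sph_pen.max(axis=1))
    return pen > 0.0, pen


def place_humerus(
    bones: BoneSet,
    pose: Pose,
    gap: float = 1.0,
    frame: BodyFrame | None = None,
    check: bool = True,
) -> np.ndarray:
    """Rigid transform (4x4) placing the humerus for a rotational pose.

    The head centre is put on the glenoid-centre normal at
    ``head_radius + gap`` (so its distance to the glenoid plane is exactly
    that), with orientation from the YZY pose expressed in the scapular
    frame (identity for the canonical synthetic construct). With
    ``check=True`` the analytic impingement model is evaluated and
    interpenetration raises with the maximum penetration depth.
    """
    axes = np.eye(3) if frame is None else frame.axes
    R = axes @ pose.rotation()
    if check:
        bad, pen = _infeasible_mask(bones, R[None], gap)
        if bad[0]:
            raise ValueError(
                f"humerus interpenetrates the scapula at this pose "
                f"(max penetration {pen[0]:.2f} mm)"
            )
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = _head_position(bones, gap)
    return T


@dataclass
class RomGrid:
    """Euler grid bounds (degrees) for the range-of-motion scan."""

    plane: tuple[float, float] = (-60.0, 90.0)
    abduction: tuple[float, float] = (10.0, 140.0)
    axial: tuple[float, float] = (-90.0, 90.0)
    spacing: float = 10.0

    def axis(self, lo: float, hi: float) -> np.ndarray:
        n = int(round((hi - lo) / self.spacing))
        return lo + self.spacing * np.arange(n + 1)


def neutral_pose(
    bones: BoneSet,
    grid: RomGrid | None = None,
    gap: float = 1.0,
    return_feasible: bool = False,
):
    """Kinematic neutral pose: centroid of the feasible rotational range of motion.

    Scans the Euler grid, marks poses passing the impingement test, and
    returns the centroid (plane, abduction, axial) of the feasible triples.
    """
    grid = grid or RomGrid()
    planes = grid.axis(*grid.plane)
    abds = grid.axis(*grid.abduction)
    axials = grid.axis(*grid.axial)
    mesh = np.array(np.meshgrid(planes, abds, axials, indexing="ij"))
    triples = mesh.reshape(3, -1).T
    rotations = Rotation.from_euler("YZY", triples, degrees=True).as_matrix()
    bad, _ = _infeasible_mask(bones, rotations, gap)
    feasible = triples[~bad]
    if len(feasible) == 0:
        raise ValueError("no feasible pose in the range-of-motion grid")
    centroid = tuple(feasible.mean(axis=0))
    if return_feasible:
        return centroid, feasible
    return centroid


def path_to_frame(path: KinematicPath) -> "pd.DataFrame":  # noqa: F821
    """Path as a table (pose index, angles, flattened 3x4 transform)."""
    import pandas as pd  # noqa: PLC0415

    rows = []
    for i, p in enumerate(path):
        row = {
            "pose": i,
            "elevation_plane": p.elevation_plane,
            "abduction": p.abduction,
            "axial_rotation": p.axial_rotation,
        }
        T = p.humerus_transform
        if T is None:
            T = np.eye(4)
        for r in range(3):
            for cidx in range(4):
                row[f"T{r}{cidx}"] = T[r, cidx]
        rows.append(row)
    return pd.DataFrame(rows)
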