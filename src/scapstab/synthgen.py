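"""Synthetic landmark cohorts and parametric bone geometry.

The cohorts the original shape analysis was built on (CT-segmented
scapulae) are not redistributable, so this module generates stand-in data
with *known* ground truth:

* two groups of 29-landmark configurations sharing the packaged template,
  where the tear (FTT) group receives a known displacement field (the
  "effect vector") plus isotropic landmark noise and optional nuisance
  similarity transforms;
* parametric bone geometry (ellipsoidal glenoid rim, spherical humeral
  head with shaft, supraspinous-fossa origin patch, greater-tuberosity
  insertion patch) whose version/inclination/width parameters are exact by
  construction, giving every downstream stage an oracle.

The default effect vector bundles the qualitative tear-associated suite:
a narrower supraspinous fossa, an anteverted and more superiorly inclined
glenoid, a slightly smaller glenoid face, a more lateral acromion with a
narrower anteroposterior span, and a cranially shifted spine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .landmarks import (
    CONTROL,
    FTT,
    LANDMARK_NAMES,
    LandmarkConfiguration,
    landmark_index,
    template_coords,
)

__all__ = [
    "SynthConfig",
    "BoneParams",
    "BoneSet",
    "default_effect_vector",
    "generate_landmark_sample",
    "generate_bone_geometry",
    "write_meshes",
]


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_RIM_NAMES = [n for n in LANDMARK_NAMES if n.startswith("glenoid_rim_")]
_FOSSA_NAMES = ["fossa_medial", "fossa_anterior", "fossa_lateral", "fossa_posterior"]


def default_effect_vector(
    version_deg: float = 6.0,
    inclination_deg: float = 2.0,
    glenoid_shrink: float = 0.965,
    fossa_narrowing: float = 0.8,
    acromion_lateral_shift: float = 2.0,
    acromion_narrowing: float = 0.85,
) -> np.ndarray:
    """Displacement field (29x3) carrying the tear-associated shape suite.

    At unit effect scale the glenoid face is anteverted by ``version_deg``
    and superiorly inclined by ``inclination_deg`` (rotations of the rim
    about its centroid), the rim is shrunk in-plane by ``glenoid_shrink``,
    the fossa anteroposterior extent is multiplied by ``fossa_narrowing``,
    the lateral acromion shifts laterally and the acromial AP span
    contracts by ``acromion_narrowing``.
    """
    base = template_coords()
    ftt = base.copy()

    rim_idx = [landmark_index(n) for n in _RIM_NAMES]
    glen_idx = rim_idx + [landmark_index("supraglenoid_tubercle"),
                          landmark_index("infraglenoid_tubercle")]
    centroid = base[rim_idx].mean(axis=0)
    rot = _rot_y(version_deg) @ _rot_z(inclination_deg)
    # shrink the rim in its own plane, then tilt the whole glenoid block
    ftt[rim_idx] = centroid + (base[rim_idx] - centroid) * glenoid_shrink
    ftt[glen_idx] = centroid + (ftt[glen_idx] - centroid) @ rot.T

    fossa_idx = [landmark_index(n) for n in _FOSSA_NAMES]
    z_mid = base[fossa_idx, 2].mean()
    ftt[fossa_idx, 2] = z_mid + (base[fossa_idx, 2] - z_mid) * fossa_narrowing

    ftt[landmark_index("acromion_lateral"), 0] += acromion_lateral_shift
    for n in ("acromion_anterior", "acromion_posterior"):
        i = landmark_index(n)
        ftt[i, 2] *= acromion_narrowing
    ftt[landmark_index("coracoid_tip")] += np.array([0.8, -1.2, -1.2])
    for n in ("spine_lateral", "spine_medial"):
        ftt[landmark_index(n), 1] += 1.0

    return ftt - base


@dataclass
class SynthConfig:
    """Configuration for a synthetic two-group landmark cohort.

    ``effect_vector`` is expressed in template units (mm); the FTT group is
    ``template + effect_scale * effect_vector`` before noise and nuisance
    transforms. With ``effect_scale == 0`` the groups are exchangeable by
    construction.
    """

    n_control: int = 91
    n_ftt: int = 24
    effect_vector: np.ndarray = field(default_factory=default_effect_vector)
    effect_scale: float = 1.0
    # landmark-level scatter: digitization error plus a proxy for
    # interindividual shape variation, isotropic per coordinate (mm)
    noise_sd: float = 1.5
    nuisance: frozenset[str] = frozenset({"rotation", "translation", "scale"})
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_vector = np.asarray(self.effect_vector, dtype=float)
        if self.n_control < 1 or self.n_ftt < 1:
            raise ValueError("group counts must be >= 1")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_vector.shape != (29, 3):
            raise ValueError("effect_vector must be 29x3")
        unknown = set(self.nuisance) - {"rotation", "translation", "scale"}
        if unknown:
            raise ValueError(f"unknown nuisance transforms: {sorted(unknown)}")


def _nuisance_transform(coords: np.ndarray, kinds: frozenset[str], rng: np.random.Generator) -> np.ndarray:
    out = coords
    if "scale" in kinds:
        # log-uniform in [0.8, 1.25]: symmetric about 1 on the log scale
        s = float(np.exp(rng.uniform(np.log(0.8), np.log(1.25))))
        out = out * s
    if "rotation" in kinds:
        rot = Rotation.random(rng=rng).as_matrix()
        out = out @ rot.T
    if "translation" in kinds:
        out = out + rng.uniform(-50.0, 50.0, size=3)
    return out


def generate_landmark_sample(config: SynthConfig) -> list[LandmarkConfiguration]:
    """Generate a labelled cohort of landmark configurations.

    Controls are ``template + noise``; FTT specimens additionally receive
    ``effect_scale * effect_vector`` before noise. Nuisance similarity
    transforms (if enabled) are applied last, per specimen. Fully
    deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = template_coords()
    configs: list[LandmarkConfiguration] = []
    for group, count in ((CONTROL, config.n_control), (FTT, config.n_ftt)):
        shift = config.effect_scale * config.effect_vector if group == FTT else 0.0
        for i in range(count):
            coords = base + shift + config.noise_sd * rng.standard_normal((29, 3))
            coords = _nuisance_transform(coords, config.nuisance, rng)
            tag = "ctrl" if group == CONTROL else "ftt"
            configs.append(
                LandmarkConfiguration(coords, specimen_id=f"{tag}_{i:03d}", group=group)
            )
    return configs


# ---------------------------------------------------------------------------
# parametric bone geometry


@dataclass
class BoneParams:
    """Parameters of the synthetic glenohumeral construct (mm, degrees)."""

    glenoid_semi_axes: tuple[float, float] = (16.0, 12.0)  # (SI, AP)
    version_deg: float = 0.0          # anterior tilt of the glenoid face, positive
    inclination_deg: float = 0.0      # superior tilt of the glenoid face, positive
    fossa_width_factor: float = 1.0   # multiplies the fossa AP half-width
    head_radius: float = 24.0
    rim_points: int = 24
    fossa_points: int = 40
    insertion_points: int = 24
    fossa_tilt_deg: float = 20.0      # fossa plane tilt: posterior edge superior
    include_coracoid: bool = True
    symmetric_humerus: bool = False   # drop the anterior (lesser-tuberosity) bump

    def __post_init__(self) -> None:
        if min(self.glenoid_semi_axes) <= 0:
            raise ValueError("glenoid semi-axes must be positive")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")
        if self.fossa_width_factor <= 0:
            raise ValueError("fossa_width_factor must be positive")


# humerus-local attachment/obstacle directions (unit vectors)
_GREATER_TUB_DIR = np.array([0.92, 0.38, 0.0]) / np.linalg.norm([0.92, 0.38, 0.0])
_LESSER_TUB_DIR = np.array([0.55, 0.10, -0.83]) / np.linalg.norm([0.55, 0.10, -0.83])
_INSERTION_HALF_ANGLE_DEG = 14.0
_SHAFT_RADIUS = 11.0
_SHAFT_LENGTH = 120.0

# scapular obstacle spheres (canonical frame): (center, radius)
_ACROMION_SPHERES = [
    (np.array([15.0, 29.0, -13.0]), 4.0),
    (np.array([25.0, 31.0, 0.0]), 4.0),
    (np.array([5.0, 29.0, 13.0]), 4.0),
]
_CORACOID_SPHERE = (np.array([4.0, 10.0, -22.0]), 6.0)


@dataclass
class BoneSet:
    """Synthetic bone geometry for one scapula shape.

    The scapula (mesh, rim, fossa perimeter, obstacle spheres) lives in the
    canonical scapula frame. The humerus mesh, landmarks and insertion
    perimeter live in the humerus-local frame with the head centre at the
    origin; :func:`scapstab.kinematics.place_humerus` maps them into the
    scapula frame for a given pose.
    """

    scapula_mesh: trimesh.Trimesh
    humerus_mesh: trimesh.Trimesh
    glenoid_rim: np.ndarray             # (n, 3), ordered, scapula frame
    fossa_origin_perimeter: np.ndarray  # (n, 3), ordered closed loop, scapula frame
    insertion_perimeter: np.ndarray     # (n, 3), ordered closed loop, humerus frame
    head_center: np.ndarray             # humerus frame (origin)
    head_radius: float
    glenoid_center: np.ndarray          # scapula frame
    glenoid_normal: np.ndarray          # unit, points laterally out of the face
    humerus_landmarks: dict[str, np.ndarray]
    obstacle_spheres: list[tuple[np.ndarray, float]]
    humerus_collision_dirs: list[np.ndarray]  # unit dirs of tuberosity bumps
    params: BoneParams

    def validate(self, tol: float = 1.5) -> None:
        rim = self.glenoid_rim - self.glenoid_rim.mean(axis=0)
        if np.max(np.abs(rim @ self.glenoid_normal)) > 1e-6:
            raise ValueError("glenoid rim points are not coplanar")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")
        d = np.abs(np.linalg.norm(self.insertion_perimeter - self.head_center, axis=1)
                   - self.head_radius)
        if np.max(d) > tol:
            raise ValueError("insertion perimeter does not lie on the humeral head")


def _ellipse_loop(center, u, v, a, b, n, start_angle=0.0):
    t = start_angle + 2.0 * np.pi * np.arange(n) / n
    return center + np.outer(a * np.cos(t), u) + np.outer(b * np.sin(t), v)


def generate_bone_geometry(params: BoneParams | None = None) -> BoneSet:
    """Build the parametric glenohumeral construct.

    The glenoid rim is an ellipse in the canonical sagittal (y-z) plane,
    rotated about its centre by the version angle (about the SI axis) and
    the inclination angle (about the AP axis); its outward normal therefore
    tilts anteriorly/superiorly by exactly those angles. The fossa origin
    perimeter is an ellipse on a plane tilted so its posterior edge sits
    superiorly, with AP half-width scaled by ``fossa_width_factor``.
    """
    p = params or BoneParams()
    a_si, b_ap = p.glenoid_semi_axes

    rot = _rot_y(p.version_deg) @ _rot_z(p.inclination_deg)
    normal = rot @ np.array([1.0, 0.0, 0.0])
    e_si = rot @ np.array([0.0, 1.0, 0.0])
    e_ap = rot @ np.array([0.0, 0.0, 1.0])
    center = np.zeros(3)
    rim = _ellipse_loop(center, e_si, e_ap, a_si, b_ap, p.rim_points)

    # fossa origin patch: plane tilted about x so the posterior edge is superior
    tilt = np.radians(p.fossa_tilt_deg)
    n_fossa = np.array([0.0, np.cos(tilt), -np.sin(tilt)])
    u = np.array([1.0, 0.0, 0.0])
    v = np.cross(n_fossa, u)  # points anteriorly and slightly inferiorly
    fossa_center = np.array([-50.0, 13.0, 0.0])
    fossa = _ellipse_loop(fossa_center, u, v, 32.0, 8.0 * p.fossa_width_factor,
                          p.fossa_points)

    # humerus: spherical head + shaft, in humerus-local coordinates
    head = trimesh.creation.icosphere(subdivisions=3, radius=p.head_radius)
    shaft = trimesh.creation.cylinder(radius=_SHAFT_RADIUS, height=_SHAFT_LENGTH,
                                      sections=24)
    shaft.apply_transform(trimesh.transformations.rotation_matrix(
        np.pi / 2.0, [1.0, 0.0, 0.0]))
    shaft.apply_translation([0.0, -_SHAFT_LENGTH / 2.0, 0.0])
    humerus = trimesh.util.concatenate([head, shaft])

    w1 = np.array([0.0, 1.0, 0.0]) - _GREATER_TUB_DIR[1] * _GREATER_TUB_DIR
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(_GREATER_TUB_DIR, w1)
    alpha = np.radians(_INSERTION_HALF_ANGLE_DEG)
    s = 2.0 * np.pi * np.arange(p.insertion_points) / p.insertion_points
    insertion = p.head_radius * (
        np.cos(alpha) * _GREATER_TUB_DIR
        + np.sin(alpha) * (np.outer(np.cos(s), w1) + np.outer(np.sin(s), w2))
    )

    humerus_landmarks = {
        "head_center": np.zeros(3),
        "greater_tuberosity": 1.02 * p.head_radius * _GREATER_TUB_DIR,
        "lesser_tuberosity": 1.02 * p.head_radius * _LESSER_TUB_DIR,
        "lateral_epicondyle": np.array([10.0, -_SHAFT_LENGTH, 0.0]),
        "medial_epicondyle": np.array([-10.0, -_SHAFT_LENGTH, 0.0]),
    }

    # scapula surface: blade + spine ridge + glenoid disk + obstacle blobs
    blade = trimesh.creation.box(extents=[100.0, 80.0, 4.0])
    blade.apply_translation([-52.0, -30.0, 0.0])
    spine = trimesh.creation.box(extents=[70.0, 8.0, 6.0])
    spine.apply_translation([-55.0, 10.0, 9.0])
    disk = trimesh.creation.cylinder(radius=max(a_si, b_ap) + 1.0, height=6.0,
                                     sections=32)
    z_to_n = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], normal)
    disk.apply_transform(z_to_n)
    disk.apply_translation(center - 3.0 * normal)
    parts = [blade, spine, disk]
    obstacles = [(c.copy(), r) for c, r in _ACROMION_SPHERES]
    if p.include_coracoid:
        obstacles.append((_CORACOID_SPHERE[0].copy(), _CORACOID_SPHERE[1]))
    for c, r in obstacles:
        blob = trimesh.creation.icosphere(subdivisions=2, radius=r)
        blob.apply_translation(c)
        parts.append(blob)
    scapula = trimesh.util.concatenate(parts)

    bones = BoneSet(
        scapula_mesh=scapula,
        humerus_mesh=humerus,
        glenoid_rim=rim,
        fossa_origin_perimeter=fossa,
        insertion_perimeter=insertion,
        head_center=np.zeros(3),
        head_radius=p.head_radius,
        glenoid_center=center,
        glenoid_normal=normal,
        humerus_landmarks=humerus_landmarks,
        obstacle_spheres=obstacles,
        humerus_collision_dirs=(
            [_GREATER_TUB_DIR.copy()] if p.symmetric_humerus
            else [_GREATER_TUB_DIR.copy(), _LESSER_TUB_DIR.copy()]
        ),
        params=p,
    )
    bones.validate()
    return bones


def write_meshes(bones: BoneSet, outdir: str | Path, fmt: str = "stl") -> list[Path]:
    """Export scapula and humerus meshes as STL or PLY."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mesh in (("scapula", bones.scapula_mesh), ("humerus", bones.humerus_mesh)):
        path = outdir / f"{name}.{fmt}"
        mesh.export(path)
        paths.append(path)
    return paths
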