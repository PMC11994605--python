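"""Multi-fibre supraspinatus model: geometry, wrapping, lines-of-action.

The muscle is represented as 50 longitudinal fibres spanning the
supraspinous-fossa origin to the greater-tuberosity insertion: a deep
sheet of 30 fibres equally spaced (by arc length) around the full origin
perimeter and a superficial sheet of 20 fibres sampling the superior
segment, each fibre paired to the insertion point at the matching
normalized arc length. Every fibre is discretized into 100 nodes from
origin to insertion.

Fibre paths wrap over the humeral head, treated as its fitted sphere: the
shortest admissible path is a straight segment when unobstructed and a
tangent-arc-tangent construction otherwise (the wrap plane of a sphere
contains both endpoints and the centre, so the construction is exact). A
lateral-coherence regularizer optionally blends adjacent fibres' paths so
the sheet does not splay while wrapping -- the geometric role the
fibre-reinforced sheets play in the full finite-element treatment, whose
material mechanics are not needed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "Fibre",
    "FibreSet",
    "FibrePath",
    "SphereSurface",
    "MeshSurface",
    "build_fibre_set",
    "solve_path",
    "solve_fibre_set",
    "effective_endpoints",
    "line_of_action",
    "check_tension",
    "tension_report",
]

N_NODES = 100
N_DEEP = 30
N_SUPERFICIAL = 20
_INSIDE_RTOL = 0.02

ANTERIOR = "anterior"
POSTERIOR = "posterior"


# ---------------------------------------------------------------------------
# fibre set construction


def _loop_cumlen(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length of a closed polyline (len n+1, total at end)."""
    closed = np.vstack([points, points[0]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _sample_loop(points: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at normalized arc-length fractions along a closed polyline."""
    cum = _loop_cumlen(points)
    total = cum[-1]
    closed = np.vstack([points, points[0]])
    s = np.mod(fractions, 1.0) * total
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(points) - 1)
    seg_len = cum[idx + 1] - cum[idx]
    t = np.where(seg_len > 0, (s - cum[idx]) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
    return closed[idx] + t[:, None] * (closed[idx + 1] - closed[idx])


def _newell_normal(points: np.ndarray) -> np.ndarray:
    nxt = np.roll(points, -1, axis=0)
    n = np.sum(np.cross(points, nxt), axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate perimeter (zero area)")
    return n / norm


def _canonical_loop(points: np.ndarray, normal_ref: np.ndarray) -> np.ndarray:
    """Rotate a closed loop to start at its most anterior (min z) point and
    orient its traversal so the Newell normal points along ``normal_ref``."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("perimeter needs at least 3 points")
    if np.dot(_newell_normal(points), normal_ref) < 0:
        points = points[::-1]
    start = int(np.argmin(points[:, 2]))
    return np.roll(points, -start, axis=0)


@dataclass
class Fibre:
    fibre_id: int
    sheet: str              # "deep" | "superficial"
    subregion: str          # "anterior" | "posterior"
    origin: np.ndarray      # scapula frame
    insertion: np.ndarray   # humerus-local frame


@dataclass
class FibreSet:
    """The 30 deep + 20 superficial supraspinatus fibres."""

    fibres: list[Fibre]

    def __len__(self) -> int:
        return len(self.fibres)

    def by_sheet(self, sheet: str) -> list[Fibre]:
        return [f for f in self.fibres if f.sheet == sheet]


def build_fibre_set(
    origin_perimeter: np.ndarray,
    insertion_perimeter: np.ndarray,
    origin_normal_ref: np.ndarray = (0.0, 1.0, 0.0),
    insertion_normal_ref: np.ndarray = (1.0, 0.5, 0.0),
) -> FibreSet:
    """Build the fibre set from ordered closed attachment perimeters.

    Deep fibres sample the full origin loop at 30 equal arc-length steps;
    superficial fibres sample 20 points along the superior half of the
    loop (the contiguous half-arc centred on the loop's highest point).
    Each fibre attaches to the insertion perimeter at the matching
    normalized arc-length fraction. The anterior/posterior subregion split
    is at the median anteroposterior origin coordinate (rank split, so a
    symmetric construct yields exactly 25/25).
    """
    origin_loop = _canonical_loop(origin_perimeter, np.asarray(origin_normal_ref, float))
    ins_loop = _canonical_loop(insertion_perimeter, np.asarray(insertion_normal_ref, float))

    deep_fr = np.arange(N_DEEP) / N_DEEP
    # superior half-arc: centred (in arc length) on the highest origin point
    cum = _loop_cumlen(origin_loop)
    top = int(np.argmax(origin_loop[:, 1]))
    top_frac = cum[top] / cum[-1]
    sup_fr = np.mod(top_frac - 0.25 + 0.5 * (np.arange(N_SUPERFICIAL) + 0.5) / N_SUPERFICIAL, 1.0)

    fibres: list[Fibre] = []
    for sheet, fractions in (("deep", deep_fr), ("superficial", sup_fr)):
        origins = _sample_loop(origin_loop, fractions)
        insertions = _sample_loop(ins_loop, fractions)
        for o, i in zip(origins, insertions):
            fibres.append(Fibre(len(fibres), sheet, "", o, i))

    order = np.argsort([f.origin[2] for f in fibres], kind="stable")
    half = len(fibres) // 2
    for rank, fi in enumerate(order):
        fibres[fi].subregion = ANTERIOR if rank < half else POSTERIOR
    return FibreSet(fibres=fibres)


# ---------------------------------------------------------------------------
# path solving


@dataclass
class FibrePath:
    """Ordered 100-node chain from origin to insertion."""

    nodes: np.ndarray                     # (100, 3)
    length: float
    wrapped: bool
    effective_origin_index: int = 0
    effective_insertion_index: int = N_NODES - 1
    line_of_action: np.ndarray | None = None
    in_tension: bool | None = None
    fibre_id: int | None = None

    def __post_init__(self) -> None:
        if self.nodes.shape != (N_NODES, 3):
            raise ValueError(f"paths carry exactly {N_NODES} nodes")


def _resample_polyline(nodes: np.ndarray, n: int = N_NODES) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, nodes[:, d])
    return out


def solve_path(
    origin: np.ndarray,
    insertion: np.ndarray,
    sphere: tuple[np.ndarray, float] | None = None,
    scapula_mesh: trimesh.Trimesh | None = None,
) -> FibrePath:
    """Shortest admissible fibre path from origin to insertion.

    With no obstruction the path is the straight segment. When the segment
    would pass through the humeral-head sphere, the path is the exact
    tangent-arc-tangent wrap in the plane spanned by the endpoints and the
    sphere centre; its length is measured from the constructed tangent
    points and arc. The path is discretized to 100 nodes equally spaced by
    arc length. A watertight scapula mesh, if supplied, is enforced by
    projecting offending nodes out along the nearest-surface direction
    (fixed-point iteration).
    """
    origin = np.asarray(origin, dtype=float)
    insertion = np.asarray(insertion, dtype=float)

    path = _solve_sphere_path(origin, insertion, sphere)
    if scapula_mesh is not None and scapula_mesh.is_watertight:
        nodes = _project_out_of_mesh(path.nodes, scapula_mesh, sphere)
        seg = float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1)))
        path = FibrePath(nodes=nodes, length=seg, wrapped=path.wrapped)
    return path


def _solve_sphere_path(origin, insertion, sphere) -> FibrePath:
    straight_len = float(np.linalg.norm(insertion - origin))
    if sphere is None:
        return FibrePath(
            nodes=np.linspace(origin, insertion, N_NODES),
            length=straight_len, wrapped=False,
        )
    center, radius = np.asarray(sphere[0], dtype=float), float(sphere[1])
    v1 = origin - center
    v2 = insertion - center
    d1 = np.linalg.norm(v1)
    d2 = np.linalg.norm(v2)
    # attachment points may sit marginally below the idealized sphere
    # (e.g. interpolated between perimeter points); clamp shallow embedding
    # but reject endpoints genuinely interior to the obstacle
    deep = (1.0 - _INSIDE_RTOL) * radius
    if d1 < deep:
        raise ValueError("fibre origin lies inside the wrapping sphere")
    if d2 < deep:
        raise ValueError("fibre insertion lies inside the wrapping sphere")
    d1 = max(d1, radius)
    d2 = max(d2, radius)

    alpha = np.arccos(np.clip(np.dot(v1, v2) / (d1 * d2), -1.0, 1.0))
    beta1 = np.arccos(np.clip(radius / d1, -1.0, 1.0))
    beta2 = np.arccos(np.clip(radius / d2, -1.0, 1.0))
    theta = alpha - beta1 - beta2
    if theta <= 1e-12 or _segment_clears_sphere(origin, insertion, center, radius):
        return FibrePath(
            nodes=np.linspace(origin, insertion, N_NODES),
            length=straight_len, wrapped=False,
        )

    e1 = v1 / d1
    perp = v2 - np.dot(v2, e1) * e1
    np_norm = np.linalg.norm(perp)
    if np_norm < 1e-12:
        # endpoints collinear with the centre: wrap plane is ambiguous
        perp = np.cross(e1, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(e1, [0.0, 1.0, 0.0])
        np_norm = np.linalg.norm(perp)
    em = perp / np_norm

    def on_circle(phi: float) -> np.ndarray:
        return center + radius * (np.cos(phi) * e1 + np.sin(phi) * em)

    t1 = on_circle(beta1)
    t2 = on_circle(alpha - beta2)
    len1 = float(np.linalg.norm(t1 - origin))
    len3 = float(np.linalg.norm(insertion - t2))
    theta_actual = np.arccos(np.clip(
        np.dot(t1 - center, t2 - center) / radius**2, -1.0, 1.0))
    arc_len = radius * theta_actual
    total = len1 + arc_len + len3

    s = np.linspace(0.0, total, N_NODES)
    nodes = np.empty((N_NODES, 3))
    for k, sk in enumerate(s):
        if sk <= len1:
            t = sk / len1 if len1 > 0 else 0.0
            nodes[k] = origin + t * (t1 - origin)
        elif sk <= len1 + arc_len:
            phi = beta1 + (sk - len1) / radius
            nodes[k] = on_circle(phi)
        else:
            t = (sk - len1 - arc_len) / len3 if len3 > 0 else 1.0
            nodes[k] = t2 + t * (insertion - t2)
    nodes[0], nodes[-1] = origin, insertion
    return FibrePath(nodes=nodes, length=total, wrapped=True)


def _segment_clears_sphere(a, b, center, radius) -> bool:
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = 0.0 if denom == 0 else np.clip(np.dot(center - a, ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(a + t * ab - center)) >= radius - 1e-9


def _project_out_of_mesh(nodes, mesh, sphere, iters: int = 50, tol: float = 1e-6):
    nodes = nodes.copy()
    pq = trimesh.proximity.ProximityQuery(mesh)
    for _ in range(iters):
        inside = mesh.contains(nodes[1:-1])
        if not inside.any():
            break
        idx = np.nonzero(inside)[0] + 1
        closest, dist, _ = pq.on_surface(nodes[idx])
        outward = nodes[idx] - closest
        norms = np.linalg.norm(outward, axis=1, keepdims=True)
        # inside the mesh the nearest-surface direction points inward
        nodes[idx] = closest - outward / np.maximum(norms, 1e-12) * 1e-3
        if sphere is not None:
            nodes = _push_out_of_sphere(nodes, *sphere)
        if np.max(dist) < tol:
            break
    return _resample_polyline(nodes)


def _push_out_of_sphere(nodes, center, radius):
    rel = nodes[1:-1] - center
    d = np.linalg.norm(rel, axis=1)
    bad = d < radius
    if bad.any():
        nodes = nodes.copy()
        rel_bad = rel[bad] / d[bad, None]
        nodes[1:-1][bad] = center + radius * rel_bad
    return nodes


def solve_fibre_set(
    fibre_set: FibreSet,
    sphere: tuple[np.ndarray, float] | None,
    humerus_transform: np.ndarray | None = None,
    coherence_weight: float = 0.1,
    scapula_mesh: trimesh.Trimesh | None = None,
) -> list[FibrePath]:
    """Solve all fibre paths at one pose, with lateral coherence.

    Insertions (humerus-local) are mapped through ``humerus_transform``
    first. With ``coherence_weight`` > 0, each interior node of a fibre is
    blended toward the mean of its within-sheet neighbours' corresponding
    nodes, then pushed back out of the wrapping sphere and resampled --
    penalizing divergence of adjacent wrap arcs without letting fibres cut
    through bone. At weight 0 every fibre is its independent shortest path.
    """
    if not 0.0 <= coherence_weight < 1.0:
        raise ValueError("coherence_weight must be in [0, 1)")
    T = np.eye(4) if humerus_transform is None else np.asarray(humerus_transform, float)
    paths: list[FibrePath] = []
    for f in fibre_set.fibres:
        ins_world = T[:3, :3] @ f.insertion + T[:3, 3]
        p = solve_path(f.origin, ins_world, sphere=sphere, scapula_mesh=scapula_mesh)
        p.fibre_id = f.fibre_id
        paths.append(p)

    if coherence_weight > 0.0:
        for sheet in ("deep", "superficial"):
            idx = [i for i, f in enumerate(fibre_set.fibres) if f.sheet == sheet]
            stack = np.array([paths[i].nodes for i in idx])
            nbr_mean = np.empty_like(stack)
            nbr_mean[0] = stack[1]
            nbr_mean[-1] = stack[-2]
            nbr_mean[1:-1] = 0.5 * (stack[:-2] + stack[2:])
            blended = stack.copy()
            blended[:, 1:-1] = ((1.0 - coherence_weight) * stack[:, 1:-1]
                                + coherence_weight * nbr_mean[:, 1:-1])
            for row, i in enumerate(idx):
                nodes = blended[row]
                if sphere is not None:
                    nodes = _push_out_of_sphere(nodes, np.asarray(sphere[0], float),
                                                float(sphere[1]))
                nodes = _resample_polyline(nodes)
                length = float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1)))
                paths[i] = FibrePath(nodes=nodes, length=length,
                                     wrapped=paths[i].wrapped, fibre_id=paths[i].fibre_id)
    return paths


# ---------------------------------------------------------------------------
# effective endpoints and line of action


class SphereSurface:
    """Distance-to-surface queries against a sphere."""

    def __init__(self, center: np.ndarray, radius: float) -> None:
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(np.linalg.norm(points - self.center, axis=-1) - self.radius)


class MeshSurface:
    """Distance-to-surface queries against a triangulated mesh."""

    def __init__(self, mesh: trimesh.Trimesh) -> None:
        self._pq = trimesh.proximity.ProximityQuery(mesh)

    def distance(self, points: np.ndarray) -> np.ndarray:
        _, dist, _ = self._pq.on_surface(np.atleast_2d(points))
        return dist


def effective_endpoints(
    path: FibrePath,
    scapula_surface,
    humerus_surface,
    contact_tol: float,
    max_tol: float | None = None,
) -> tuple[int, int]:
    """Node indices where force is transmitted to each bone.

    Effective origin: the last node of the contiguous scapula-contact run
    starting at the origin node. Effective insertion: the first node of
    the contiguous humerus-contact run ending at the insertion node. A
    fibre without bone contact at an end falls back to node 0 / node 99.
    ``contact_tol`` must be positive and no larger than ``max_tol``
    (default 5% of the path length) so "everything is in contact"
    degeneracies are rejected.
    """
    cap = 0.05 * path.length if max_tol is None else max_tol
    if not 0.0 < contact_tol <= cap:
        raise ValueError(f"contact_tol must be in (0, {cap:.3g}]")

    eo = 0
    if scapula_surface is not None:
        contact = scapula_surface.distance(path.nodes) <= contact_tol
        if contact[0]:
            run_end = np.argmin(contact) if not contact.all() else len(contact)
            eo = int(run_end) - 1
    ei = N_NODES - 1
    if humerus_surface is not None:
        contact = humerus_surface.distance(path.nodes) <= contact_tol
        if contact[-1]:
            rev = contact[::-1]
            run_end = np.argmin(rev) if not rev.all() else len(rev)
            ei = N_NODES - int(run_end)
    if ei <= eo:  # overlapping contact runs: fall back to the raw endpoints
        eo, ei = 0, N_NODES - 1
    path.effective_origin_index = eo
    path.effective_insertion_index = ei
    return eo, ei


def line_of_action(path: FibrePath) -> np.ndarray:
    """Unit force direction on the humerus: effective insertion -> effective origin."""
    v = path.nodes[path.effective_origin_index] - path.nodes[path.effective_insertion_index]
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("effective endpoints coincide; line of action undefined")
    loa = v / n
    path.line_of_action = loa
    return loa


def check_tension(path: FibrePath, slack_length: float) -> bool:
    """True iff the fibre's geometric length is at least the slack length."""
    flag = path.length >= slack_length
    path.in_tension = flag
    return flag


def tension_report(lengths_per_pose: np.ndarray, slack_lengths: np.ndarray | None = None):
    """Per-pose, per-fibre tension flags.

    ``lengths_per_pose`` is (n_poses, n_fibres); the slack length defaults
    to each fibre's length at the first (lowest-abduction) pose.
    """
    lengths = np.asarray(lengths_per_pose, dtype=float)
    slack = lengths[0] if slack_lengths is None else np.asarray(slack_lengths, float)
    return lengths >= slack[None, :]
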