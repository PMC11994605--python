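"""3D thin-plate-spline (biharmonic) landmark interpolation.

Warps space so a set of source landmarks maps exactly onto target
landmarks while minimizing bending energy; the kernel is the 3D biharmonic
interpolant U(r) = r (the 2D r^2 log r kernel does not apply here). No
regularization is used: the warp interpolates exactly, so warped template
meshes keep point correspondence across targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = ["TPSWarp", "tps_fit", "tps_apply", "warp_mesh"]


@dataclass
class TPSWarp:
    """Fitted thin-plate-spline coefficients.

    ``affine`` is 4x3 (row 0 the translation, rows 1-3 the linear map);
    ``kernel_weights`` (k x 3) satisfy the polynomial annihilation
    constraints P^T w = 0, which make the kernel part decay to zero
    relative to the affine part far from the landmarks.
    """

    source_landmarks: np.ndarray
    affine: np.ndarray
    kernel_weights: np.ndarray
    bending_energy: float

    def constraint_residual(self) -> float:
        """Max |P^T w| over the four annihilation constraints."""
        k = len(self.source_landmarks)
        P = np.hstack([np.ones((k, 1)), self.source_landmarks])
        return float(np.max(np.abs(P.T @ self.kernel_weights)))


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Fit the interpolating 3D thin-plate spline from source to target.

    Requires >= 4 non-coplanar source landmarks; coincident source
    landmarks make the system singular and are reported by index pair.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.ndim != 2 or source.shape[1] != 3 or source.shape != target.shape:
        raise ValueError("source and target must be matching (k, 3) arrays")
    k = len(source)
    if k < 4:
        raise ValueError("need at least 4 landmarks")

    diff = source[:, None, :] - source[None, :, :]
    K = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(k, 1)
    coincident = np.nonzero(K[iu] < 1e-12)[0]
    if len(coincident):
        i, j = iu[0][coincident[0]], iu[1][coincident[0]]
        raise ValueError(f"coincident source landmarks {i} and {j} make the spline singular")

    P = np.hstack([np.ones((k, 1)), source])
    if np.linalg.matrix_rank(source - source.mean(axis=0)) < 3:
        raise ValueError("source landmarks are coplanar; 3D spline is singular")

    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    sol = np.linalg.solve(L, rhs)
    w, a = sol[:k], sol[k:]

    # U(r) = -r is the conditionally positive definite form, so the
    # bending functional is -w^T K w (>= 0 under the constraints P^T w = 0)
    energy = float(max(0.0, -np.sum(w * (K @ w))))
    return TPSWarp(source_landmarks=source, affine=a, kernel_weights=w,
                   bending_energy=energy)


def tps_apply(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate the warp at arbitrary points (n x 3 -> n x 3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = len(points)
    out = np.hstack([np.ones((n, 1)), points]) @ warp.affine
    # kernel part, chunked so big meshes do not allocate n x k x 3
    chunk = max(1, int(2e7) // max(1, len(warp.source_landmarks)))
    for lo in range(0, n, chunk):
        seg = points[lo:lo + chunk]
        d = np.linalg.norm(seg[:, None, :] - warp.source_landmarks[None], axis=-1)
        out[lo:lo + chunk] += d @ warp.kernel_weights
    return out


def warp_mesh(
    template_mesh: trimesh.Trimesh,
    template_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
) -> trimesh.Trimesh:
    """Warp a template mesh so its landmarks match the target landmarks.

    Vertex-wise spline evaluation; topology (faces) is untouched, so point
    correspondence across warped meshes is preserved. Non-watertight input
    passes through with a warning.
    """
    if not template_mesh.is_watertight:
        warnings.warn("template mesh is not watertight; warping vertices anyway",
                      stacklevel=2)
    warp = tps_fit(np.asarray(template_landmarks, float),
                   np.asarray(target_landmarks, float))
    vertices = tps_apply(warp, template_mesh.vertices.view(np.ndarray))
    return trimesh.Trimesh(vertices=vertices, faces=template_mesh.faces.copy(),
                           process=False)
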