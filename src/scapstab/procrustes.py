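"""Generalized Procrustes analysis (GPA) for 3D landmark configurations.

Full similarity superimposition: each configuration is centred, scaled to
unit centroid size, and rotated onto the running mean by orthogonal least
squares with a determinant correction so reflections are never used
(anatomical handedness is preserved). The resulting Procrustes shape
coordinates carry only shape information and feed the supervised shape
model directly (no tangent-space projection is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration

__all__ = ["AlignedShapes", "gpa", "procrustes_distance", "closest_to_mean"]

_MAX_ITER = 100
_TOL = 1e-10


def centroid_size(coords: np.ndarray) -> float:
    """Root-sum-of-squared distances of landmarks from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(c * c)))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a @ R - b||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(len(vt))
    flip[-1] = d
    return u @ np.diag(flip) @ vt


@dataclass
class AlignedShapes:
    """Procrustes-aligned shapes with their mean.

    Each aligned shape is centred at the origin with unit centroid size;
    ``mean_shape`` is likewise scaled to unit centroid size.
    """

    shapes: np.ndarray          # (N, k, 3)
    mean_shape: np.ndarray      # (k, 3)
    centroid_sizes: np.ndarray  # (N,)
    specimen_ids: list[str]
    groups: np.ndarray          # (N,), -1 where unlabelled
    iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return len(self.shapes)

    def flat(self) -> np.ndarray:
        """Shape block as an (N, 3k) matrix for regression models."""
        return self.shapes.reshape(self.n_specimens, -1)


def gpa(configs: list[LandmarkConfiguration]) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Iterates rotate-to-mean / re-estimate-mean until the mean shape moves
    by less than 1e-10 (RMS) or 100 iterations; non-convergence is flagged
    on the result rather than raised.
    """
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    k = configs[0].coords.shape[0]
    sizes = np.empty(len(configs))
    shapes = np.empty((len(configs), k, 3))
    for i, cfg in enumerate(configs):
        c = cfg.coords - cfg.coords.mean(axis=0)
        size = centroid_size(cfg.coords)
        if size < 1e-12:
            raise ValueError(f"degenerate (all-coincident) landmarks in {cfg.specimen_id!r}")
        sizes[i] = size
        shapes[i] = c / size
    if np.linalg.matrix_rank(shapes[0] - shapes[0].mean(axis=0)) < 3 and k >= 4:
        # coplanar landmarks leave the out-of-plane rotation unconstrained
        raise ValueError("landmarks are coplanar; 3D alignment is ill-posed")

    mean = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, _MAX_ITER + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], mean)
        new_mean = shapes.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        new_mean /= centroid_size(new_mean)
        delta = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if delta < _TOL:
            converged = True
            break
    # final pass so every shape is aligned to the converged mean
    for i in range(len(shapes)):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], mean)

    return AlignedShapes(
        shapes=shapes,
        mean_shape=mean,
        centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        groups=np.array([-1 if c.group is None else c.group for c in configs]),
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squared coordinate differences between aligned shapes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def closest_to_mean(aligned: AlignedShapes) -> int:
    """Index of the specimen with the lowest Procrustes distance to the mean.

    Ties are broken by the lowest index (argmin semantics).
    """
    if aligned.n_specimens == 0:
        raise ValueError("empty alignment")
    d = [procrustes_distance(s, aligned.mean_shape) for s in aligned.shapes]
    return int(np.argmin(d))
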