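"""Discrete scapular metrics from named landmarks.

Landmark-only constructions of the classic clinical measurements:

* **Critical shoulder angle (CSA)** -- angle at the inferior glenoid rim
  between rays to the superior glenoid rim and to the most lateral
  acromion point.
* **Glenoid inclination** -- signed angle between the glenoid
  superior-inferior rim chord and the scapular SI axis, measured in the
  blade plane; positive when the glenoid face tips superiorly.
* **Glenoid version** -- signed angle between the glenoid plane normal and
  the scapular mediolateral axis, measured in the transverse plane;
  anterior tilt (anteversion) positive.
* **Glenoid height / width** -- rim extents along the in-plane principal
  axes (SI and AP); for near-circular rims the axes are tie-broken to the
  scapular SI direction.
* **Acromion coverage** -- angle subtended at the glenoid centre by the
  anterior and posterior acromial undersurface landmarks.
* **Lateral acromion ratio** -- lateral acromial overhang beyond the
  glenoid centre divided by the scapular width, as a percentage.

All metrics are invariant to rigid motion and uniform scaling of the
input (with the frame recomputed alongside), except height and width
which scale linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import BodyFrame, _fit_plane_normal, _get

__all__ = ["ScapularMetrics", "compute_metrics", "metrics_to_frame"]

_RIM_NAMES = [
    "glenoid_rim_superior", "glenoid_rim_posterosuperior", "glenoid_rim_posterior",
    "glenoid_rim_posteroinferior", "glenoid_rim_inferior",
    "glenoid_rim_anteroinferior", "glenoid_rim_anterior", "glenoid_rim_anterosuperior",
]
_AXIS_TIE_RTOL = 0.05


@dataclass
class ScapularMetrics:
    critical_shoulder_angle: float  # degrees
    glenoid_inclination: float      # degrees, superior tilt positive
    glenoid_version: float          # degrees, anteversion positive
    glenoid_height: float           # length units of the input
    glenoid_width: float
    acromion_coverage: float        # degrees
    lateral_acromion_ratio: float   # percent

    def __post_init__(self) -> None:
        if self.glenoid_height <= 0 or self.glenoid_width <= 0:
            raise ValueError("glenoid height/width must be positive")
        if not 0.0 <= self.lateral_acromion_ratio <= 200.0:
            raise ValueError("lateral acromion ratio out of range [0, 200]%")

    def as_dict(self) -> dict[str, float]:
        return {
            "critical_shoulder_angle": self.critical_shoulder_angle,
            "glenoid_inclination": self.glenoid_inclination,
            "glenoid_version": self.glenoid_version,
            "glenoid_height": self.glenoid_height,
            "glenoid_width": self.glenoid_width,
            "acromion_coverage": self.acromion_coverage,
            "lateral_acromion_ratio": self.lateral_acromion_ratio,
        }


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_metrics(landmarks, frame: BodyFrame) -> ScapularMetrics:
    """Compute the discrete metric panel for one scapula.

    ``landmarks`` is a LandmarkConfiguration or a name->xyz mapping;
    ``frame`` is the scapular body frame (see
    :func:`scapstab.kinematics.scapula_frame`). A missing named landmark
    raises a KeyError naming it.
    """
    rim = np.array([_get(landmarks, n) for n in _RIM_NAMES])
    center = rim.mean(axis=0)
    x_s, y_s, z_s = frame.x, frame.y, frame.z

    normal = _fit_plane_normal(rim)
    if np.dot(normal, x_s) < 0:
        normal = -normal

    # critical shoulder angle
    inf = _get(landmarks, "glenoid_rim_inferior")
    sup = _get(landmarks, "glenoid_rim_superior")
    acr_lat = _get(landmarks, "acromion_lateral")
    csa = _angle_deg(sup - inf, acr_lat - inf)

    # inclination: SI rim chord vs scapular SI axis, in the blade plane;
    # positive when the chord top tips medially (face tips superiorly)
    chord = sup - inf
    inclination = float(np.degrees(np.arctan2(-np.dot(chord, x_s), np.dot(chord, y_s))))

    # version: rim normal vs scapular ML axis, in the transverse plane;
    # anterior (-z) tilt positive
    version = float(np.degrees(np.arctan2(-np.dot(normal, z_s), np.dot(normal, x_s))))

    # height/width: extents along in-plane principal axes of the rim
    centered = rim - center
    inplane = centered - np.outer(centered @ normal, normal)
    cov = inplane.T @ inplane
    evals, evecs = np.linalg.eigh(cov)
    si_axis, ap_axis = evecs[:, 2], evecs[:, 1]  # descending variance
    if evals[2] - evals[1] < _AXIS_TIE_RTOL * evals[2]:
        # near-circular rim: seed the SI axis from the scapular frame
        si_axis = y_s - np.dot(y_s, normal) * normal
        si_axis = si_axis / np.linalg.norm(si_axis)
        ap_axis = np.cross(normal, si_axis)
    height = float(np.ptp(inplane @ si_axis))
    width = float(np.ptp(inplane @ ap_axis))

    coverage = _angle_deg(
        _get(landmarks, "acromion_anterior") - center,
        _get(landmarks, "acromion_posterior") - center,
    )

    l_a = float(np.dot(acr_lat - center, x_s))
    l_s = float(np.dot(center - _get(landmarks, "medial_border_mid"), x_s))
    if l_s == 0:
        raise ValueError("degenerate scapular width (medial border under the glenoid)")
    if l_s < 0:  # mirrored input measured in the opposite convention
        l_a, l_s = -l_a, -l_s
    ratio = max(0.0, l_a) / l_s * 100.0

    return ScapularMetrics(
        critical_shoulder_angle=csa,
        glenoid_inclination=inclination,
        glenoid_version=version,
        glenoid_height=height,
        glenoid_width=width,
        acromion_coverage=coverage,
        lateral_acromion_ratio=ratio,
    )


def metrics_to_frame(named_metrics: dict[str, ScapularMetrics]) -> pd.DataFrame:
    """Table with one row per shape (mirrors the usual reporting layout)."""
    return pd.DataFrame({name: m.as_dict() for name, m in named_metrics.items()}).T
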