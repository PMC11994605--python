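"""Glenoid-frame stability ratios of muscle lines-of-action.

A fibre's tensile force stabilizes the joint when it compresses the
humeral head into the glenoid and destabilizes it when it shears the head
along the glenoid face. Resolving the unit line-of-action into a frame
fit to the glenoid rim gives the superior-inferior (SI) and
anterior-posterior (AP) stability ratios,

    SI ratio = f_shear,SI / f_compressive
    AP ratio = f_shear,AP / f_compressive

with SI positive superiorly, AP positive anteriorly, and the compressive
axis directed medially into the glenoid. Higher-magnitude ratios indicate
a greater tendency to translate the humeral head. Fibres whose
compressive component is non-positive cannot be expressed as a ratio and
are flagged destabilizing instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import BodyFrame

__all__ = [
    "GlenoidFrame",
    "StabilityRecord",
    "glenoid_frame",
    "stability_ratios",
    "records_to_frame",
    "summarize",
    "compare_shapes",
]

_TIE_RTOL = 0.05


@dataclass
class GlenoidFrame:
    """Principal-axes frame of the glenoid rim.

    ``e_comp`` points medially into the glenoid (least-variance rim axis),
    ``e_sup`` superiorly (greatest-variance axis) and ``e_ant`` anteriorly.
    """

    center: np.ndarray
    e_comp: np.ndarray
    e_sup: np.ndarray
    e_ant: np.ndarray

    def __post_init__(self) -> None:
        M = np.column_stack([self.e_comp, self.e_sup, self.e_ant])
        if np.max(np.abs(M.T @ M - np.eye(3))) > 1e-10:
            raise ValueError("glenoid frame axes are not orthonormal")


def glenoid_frame(rim_points: np.ndarray, scapula: BodyFrame) -> GlenoidFrame:
    """Fit the glenoid frame to rim perimeter points.

    Principal axes of the rim point cloud: the least-variance axis is the
    compression direction (sign fixed medially, i.e. against the scapular
    lateral axis), the greatest-variance axis is SI (sign fixed superiorly)
    and AP completes the triad (sign fixed anteriorly). For near-circular
    rims, where SI and AP variances tie, the SI axis is seeded from the
    scapular superior axis.
    """
    rim = np.asarray(rim_points, dtype=float)
    if len(rim) < 5:
        raise ValueError("need at least 5 rim points")
    center = rim.mean(axis=0)
    c = rim - center
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("rim points are collinear")

    e_comp = vt[2]
    if np.dot(e_comp, -scapula.x) < 0:
        e_comp = -e_comp
    if s[0] - s[1] < _TIE_RTOL * s[0]:
        e_sup = scapula.y - np.dot(scapula.y, e_comp) * e_comp
        e_sup /= np.linalg.norm(e_sup)
    else:
        e_sup = vt[0]
        if np.dot(e_sup, scapula.y) < 0:
            e_sup = -e_sup
    e_ant = np.cross(e_sup, e_comp)
    if np.dot(e_ant, -scapula.z) < 0:
        e_ant = -e_ant
    return GlenoidFrame(center=center, e_comp=e_comp, e_sup=e_sup, e_ant=e_ant)


@dataclass
class StabilityRecord:
    """Per fibre, per pose stability decomposition."""

    fibre_id: int
    sheet: str
    subregion: str
    pose_index: int
    abduction: float
    si_ratio: float     # NaN when destabilizing
    ap_ratio: float
    f_comp: float
    destabilizing: bool


def stability_ratios(loa: np.ndarray, frame: GlenoidFrame) -> tuple[float, float, float]:
    """Resolve a unit line-of-action into (si_ratio, ap_ratio, f_comp).

    A non-positive compressive component leaves the ratios undefined:
    (nan, nan, f_comp) is returned and callers flag the fibre
    destabilizing.
    """
    loa = np.asarray(loa, dtype=float)
    if abs(np.linalg.norm(loa) - 1.0) > 1e-6:
        raise ValueError("line of action must be a unit vector")
    f_comp = float(np.dot(loa, frame.e_comp))
    if f_comp <= 0.0:
        return float("nan"), float("nan"), f_comp
    si = float(np.dot(loa, frame.e_sup)) / f_comp
    ap = float(np.dot(loa, frame.e_ant)) / f_comp
    return si, ap, f_comp


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(records: list[StabilityRecord] | pd.DataFrame, by: str = "all") -> pd.DataFrame:
    """Per-pose mean/min/max/range of the SI and AP ratios.

    ``by`` is "all", "sheet" or "subregion". Destabilizing fibres (NaN
    ratios) are excluded; empty groups are omitted with a warning column
    rather than raised.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if by not in ("all", "sheet", "subregion"):
        raise ValueError("by must be 'all', 'sheet' or 'subregion'")
    keys = ["pose_index", "abduction"] + ([] if by == "all" else [by])
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        vals = {}
        for metric in ("si_ratio", "ap_ratio"):
            v = grp[metric].dropna()
            if len(v) == 0:
                continue
            vals[f"{metric}_mean"] = v.mean()
            vals[f"{metric}_min"] = v.min()
            vals[f"{metric}_max"] = v.max()
            vals[f"{metric}_range"] = v.max() - v.min()
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n_fibres"] = int(grp["si_ratio"].notna().sum())
        row["n_destabilizing"] = int(grp["destabilizing"].sum())
        row.update(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_shapes(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Per-pose differences (B - A) of ratio means and ranges.

    Requires matched pose grids; also reports percent range change,
    negative when B's fibre spread is narrower than A's.
    """
    a = summary_a.set_index("pose_index").sort_index()
    b = summary_b.set_index("pose_index").sort_index()
    if not a.index.equals(b.index) or not np.allclose(a["abduction"], b["abduction"]):
        raise ValueError("pose grids do not match")
    out = pd.DataFrame(index=a.index)
    out["abduction"] = a["abduction"]
    for metric in ("si_ratio", "ap_ratio"):
        out[f"{metric}_mean_diff"] = b[f"{metric}_mean"] - a[f"{metric}_mean"]
        out[f"{metric}_range_diff"] = b[f"{metric}_range"] - a[f"{metric}_range"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{metric}_range_pct_change"] = (
                100.0 * out[f"{metric}_range_diff"] / a[f"{metric}_range"]
            )
    return out.reset_index()
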