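"""Named 3D landmark configurations and their CSV/JSON dialects.

A scapula is represented by 29 named homologous landmarks. The landmark
names and their canonical ordering are fixed by the packaged template
schema (``data/scapula_template.json``); every dataset read or written by
this package uses that ordering so that coordinates are comparable
across specimens without re-matching names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_LANDMARKS = 29

CONTROL = 0
FTT = 1


def _load_template_record() -> dict:
    with resources.files("scapstab.data").joinpath("scapula_template.json").open() as fh:
        return json.load(fh)


_TEMPLATE = _load_template_record()

#: Canonical landmark name order shared by every configuration.
LANDMARK_NAMES: tuple[str, ...] = tuple(lm["name"] for lm in _TEMPLATE["landmarks"])

if len(LANDMARK_NAMES) != N_LANDMARKS:  # pragma: no cover - packaging guard
    raise RuntimeError("packaged landmark schema must define exactly 29 landmarks")


def template_coords() -> np.ndarray:
    """Return the 29x3 template landmark coordinates (mm, canonical frame)."""
    return np.array([lm["xyz"] for lm in _TEMPLATE["landmarks"]], dtype=float)


def landmark_index(name: str) -> int:
    """Index of a named landmark in the canonical ordering."""
    try:
        return LANDMARK_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown landmark name: {name!r}") from None


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D landmarks plus an optional group label.

    Parameters
    ----------
    coords
        29x3 array of landmark coordinates.
    specimen_id
        Identifier, unique within a dataset.
    group
        0 for control, 1 for full-thickness-tear (FTT), or None if
        unlabelled.
    landmark_names
        Ordered names; defaults to the packaged schema ordering.
    """

    coords: np.ndarray
    specimen_id: str = "specimen"
    group: int | None = None
    landmark_names: tuple[str, ...] = field(default=LANDMARK_NAMES)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.landmark_names), 3):
            raise ValueError(
                f"coords must be {len(self.landmark_names)}x3, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if tuple(self.landmark_names) != LANDMARK_NAMES and len(self.landmark_names) == N_LANDMARKS:
            raise ValueError("landmark names do not match the packaged schema order")
        if self.group is not None and self.group not in (CONTROL, FTT):
            raise ValueError("group must be 0 (control), 1 (FTT) or None")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[self.landmark_names.index(name)]

    def flat(self) -> np.ndarray:
        """Flattened 87-vector (landmark-major, xyz within landmark)."""
        return self.coords.reshape(-1)


def template_configuration() -> LandmarkConfiguration:
    """The packaged schematic template as a configuration (unlabelled)."""
    return LandmarkConfiguration(template_coords(), specimen_id="template")


# ---------------------------------------------------------------------------
# dataset I/O: long CSV (specimen_id, landmark_name, x, y, z, group) and JSON


def to_frame(configs: list[LandmarkConfiguration]) -> pd.DataFrame:
    rows = []
    for cfg in configs:
        for name, (x, y, z) in zip(cfg.landmark_names, cfg.coords):
            rows.append(
                {
                    "specimen_id": cfg.specimen_id,
                    "landmark_name": name,
                    "x": x,
                    "y": y,
                    "z": z,
                    "group": -1 if cfg.group is None else cfg.group,
                }
            )
    return pd.DataFrame(rows)


def write_csv(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    to_frame(configs).to_csv(path, index=False, float_format="%.12g")


def read_csv(path: str | Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    configs = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.set_index("landmark_name").loc[list(LANDMARK_NAMES)]
        group = int(sub["group"].iloc[0])
        configs.append(
            LandmarkConfiguration(
                sub[["x", "y", "z"]].to_numpy(float),
                specimen_id=str(sid),
                group=None if group < 0 else group,
            )
        )
    return configs


def write_json(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    payload = [
        {
            "specimen_id": cfg.specimen_id,
            "group": cfg.group,
            "landmarks": {n: list(map(float, p)) for n, p in zip(cfg.landmark_names, cfg.coords)},
        }
        for cfg in configs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_json(path: str | Path) -> list[LandmarkConfiguration]:
    payload = json.loads(Path(path).read_text())
    return [
        LandmarkConfiguration(
            np.array([rec["landmarks"][n] for n in LANDMARK_NAMES], dtype=float),
            specimen_id=rec["specimen_id"],
            group=rec["group"],
        )
        for rec in payload
    ]
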