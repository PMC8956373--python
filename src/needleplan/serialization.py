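"""Plain-text exchange formats: pose pairs, fiducials, transforms, targets.

Pose pairs are stored one row per pose with the robot and tracker transforms
flattened row-major as 3x4 blocks (12 numbers each). Transforms are JSON 4x4
row-major matrices. Fiducials are CSV with world coordinates and component
volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import PosePairSet
from .transforms import RigidTransform

_POSE_COLS = [f"{who}_{r}{c}" for who in ("robot", "tracker") for r in range(3) for c in range(4)]


def _flatten(t: RigidTransform) -> list[float]:
    return [float(x) for x in t.matrix[:3, :].ravel()]


def _unflatten(row: np.ndarray) -> RigidTransform:
    m = np.eye(4)
    m[:3, :] = np.asarray(row, dtype=float).reshape(3, 4)
    return RigidTransform(m)


def write_pose_pairs_csv(pairs: PosePairSet, path: str | Path) -> None:
    rows = [
        _flatten(b) + _flatten(c)
        for b, c in zip(pairs.robot_poses, pairs.tracker_poses)
    ]
    pd.DataFrame(rows, columns=_POSE_COLS).to_csv(path, index=False)


def read_pose_pairs_csv(path: str | Path) -> PosePairSet:
    df = pd.read_csv(path)
    missing = set(_POSE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pose-pair CSV missing columns: {sorted(missing)[:4]}...")
    robot = [_unflatten(r) for r in df[_POSE_COLS[:12]].to_numpy()]
    tracker = [_unflatten(r) for r in df[_POSE_COLS[12:]].to_numpy()]
    return PosePairSet(robot_poses=robot, tracker_poses=tracker)


def write_fiducials_csv(records: list[tuple[np.ndarray, float]], path: str | Path) -> None:
    rows = [[*c, v] for c, v in records]
    pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "volume_mm3"]).to_csv(path, index=False)


def read_fiducials_csv(path: str | Path) -> list[tuple[np.ndarray, float]]:
    df = pd.read_csv(path)
    return [
        (row[["x_mm", "y_mm", "z_mm"]].to_numpy(float), float(row["volume_mm3"]))
        for _, row in df.iterrows()
    ]


def transform_to_json(t: RigidTransform, path: str | Path | None = None) -> str:
    payload = json.dumps({"matrix": [[float(x) for x in row] for row in t.matrix]}, indent=2)
    if path is not None:
        Path(path).write_text(payload)
    return payload


def transform_from_json(path: str | Path) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    return RigidTransform(np.asarray(data["matrix"], dtype=float))


def read_targets(path: str | Path) -> list[np.ndarray]:
    """Targets as JSON [[x,y,z], ...] or CSV with x_mm,y_mm,z_mm columns."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [np.asarray(p, dtype=float) for p in data]
    df = pd.read_csv(path)
    return [row[["x_mm", "y_mm", "z_mm"]].to_numpy(float) for _, row in df.iterrows()]
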