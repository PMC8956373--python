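"""Needle placement accuracy metrics.

The sampled tissue is not at the guide-needle tip: the biopsy notch extends
past the cannula, so the biopsy center is taken 10 mm beyond the detected tip
along the needle axis. Placement error is then the vector from the annotated
target to that center, decomposed into a signed axial component (along the
needle) and a lateral component (normal to it), with
dev3d^2 = lateral^2 + axial^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BIOPSY_CENTER_OFFSET_MM = 10.0


@dataclass
class NeedleObservation:
    """One insertion: detected needle tip and entry, annotated target."""

    tip: np.ndarray
    entry: np.ndarray
    target: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        self.entry = np.asarray(self.entry, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if np.allclose(self.tip, self.entry):
            raise ValueError("tip and entry coincide; needle axis undefined")


@dataclass
class DeviationResult:
    biopsy_center: np.ndarray
    dev3d: float  # mm
    lateral: float  # mm, >= 0
    axial: float  # mm, signed along the insertion direction
    label: str = ""


def biopsy_center(
    obs: NeedleObservation,
    offset: float = BIOPSY_CENTER_OFFSET_MM,
    beyond_tip: bool = True,
) -> np.ndarray:
    """Center of the biopsy sample: ``offset`` mm from the tip along the
    needle axis, beyond the tip by default (where the notch sits)."""
    u = obs.tip - obs.entry
    u = u / np.linalg.norm(u)
    return obs.tip + (offset if beyond_tip else -offset) * u


def deviations(
    obs: NeedleObservation,
    offset: float = BIOPSY_CENTER_OFFSET_MM,
    beyond_tip: bool = True,
    from_tip: bool = False,
) -> DeviationResult:
    """Placement error of one insertion.

    ``from_tip=True`` measures the lateral/axial decomposition from the tip
    instead of the biopsy center.
    """
    center = biopsy_center(obs, offset=offset, beyond_tip=beyond_tip)
    ref = obs.tip if from_tip else center
    u = obs.tip - obs.entry
    u = u / np.linalg.norm(u)
    e = ref - obs.target
    axial = float(e @ u)
    lateral = float(np.linalg.norm(e - axial * u))
    return DeviationResult(
        biopsy_center=center,
        dev3d=float(np.linalg.norm(e)),
        lateral=lateral,
        axial=axial,
        label=obs.label,
    )


def summarize(results: list[DeviationResult]) -> pd.DataFrame:
    """Per-label mean +/- sample SD of the 3-D and lateral deviations.

    Groups appear in first-encounter order. Single-member groups report
    SD 0 with ``single_observation`` flagged.
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    order: list[str] = []
    for r in results:
        if r.label not in order:
            order.append(r.label)
        rows.append({"label": r.label, "dev3d_mm": r.dev3d, "lateral_mm": r.lateral})
    df = pd.DataFrame(rows)
    out = []
    for label in order:
        g = df[df.label == label]
        n = len(g)
        out.append({
            "label": label,
            "n": n,
            "mean_dev3d_mm": g.dev3d_mm.mean(),
            "sd_dev3d_mm": g.dev3d_mm.std(ddof=1) if n > 1 else 0.0,
            "mean_lateral_mm": g.lateral_mm.mean(),
            "sd_lateral_mm": g.lateral_mm.std(ddof=1) if n > 1 else 0.0,
            "single_observation": n == 1,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_OBS_COLUMNS = [
    "label",
    "target_x_mm", "target_y_mm", "target_z_mm",
    "tip_x_mm", "tip_y_mm", "tip_z_mm",
    "entry_x_mm", "entry_y_mm", "entry_z_mm",
]


def read_observations(path: str | Path) -> list[NeedleObservation]:
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    return [
        NeedleObservation(
            tip=row[["tip_x_mm", "tip_y_mm", "tip_z_mm"]].to_numpy(float),
            entry=row[["entry_x_mm", "entry_y_mm", "entry_z_mm"]].to_numpy(float),
            target=row[["target_x_mm", "target_y_mm", "target_z_mm"]].to_numpy(float),
            label=str(row["label"]),
        )
        for _, row in df.iterrows()
    ]


def write_observations(observations: list[NeedleObservation], path: str | Path) -> None:
    rows = [
        [o.label, *o.target, *o.tip, *o.entry]
        for o in observations
    ]
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, index=False)
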