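"""Immunoblot densitometry arithmetic for in vitro sensor validation.

Band densities arrive pre-quantified (gel-image segmentation is out of
scope): per lane, a full-length sensor band, the summed cleavage-fragment
bands, a beta-actin loading control and optionally a calpain-1 band.
Two normalisations are supported: any band against the loading control,
and cleaved against full-length sensor (the cleavage ratio).  Both are
ratios and therefore invariant to uniform lane-wise exposure changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "BlotLane",
    "normalize_to_loading",
    "cleavage_ratio",
    "read_lane_table",
    "normalize_table",
]


@dataclass(frozen=True)
class BlotLane:
    """One gel lane: condition label plus band densities in arbitrary units."""

    label: str
    full_length_density: float
    cleaved_density: float
    loading_control_density: float
    target_density: float | None = None

    def __post_init__(self) -> None:
        for name in ("full_length_density", "cleaved_density", "loading_control_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.target_density is not None and self.target_density < 0:
            raise ValueError("target_density must be >= 0")


def normalize_to_loading(
    lane: BlotLane, which: Literal["full_length", "cleaved", "target"]
) -> float:
    """Selected band density divided by the beta-actin loading control."""
    if lane.loading_control_density <= 0:
        raise DegenerateDataError(
            f"lane {lane.label!r}: loading control density is zero; "
            "normalisation is undefined"
        )
    if which == "full_length":
        num = lane.full_length_density
    elif which == "cleaved":
        num = lane.cleaved_density
    elif which == "target":
        if lane.target_density is None:
            raise DegenerateDataError(f"lane {lane.label!r} has no target band")
        num = lane.target_density
    else:
        raise ValueError(f"unknown band {which!r}")
    return num / lane.loading_control_density


def cleavage_ratio(lane: BlotLane) -> float:
    """Cleaved-sensor density divided by full-length sensor density."""
    if lane.full_length_density <= 0:
        raise DegenerateDataError(
            f"lane {lane.label!r}: full-length density is zero; the cleavage "
            "ratio is undefined"
        )
    return lane.cleaved_density / lane.full_length_density


def read_lane_table(path: str | Path) -> list[BlotLane]:
    """Read a lane table CSV (columns: lane, condition, full_length, cleaved,
    actin, optional target) into :class:`BlotLane` objects labelled by condition."""
    df = pd.read_csv(path)
    required = {"condition", "full_length", "cleaved", "actin"}
    missing = required - set(df.columns)
    if missing:
        raise DegenerateDataError(f"lane table missing column(s): {sorted(missing)}")
    lanes = []
    for _, row in df.iterrows():
        lanes.append(
            BlotLane(
                label=str(row["condition"]),
                full_length_density=float(row["full_length"]),
                cleaved_density=float(row["cleaved"]),
                loading_control_density=float(row["actin"]),
                target_density=float(row["target"]) if "target" in df.columns else None,
            )
        )
    return lanes


def normalize_table(lanes: Sequence[BlotLane]) -> pd.DataFrame:
    """Per-lane normalised quantities as a tidy DataFrame."""
    rows = []
    for lane in lanes:
        rows.append(
            {
                "condition": lane.label,
                "full_length_over_actin": normalize_to_loading(lane, "full_length"),
                "cleaved_over_actin": normalize_to_loading(lane, "cleaved"),
                "cleavage_ratio": cleavage_ratio(lane),
                "target_over_actin": (
                    normalize_to_loading(lane, "target")
                    if lane.target_density is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
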