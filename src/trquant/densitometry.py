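"""Western-blot densitometry: readthrough fraction and relative protein level.

Each lane of a quantified blot contributes a full-length band intensity,
a truncated band intensity, and optionally a loading-control intensity.
Readthrough is the full-length fraction of total reporter protein,

    RT = I_fl / (I_fl + I_trunc),

and the relative protein level of a PTC construct is its total signal
(full-length + truncated by default) divided by the wildtype lane's
signal on the same blot — cross-blot comparisons are refused because
densitometric intensities are not comparable between exposures.
Loading-control normalization is available but off by default, matching
the plain ratio formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BlotPairingError, FormatError, RatioError


@dataclass(frozen=True)
class BlotLane:
    construct_id: str
    treatment: str
    intensity_fl: float
    intensity_trunc: float
    blot_id: str = "blot1"
    intensity_loading: float | None = None

    def __post_init__(self) -> None:
        for name in ("intensity_fl", "intensity_trunc"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.intensity_loading is not None and self.intensity_loading <= 0:
            raise ValueError("intensity_loading must be positive when present")

    @property
    def total(self) -> float:
        return self.intensity_fl + self.intensity_trunc


def blot_readthrough(lane: BlotLane) -> float:
    """Full-length fraction of total signal, in [0, 1]."""
    if lane.total == 0:
        raise RatioError(
            f"lane {lane.construct_id}/{lane.treatment}: both band intensities are zero"
        )
    return lane.intensity_fl / lane.total


def relative_level(
    lane: BlotLane,
    wildtype_lane: BlotLane,
    use_total: bool = True,
    normalize_loading: bool = False,
) -> float:
    """PTC-construct signal relative to the wildtype lane on the same blot.

    ``use_total`` selects total (FL + truncated) versus full-length-only
    signal for the PTC lane; ``normalize_loading`` divides each lane's
    signal by its loading-control intensity first.
    """
    if lane.blot_id != wildtype_lane.blot_id:
        raise BlotPairingError(
            f"cannot compare lane on blot {lane.blot_id!r} with wildtype on "
            f"blot {wildtype_lane.blot_id!r}"
        )
    signal = lane.total if use_total else lane.intensity_fl
    reference = wildtype_lane.total
    if normalize_loading:
        if lane.intensity_loading is None or wildtype_lane.intensity_loading is None:
            raise RatioError("loading-control normalization requires loading intensities")
        signal /= lane.intensity_loading
        reference /= wildtype_lane.intensity_loading
    if reference == 0:
        raise RatioError("wildtype lane has zero total intensity")
    return signal / reference


def read_lane_csv(path: str | Path) -> list[BlotLane]:
    """Read lanes from CSV (blot_id, construct_id, treatment, intensity_fl,
    intensity_trunc[, intensity_loading])."""
    frame = pd.read_csv(path)
    required = ["blot_id", "construct_id", "treatment", "intensity_fl", "intensity_trunc"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    lanes = []
    for row in frame.itertuples(index=False):
        loading = getattr(row, "intensity_loading", None)
        if loading is not None and pd.isna(loading):
            loading = None
        lanes.append(
            BlotLane(
                blot_id=str(row.blot_id),
                construct_id=str(row.construct_id),
                treatment=str(row.treatment),
                intensity_fl=float(row.intensity_fl),
                intensity_trunc=float(row.intensity_trunc),
                intensity_loading=None if loading is None else float(loading),
            )
        )
    return lanes


def quantify_lanes(lanes: list[BlotLane]) -> pd.DataFrame:
    """Per-lane readthrough plus per-group (construct x treatment) mean/sd."""
    rows = [
        {
            "blot_id": lane.blot_id,
            "construct_id": lane.construct_id,
            "treatment": lane.treatment,
            "readthrough_fraction": blot_readthrough(lane),
        }
        for lane in lanes
    ]
    frame = pd.DataFrame(rows)
    summary = (
        frame.groupby(["construct_id", "treatment"])["readthrough_fraction"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return frame.merge(summary, on=["construct_id", "treatment"], how="left")
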