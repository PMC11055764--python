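"""Reading per-event flow-cytometry tables and 96-well plate layouts.

The canonical interchange format is plain CSV: one event table with
columns ``well_id, fsc, ssc, rfp, gfp`` and one layout table mapping
every well to its plate, construct, role, treatment, replicate and
experiment.  Events are held as a pandas DataFrame per well; no
compensation or transformation is applied (gating operates on raw
intensities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, LayoutError

EVENT_COLUMNS = ["fsc", "ssc", "rfp", "gfp"]

#: Well roles recognised by the pipeline.
ROLE_SAMPLE = "sample"
ROLE_CONTROL_100 = "control_100"
ROLE_BACKGROUND = "background_rfp_only"
ROLE_UNTRANSFECTED = "untransfected"
ROLES = (ROLE_SAMPLE, ROLE_CONTROL_100, ROLE_BACKGROUND, ROLE_UNTRANSFECTED)

TREATMENTS = ("none", "geneticin")

LAYOUT_COLUMNS = [
    "well_id",
    "plate_id",
    "construct_id",
    "role",
    "treatment",
    "replicate_id",
    "experiment_id",
]


class FlowEvent(NamedTuple):
    """One measured cell: scatter and fluorescence intensities (a.u.)."""

    fsc: float
    ssc: float
    rfp: float
    gfp: float


@dataclass
class WellRecord:
    """A well's events plus its plate metadata and role."""

    plate_id: str
    well_id: str
    construct_id: str
    role: str
    treatment: str = "none"
    replicate_id: str = "1"
    experiment_id: str = "1"
    events: pd.DataFrame = field(default_factory=lambda: _empty_events())

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LayoutError(
                f"well {self.well_id}: unknown role {self.role!r}; expected one of {ROLES}"
            )

    @property
    def n_events(self) -> int:
        return len(self.events)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS})


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_event_table(path: str | Path, layout_path: str | Path) -> list[WellRecord]:
    """Attach every event to its well, using the plate layout as ground truth.

    Wells present in the layout but absent from the event table are
    returned empty with a warning; an event referencing a well that the
    layout does not know is an error.
    """
    events = pd.read_csv(path)
    _require_columns(events, ["well_id"] + EVENT_COLUMNS, str(path))
    layout = read_layout(layout_path)

    if not np.isfinite(events[EVENT_COLUMNS].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite event values")

    known = set(zip(layout["plate_id"], layout["well_id"]))
    if "plate_id" in events.columns:
        keys = list(zip(events["plate_id"], events["well_id"]))
        unknown = sorted({k for k in keys if k not in known})
    else:
        wells = set(layout["well_id"])
        if len(wells) < len(layout):
            raise LayoutError(
                "event table has no plate_id column but layout well_ids are "
                "not unique across plates"
            )
        unknown = sorted(set(events["well_id"]) - wells)
    if unknown:
        raise LayoutError(f"events reference wells absent from layout: {unknown}")

    records: list[WellRecord] = []
    grouped = (
        events.groupby(["plate_id", "well_id"], sort=False)
        if "plate_id" in events.columns
        else events.groupby("well_id", sort=False)
    )
    chunks = {key: df for key, df in grouped}
    for row in layout.itertuples(index=False):
        key = (
            (row.plate_id, row.well_id)
            if "plate_id" in events.columns
            else row.well_id
        )
        chunk = chunks.get(key)
        if chunk is None:
            warnings.warn(
                f"well {row.plate_id}/{row.well_id} is in the layout but has no events",
                stacklevel=2,
            )
            well_events = _empty_events()
        else:
            well_events = chunk[EVENT_COLUMNS].reset_index(drop=True).astype(float)
        records.append(
            WellRecord(
                plate_id=str(row.plate_id),
                well_id=str(row.well_id),
                construct_id=str(row.construct_id),
                role=str(row.role),
                treatment=str(row.treatment),
                replicate_id=str(row.replicate_id),
                experiment_id=str(row.experiment_id),
                events=well_events,
            )
        )
    return records


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path, dtype=str)
    _require_columns(layout, LAYOUT_COLUMNS, str(path))
    bad_roles = sorted(set(layout["role"]) - set(ROLES))
    if bad_roles:
        raise LayoutError(f"{path}: unknown roles {bad_roles}")
    return layout


def write_well_records(
    records: list[WellRecord], event_path: str | Path, layout_path: str | Path
) -> None:
    """Write wells back to the canonical event + layout CSV pair."""
    layout_rows = []
    event_frames = []
    for rec in records:
        layout_rows.append(
            {
                "well_id": rec.well_id,
                "plate_id": rec.plate_id,
                "construct_id": rec.construct_id,
                "role": rec.role,
                "treatment": rec.treatment,
                "replicate_id": rec.replicate_id,
                "experiment_id": rec.experiment_id,
            }
        )
        if rec.n_events:
            chunk = rec.events[EVENT_COLUMNS].copy()
            chunk.insert(0, "well_id", rec.well_id)
            chunk.insert(0, "plate_id", rec.plate_id)
            event_frames.append(chunk)
    pd.DataFrame(layout_rows, columns=LAYOUT_COLUMNS).to_csv(layout_path, index=False)
    if event_frames:
        pd.concat(event_frames, ignore_index=True).to_csv(event_path, index=False)
    else:
        pd.DataFrame(columns=["plate_id", "well_id"] + EVENT_COLUMNS).to_csv(
            event_path, index=False
        )
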