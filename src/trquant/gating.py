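"""Rectangular scatter gating and fluorescence inclusion.

Cells are first gated on forward/side scatter with inclusive bounds
(defaults: FSC 23,000-75,000, SSC 12,500-67,500 a.u., the settings used
for HeLa cells on the assay's cytometer).  Of the gated cells, only
those with RFP strictly above 700 or GFP strictly above 100 enter the
readthrough calculation — this keeps reporter-expressing cells and
drops the untransfected background population.  Both boundary
conventions (inclusive scatter, strict fluorescence) follow the assay
description literally and can be flipped via the config if an
instrument's export semantics differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GateConfig:
    """Scatter gate bounds and fluorescence inclusion thresholds (a.u.)."""

    fsc_min: float = 23_000.0
    fsc_max: float = 75_000.0
    ssc_min: float = 12_500.0
    ssc_max: float = 67_500.0
    rfp_threshold: float = 700.0
    gfp_threshold: float = 100.0
    scatter_inclusive: bool = True
    fluorescence_strict: bool = True
    #: wells with fewer included events than this are flagged low-n and
    #: excluded from replicate aggregation (guards ratio instability)
    min_included_events: int = 500

    def __post_init__(self) -> None:
        if not (self.fsc_min < self.fsc_max and self.ssc_min < self.ssc_max):
            raise ValueError("scatter gate bounds must satisfy min < max")
        if self.rfp_threshold < 0 or self.gfp_threshold < 0:
            raise ValueError("fluorescence thresholds must be non-negative")


def gate_scatter(events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Keep events inside the rectangular FSC/SSC gate; order preserved."""
    fsc = events["fsc"].to_numpy()
    ssc = events["ssc"].to_numpy()
    if cfg.scatter_inclusive:
        keep = (
            (fsc >= cfg.fsc_min)
            & (fsc <= cfg.fsc_max)
            & (ssc >= cfg.ssc_min)
            & (ssc <= cfg.ssc_max)
        )
    else:
        keep = (
            (fsc > cfg.fsc_min)
            & (fsc < cfg.fsc_max)
            & (ssc > cfg.ssc_min)
            & (ssc < cfg.ssc_max)
        )
    return events.loc[keep]


def select_fluorescent(gated_events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Keep gated events with RFP above the red or GFP above the green threshold."""
    rfp = gated_events["rfp"].to_numpy()
    gfp = gated_events["gfp"].to_numpy()
    if cfg.fluorescence_strict:
        keep = (rfp > cfg.rfp_threshold) | (gfp > cfg.gfp_threshold)
    else:
        keep = (rfp >= cfg.rfp_threshold) | (gfp >= cfg.gfp_threshold)
    return gated_events.loc[keep]


@dataclass(frozen=True)
class WellSummary:
    """Per-well aggregate of included events."""

    n_included: int
    mean_rfp: float
    mean_gfp: float

    @property
    def empty(self) -> bool:
        return self.n_included == 0


def well_summary(included_events: pd.DataFrame) -> WellSummary:
    """Mean RFP/GFP over included events; an empty well yields NaN means."""
    n = len(included_events)
    if n == 0:
        return WellSummary(n_included=0, mean_rfp=float("nan"), mean_gfp=float("nan"))
    return WellSummary(
        n_included=n,
        mean_rfp=float(np.mean(included_events["rfp"].to_numpy())),
        mean_gfp=float(np.mean(included_events["gfp"].to_numpy())),
    )


def apply_gates(events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Scatter gate followed by the fluorescence inclusion rule."""
    return select_fluorescent(gate_scatter(events, cfg), cfg)
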