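"""Background-corrected, control-normalized readthrough quantification.

The dual reporter expresses RFP constitutively and GFP only when the
ribosome reads through the stop codon between them, so a well's
readthrough is proportional to its GFP/RFP ratio.  Three corrections
turn raw ratios into comparable percentages:

1. the plate's mean GFP signal from RFP-only background wells (channel
   bleed-through plus autofluorescence) is subtracted from every well's
   mean GFP;
2. the corrected GFP/RFP ratio is computed as a ratio of well-level
   means (robust to low-RFP events);
3. the ratio is normalized to the mean ratio of the same plate's 100%
   readthrough control wells (RFP fused in frame to GFP with no stop),
   yielding TR% = 100 x sample_ratio / control_ratio.

All normalization is strictly per plate: control and background wells
are measured on every plate.  Replicate wells are aggregated per
construct x treatment, and groups are compared by one-way ANOVA with
Bonferroni-corrected post hoc t-tests against a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AggregationError, NormalizationError, RatioError, StatError
from .flow_io import ROLE_BACKGROUND, ROLE_CONTROL_100, ROLE_SAMPLE, WellRecord
from .gating import GateConfig, WellSummary, apply_gates, well_summary

#: significance tiers at the printed post hoc cutoffs
SIGNIFICANCE_TIERS = ((0.001, "***"), (0.002, "**"), (0.033, "*"))


@dataclass
class TRResult:
    """Aggregated readthrough for one construct x treatment group."""

    construct_id: str
    treatment: str
    per_well_tr: list[float]
    wells: list[tuple[str, str, str]] = field(default_factory=list)  # (plate, well, experiment)
    mean_tr: float = float("nan")
    sd_tr: float = float("nan")
    n: int = 0


def plate_background_gfp(plate_wells: list[tuple[WellRecord, WellSummary]]) -> float:
    """Mean of mean-GFP over the plate's RFP-only background wells."""
    values = [
        s.mean_gfp
        for rec, s in plate_wells
        if rec.role == ROLE_BACKGROUND and not s.empty
    ]
    if not values:
        raise NormalizationError("plate has no background (RFP-only) well with events")
    return float(np.mean(values))


def well_ratio(summary: WellSummary, background_gfp: float) -> float:
    """Background-corrected GFP/RFP ratio; negative corrected GFP clamps to 0."""
    if summary.empty:
        raise RatioError("cannot compute a ratio for an empty well")
    if summary.mean_rfp == 0:
        raise RatioError("mean RFP is zero")
    return max(0.0, summary.mean_gfp - background_gfp) / summary.mean_rfp


def normalize_tr(sample_ratio: float, plate_control_ratios: list[float]) -> float:
    """TR% = 100 x sample ratio / mean ratio of the plate's 100% controls."""
    if not plate_control_ratios:
        raise NormalizationError("plate has no 100% readthrough control ratio")
    control = float(np.mean(plate_control_ratios))
    if control == 0:
        raise NormalizationError("100% control ratio is zero")
    return 100.0 * sample_ratio / control


def aggregate_tr(
    per_well: list[tuple[float, tuple[str, str, str]]],
    construct_id: str,
    treatment: str,
) -> TRResult:
    """Mean and sample sd (n-1) of TR% across a group's wells."""
    if not per_well:
        raise AggregationError(f"no wells for group ({construct_id}, {treatment})")
    values = [v for v, _ in per_well]
    result = TRResult(
        construct_id=construct_id,
        treatment=treatment,
        per_well_tr=values,
        wells=[w for _, w in per_well],
        n=len(values),
    )
    result.mean_tr = float(np.mean(values))
    result.sd_tr = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return result


# --- group comparison --------------------------------------------------------


@dataclass
class AnovaTable:
    F: float
    df_between: int
    df_within: int
    p_overall: float
    pairwise: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise)


def _tier(p: float) -> str:
    for cutoff, symbol in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return symbol
    return "ns"


def anova_bonferroni(
    groups: dict[str, list[float]], reference_group: str
) -> AnovaTable:
    """One-way fixed-effects ANOVA with Bonferroni post hoc vs a reference.

    The F statistic is computed from between/within sums of squares; the
    post hoc comparisons are two-sided t-tests of each group against the
    reference using the pooled within-group mean square, with p values
    multiplied by the number of comparisons (clamped at 1).
    """
    if reference_group not in groups:
        raise StatError(f"reference group {reference_group!r} not among groups")
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise StatError("ANOVA needs >= 2 groups with >= 2 values each")

    n_total = sum(len(a) for a in arrays)
    grand = float(np.concatenate(arrays).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
        p_overall = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = ms_between / ms_within
        p_overall = float(stats.f.sf(f_stat, df_between, df_within))

    ref = np.asarray(groups[reference_group], dtype=float)
    m = len(names) - 1  # comparisons against the reference
    pairwise = []
    for name in names:
        if name == reference_group:
            continue
        a = np.asarray(groups[name], dtype=float)
        diff = a.mean() - ref.mean()
        if ms_within == 0:
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(ms_within * (1 / len(a) + 1 / len(ref)))
            t = diff / se
            p_raw = 2.0 * float(stats.t.sf(abs(t), df_within))
        p_bonf = min(1.0, m * p_raw)
        pairwise.append(
            {
                "group": name,
                "reference": reference_group,
                "mean_difference": float(diff),
                "p_raw": float(p_raw),
                "p_bonferroni": float(p_bonf),
                "significance": _tier(p_bonf),
            }
        )
    return AnovaTable(
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_overall=p_overall,
        pairwise=pairwise,
    )


# --- orchestration -----------------------------------------------------------


def quantify_wells(
    records: list[WellRecord], cfg: GateConfig | None = None
) -> tuple[pd.DataFrame, list[TRResult]]:
    """Run gating, background correction and per-plate normalization.

    Returns the tidy per-well table (one row per control_100 or sample
    well, columns plate_id/well_id/construct_id/treatment/n_included/
    mean_rfp/mean_gfp_corrected/ratio/tr_percent/low_n) and the
    aggregated per-group results.  Wells below the minimum included-event
    count are kept in the table, flagged low_n, and left out of the
    aggregation.
    """
    cfg = cfg or GateConfig()

    by_plate: dict[str, list[tuple[WellRecord, WellSummary]]] = {}
    for rec in records:
        included = apply_gates(rec.events, cfg)
        by_plate.setdefault(rec.plate_id, []).append((rec, well_summary(included)))

    rows = []
    grouped: dict[tuple[str, str], list[tuple[float, tuple[str, str, str]]]] = {}
    for plate_id, plate_wells in by_plate.items():
        background = plate_background_gfp(plate_wells)
        control_ratios = [
            well_ratio(s, background)
            for rec, s in plate_wells
            if rec.role == ROLE_CONTROL_100 and not s.empty
        ]
        if not control_ratios:
            raise NormalizationError(f"plate {plate_id} has no usable 100% control")
        for rec, s in plate_wells:
            if rec.role not in (ROLE_SAMPLE, ROLE_CONTROL_100):
                continue
            if s.empty:
                continue
            ratio = well_ratio(s, background)
            tr = normalize_tr(ratio, control_ratios)
            low_n = s.n_included < cfg.min_included_events
            rows.append(
                {
                    "plate_id": rec.plate_id,
                    "well_id": rec.well_id,
                    "construct_id": rec.construct_id,
                    "role": rec.role,
                    "treatment": rec.treatment,
                    "experiment_id": rec.experiment_id,
                    "n_included": s.n_included,
                    "mean_rfp": s.mean_rfp,
                    "mean_gfp_corrected": max(0.0, s.mean_gfp - background),
                    "ratio": ratio,
                    "tr_percent": tr,
                    "low_n": low_n,
                }
            )
            if rec.role == ROLE_SAMPLE and not low_n:
                grouped.setdefault((rec.construct_id, rec.treatment), []).append(
                    (tr, (rec.plate_id, rec.well_id, rec.experiment_id))
                )

    results = [
        aggregate_tr(values, construct_id, treatment)
        for (construct_id, treatment), values in grouped.items()
    ]
    return pd.DataFrame(rows), results


def results_to_frame(results: list[TRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": r.construct_id,
                "treatment": r.treatment,
                "mean_tr": r.mean_tr,
                "sd_tr": r.sd_tr,
                "n": r.n,
            }
            for r in results
        ]
    )
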