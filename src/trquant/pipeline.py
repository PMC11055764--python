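"""Pipeline orchestration: file-in, file-out runs of each analysis.

Each ``run_*`` function is pure given (input files, config, seed): it
reads the canonical CSV formats, executes the corresponding module, and
writes tidy CSV outputs.  The CLI in :mod:`trquant.cli` is a thin shell
over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, densitometry, localization, synthetic
from .errors import ConfigError
from .flow_io import read_event_table, write_well_records
from .gating import GateConfig
from .readthrough import anova_bonferroni, quantify_wells, results_to_frame

log = logging.getLogger("trquant")


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide settings; defaults reproduce the assay's published setup."""

    gate: GateConfig = dataclasses.field(default_factory=GateConfig)
    reference_group: str | None = None  # construct_id to compare against
    nuclear_cutoff: float = 2.0
    cytoplasmic_cutoff: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gate = GateConfig(**raw.pop("gate", {}))
        try:
            return cls(gate=gate, **raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_quantify_flow(
    event_path: str | Path,
    layout_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Gate, correct, normalize and aggregate a flow run.

    Writes ``per_well.csv`` and ``per_group.csv`` (and ``anova.csv`` when
    a reference group is configured) into ``out_dir``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("quantify-flow config %s", config.digest())

    records = read_event_table(event_path, layout_path)
    per_well, results = quantify_wells(records, config.gate)
    for row in per_well.itertuples(index=False):
        log.info(
            "well %s/%s: %d events included", row.plate_id, row.well_id, row.n_included
        )

    outputs = {}
    per_well_path = out_dir / "per_well.csv"
    per_well.to_csv(per_well_path, index=False)
    outputs["per_well"] = per_well_path

    per_group = results_to_frame(results)
    per_group_path = out_dir / "per_group.csv"
    per_group.to_csv(per_group_path, index=False)
    outputs["per_group"] = per_group_path

    if config.reference_group is not None:
        treated = {
            f"{r.construct_id}:{r.treatment}": r.per_well_tr
            for r in results
        }
        reference = next(
            (k for k in treated if k.startswith(config.reference_group + ":")), None
        )
        if reference is None:
            raise ConfigError(
                f"reference group {config.reference_group!r} not found in results"
            )
        table = anova_bonferroni(treated, reference)
        anova_path = out_dir / "anova.csv"
        frame = table.to_frame()
        frame.insert(0, "F", table.F)
        frame.insert(1, "p_overall", table.p_overall)
        frame.to_csv(anova_path, index=False)
        outputs["anova"] = anova_path
    return outputs


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    config: synthetic.SimConfig | None = None,
    n_events_per_well: int | None = None,
) -> dict[str, Path]:
    """Simulate a full plate set and write the canonical event/layout CSVs."""
    cfg = config or synthetic.SimConfig(seed=seed)
    if config is not None and seed != cfg.seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    if n_events_per_well is not None:
        cfg = dataclasses.replace(cfg, n_events_per_well=n_events_per_well)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = synthetic.simulate_plate_set(cfg)
    event_path = out_dir / "events.csv"
    layout_path = out_dir / "layout.csv"
    write_well_records(records, event_path, layout_path)
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(
        [
            {"construct_id": c, "treatment": t, "tr_true": v}
            for (c, t), v in cfg.truth_table.items()
        ]
    ).to_csv(truth_path, index=False)
    return {"events": event_path, "layout": layout_path, "truth": truth_path}


def run_agreement(
    paired_csv: str | Path, out_dir: str | Path, plot: bool = False
) -> dict[str, Path]:
    """Lin's CCC + Bland-Altman for a paired two-assay table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, y, constructs = agreement.read_paired_csv(paired_csv)
    result = agreement.compare_assays(x, y)
    summary_path = out_dir / "agreement.csv"
    pd.DataFrame(
        [
            {
                "ccc": result.ccc,
                "pearson": result.pearson,
                "bias": result.bias,
                "loa_low": result.loa_low,
                "loa_high": result.loa_high,
                "n_pairs": len(result.pairs),
                "n_outside_limits": int(result.pairs["outside_limits"].sum()),
            }
        ]
    ).to_csv(summary_path, index=False)
    pairs = result.pairs.copy()
    pairs.insert(0, "construct_id", constructs)
    pairs_path = out_dir / "agreement_pairs.csv"
    pairs.to_csv(pairs_path, index=False)
    outputs = {"agreement": summary_path, "pairs": pairs_path}
    if plot:
        plot_path = out_dir / "bland_altman.png"
        agreement.plot_bland_altman(result, plot_path)
        outputs["plot"] = plot_path
    return outputs


def run_quantify_blot(lane_csv: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Per-lane and per-group densitometric readthrough."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lanes = densitometry.read_lane_csv(lane_csv)
    frame = densitometry.quantify_lanes(lanes)
    path = out_dir / "blot_readthrough.csv"
    frame.to_csv(path, index=False)
    return {"blot_readthrough": path}


def run_profiles(profile_csv: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> dict[str, Path]:
    """Score nuclear enrichment for every cell in a profile table."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = localization.read_profile_csv(profile_csv)
    scorer = localization.LocalizationScorer(
        nuclear_cutoff=config.nuclear_cutoff,
        cytoplasmic_cutoff=config.cytoplasmic_cutoff,
    )
    frame = localization.score_profiles(profiles, scorer)
    path = out_dir / "localization_scores.csv"
    frame.to_csv(path, index=False)
    return {"scores": path}
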