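"""Synthetic assay data with known ground truth.

Generators for the three data types the pipeline consumes:

* 96-well flow-cytometry plates whose wells mix an untransfected
  subpopulation with transfected cells expressing the dual reporter.
  Per-cell reporter expression E is log-normal; the red channel reads
  c_R * E and the green channel reads tr_true * c_G * E plus a
  bleed-through term proportional to the red signal, each with
  multiplicative log-normal measurement noise and additive
  autofluorescence.  GFP output is linear in the readthrough fraction
  (one GFP per readthrough event per transcript).  Every plate carries
  triplicate 100%-control, RFP-only background, and untransfected
  wells, and each sample group appears as 3 replicate wells on each of
  3 experiment plates (9 wells per group), with 10,000 events per well.
* Western-blot lanes splitting a common lane amount A into full-length
  (A * r) and truncated (A * (1 - r)) bands, each with independent
  multiplicative log-normal noise.
* Localization line profiles: a Gaussian DAPI bump in the central third
  of the line and a Flag channel whose inside/outside mean ratio is set
  by the planted localization class.

Randomness: one root seed; each well draws from an independent child
generator keyed by (root seed, plate index, well index), so any well is
reproducible on its own.  The packaged truth tables carry the TR values
reported for this assay where a number was printed; other entries are
representative values within the reported ranges and are marked
``approx`` below.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .densitometry import BlotLane
from .errors import ConfigError
from .flow_io import (
    ROLE_BACKGROUND,
    ROLE_CONTROL_100,
    ROLE_SAMPLE,
    ROLE_UNTRANSFECTED,
    ROLES,
    WellRecord,
)
from .localization import CYTOPLASMIC, MIXED, NUCLEAR, LineProfile

# --- packaged ground-truth tables -------------------------------------------

#: Dual-reporter TR fractions per (construct, treatment).  Printed assay
#: values: R198X basal 1.4%, R198X induced 17%, R270X induced 21%,
#: K175X induced 5.35%.  Remaining entries are representative of the
#: reported ranges (basal ~0.1% except the two elevated UGA variants;
#: induced <1% for UAA, ~3-4% for UAG, ~4-21% for UGA) -- approx.
FLOW_TRUTH: Mapping[tuple[str, str], float] = {
    ("R198X", "none"): 0.014,
    ("R270X", "none"): 0.012,  # approx (>1%)
    ("Q244X", "none"): 0.004,  # approx (elevated basal)
    ("S49X", "none"): 0.001,  # approx
    ("S68X", "none"): 0.001,  # approx
    ("Y141X", "none"): 0.001,  # approx
    ("R168X", "none"): 0.001,  # approx
    ("K175X", "none"): 0.001,  # approx
    ("K177X", "none"): 0.001,  # approx
    ("S204X", "none"): 0.001,  # approx
    ("R255X", "none"): 0.001,  # approx
    ("R294X", "none"): 0.001,  # approx
    ("K363X", "none"): 0.001,  # approx
    ("Q406X", "none"): 0.001,  # approx
    ("R198X", "geneticin"): 0.17,
    ("R270X", "geneticin"): 0.21,
    ("K175X", "geneticin"): 0.0535,
    ("S49X", "geneticin"): 0.007,  # approx (UAA, <1%)
    ("K177X", "geneticin"): 0.008,  # approx (UAA, <1%)
    ("Y141X", "geneticin"): 0.035,  # approx (UAG, intermediate)
    ("Q244X", "geneticin"): 0.035,  # approx
    ("K363X", "geneticin"): 0.03,  # approx
    ("Q406X", "geneticin"): 0.03,  # approx
    ("R294X", "geneticin"): 0.035,  # approx
    ("S68X", "geneticin"): 0.08,  # approx (UGA G, twofold spread)
    ("R168X", "geneticin"): 0.04,  # approx
    ("S204X", "geneticin"): 0.06,  # approx
    ("R255X", "geneticin"): 0.035,  # approx (UAG-like despite UGA)
}

#: Densitometric readthrough fractions per (construct, treatment).
#: Printed induced values: S49X 1.62%, K177X 2.1%, K363X 2.3%,
#: Q406X 2.5%; R198X reaches ~40%.  Others approx.
BLOT_TRUTH: Mapping[tuple[str, str], float] = {
    ("S49X", "geneticin"): 0.0162,
    ("K177X", "geneticin"): 0.021,
    ("K363X", "geneticin"): 0.023,
    ("Q406X", "geneticin"): 0.025,
    ("R198X", "geneticin"): 0.40,  # approx (~40%)
    ("S68X", "geneticin"): 0.15,  # approx
    ("Y141X", "geneticin"): 0.06,  # approx
    ("R168X", "geneticin"): 0.08,  # approx
    ("K175X", "geneticin"): 0.10,  # approx
    ("S204X", "geneticin"): 0.10,  # approx
    ("Q244X", "geneticin"): 0.07,  # approx
    ("R255X", "geneticin"): 0.03,  # approx
    ("R270X", "geneticin"): 0.03,  # approx (low full-length recovery)
    ("R294X", "geneticin"): 0.07,  # approx
    ("R198X", "none"): 0.02,  # approx (only variant with a basal band)
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the flow-plate generator.

    Defaults emulate the assay's acquisition settings (10,000 events per
    well, triplicate controls per plate, 3 replicates x 3 experiments
    per sample group); expression, gain, noise and transfection values
    are free parameters chosen to put transfected cells well above the
    inclusion thresholds and untransfected cells below them.
    """

    truth_table: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(FLOW_TRUTH)
    )
    n_events_per_well: int = 10_000
    f_transfected: float = 0.4
    mu_expression: float = 7.6  # log a.u.; median E ~ 2000
    sigma_expression: float = 1.0
    gain_rfp: float = 5.0
    gain_gfp: float = 5.0
    sigma_meas: float = 0.05
    gfp_bleed_fraction: float = 0.003  # GFP-channel signal per unit RFP signal
    autofluor_rfp: float = 80.0  # median autofluorescence, a.u.
    autofluor_gfp: float = 10.0
    autofluor_sigma: float = 0.5
    fsc_transfected: tuple[float, float] = (45_000.0, 8_000.0)  # (mean, sd)
    ssc_transfected: tuple[float, float] = (30_000.0, 8_000.0)
    fsc_untransfected: tuple[float, float] = (42_000.0, 8_000.0)
    ssc_untransfected: tuple[float, float] = (28_000.0, 8_000.0)
    n_replicates_per_plate: int = 3
    n_experiments: int = 3
    n_control_wells: int = 3
    n_background_wells: int = 3
    n_untransfected_wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_transfected <= 1:
            raise ConfigError("f_transfected must be in (0, 1]")
        if any(v < 0 for v in (self.sigma_expression, self.sigma_meas)):
            raise ConfigError("noise scales must be non-negative")
        for (construct, treatment), tr in self.truth_table.items():
            if not 0 <= tr <= 1:
                raise ConfigError(
                    f"truth TR for ({construct}, {treatment}) must be in [0, 1]"
                )

    def zero_noise(self) -> "SimConfig":
        """A copy with all stochastic terms switched off.

        Expression is fixed at its median, measurement noise, bleed and
        autofluorescence are zero, so estimator identities hold exactly
        (100% controls evaluate to exactly 100%, tr=0 to exactly 0%).
        """
        return replace(
            self,
            sigma_expression=0.0,
            sigma_meas=0.0,
            gfp_bleed_fraction=0.0,
            autofluor_rfp=0.0,
            autofluor_gfp=0.0,
            autofluor_sigma=0.0,
        )


def _well_rng(cfg: SimConfig, plate_index: int, well_index: int) -> np.random.Generator:
    """Child generator keyed by (root seed, plate index, well index)."""
    return np.random.default_rng([cfg.seed, plate_index, well_index])


def _lognormal_noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 (mu = -sigma^2/2)."""
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(-0.5 * sigma**2, sigma, n)


def _autofluor(
    rng: np.random.Generator, median: float, sigma: float, n: int
) -> np.ndarray:
    if median == 0:
        return np.zeros(n)
    return median * rng.lognormal(0.0, sigma, n)


def _scatter(
    rng: np.random.Generator, params: tuple[float, float], n: int
) -> np.ndarray:
    mean, sd = params
    return np.clip(rng.normal(mean, sd, n), 0.0, None)


def simulate_events(
    cfg: SimConfig, role: str, tr_true: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one well's events for the given role and true TR fraction."""
    if role not in ROLES:
        raise ConfigError(f"unknown well role {role!r}")
    n = cfg.n_events_per_well
    n_trans = 0 if role == ROLE_UNTRANSFECTED else int(round(cfg.f_transfected * n))
    n_untrans = n - n_trans

    # untransfected subpopulation: autofluorescence only
    rfp_u = _autofluor(rng, cfg.autofluor_rfp, cfg.autofluor_sigma, n_untrans)
    gfp_u = _autofluor(rng, cfg.autofluor_gfp, cfg.autofluor_sigma, n_untrans)
    fsc_u = _scatter(rng, cfg.fsc_untransfected, n_untrans)
    ssc_u = _scatter(rng, cfg.ssc_untransfected, n_untrans)

    # transfected subpopulation
    if cfg.sigma_expression == 0:
        expr = np.full(n_trans, np.exp(cfg.mu_expression))
    else:
        expr = rng.lognormal(cfg.mu_expression, cfg.sigma_expression, n_trans)
    rfp_signal = cfg.gain_rfp * expr * _lognormal_noise(rng, cfg.sigma_meas, n_trans)
    bleed = (
        cfg.gfp_bleed_fraction
        * cfg.gain_rfp
        * expr
        * _lognormal_noise(rng, cfg.sigma_meas, n_trans)
    )
    if role == ROLE_BACKGROUND:
        gfp_signal = bleed
    else:
        tr = 1.0 if role == ROLE_CONTROL_100 else tr_true
        gfp_signal = (
            tr * cfg.gain_gfp * expr * _lognormal_noise(rng, cfg.sigma_meas, n_trans)
            + bleed
        )
    rfp_t = rfp_signal + _autofluor(rng, cfg.autofluor_rfp, cfg.autofluor_sigma, n_trans)
    gfp_t = gfp_signal + _autofluor(rng, cfg.autofluor_gfp, cfg.autofluor_sigma, n_trans)
    fsc_t = _scatter(rng, cfg.fsc_transfected, n_trans)
    ssc_t = _scatter(rng, cfg.ssc_transfected, n_trans)

    frame = pd.DataFrame(
        {
            "fsc": np.concatenate([fsc_t, fsc_u]),
            "ssc": np.concatenate([ssc_t, ssc_u]),
            "rfp": np.concatenate([rfp_t, rfp_u]),
            "gfp": np.concatenate([gfp_t, gfp_u]),
        }
    )
    # shuffle so the two subpopulations are interleaved as on an instrument
    order = rng.permutation(len(frame))
    return frame.iloc[order].reset_index(drop=True)


def simulate_well(
    cfg: SimConfig,
    role: str,
    tr_true: float = 0.0,
    plate_index: int = 0,
    well_index: int = 0,
    **metadata,
) -> WellRecord:
    """Simulate one well reproducibly from its (plate, well) indices."""
    rng = _well_rng(cfg, plate_index, well_index)
    events = simulate_events(cfg, role, tr_true, rng)
    defaults = dict(
        plate_id=f"P{plate_index + 1}",
        well_id=_well_id(well_index),
        construct_id=role,
        role=role,
        treatment="none",
        replicate_id="1",
        experiment_id=str(plate_index + 1),
    )
    defaults.update(metadata)
    return WellRecord(events=events, **defaults)


def _well_id(index: int) -> str:
    if index >= 96:
        raise ConfigError("plate layout exceeds 96 wells")
    row = string.ascii_uppercase[index // 12]
    return f"{row}{index % 12 + 1:02d}"


def simulate_plate_set(cfg: SimConfig) -> list[WellRecord]:
    """Simulate one plate per experiment, each holding every sample group
    in triplicate plus the per-plate control/background/untransfected
    triplicates."""
    if not cfg.truth_table:
        raise ConfigError("truth table is empty")
    groups = list(cfg.truth_table.items())
    wells_needed = (
        len(groups) * cfg.n_replicates_per_plate
        + cfg.n_control_wells
        + cfg.n_background_wells
        + cfg.n_untransfected_wells
    )
    if wells_needed > 96:
        raise ConfigError(f"layout needs {wells_needed} wells; a plate has 96")

    records: list[WellRecord] = []
    for plate_index in range(cfg.n_experiments):
        well_index = 0
        for role, count in (
            (ROLE_CONTROL_100, cfg.n_control_wells),
            (ROLE_BACKGROUND, cfg.n_background_wells),
            (ROLE_UNTRANSFECTED, cfg.n_untransfected_wells),
        ):
            for rep in range(count):
                records.append(
                    simulate_well(
                        cfg,
                        role,
                        plate_index=plate_index,
                        well_index=well_index,
                        construct_id=role,
                        replicate_id=str(rep + 1),
                    )
                )
                well_index += 1
        for (construct, treatment), tr_true in groups:
            for rep in range(cfg.n_replicates_per_plate):
                records.append(
                    simulate_well(
                        cfg,
                        ROLE_SAMPLE,
                        tr_true=tr_true,
                        plate_index=plate_index,
                        well_index=well_index,
                        construct_id=construct,
                        treatment=treatment,
                        replicate_id=str(rep + 1),
                    )
                )
                well_index += 1
    return records


# --- blot lanes --------------------------------------------------------------


def simulate_blot(
    truth_ratio: float,
    n_replicates: int = 4,
    sigma: float = 0.1,
    seed: int = 0,
    construct_id: str = "construct",
    treatment: str = "geneticin",
    lane_amount: float = 10_000.0,
) -> list[BlotLane]:
    """Synthetic quantified lanes: a shared amount split into full-length
    and truncated bands with independent multiplicative log-normal noise."""
    if not 0 <= truth_ratio <= 1:
        raise ConfigError("truth_ratio must be in [0, 1]")
    rng = np.random.default_rng([seed, 1])
    lanes = []
    for i in range(n_replicates):
        eps_fl = 1.0 if sigma == 0 else rng.lognormal(0.0, sigma)
        eps_tr = 1.0 if sigma == 0 else rng.lognormal(0.0, sigma)
        lanes.append(
            BlotLane(
                blot_id=f"blot{i + 1}",
                construct_id=construct_id,
                treatment=treatment,
                intensity_fl=lane_amount * truth_ratio * eps_fl,
                intensity_trunc=lane_amount * (1.0 - truth_ratio) * eps_tr,
                intensity_loading=lane_amount,
            )
        )
    return lanes


# --- line profiles -----------------------------------------------------------

#: planted inside/outside Flag mean ratios per localization class
_PROFILE_LEVELS = {
    NUCLEAR: (80.0, 10.0),  # ratio 8
    MIXED: (45.0, 30.0),  # ratio 1.5
    CYTOPLASMIC: (10.0, 67.0),  # ratio ~0.15
}


def simulate_profile(
    localization_class: str,
    seed: int = 0,
    n_positions: int = 200,
    noise_sd: float = 3.0,
    **metadata,
) -> LineProfile:
    """One cell's line profile with a planted localization class.

    DAPI is a Gaussian bump centred in the middle third of the line;
    Flag levels inside/outside the DAPI half-max region follow the
    planted class ratio, plus additive Gaussian noise clipped at zero.
    """
    if localization_class not in _PROFILE_LEVELS:
        raise ConfigError(f"unknown localization class {localization_class!r}")
    rng = np.random.default_rng([seed, 2])
    positions = np.arange(n_positions, dtype=float)
    center = n_positions / 2 + rng.uniform(-n_positions / 12, n_positions / 12)
    width = n_positions / 10
    dapi = 100.0 * np.exp(-0.5 * ((positions - center) / width) ** 2)

    inside_level, outside_level = _PROFILE_LEVELS[localization_class]
    half_max_region = dapi >= 0.5 * dapi.max()
    flag = np.where(half_max_region, inside_level, outside_level).astype(float)
    if noise_sd > 0:
        flag = np.clip(flag + rng.normal(0.0, noise_sd, n_positions), 0.0, None)
        dapi = np.clip(dapi + rng.normal(0.0, noise_sd, n_positions), 0.0, None)
    return LineProfile(
        positions=positions,
        flag_signal=flag,
        dapi_signal=dapi,
        cell_id=metadata.get("cell_id", f"{localization_class}-{seed}"),
        construct_id=metadata.get("construct_id", ""),
        treatment=metadata.get("treatment", "none"),
    )
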