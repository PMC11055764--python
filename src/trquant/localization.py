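"""Nuclear vs cytoplasmic localization from 1-D fluorescence line profiles.

A line drawn across a cell yields paired intensity traces: a DAPI
(nuclear stain) channel and a Flag (tagged protein) channel.  The
nucleus is operationalized as the largest contiguous run of positions
where DAPI is at least half its maximum, and localization is scored as
the ratio of mean Flag signal inside that mask to mean Flag signal
outside it.  Scores >= 2 are called nuclear, <= 0.5 cytoplasmic, and
anything between mixed; the cutoffs are exposed on the scorer.

The module also encodes the biological expectation for MeCP2 nonsense
variants: the protein carries two nuclear localization signals (NLS) at
residues 173-193 and 251-270, and the first alone suffices for import.
A premature stop upstream of residue 193 therefore removes all import
capability (cytoplasmic protein; readthrough induction restores a
nuclear fraction, i.e. mixed), whereas any stop downstream of NLS1
leaves the protein nuclear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EnrichmentError, FormatError, MaskError

#: intensity floor guarding against division by zero on dark cytoplasm
EPSILON = 1e-6

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"
MIXED = "mixed"
UNPOLARIZED_SCORE = 1.0


@dataclass
class LineProfile:
    positions: np.ndarray
    flag_signal: np.ndarray
    dapi_signal: np.ndarray
    cell_id: str = "cell1"
    construct_id: str = ""
    treatment: str = "none"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.flag_signal = np.asarray(self.flag_signal, dtype=float)
        self.dapi_signal = np.asarray(self.dapi_signal, dtype=float)
        n = len(self.positions)
        if n < 10 or len(self.flag_signal) != n or len(self.dapi_signal) != n:
            raise ValueError("profile needs >= 10 positions with matching channels")
        if (self.flag_signal < 0).any() or (self.dapi_signal < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class NLSInterval:
    start: int
    end: int

    def truncated_by(self, residue: int) -> bool:
        """A PTC at this residue removes the NLS iff it lies at or before its end."""
        return residue <= self.end


@dataclass(frozen=True)
class NLSAnnotation:
    """MeCP2's two annotated nuclear localization signals."""

    nls1: NLSInterval = NLSInterval(173, 193)
    nls2: NLSInterval = NLSInterval(251, 270)


def nuclear_mask(profile: LineProfile, threshold_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of the nucleus: largest run of DAPI >= fraction of max."""
    dapi = profile.dapi_signal
    peak = dapi.max()
    if peak <= 0:
        raise MaskError("DAPI profile is flat zero; no nuclear region")
    above = dapi >= threshold_fraction * peak
    # largest contiguous run of True
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    mask = np.zeros(len(dapi), dtype=bool)
    mask[best_start : best_start + best_len] = True
    return mask


def nuclear_enrichment(profile: LineProfile, threshold_fraction: float = 0.5) -> float:
    """Mean Flag inside the nuclear mask over mean Flag outside it."""
    mask = nuclear_mask(profile, threshold_fraction)
    if mask.all() or not mask.any():
        raise EnrichmentError("nuclear mask leaves no outside region")
    inside = float(np.mean(profile.flag_signal[mask]))
    outside = float(np.mean(profile.flag_signal[~mask]))
    return inside / max(outside, EPSILON)


@dataclass(frozen=True)
class LocalizationScorer:
    """Classify enrichment scores into nuclear/cytoplasmic/mixed calls."""

    nuclear_cutoff: float = 2.0
    cytoplasmic_cutoff: float = 0.5

    def classify(self, score: float) -> str:
        if score >= self.nuclear_cutoff:
            return NUCLEAR
        if score <= self.cytoplasmic_cutoff:
            return CYTOPLASMIC
        return MIXED


def expected_localization(
    residue: int,
    annotation: NLSAnnotation | None = None,
    treated: bool = False,
) -> str:
    """Expected localization class of a PTC variant's protein product.

    Untreated variants truncated upstream of NLS1 are cytoplasmic;
    readthrough induction partially restores full-length protein, giving
    a mixed pattern.  Variants retaining NLS1 are nuclear regardless of
    treatment.
    """
    annotation = annotation or NLSAnnotation()
    if annotation.nls1.truncated_by(residue):
        return MIXED if treated else CYTOPLASMIC
    return NUCLEAR


def read_profile_csv(path: str | Path) -> list[LineProfile]:
    """Read profiles from CSV (cell_id, construct_id, treatment, position, flag, dapi)."""
    frame = pd.read_csv(path)
    required = ["cell_id", "position", "flag", "dapi"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    profiles = []
    for cell_id, chunk in frame.groupby("cell_id", sort=False):
        chunk = chunk.sort_values("position")
        profiles.append(
            LineProfile(
                positions=chunk["position"].to_numpy(),
                flag_signal=chunk["flag"].to_numpy(),
                dapi_signal=chunk["dapi"].to_numpy(),
                cell_id=str(cell_id),
                construct_id=str(chunk["construct_id"].iloc[0]) if "construct_id" in chunk else "",
                treatment=str(chunk["treatment"].iloc[0]) if "treatment" in chunk else "none",
            )
        )
    return profiles


def score_profiles(
    profiles: list[LineProfile], scorer: LocalizationScorer | None = None
) -> pd.DataFrame:
    """Per-cell enrichment score and localization call."""
    scorer = scorer or LocalizationScorer()
    rows = []
    for profile in profiles:
        score = nuclear_enrichment(profile)
        rows.append(
            {
                "cell_id": profile.cell_id,
                "construct_id": profile.construct_id,
                "treatment": profile.treatment,
                "enrichment_score": score,
                "localization": scorer.classify(score),
            }
        )
    return pd.DataFrame(rows)
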