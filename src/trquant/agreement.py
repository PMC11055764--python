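"""Method-agreement statistics for paired readthrough measurements.

When the same constructs are measured by two assays (for example the
96-well high-content reporter assay versus an earlier plate-based
protocol), agreement is assessed two ways:

* Lin's concordance correlation coefficient (CCC), which measures how
  well the paired values fall on the identity line y = x.  Using
  population (1/n) moments,

      CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

  so both scatter and location/scale shifts lower the coefficient.
* Bland-Altman analysis: the mean difference (bias, oriented as new
  assay minus reference) and the limits of agreement bias +/- 1.96 x
  sample sd of the differences, with per-pair flags for values outside
  the limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, StatError


@dataclass
class AgreementResult:
    ccc: float
    pearson: float
    bias: float
    loa_low: float
    loa_high: float
    pairs: pd.DataFrame  # columns: mean, difference, outside_limits


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError("x and y must be 1-D arrays of equal length")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise PairingError("need at least 3 pairs")
    sx2 = float(np.var(x))  # 1/n
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise StatError("CCC undefined: both variances and the mean shift are zero")
    return 2.0 * sxy / denom


def pearson_r(x, y) -> float:
    x, y = _paired(x, y)
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> tuple[float, float, float, pd.DataFrame]:
    """Bias and 1.96-sd limits of agreement for differences x - y.

    x is the new assay, y the reference.  Returns (bias, loa_low,
    loa_high, pairs) where pairs holds each pair's mean, difference and
    an outside-limits flag.
    """
    x, y = _paired(x, y)
    if len(x) < 2:
        raise PairingError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    pairs = pd.DataFrame(
        {
            "mean": (x + y) / 2.0,
            "difference": d,
            "outside_limits": (d < loa_low) | (d > loa_high),
        }
    )
    return bias, loa_low, loa_high, pairs


def compare_assays(x, y) -> AgreementResult:
    """Full agreement panel: CCC, Pearson r and Bland-Altman limits."""
    bias, loa_low, loa_high, pairs = bland_altman(x, y)
    return AgreementResult(
        ccc=lin_ccc(x, y),
        pearson=pearson_r(x, y),
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        pairs=pairs,
    )


def read_paired_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a paired-assay CSV (construct_id, tr_assay_a, tr_assay_b)."""
    frame = pd.read_csv(path)
    for col in ("construct_id", "tr_assay_a", "tr_assay_b"):
        if col not in frame.columns:
            raise PairingError(f"{path}: missing column {col!r}")
    return (
        frame["tr_assay_a"].to_numpy(dtype=float),
        frame["tr_assay_b"].to_numpy(dtype=float),
        frame["construct_id"].astype(str).tolist(),
    )


def plot_bland_altman(result: AgreementResult, path) -> None:
    """Write a Bland-Altman scatter with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pairs["mean"], result.pairs["difference"], s=18)
    for value, style in (
        (result.bias, "-"),
        (result.loa_low, "--"),
        (result.loa_high, "--"),
    ):
        ax.axhline(value, linestyle=style, color="grey")
    ax.set_xlabel("mean of assays (TR %)")
    ax.set_ylabel("difference, new - reference (TR %)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
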