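"""Sample sex inference from per-chromosome depth summaries.

The X:autosome and Y:autosome depth ratios place each sample into one of
four classes (XX, XY, XYY_like, ambiguous). The default rectangular class
regions are heuristics chosen to separate typical clusters with wide
margins; all thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DegenerateInputError

log = logging.getLogger(__name__)

DEPTH_COLUMNS = ["sample", "chrom", "mean_depth"]


@dataclass(frozen=True)
class SexThresholds:
    xx_x_min: float = 0.8
    xx_y_max: float = 0.1
    xy_x_range: tuple[float, float] = (0.35, 0.65)
    xy_y_range: tuple[float, float] = (0.25, 0.75)
    xyy_y_min: float = 0.85


@dataclass(frozen=True)
class SexCall:
    sample: str
    x_ratio: float
    y_ratio: float
    label: str


def read_depth_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth summary missing columns {sorted(missing)}")
    return df


def _is_autosome(chrom: str) -> bool:
    return str(chrom).removeprefix("chr").isdigit()


def depth_ratios(summary: pd.DataFrame, sample: str) -> tuple[float, float]:
    """(X:autosome, Y:autosome) depth ratios for one sample.

    The autosome baseline is the unweighted mean of per-chromosome means.
    A missing X or Y row yields ratio 0 with a warning.
    """
    rows = summary[summary["sample"] == sample]
    if rows.empty:
        raise KeyError(f"sample {sample!r} not in depth summary")
    auto = rows[rows["chrom"].map(_is_autosome)]["mean_depth"]
    if auto.empty or auto.mean() <= 0:
        raise DegenerateInputError(f"{sample}: no positive autosome depth")
    baseline = float(auto.mean())
    ratios = []
    for chrom in ("X", "Y"):
        sub = rows[rows["chrom"].astype(str).str.removeprefix("chr") == chrom]
        if sub.empty:
            log.warning("%s: no %s depth row; ratio set to 0", sample, chrom)
            ratios.append(0.0)
        else:
            ratios.append(float(sub["mean_depth"].iloc[0]) / baseline)
    return ratios[0], ratios[1]


def classify_sex(
    x_ratio: float, y_ratio: float, thresholds: SexThresholds = SexThresholds()
) -> str:
    t = thresholds
    if x_ratio >= t.xx_x_min and y_ratio <= t.xx_y_max:
        return "XX"
    if t.xy_x_range[0] <= x_ratio <= t.xy_x_range[1]:
        if t.xy_y_range[0] <= y_ratio <= t.xy_y_range[1]:
            return "XY"
        if y_ratio >= t.xyy_y_min:
            return "XYY_like"
    return "ambiguous"


def infer_sex(
    summary: pd.DataFrame, thresholds: SexThresholds = SexThresholds()
) -> list[SexCall]:
    """Classify every sample in a depth summary table."""
    calls = []
    for sample in pd.unique(summary["sample"]):
        x, y = depth_ratios(summary, sample)
        calls.append(SexCall(sample, x, y, classify_sex(x, y, thresholds)))
    return calls


def sex_calls_to_frame(calls: list[SexCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample, round(c.x_ratio, 4), round(c.y_ratio, 4), c.label) for c in calls],
        columns=["sample", "x_ratio", "y_ratio", "label"],
    )
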