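"""Chip-marker overlap and tag-SNP discovery for structural variants.

Overlapping SNPs are markers positioned inside the SV's affected interval
(POS+1..END; empty for insertions). Tag SNPs are SNPs outside the interval
within ``window`` bp of the nearer SV edge whose dosage r-squared with the
SV is at least ``r2_min``; candidates are visited nearest-first (ties:
left flank before right) and recording stops after ``max_tags`` tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix, SVRecord, affected_interval

MANIFEST_COLUMNS = ["marker_name", "chrom", "pos"]


@dataclass
class ChipManifest:
    """SNP-chip marker positions (1-based), deduplicated and position-sorted."""

    markers: pd.DataFrame
    panel_label: str

    @classmethod
    def from_tsv(cls, path: str | Path, panel_label: str) -> "ChipManifest":
        df = pd.read_csv(path, sep="\t")
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        return cls.from_frame(df, panel_label)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel_label: str) -> "ChipManifest":
        df = (
            df.drop_duplicates(subset=["chrom", "pos"])
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(df, panel_label)


@dataclass
class TagSNPReport:
    sv_id: str
    panel_label: str
    overlapping_markers: list[str] = field(default_factory=list)
    tag_snps: list[tuple[str, float, int]] = field(default_factory=list)
    capped: bool = False

    @property
    def has_overlap(self) -> bool:
        return bool(self.overlapping_markers)

    @property
    def has_tag(self) -> bool:
        return bool(self.tag_snps)


def overlapping_snps(sv: SVRecord, manifest: ChipManifest) -> list[str]:
    """Marker names positioned inside the SV's affected interval."""
    iv = affected_interval(sv)
    if iv.length <= 0:  # insertions: zero-length region
        return []
    m = manifest.markers
    hit = m[(m["chrom"] == iv.chrom) & (m["pos"] >= iv.start) & (m["pos"] <= iv.stop)]
    return hit["marker_name"].tolist()


def r2_dosage(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of 0/1/2 dosages, pairwise-complete.

    Returns None when fewer than two complete pairs exist or either vector
    is constant over the complete pairs (vcftools --geno-r2 convention).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return None
    sxy = float(dx @ dy)
    return (sxy * sxy) / (sxx * syy)


def tag_scan(
    sv: SVRecord,
    snp_matrix: GenotypeMatrix,
    window: int = 10_000,
    r2_min: float = 0.8,
    max_tags: int = 5,
    panel_label: str = "WGS",
    sv_dosage: np.ndarray | None = None,
) -> TagSNPReport:
    """Scan both flanks of an SV for tag SNPs.

    Distances are measured from the SV edges (left edge POS, right edge END);
    SNPs inside the affected interval are never tag candidates. The reported
    distance is signed (negative = left flank).
    """
    report = TagSNPReport(sv_id=sv.id, panel_label=panel_label)
    iv = affected_interval(sv)
    loci = snp_matrix.loci
    on_chrom = np.flatnonzero(loci["chrom"].to_numpy() == sv.chrom)
    if on_chrom.size == 0:
        return report
    pos = loci["pos"].to_numpy()[on_chrom]

    left = (pos <= sv.pos) & (sv.pos - pos <= window)
    right = (pos > sv.end) & (pos - sv.end <= window)
    if iv.length > 0:
        # exclude markers inside the affected interval (they are "overlapping")
        left &= pos < iv.start

    candidates = []  # (distance, flank_order, pos, matrix row)
    for flank_order, mask, dist in (
        (0, left, sv.pos - pos),
        (1, right, pos - sv.end),
    ):
        for k in np.flatnonzero(mask):
            candidates.append((int(dist[k]), flank_order, int(pos[k]), int(on_chrom[k])))
    candidates.sort()

    if sv_dosage is None:
        sv_dosage = sv.dosage_vector(snp_matrix.samples)
    for dist, flank_order, _p, row in candidates:
        if len(report.tag_snps) >= max_tags:
            report.capped = True
            break
        r2 = r2_dosage(sv_dosage, snp_matrix.dosages[row])
        if r2 is not None and r2 >= r2_min:
            signed = -dist if flank_order == 0 else dist
            report.tag_snps.append((str(loci["id"].iloc[row]), r2, signed))
    return report


def tag_overlap_summary(
    counts: dict[str, int], totals: dict[str, int]
) -> pd.DataFrame:
    """Count/percent table (Table-3/4 style) from per-category counts.

    Percent = 100 * count / total, round-half-even to 2 decimals; a zero
    count renders as "0 (0%)" and a zero total leaves the percent blank.
    """
    rows = []
    for key, total in totals.items():
        count = counts.get(key, 0)
        rows.append((key, count, percent_of(count, total), format_count_percent(count, total)))
    return pd.DataFrame(rows, columns=["category", "count", "percent", "display"])


def percent_of(count: int, total: int) -> float | None:
    if total == 0:
        return None
    return round(100.0 * count / total, 2)


def format_count_percent(count: int, total: int) -> str:
    if total == 0:
        return f"{count:,} ()"
    if count == 0:
        return "0 (0%)"
    return f"{count:,} ({percent_of(count, total):.2f}%)"
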