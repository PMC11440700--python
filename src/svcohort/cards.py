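"""Per-SV report cards: allele frequency, genotype counts, exact HWE,
shared status, SNP overlap/tag results and gene overlaps; plus the
caller-level summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import SharedPair
from .errors import SvcohortError
from .filters import AffectedBasesSummary
from .ldtags import TagSNPReport, format_count_percent
from .sexinfer import SexCall
from .vcfio import MISSING, SVRecord

_LN2 = log(2.0)


def hwe_exact(hom_ref: int, het: int, hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test conditional on allele counts.

    Enumerates every heterozygote count h with the parity of the minor
    allele count; the p-value is the summed probability of all
    configurations no more likely than the observed one (plain two-sided
    minimum-likelihood tail, no mid-p). Monomorphic sites return 1.0.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise SvcohortError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise SvcohortError("need at least one genotyped sample")
    n_alt = het + 2 * hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # log-weight of each configuration: 2^h * n! / (nAA! h! naa!)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    n_minor_hom = (n_minor - hs) // 2
    n_major_hom = n - hs - n_minor_hom
    valid = n_major_hom >= 0
    hs, n_minor_hom, n_major_hom = hs[valid], n_minor_hom[valid], n_major_hom[valid]
    lg = np.vectorize(lgamma)
    logw = (
        hs * _LN2
        - lg(n_major_hom + 1.0)
        - lg(hs + 1.0)
        - lg(n_minor_hom + 1.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hs == het]
    if p_obs.size == 0:
        raise SvcohortError(
            f"genotype counts ({hom_ref},{het},{hom_alt}) inconsistent with "
            "allele-count conditioning"
        )
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


@dataclass(frozen=True)
class GenotypeCounts:
    hom_ref: int
    het: int
    hom_alt: int
    missing: int

    @property
    def n_called(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    @property
    def alt_allele_frequency(self) -> float | None:
        if self.n_called == 0:
            return None
        return (self.het + 2 * self.hom_alt) / (2 * self.n_called)


def genotype_counts(
    sv: SVRecord, samples: Sequence[str]
) -> GenotypeCounts:
    dos = sv.dosage_vector(samples)
    return GenotypeCounts(
        hom_ref=int((dos == 0).sum()),
        het=int((dos == 1).sum()),
        hom_alt=int((dos == 2).sum()),
        missing=int((dos == MISSING).sum()),
    )


@dataclass
class SVCard:
    sv_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int | None
    alt_allele_frequency: float | None
    genotype_counts: GenotypeCounts
    hwe_p: float | None
    shared: bool = False
    shared_partner: str | None = None
    overlapping_snps: dict[str, list[str]] = field(default_factory=dict)
    tag_snps: dict[str, list[tuple[str, float, int]]] = field(default_factory=dict)
    gene_overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    sex_stratified_counts: dict[str, GenotypeCounts] | None = None

    def to_dict(self) -> dict:
        d = {
            "sv_id": self.sv_id,
            "chrom": self.chrom,
            "pos": self.pos,
            "end": self.end,
            "svtype": self.svtype,
            "svlen": self.svlen,
            "alt_allele_frequency": self.alt_allele_frequency,
            "genotype_counts": [
                self.genotype_counts.hom_ref,
                self.genotype_counts.het,
                self.genotype_counts.hom_alt,
                self.genotype_counts.missing,
            ],
            "hwe_p": self.hwe_p,
            "shared": self.shared,
            "shared_partner": self.shared_partner,
            "overlapping_snps": self.overlapping_snps,
            "tag_snps": {
                panel: [[name, round(r2, 6), dist] for name, r2, dist in tags]
                for panel, tags in self.tag_snps.items()
            },
            "gene_overlaps": [list(t) for t in self.gene_overlaps],
        }
        if self.sex_stratified_counts is not None:
            d["sex_stratified_counts"] = {
                label: [c.hom_ref, c.het, c.hom_alt, c.missing]
                for label, c in self.sex_stratified_counts.items()
            }
        return d


def build_sv_card(
    sv: SVRecord,
    samples: Sequence[str],
    shared_index: Mapping[str, str] | None = None,
    tag_reports: Mapping[str, TagSNPReport] | None = None,
    overlap_reports: Mapping[str, list[str]] | None = None,
    gene_overlap_list: list[tuple[str, str, int]] | None = None,
    sex_calls: Sequence[SexCall] | None = None,
) -> SVCard:
    """Assemble one card; ``shared_index`` maps sv_id -> partner id,
    ``tag_reports``/``overlap_reports`` are keyed by panel label.
    """
    counts = genotype_counts(sv, samples)
    hwe_p = (
        hwe_exact(counts.hom_ref, counts.het, counts.hom_alt)
        if counts.n_called > 0
        else None
    )
    shared_index = shared_index or {}
    partner = shared_index.get(sv.id)
    card = SVCard(
        sv_id=sv.id,
        chrom=sv.chrom,
        pos=sv.pos,
        end=sv.end,
        svtype=sv.svtype,
        svlen=sv.svlen,
        alt_allele_frequency=counts.alt_allele_frequency,
        genotype_counts=counts,
        hwe_p=hwe_p,
        shared=partner is not None,
        shared_partner=partner,
        gene_overlaps=gene_overlap_list or [],
    )
    if overlap_reports:
        card.overlapping_snps = {k: list(v) for k, v in overlap_reports.items()}
    if tag_reports:
        card.tag_snps = {k: list(v.tag_snps) for k, v in tag_reports.items()}
    if sex_calls:
        by_label: dict[str, list[str]] = {}
        for c in sex_calls:
            by_label.setdefault(c.label, []).append(c.sample)
        card.sex_stratified_counts = {
            label: genotype_counts(sv, group) for label, group in by_label.items()
        }
    return card


def count_table(
    call_sets: Mapping[str, Sequence[SVRecord]],
    shared_pairs: Sequence[SharedPair] | None = None,
    shared_types: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-type, per-caller variant counts with an ALL row (Table-1 style).

    ``shared_types`` maps a shared pair's id_a to its svtype (needed because
    SharedPair carries ids only); when omitted the shared column is skipped.
    """
    types = sorted({r.svtype for rs in call_sets.values() for r in rs})
    rows = []
    for t in types + ["ALL"]:
        row: dict[str, object] = {"type": t}
        for name, records in call_sets.items():
            row[name] = (
                len(records)
                if t == "ALL"
                else sum(1 for r in records if r.svtype == t)
            )
        if shared_pairs is not None and shared_types is not None:
            row["shared"] = (
                len(shared_pairs)
                if t == "ALL"
                else sum(1 for p in shared_pairs if shared_types.get(p.id_a) == t)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def affected_bases_table(
    summaries: Mapping[str, AffectedBasesSummary]
) -> pd.DataFrame:
    """Affected bases with bracketed percents per caller (Table-2 style)."""
    types = sorted({t for s in summaries.values() for t in s.per_type_bases})
    rows = []
    for t in types + ["ALL"]:
        row: dict[str, object] = {"type": t}
        for name, s in summaries.items():
            if t == "ALL":
                bases, pct = s.total_bases, s.total_percent
            elif t in s.per_type_bases:
                bases, pct = s.per_type_bases[t], s.per_type_percent[t]
            else:
                row[name] = "-"
                continue
            row[name] = f"{bases:,} ({pct:.2f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_tag_counts(
    reports: Sequence[tuple[str, TagSNPReport]], kind: str = "tag"
) -> dict[str, int]:
    """Count SVs with >=1 tag (or overlap) per svtype, plus an ALL entry.

    ``reports`` pairs each SV's svtype with its TagSNPReport.
    """
    if kind not in ("tag", "overlap"):
        raise SvcohortError("kind must be 'tag' or 'overlap'")
    counts: dict[str, int] = {"ALL": 0}
    for svtype, report in reports:
        hit = report.has_tag if kind == "tag" else report.has_overlap
        counts.setdefault(svtype, 0)
        if hit:
            counts[svtype] += 1
            counts["ALL"] += 1
    return counts


def overlap_tag_table(
    reports: Sequence[tuple[str, TagSNPReport]],
    totals: Mapping[str, int],
    kind: str = "tag",
) -> pd.DataFrame:
    """Table-3/4 style count (percent) rows per svtype from per-SV reports."""
    counts = overlap_tag_counts(reports, kind)
    rows = []
    for svtype, total in totals.items():
        count = counts.get(svtype, 0)
        rows.append(
            {
                "type": svtype,
                "count": count,
                "display": format_count_percent(count, total),
            }
        )
    return pd.DataFrame(rows)
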