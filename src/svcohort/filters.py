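"""Site-level filters for caller output and affected-base accounting.

Rule attribution is first-failing in a fixed order (size, contig, 1-bp DEL,
MSHQ, DHFFC) so filter reports are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .vcfio import SVRecord, affected_length

log = logging.getLogger(__name__)

MAX_SV_SPAN = 500_000
MSHQ_MIN = 3.0
DHFFC_DEL_MAX = 0.7
DHFFC_DUP_MIN = 1.25

RULE_ORDER = ("max_size", "contig", "del_1bp", "mshq", "dhffc")


@dataclass
class FilterReport:
    input_count: int = 0
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def remove(self, rule: str) -> None:
        self.removed_by_rule[rule] = self.removed_by_rule.get(rule, 0) + 1

    @property
    def total_removed(self) -> int:
        return sum(self.removed_by_rule.values())

    def check(self) -> None:
        assert self.input_count == self.output_count + self.total_removed


def _aggregate_dhffc(record: SVRecord) -> float | None:
    """Median DHFFC over samples carrying >=1 alternate allele."""
    if not record.per_sample_dhffc:
        return None
    vals = [
        v
        for s, v in record.per_sample_dhffc.items()
        if record.genotypes.get(s, -1) >= 1
    ]
    if not vals:
        return None
    return float(np.median(vals))


def filter_smoove_site(record: SVRecord) -> tuple[bool, str | None]:
    """Apply MSHQ/DHFFC site filters; returns (keep, failing rule).

    Keeps require MSHQ strictly > 3; deletions require aggregated (carrier
    median) DHFFC strictly < 0.7 and duplications strictly > 1.25. Records
    with no MSHQ (no het samples) or no carrier DHFFC pass the respective
    rule with a logged note.
    """
    if record.site_quality_mshq is not None and not (
        record.site_quality_mshq > MSHQ_MIN
    ):
        return False, "mshq"
    if record.site_quality_mshq is None:
        log.debug("%s: no MSHQ (no het samples); MSHQ rule passed through", record.id)
    if record.svtype in ("DEL", "DUP"):
        agg = _aggregate_dhffc(record)
        if agg is None:
            log.debug("%s: no carrier DHFFC; DHFFC rule passed through", record.id)
        elif record.svtype == "DEL" and not (agg < DHFFC_DEL_MAX):
            return False, "dhffc"
        elif record.svtype == "DUP" and not (agg > DHFFC_DUP_MIN):
            return False, "dhffc"
    return True, None


def filter_universal(
    records: Iterable[SVRecord],
    chromosome_whitelist: Sequence[str],
    max_len: int = MAX_SV_SPAN,
) -> tuple[list[SVRecord], FilterReport]:
    """Remove SVs spanning > max_len bp, off-whitelist contigs and 1-bp DELs."""
    whitelist = set(chromosome_whitelist)
    if not whitelist:
        raise ConfigurationError("chromosome whitelist is empty")
    kept: list[SVRecord] = []
    report = FilterReport()
    for rec in records:
        report.input_count += 1
        if rec.span > max_len:
            report.remove("max_size")
        elif rec.chrom not in whitelist:
            report.remove("contig")
        elif rec.svtype == "DEL" and rec.span == 1:
            report.remove("del_1bp")
        else:
            kept.append(rec)
    report.output_count = len(kept)
    report.check()
    return kept, report


def filter_call_set(
    records: Iterable[SVRecord],
    chromosome_whitelist: Sequence[str],
    smoove_rules: bool = False,
    max_len: int = MAX_SV_SPAN,
) -> tuple[list[SVRecord], FilterReport]:
    """Universal filters, optionally followed by the Smoove MSHQ/DHFFC rules."""
    kept, report = filter_universal(records, chromosome_whitelist, max_len)
    if not smoove_rules:
        return kept, report
    out: list[SVRecord] = []
    for rec in kept:
        keep, rule = filter_smoove_site(rec)
        if keep:
            out.append(rec)
        else:
            report.remove(rule)
    report.output_count = len(out)
    report.check()
    return out, report


# Hard-filter rules: metric -> (comparison, threshold); a site is dropped if
# any present metric satisfies the comparison. Absent metrics never trigger.
GATK_RULES: dict[str, dict[str, tuple[str, float]]] = {
    "SNP": {
        "QD": ("<", 2.0),
        "FS": (">", 60.0),
        "MQ": ("<", 40.0),
        "MQRankSum": ("<", -12.5),
        "ReadPosRankSum": ("<", -8.0),
    },
    "INDEL": {
        "QD": ("<", 2.0),
        "FS": (">", 200.0),
        "ReadPosRankSum": ("<", -20.0),
    },
}


def gatk_hard_filter(
    site_metrics: Mapping[str, float], variant_class: str
) -> tuple[bool, list[str]]:
    """Hard-filter a small-variant site; returns (keep, failed rule names)."""
    try:
        rules = GATK_RULES[variant_class]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant class {variant_class!r}; expected SNP or INDEL"
        ) from None
    failed = []
    for name, (op, thr) in rules.items():
        value = site_metrics.get(name)
        if value is None:
            continue
        if (op == "<" and value < thr) or (op == ">" and value > thr):
            failed.append(name)
    return (not failed), failed


@dataclass
class AffectedBasesSummary:
    """Per-type affected base totals and percent-of-genome (Table-2 style)."""

    per_type_bases: dict[str, int]
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")

    @property
    def total_bases(self) -> int:
        return sum(self.per_type_bases.values())

    def percent(self, bases: int) -> float:
        """Percent of genome, round-half-even to 2 decimals."""
        return round(100.0 * bases / self.genome_length, 2)

    @property
    def per_type_percent(self) -> dict[str, float]:
        return {t: self.percent(b) for t, b in self.per_type_bases.items()}

    @property
    def total_percent(self) -> float:
        return self.percent(self.total_bases)


def affected_bases(
    variant_sets: Mapping[str, Iterable[SVRecord]] | Mapping[str, int],
    genome_length: int,
) -> AffectedBasesSummary:
    """Total affected bases per variant type, additively (no deduplication).

    ``variant_sets`` maps a type label either to an iterable of records or
    directly to a precomputed base total.
    """
    totals: dict[str, int] = {}
    for vtype, value in variant_sets.items():
        if isinstance(value, (int, np.integer)):
            totals[vtype] = int(value)
        else:
            totals[vtype] = int(sum(affected_length(r) for r in value))
    return AffectedBasesSummary(totals, genome_length)
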