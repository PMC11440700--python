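"""Gene-feature overlap for SVs and processed-pseudogene artifact flagging.

Coordinates are 1-based inclusive throughout (GTF native). Gene overlaps
use the union of exon (or CDS) intervals over all transcripts of a gene and
require a minimum overlap (default 10 bp) to be recorded — small overlaps
are disproportionately caused by processed-pseudogene deletion artifacts.

A processed pseudogene aligned back to its parent gene produces a ladder of
apparent intronic deletions: boundaries matching intron boundaries, several
introns of the same gene affected in the same individual(s), predominantly
heterozygous genotypes, and elevated exon coverage in carriers. The
flagging thresholds here are heuristic operationalizations of those signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import UnsupportedInputError
from .vcfio import SVRecord, affected_interval

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons (1-based inclusive)."""
        exons = sorted(self.exons)
        return [
            (exons[k][1] + 1, exons[k + 1][0] - 1)
            for k in range(len(exons) - 1)
            if exons[k + 1][0] - exons[k][1] > 1
        ]


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def exon_union(self) -> list[Interval]:
        return merge_intervals(
            iv for t in self.transcripts.values() for iv in t.exons
        )

    def cds_union(self) -> list[Interval]:
        return merge_intervals(
            iv for t in self.transcripts.values() for iv in t.cds
        )

    def all_introns(self) -> list[Interval]:
        seen: set[Interval] = set()
        for t in self.transcripts.values():
            seen.update(t.introns)
        return sorted(seen)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gtf_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Parse gene models (exon and CDS features) from a GTF file."""
    genes: dict[str, GeneModel] = {}
    names = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype={"chrom": str})
    for row in df.itertuples(index=False):
        if row.feature not in ("exon", "CDS"):
            continue
        attrs = _gtf_attributes(row.attributes)
        gid = attrs.get("gene_id", "")
        tid = attrs.get("transcript_id", "")
        gene = genes.setdefault(
            gid, GeneModel(gid, attrs.get("gene_name", gid), str(row.chrom))
        )
        tx = gene.transcripts.setdefault(tid, Transcript(tid))
        iv = (int(row.start), int(row.end))
        if row.feature == "exon":
            tx.exons.append(iv)
        else:
            tx.cds.append(iv)
    return genes


def write_gtf(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes.values():
            for tx in gene.transcripts.values():
                for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                    for s, e in sorted(ivs):
                        attrs = (
                            f'gene_id "{gene.gene_id}"; '
                            f'transcript_id "{tx.transcript_id}"; '
                            f'gene_name "{gene.gene_name}";'
                        )
                        fh.write(
                            f"{gene.chrom}\tsvcohort\t{feature}\t{s}\t{e}"
                            f"\t.\t+\t.\t{attrs}\n"
                        )


def _overlap_bp(interval, ivs: Sequence[Interval]) -> int:
    total = 0
    for s, e in ivs:
        total += max(0, min(interval.stop, e) - max(interval.start, s) + 1)
    return total


def gene_overlaps(
    sv: SVRecord,
    genes: Mapping[str, GeneModel],
    min_overlap: int = 10,
) -> list[tuple[str, str, int]]:
    """(gene_id, feature class, overlap bp) for exon/CDS overlaps >= min_overlap."""
    iv = affected_interval(sv)
    out = []
    for gene in genes.values():
        if gene.chrom != iv.chrom:
            continue
        for feature, ivs in (("exon", gene.exon_union()), ("CDS", gene.cds_union())):
            bp = _overlap_bp(iv, ivs)
            if bp >= min_overlap:
                out.append((gene.gene_id, feature, bp))
    return sorted(out)


@dataclass
class PseudogeneFlag:
    gene_id: str
    carrier_samples: list[str]
    supporting_deletions: list[str]
    evidence: set[str]


def _intron_matches(
    deletion: SVRecord, introns: Sequence[Interval], tol: int
) -> bool:
    iv = affected_interval(deletion)
    return any(
        abs(iv.start - s) <= tol and abs(iv.stop - e) <= tol for s, e in introns
    )


def flag_pseudogene_artifacts(
    deletions: Sequence[SVRecord],
    genes: Mapping[str, GeneModel],
    coverage_track: Mapping[tuple[str, str], float] | None = None,
    boundary_tol: int = 20,
    min_introns: int = 2,
    het_fraction_min: float = 0.8,
    exon_cov_ratio_min: float = 1.3,
) -> list[PseudogeneFlag]:
    """Flag genes whose deletion calls look like processed-pseudogene artifacts.

    A deletion "intron-matches" when both of its boundaries lie within
    ``boundary_tol`` bp of the same intron's boundaries. A gene is flagged
    when at least ``min_introns`` intron-matching deletions share a carrier.
    ``coverage_track`` maps (gene_id, sample) to the carrier's exon coverage
    relative to the cohort median; its absence downgrades, never blocks.
    """
    flags = []
    for gene in genes.values():
        introns = gene.all_introns()
        if len(introns) < min_introns:
            continue
        matching = [
            d
            for d in deletions
            if d.svtype == "DEL"
            and d.chrom == gene.chrom
            and _intron_matches(d, introns, boundary_tol)
        ]
        if len(matching) < min_introns:
            continue
        # carriers shared by enough of the matching deletions
        carrier_hits: dict[str, list[SVRecord]] = {}
        for d in matching:
            for s in d.carriers():
                carrier_hits.setdefault(s, []).append(d)
        shared = sorted(
            s for s, ds in carrier_hits.items() if len(ds) >= min_introns
        )
        if not shared:
            continue
        support = sorted({d.id for s in shared for d in carrier_hits[s]})
        evidence = {"intron_match", "multi_intron_series"}
        dosages = [
            d.genotypes[s]
            for s in shared
            for d in carrier_hits[s]
            if d.genotypes.get(s, 0) >= 1
        ]
        if dosages and sum(1 for d in dosages if d == 1) / len(dosages) >= het_fraction_min:
            evidence.add("het_only")
        if coverage_track is not None:
            ratios = [
                coverage_track.get((gene.gene_id, s)) for s in shared
            ]
            ratios = [r for r in ratios if r is not None]
            if ratios and max(ratios) >= exon_cov_ratio_min:
                evidence.add("exon_coverage_elevated")
        flags.append(
            PseudogeneFlag(
                gene_id=gene.gene_id,
                carrier_samples=shared,
                supporting_deletions=support,
                evidence=evidence,
            )
        )
    return flags
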