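"""VCF and tabular I/O with 1-based inclusive coordinate conventions.

All coordinates are kept 1-based inclusive (VCF/GTF native). For symbolic
DEL/DUP records POS is the base *before* the event, so the affected interval
is POS+1..END. Dosages are encoded 0/1/2 with -1 for missing.

Sample alignment across files is always by sample ID, never by column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import EmptyResultError, VcfParseError

log = logging.getLogger(__name__)

MISSING = -1

SV_TYPES = ("DEL", "DUP", "INS")
#: symbolic ALTs we deliberately do not model
_SKIPPED_SVTYPES = {"BND", "INV", "CNV", "TRA"}


@dataclass
class SVRecord:
    """One structural-variant site with caller provenance and genotypes.

    ``pos`` is the VCF POS (base before the event for symbolic records) and
    ``end`` the last affected base, both 1-based.
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int | None = None
    ref_allele: str = "N"
    alt_allele: str = ""
    site_quality_mshq: float | None = None
    per_sample_dhffc: dict[str, float] | None = None
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.pos:
            raise VcfParseError(
                f"{self.id}: end ({self.end}) < pos ({self.pos})"
            )
        if self.svlen is not None and self.svtype == "DEL" and self.svlen > 0:
            raise VcfParseError(f"{self.id}: DEL with positive SVLEN {self.svlen}")

    @property
    def span(self) -> int:
        """END - POS; the affected reference length for DEL/DUP, 0 for INS."""
        if self.svtype == "INS":
            return 0
        return self.end - self.pos

    def dosage_vector(self, samples: Sequence[str]) -> np.ndarray:
        """Dosages aligned to ``samples``; absent samples become missing."""
        return np.array(
            [self.genotypes.get(s, MISSING) for s in samples], dtype=np.int8
        )

    def carriers(self) -> list[str]:
        return [s for s, d in self.genotypes.items() if d >= 1]


@dataclass(frozen=True)
class AffectedInterval:
    """1-based inclusive reference span counted toward genome coverage."""

    chrom: str
    start: int
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def intersect_bp(self, other: "AffectedInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.stop, other.stop)
        return max(0, hi - lo + 1)


def affected_interval(record: SVRecord) -> AffectedInterval:
    """Reference span affected by a record.

    DEL/DUP: POS+1..END (length END-POS). INS: zero-length breakpoint at POS
    (represented as POS+1..POS). SNP-like records span a single base.
    """
    if record.svtype in ("DEL", "DUP"):
        return AffectedInterval(record.chrom, record.pos + 1, record.end)
    if record.svtype == "INS":
        return AffectedInterval(record.chrom, record.pos + 1, record.pos)
    # SNP-like / other sequence-resolved records
    return AffectedInterval(record.chrom, record.pos, record.pos)


def affected_length(record: SVRecord) -> int:
    """Base count a record contributes to affected-base accounting.

    DEL/DUP contribute their reference span (END-POS); insertions the
    absolute ref/alt length difference; SNP-like records one base.
    """
    if record.svtype in ("DEL", "DUP"):
        return record.end - record.pos
    if record.svtype == "INS":
        if record.svlen is not None:
            return abs(record.svlen)
        return abs(len(record.ref_allele) - len(record.alt_allele))
    return 1


@dataclass
class GenotypeMatrix:
    """Loci x samples dosage matrix with per-locus metadata.

    ``loci`` has columns id, chrom, pos, ref, alt; ``dosages`` is an int8
    array of shape (n_loci, n_samples) with -1 for missing calls.
    """

    loci: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_rates(self) -> np.ndarray:
        """Per-locus fraction of missing dosages."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.dosages == MISSING).mean(axis=1)

    def subset_loci(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.loci.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            list(self.samples),
        )

    def align_samples(self, sample_order: Sequence[str]) -> "GenotypeMatrix":
        """Reorder columns to ``sample_order`` (every sample must be present)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_order if s not in pos]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [pos[s] for s in sample_order]
        return GenotypeMatrix(self.loci.copy(), self.dosages[:, cols], list(sample_order))

    def to_tsv(self, path: str | Path) -> None:
        df = self.loci.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.dosages[:, j]
        df.to_csv(path, sep="\t", index=False)


def _genotype_dosage(gt: tuple) -> int:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a != 0))


def _infer_svtype(ref: str, alt: str) -> str | None:
    if alt.startswith("<") and alt.endswith(">"):
        return alt[1:-1].split(":")[0]
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    return None


def read_sv_vcf(path: str | Path, caller_label: str) -> list[SVRecord]:
    """Read an SV VCF into SVRecords with ids ``caller_label-N`` in file order.

    Multi-allelic sites and unmodelled symbolic types (BND/INV/...) are
    skipped with a logged count. A symbolic ALT without INFO END raises.
    """
    records: list[SVRecord] = []
    skipped = {"multiallelic": 0, "unmodelled_type": 0}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic"] += 1
                continue
            alt = rec.alts[0]
            svtype = rec.info.get("SVTYPE") or _infer_svtype(rec.ref, alt)
            if svtype in _SKIPPED_SVTYPES or svtype is None:
                skipped["unmodelled_type"] += 1
                continue
            symbolic = alt.startswith("<")
            end = rec.stop  # pysam: 0-based exclusive == 1-based inclusive END
            # htslib hides INFO/END behind rlen; with END absent the record
            # collapses to a 1-bp span ending at POS
            if symbolic and svtype in ("DEL", "DUP") and end <= rec.pos:
                raise VcfParseError(
                    f"{path}: symbolic record at {rec.chrom}:{rec.pos} lacks INFO END"
                )
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            genotypes = {
                s: _genotype_dosage(rec.samples[s].get("GT")) for s in samples
            }
            dhffc = None
            if any("DHFFC" in rec.samples[s] for s in samples):
                dhffc = {}
                for s in samples:
                    v = rec.samples[s].get("DHFFC")
                    if v is not None:
                        dhffc[s] = float(v)
            n += 1
            records.append(
                SVRecord(
                    id=f"{caller_label}-{n}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    end=end if svtype != "INS" else rec.pos,
                    svtype=svtype,
                    svlen=int(svlen) if svlen is not None else None,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    site_quality_mshq=(
                        float(rec.info["MSHQ"]) if "MSHQ" in rec.info else None
                    ),
                    per_sample_dhffc=dhffc,
                    genotypes=genotypes,
                )
            )
    if any(skipped.values()):
        log.info("read_sv_vcf(%s): skipped %s", path, skipped)
    return records


def _sv_header(samples: Sequence[str], contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("END", 1, "Integer", "1-based inclusive end of the variant")
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Signed length of the variant")
    header.info.add(
        "MSHQ", 1, "Float", "Mean site quality over heterozygous samples (1-4)"
    )
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "DHFFC", 1, "Float", "Depth fold change within the SV vs flanking region"
    )
    for s in samples:
        header.add_sample(s)
    return header


_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_sv_vcf(
    records: Iterable[SVRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int],
) -> None:
    """Write SVRecords as a VCF 4.2 file with symbolic ALT alleles."""
    header = _sv_header(samples, contigs)
    # htslib warns transiently while INFO fields are assigned one at a time
    # (END is re-derived from SVLEN mid-update); the final record is correct
    verbosity = pysam.set_verbosity(0)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref_allele, r.alt_allele or f"<{r.svtype}>"),
                id=r.id,
            )
            rec.info["SVTYPE"] = r.svtype
            if r.svlen is not None:
                rec.info["SVLEN"] = r.svlen
            # after SVLEN: htslib re-derives rlen from SVLEN for symbolic ALTs.
            # Zero-span INS keeps the default END=POS (htslib warns otherwise).
            if r.end > r.pos:
                rec.stop = r.end
            if r.site_quality_mshq is not None:
                rec.info["MSHQ"] = round(r.site_quality_mshq, 4)
            for s in samples:
                rec.samples[s]["GT"] = _GT_BY_DOSAGE[r.genotypes.get(s, MISSING)]
                if r.per_sample_dhffc and s in r.per_sample_dhffc:
                    rec.samples[s]["DHFFC"] = round(r.per_sample_dhffc[s], 4)
            out.write(rec)
    pysam.set_verbosity(verbosity)


def read_genotype_matrix(
    path: str | Path,
    site_filter: Callable[[object], bool] | None = None,
    max_missing_rate: float | None = None,
) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into a dosage matrix.

    ``site_filter`` (if given) sees the pysam record of each biallelic site;
    ``max_missing_rate`` additionally drops sites with a higher fraction of
    missing genotypes. Raises :class:`EmptyResultError` if nothing survives.
    """
    rows = []
    dosage_rows = []
    counts = {"total": 0, "multiallelic": 0, "filtered": 0, "missing_rate": 0}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            counts["total"] += 1
            if rec.alts is None or len(rec.alts) != 1:
                counts["multiallelic"] += 1
                continue
            if site_filter is not None and not site_filter(rec):
                counts["filtered"] += 1
                continue
            dos = np.array(
                [_genotype_dosage(rec.samples[s].get("GT")) for s in samples],
                dtype=np.int8,
            )
            if max_missing_rate is not None and samples:
                if (dos == MISSING).mean() > max_missing_rate:
                    counts["missing_rate"] += 1
                    continue
            rows.append(
                (rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, rec.ref, rec.alts[0])
            )
            dosage_rows.append(dos)
    if not rows:
        raise EmptyResultError(f"no sites retained from {path}", counts)
    loci = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(loci, np.vstack(dosage_rows), samples)


def write_genotype_vcf(
    matrix: GenotypeMatrix, path: str | Path, contigs: Mapping[str, int]
) -> None:
    """Write a GenotypeMatrix of SNP-like sites as a minimal VCF."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(matrix.n_loci):
            row = matrix.loci.iloc[i]
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
                id=row["id"],
            )
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = _GT_BY_DOSAGE[int(matrix.dosages[i, j])]
            out.write(rec)
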