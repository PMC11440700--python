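"""Two-caller shared-SV identification.

A candidate pair must be on the same chromosome with the same SV type, the
overlapping portion must cover at least ``min_overlap`` of the length of
*each* record, at least ``min_gt_match`` of the comparable genotypes must
match, and there must be no opposing homozygotes. Multi-candidate conflicts
are resolved one-to-one greedily by descending min(frac_a, frac_b), ties by
genotype match fraction then leftmost partner start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import SvcohortError, UndefinedConcordanceError
from .vcfio import MISSING, SVRecord, affected_interval

#: breakpoint distance (bp) within which two insertions are considered the
#: same event (insertions have zero-length affected intervals)
INS_BREAKPOINT_TOL = 100


@dataclass(frozen=True)
class SharedPair:
    id_a: str
    id_b: str
    frac_a: float
    frac_b: float
    genotype_match_fraction: float
    opposing_homozygotes: int
    genotype_source: str


def overlap_fractions(a, b) -> tuple[float, float]:
    """Overlap of two same-chromosome affected intervals as a fraction of each."""
    if a.chrom != b.chrom:
        raise SvcohortError(f"overlap_fractions across chromosomes {a.chrom}/{b.chrom}")
    ov = a.intersect_bp(b)
    frac_a = ov / a.length if a.length > 0 else 0.0
    frac_b = ov / b.length if b.length > 0 else 0.0
    return frac_a, frac_b


def genotype_concordance(
    ga: np.ndarray, gb: np.ndarray
) -> tuple[float, int]:
    """(match fraction, opposing homozygote count) over comparable samples.

    Samples where either dosage is missing are excluded from the denominator.
    An opposing homozygote is dosage 0 in one call set and 2 in the other.
    """
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise UndefinedConcordanceError("no samples comparable (all missing)")
    ga, gb = ga[ok], gb[ok]
    match = float((ga == gb).mean())
    opposing = int(((ga == 0) & (gb == 2)).sum() + ((ga == 2) & (gb == 0)).sum())
    return match, opposing


def _ins_fractions(a: SVRecord, b: SVRecord) -> tuple[float, float]:
    # insertions have no reference span; treat breakpoints within
    # INS_BREAKPOINT_TOL as full overlap, scaled so nearer pairs score higher
    dist = abs(a.pos - b.pos)
    if dist > INS_BREAKPOINT_TOL:
        return 0.0, 0.0
    f = 1.0 - dist / (2 * (INS_BREAKPOINT_TOL + 1))
    return f, f


def find_shared(
    set_a: Sequence[SVRecord],
    set_b: Sequence[SVRecord],
    samples: Sequence[str],
    min_overlap: float = 0.9,
    min_gt_match: float = 0.9,
    genotype_source: str = "a",
) -> tuple[list[SharedPair], list[SVRecord]]:
    """Identify SVs detected by both call sets; returns (pairs, merged records).

    Merged records are copies of the source-set record (set A by default)
    whose genotypes the merged set carries. ``samples`` fixes the comparison
    order; both call sets are aligned to it by sample ID.
    """
    if genotype_source not in ("a", "b"):
        raise SvcohortError("genotype_source must be 'a' or 'b'")
    samples = list(samples)
    by_key_b: dict[tuple[str, str], list[tuple[int, SVRecord]]] = {}
    for j, rb in enumerate(set_b):
        by_key_b.setdefault((rb.chrom, rb.svtype), []).append((j, rb))

    dosages_a = [r.dosage_vector(samples) for r in set_a]
    dosages_b = [r.dosage_vector(samples) for r in set_b]

    candidates = []  # (score tuple, i, j, frac_a, frac_b, gt_match, opp)
    for i, ra in enumerate(set_a):
        ia = affected_interval(ra)
        for j, rb in by_key_b.get((ra.chrom, ra.svtype), []):
            if ra.svtype == "INS":
                fa, fb = _ins_fractions(ra, rb)
            else:
                fa, fb = overlap_fractions(ia, affected_interval(rb))
            if fa < min_overlap or fb < min_overlap:
                continue
            try:
                gt_match, opp = genotype_concordance(dosages_a[i], dosages_b[j])
            except UndefinedConcordanceError:
                continue
            if gt_match < min_gt_match or opp > 0:
                continue
            candidates.append((min(fa, fb), gt_match, -rb.pos, i, j, fa, fb, opp))

    candidates.sort(key=lambda c: (-c[0], -c[1], -c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[SharedPair] = []
    merged: list[SVRecord] = []
    for score, gt_match, _negpos, i, j, fa, fb, opp in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(
            SharedPair(
                id_a=set_a[i].id,
                id_b=set_b[j].id,
                frac_a=fa,
                frac_b=fb,
                genotype_match_fraction=gt_match,
                opposing_homozygotes=opp,
                genotype_source=genotype_source,
            )
        )
        source = set_a[i] if genotype_source == "a" else set_b[j]
        merged.append(replace(source, genotypes=dict(source.genotypes)))
    # deterministic output order: by chromosome then position of merged record
    idx = sorted(range(len(merged)), key=lambda k: (merged[k].chrom, merged[k].pos, merged[k].id))
    return [pairs[k] for k in idx], [merged[k] for k in idx]
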