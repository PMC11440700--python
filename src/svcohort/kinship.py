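"""KING-robust kinship from dosage matrices and the SV-vs-SNP resampling
protocol used to evaluate SV genotype quality.

For a sample pair (i, j) the kinship coefficient is

    phi = (N_HetHet - 2 * N_OpposingHom) / (N_Het_i + N_Het_j)

where all counts are restricted to sites with a non-missing dosage in both
samples. phi is 0.5 for identical genomes and ~0.25 for parent-offspring.
The estimator mirrors the within-pair form reported by vcftools
--relatedness2; monomorphic sites contribute nothing to any count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, DegenerateInputError
from .vcfio import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCounts:
    n_het_both: int
    n_opposing_hom: int
    n_het_i: int
    n_het_j: int

    @property
    def phi(self) -> float | None:
        denom = self.n_het_i + self.n_het_j
        if denom == 0:
            return None
        return (self.n_het_both - 2 * self.n_opposing_hom) / denom


def king_counts(dos_i: np.ndarray, dos_j: np.ndarray) -> PairCounts:
    """Heterozygote-sharing and opposing-homozygote counts for one pair."""
    dos_i = np.asarray(dos_i)
    dos_j = np.asarray(dos_j)
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    a, b = dos_i[ok], dos_j[ok]
    return PairCounts(
        n_het_both=int(((a == 1) & (b == 1)).sum()),
        n_opposing_hom=int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum()),
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
    )


def king_phi(dos_i: np.ndarray, dos_j: np.ndarray) -> float | None:
    """KING kinship for one sample pair; None when no hets exist in either."""
    phi = king_counts(dos_i, dos_j).phi
    if phi is None:
        log.warning("king_phi undefined: no heterozygous sites in either sample")
    return phi


def king_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING kinship; (n_samples, n_samples), NaN where undefined.

    Vectorized with indicator-matrix products; all counts are pairwise
    complete (heterozygosity or homozygosity implies a non-missing call).
    """
    d = matrix.dosages
    valid = (d != MISSING).astype(np.float64)
    het = (d == 1).astype(np.float64)
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)
    n_hethet = het.T @ het
    opp = hom0.T @ hom2
    n_opp = opp + opp.T
    het_valid = het.T @ valid  # [i, j] = sites het in i and called in j
    denom = het_valid + het_valid.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    return phi


def upper_pairs(phi: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle (unordered sample pairs)."""
    iu = np.triu_indices(phi.shape[0], k=1)
    return phi[iu]


def subsample_loci(
    matrix: GenotypeMatrix,
    n: int,
    with_replacement: bool,
    max_missing_rate: float,
    seed,
) -> GenotypeMatrix:
    """Draw n loci uniformly from eligible loci (missing rate <= threshold)."""
    eligible = np.flatnonzero(matrix.missing_rates() <= max_missing_rate)
    if eligible.size == 0:
        raise CapacityError("no eligible loci to subsample")
    if not with_replacement and n > eligible.size:
        raise CapacityError(
            f"requested {n} loci without replacement but only "
            f"{eligible.size} eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=with_replacement)
    return matrix.subset_loci(chosen)


@dataclass
class CorrelationExperiment:
    """SV-vs-SNP kinship correlation under repeated SV locus resampling."""

    n_replicates: int = 100
    loci_per_replicate: int = 2000
    with_replacement: bool = True
    snp_baseline_size: int = 20_000
    max_missing_rate: float = 0.1
    seed: int = 0
    replicate_r: list[float] = field(default_factory=list)
    n_pairs: int = 0
    n_pairs_dropped: int = 0

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.replicate_r))

    @property
    def median_r(self) -> float:
        return float(np.median(self.replicate_r))


def kinship_correlation(
    sv_matrix: GenotypeMatrix,
    snp_matrix: GenotypeMatrix,
    experiment: CorrelationExperiment | None = None,
    **kwargs,
) -> CorrelationExperiment:
    """Correlate SV-based with SNP-based kinship over all sample pairs.

    The SNP baseline is drawn once (without replacement); each replicate
    redraws SV loci (with replacement by default), computes phi for every
    unordered pair from both sources and Pearson-correlates the two vectors
    over pairs where both are defined.
    """
    exp = experiment or CorrelationExperiment(**kwargs)
    shared = [s for s in sv_matrix.samples if s in set(snp_matrix.samples)]
    if len(shared) < 2:
        raise DegenerateInputError("need >= 2 shared samples between matrices")
    sv = sv_matrix.align_samples(shared)
    snp = snp_matrix.align_samples(shared)

    root = np.random.SeedSequence(exp.seed)
    baseline_seed, *rep_seeds = root.spawn(exp.n_replicates + 1)
    baseline = subsample_loci(
        snp, exp.snp_baseline_size, False, exp.max_missing_rate, baseline_seed
    )
    phi_snp = upper_pairs(king_matrix(baseline))
    exp.n_pairs = phi_snp.size

    eligible_sv = np.flatnonzero(sv.missing_rates() <= exp.max_missing_rate)
    if eligible_sv.size == 0:
        raise CapacityError("no eligible SV loci")
    exp.replicate_r = []
    dropped = 0
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        chosen = rng.choice(
            eligible_sv, size=exp.loci_per_replicate, replace=exp.with_replacement
        )
        phi_sv = upper_pairs(king_matrix(sv.subset_loci(chosen)))
        ok = ~(np.isnan(phi_sv) | np.isnan(phi_snp))
        dropped += int((~ok).sum())
        r = float(np.corrcoef(phi_sv[ok], phi_snp[ok])[0, 1])
        exp.replicate_r.append(r)
    exp.n_pairs_dropped = dropped
    return exp
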