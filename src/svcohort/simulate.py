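"""Synthetic cohort generator.

Produces a pedigreed diploid cohort with truth SV and SNP genotypes, two
pseudo-caller SV VCFs, a small-variant VCF, chip manifests, gene models and
per-sample per-chromosome depth summaries — the statistical structure every
downstream stage assumes:

* founder allele frequencies from a symmetric Beta (U-shaped spectrum),
  descendants by Mendelian transmission with uniform recombination;
* SNPs near an SV co-segregate with it at a configurable r-squared target;
* two caller profiles with boundary jitter, per-type genotype error
  (duplications noisier than deletions), missing calls and partial
  detection; DHFFC-like depth fold changes follow the *true* copy number
  (DEL 0.5 het / 0.05 hom, DUP 1.5 / 2.0) plus Gaussian noise so the
  filter thresholds are exercisable in both directions;
* sex-dependent X/Y depth (XX: X ~ autosome, Y ~ 0; XY: both ~ 0.5x);
* optional processed-pseudogene deletion artifacts matching gene introns.

All random streams are keyed from the config seed per purpose and per locus
(or per sample), so identical configs are byte-identical across runs and
adding loci does not perturb earlier draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, PedigreeError, UnsupportedInputError
from .features import GeneModel, Transcript, write_gtf
from .vcfio import (
    GenotypeMatrix,
    SVRecord,
    write_genotype_vcf,
    write_sv_vcf,
)

# stream tags for keyed RNGs
_T_PLACE_SV = 10
_T_PLACE_SNP = 11
_T_FOUNDER = 20
_T_CHILD = 30
_T_DEPTH = 40
_T_GENE = 50
_T_CALLER = 60

_SV_SIZE_RANGES = {"DEL": (100, 5000), "DUP": (1000, 20_000), "INS": (50, 1000)}

_DHFFC_CENTER = {
    "DEL": {0: 1.0, 1: 0.5, 2: 0.05},
    "DUP": {0: 1.0, 1: 1.5, 2: 2.0},
}


@dataclass
class CallerProfile:
    name: str
    boundary_jitter_bp: int = 0
    genotype_error_rate: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    detection_rate: float = 1.0
    emits_insertions: bool = True

    def validate(self) -> None:
        if self.boundary_jitter_bp < 0:
            raise ValueError(f"{self.name}: negative boundary jitter")
        probs = [self.missing_rate, self.detection_rate, *self.genotype_error_rate.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")


def identity_profile(name: str = "ideal") -> CallerProfile:
    """Zero error, zero jitter, full detection: output equals truth."""
    return CallerProfile(name=name, detection_rate=1.0, emits_insertions=True)


@dataclass
class CohortConfig:
    pedigree_spec: list[tuple[str, str | None, str | None]]
    n_autosomes: int = 3
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 30, "DUP": 15, "INS": 10}
    )
    snp_density: float = 1 / 2000
    ld_block_size: int = 10_000
    ld_r2_target: float = 0.9
    founder_beta: tuple[float, float] = (0.4, 0.4)
    recombination_rate: float = 1e-7
    caller_profiles: tuple[CallerProfile, CallerProfile] = field(
        default_factory=lambda: default_profiles()
    )
    sex_assignments: dict[str, str] = field(default_factory=dict)
    pseudogene_events: list[tuple[str, list[str]]] = field(default_factory=list)
    mean_depth: float = 20.0
    genes_per_chromosome: int = 2
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.pedigree_spec)

    @property
    def samples(self) -> list[str]:
        return [name for name, _, _ in self.pedigree_spec]

    @property
    def autosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_autosomes)]

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_autosomes < 1:
            raise ValueError("need at least one sample and one autosome")
        if any(c < 0 for c in self.sv_counts.values()):
            raise ValueError("sv_counts must be non-negative")
        seen: set[str] = set()
        for name, sire, dam in self.pedigree_spec:
            if name in seen:
                raise PedigreeError(f"duplicate sample {name}")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"{name}: parent {parent} unknown or listed later"
                    )
            seen.add(name)
        for chrom in self.autosomes + ["X", "Y"]:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"chrom_lengths missing {chrom}")
        for profile in self.caller_profiles:
            profile.validate()
        for sample, label in self.sex_assignments.items():
            if label not in ("XX", "XY"):
                raise ValueError(f"{sample}: sex must be XX or XY, got {label}")

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["pedigree_spec"] = [tuple(t) for t in data["pedigree_spec"]]
        data["founder_beta"] = tuple(data["founder_beta"])
        data["caller_profiles"] = tuple(
            CallerProfile(**p) for p in data["caller_profiles"]
        )
        data["pseudogene_events"] = [
            (g, list(c)) for g, c in data["pseudogene_events"]
        ]
        return cls(**data)


def default_profiles() -> tuple[CallerProfile, CallerProfile]:
    """Two pseudo-callers preserving the DEL < DUP error ordering; the
    second caller omits insertions and has higher error overall."""
    return (
        CallerProfile(
            name="alpha",
            boundary_jitter_bp=20,
            genotype_error_rate={"DEL": 0.02, "DUP": 0.10, "INS": 0.02},
            missing_rate=0.0,
            detection_rate=0.95,
            emits_insertions=True,
        ),
        CallerProfile(
            name="bravo",
            boundary_jitter_bp=40,
            genotype_error_rate={"DEL": 0.05, "DUP": 0.15},
            missing_rate=0.02,
            detection_rate=0.90,
            emits_insertions=False,
        ),
    )


def default_config(
    n_samples: int = 60,
    n_founders: int | None = None,
    female_fraction: float = 0.1,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Convenience factory: random two-generation pedigree, mostly-male sex."""
    if n_founders is None:
        n_founders = max(8, n_samples // 3)
    n_founders = min(n_founders, n_samples)
    rng = np.random.default_rng((seed, 1))
    names = [f"S{i:04d}" for i in range(n_samples)]
    pedigree: list[tuple[str, str | None, str | None]] = []
    for i, name in enumerate(names):
        if i < n_founders:
            pedigree.append((name, None, None))
        else:
            sire, dam = rng.choice(i, size=2, replace=False)
            pedigree.append((name, names[sire], names[dam]))
    n_female = max(1, round(female_fraction * n_samples))
    female_idx = set(rng.choice(n_samples, size=n_female, replace=False).tolist())
    sex = {n: ("XX" if i in female_idx else "XY") for i, n in enumerate(names)}
    chrom_lengths = {str(c + 1): 2_000_000 for c in range(overrides.get("n_autosomes", 3))}
    chrom_lengths["X"] = 1_500_000
    chrom_lengths["Y"] = 500_000
    cfg = CohortConfig(
        pedigree_spec=pedigree,
        chrom_lengths=chrom_lengths,
        sex_assignments=sex,
        seed=seed,
        **overrides,
    )
    return cfg


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort."""

    samples: list[str]
    sv_records: list[SVRecord]
    snp_matrix: GenotypeMatrix
    haplotypes: dict[str, np.ndarray]  # chrom -> (n_loci, n_samples, 2) int8
    locus_tables: dict[str, pd.DataFrame]  # chrom -> pos/kind/freq table
    sex_labels: dict[str, str]
    genes: dict[str, GeneModel]
    coverage_track: dict[tuple[str, str], float] = field(default_factory=dict)
    config: CohortConfig | None = None


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng((seed, *key))


def _place_svs(config: CohortConfig) -> pd.DataFrame:
    """Deterministic SV locus placement across autosomes."""
    rows = []
    autosomes = config.autosomes
    for svtype in sorted(config.sv_counts):
        count = config.sv_counts[svtype]
        lo, hi = _SV_SIZE_RANGES[svtype]
        for k in range(count):
            chrom = autosomes[k % len(autosomes)]
            length = config.chrom_lengths[chrom]
            rng = _rng(config.seed, _T_PLACE_SV, zlib.crc32(svtype.encode()), k)
            size = int(rng.integers(lo, hi + 1))
            span = size if svtype != "INS" else 0
            margin = config.ld_block_size + 1
            if length <= span + 2 * margin:
                raise CapacityError(
                    f"chromosome {chrom} ({length} bp) too small for a "
                    f"{size} bp {svtype} plus {margin} bp margins"
                )
            pos = int(rng.integers(margin, length - span - margin))
            end = pos + span if svtype != "INS" else pos
            svlen = -size if svtype == "DEL" else size
            rows.append((chrom, pos, end, svtype, svlen))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "end", "svtype", "svlen"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["id"] = [f"truth-{i + 1}" for i in range(len(df))]
    return df


def _place_snps(config: CohortConfig, svs: pd.DataFrame) -> dict[str, np.ndarray]:
    """SNP positions per autosome, disjoint from SV marker positions."""
    out = {}
    for ci, chrom in enumerate(config.autosomes):
        length = config.chrom_lengths[chrom]
        n = int(round(length * config.snp_density))
        if n > length // 2:
            raise CapacityError(f"chromosome {chrom}: {n} SNPs exceed capacity")
        rng = _rng(config.seed, _T_PLACE_SNP, ci)
        taken = set(svs.loc[svs["chrom"] == chrom, "pos"].tolist())
        positions = set()
        while len(positions) < n:
            draw = rng.integers(1, length + 1, size=n)
            for p in draw.tolist():
                if p not in taken and p not in positions:
                    positions.add(p)
                    if len(positions) == n:
                        break
        out[chrom] = np.array(sorted(positions), dtype=np.int64)
    return out


def _founder_indices(config: CohortConfig) -> list[int]:
    return [
        i for i, (_, sire, dam) in enumerate(config.pedigree_spec)
        if sire is None and dam is None
    ]


def simulate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> TruthSet:
    """Generate the cohort truth set and (optionally) all input files."""
    config.validate()
    samples = config.samples
    n = config.n_samples
    sample_idx = {s: i for i, s in enumerate(samples)}
    seed = config.seed

    svs = _place_svs(config)
    snp_positions = _place_snps(config, svs)
    eps = max(0.0, (1.0 - np.sqrt(config.ld_r2_target)) / 2.0)

    founder_rows = _founder_indices(config)
    haplotypes: dict[str, np.ndarray] = {}
    locus_tables: dict[str, pd.DataFrame] = {}

    for ci, chrom in enumerate(config.autosomes):
        sv_here = svs[svs["chrom"] == chrom]
        sv_pos = sv_here["pos"].to_numpy()
        snp_pos = snp_positions[chrom]
        # linked SNP -> index of the nearest SV within ld_block_size
        link = np.full(snp_pos.size, -1, dtype=np.int64)
        if sv_pos.size:
            nearest = np.abs(snp_pos[:, None] - sv_pos[None, :])
            j = nearest.argmin(axis=1)
            link = np.where(
                nearest[np.arange(snp_pos.size), j] <= config.ld_block_size, j, -1
            )

        all_pos = np.concatenate([sv_pos, snp_pos])
        kinds = np.array(["SV"] * sv_pos.size + ["SNP"] * snp_pos.size)
        order = np.argsort(all_pos, kind="stable")

        hap = np.zeros((all_pos.size, n, 2), dtype=np.int8)
        freqs = np.zeros(all_pos.size)

        # founders: SV loci first so linked SNPs can copy their alleles
        a, b = config.founder_beta
        sv_row_of = {}  # row index in hap for SV k within this chromosome
        for k, p in enumerate(sv_pos):
            rng = _rng(seed, _T_FOUNDER, ci, int(p))
            freq = float(np.clip(rng.beta(a, b), 0.1, 0.6))
            freqs[k] = freq
            draws = rng.random((len(founder_rows), 2)) < freq
            for fi, row in enumerate(founder_rows):
                hap[k, row] = draws[fi]
            sv_row_of[k] = k
        for m, p in enumerate(snp_pos):
            row = sv_pos.size + m
            rng = _rng(seed, _T_FOUNDER, ci, int(p))
            if link[m] >= 0:
                flips = rng.random((len(founder_rows), 2)) < eps
                src = hap[sv_row_of[link[m]], founder_rows].astype(bool)
                hap[row, founder_rows] = (src ^ flips).astype(np.int8)
                freqs[row] = freqs[link[m]]
            else:
                freq = float(np.clip(rng.beta(a, b), 0.05, 0.95))
                freqs[row] = freq
                draws = rng.random((len(founder_rows), 2)) < freq
                for fi, frow in enumerate(founder_rows):
                    hap[row, frow] = draws[fi]

        # sort loci by position before transmission so recombination
        # distances are physical
        hap = hap[order]
        all_pos = all_pos[order]
        kinds = kinds[order]
        freqs = freqs[order]

        # Mendelian transmission with uniform per-bp recombination
        gaps = np.diff(all_pos).astype(np.float64)
        switch_p = 1.0 - np.exp(-config.recombination_rate * gaps)
        for child_i, (name, sire, dam) in enumerate(config.pedigree_spec):
            if sire is None and dam is None:
                continue
            rng = _rng(seed, _T_CHILD, child_i, ci)
            for gi, parent in enumerate((sire, dam)):
                prow = sample_idx[parent]
                start = int(rng.integers(0, 2))
                toggles = rng.random(switch_p.size) < switch_p
                sel = (start + np.concatenate([[0], np.cumsum(toggles)])) % 2
                hap[:, child_i, gi] = hap[np.arange(all_pos.size), prow, sel]

        # linked SV position per locus (-1 for SV loci / unlinked SNPs)
        link_pos = np.full(sv_pos.size + snp_pos.size, -1, dtype=np.int64)
        for m in range(snp_pos.size):
            if link[m] >= 0:
                link_pos[sv_pos.size + m] = sv_pos[link[m]]
        link_pos = link_pos[order]

        haplotypes[chrom] = hap
        locus_tables[chrom] = pd.DataFrame(
            {"pos": all_pos, "kind": kinds, "freq": freqs, "linked_sv_pos": link_pos}
        )

    sex_labels = {
        s: config.sex_assignments.get(s, "XY") for s in samples
    }

    # truth SV records
    sv_records: list[SVRecord] = []
    for chrom in config.autosomes:
        table = locus_tables[chrom]
        hap = haplotypes[chrom]
        rows = svs[svs["chrom"] == chrom]
        for rec in rows.itertuples(index=False):
            locus_row = int(np.flatnonzero(table["pos"].to_numpy() == rec.pos)[0])
            dosage = hap[locus_row].sum(axis=1)
            sv_records.append(
                SVRecord(
                    id=rec.id,
                    chrom=chrom,
                    pos=int(rec.pos),
                    end=int(rec.end),
                    svtype=rec.svtype,
                    svlen=int(rec.svlen),
                    ref_allele="N",
                    alt_allele=f"<{rec.svtype}>",
                    genotypes={s: int(dosage[i]) for i, s in enumerate(samples)},
                )
            )
    sv_records.sort(key=lambda r: (r.chrom, r.pos, r.id))

    # truth SNP matrix
    loci_rows = []
    dosage_rows = []
    for chrom in config.autosomes:
        table = locus_tables[chrom]
        hap = haplotypes[chrom]
        for row in np.flatnonzero((table["kind"] == "SNP").to_numpy()):
            p = int(table["pos"].iloc[row])
            loci_rows.append((f"snp-{chrom}-{p}", chrom, p, "A", "G"))
            dosage_rows.append(hap[row].sum(axis=1).astype(np.int8))
    snp_matrix = GenotypeMatrix(
        pd.DataFrame(loci_rows, columns=["id", "chrom", "pos", "ref", "alt"]),
        np.vstack(dosage_rows) if dosage_rows else np.zeros((0, n), dtype=np.int8),
        list(samples),
    )

    genes = _make_genes(config)

    truth = TruthSet(
        samples=list(samples),
        sv_records=sv_records,
        snp_matrix=snp_matrix,
        haplotypes=haplotypes,
        locus_tables=locus_tables,
        sex_labels=sex_labels,
        genes=genes,
        config=config,
    )

    for gene_id, carriers in config.pseudogene_events:
        if gene_id not in genes:
            raise UnsupportedInputError(f"pseudogene event for unknown gene {gene_id}")
        records, coverage = inject_pseudogene_artifact(truth, genes[gene_id], carriers)
        truth.sv_records.extend(records)
        truth.coverage_track.update(coverage)

    if out_dir is not None:
        _write_outputs(truth, Path(out_dir))
    return truth


def _make_genes(config: CohortConfig) -> dict[str, GeneModel]:
    """A few multi-exon single-transcript genes per autosome."""
    genes: dict[str, GeneModel] = {}
    for ci, chrom in enumerate(config.autosomes):
        length = config.chrom_lengths[chrom]
        for g in range(config.genes_per_chromosome):
            rng = _rng(config.seed, _T_GENE, ci, g)
            n_exons = int(rng.integers(4, 9))
            exon_lens = rng.integers(150, 301, size=n_exons)
            intron_lens = rng.integers(500, 2001, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            lo = 1 + (g * length) // config.genes_per_chromosome
            hi = ((g + 1) * length) // config.genes_per_chromosome - span
            if hi <= lo:
                raise CapacityError(f"chromosome {chrom} too small for gene models")
            start = int(rng.integers(lo, hi))
            exons = []
            cursor = start
            for e in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[e]) - 1))
                cursor += int(exon_lens[e])
                if e < n_exons - 1:
                    cursor += int(intron_lens[e])
            gene_id = f"GENE{ci + 1}{g + 1:02d}"
            tx = Transcript(f"{gene_id}.t1", exons=exons, cds=[
                (s + 3, e - 3) for s, e in exons
            ])
            genes[gene_id] = GeneModel(gene_id, gene_id, chrom, {tx.transcript_id: tx})
    return genes


def depth_summary_table(truth: TruthSet) -> pd.DataFrame:
    """Per-sample per-chromosome mean depth following the sex labels."""
    config = truth.config
    rows = []
    for i, sample in enumerate(truth.samples):
        rng = _rng(config.seed, _T_DEPTH, i)
        base = max(5.0, float(rng.normal(config.mean_depth, 1.5)))
        is_xx = truth.sex_labels[sample] == "XX"
        for chrom in config.autosomes:
            rows.append((sample, chrom, round(base * float(rng.normal(1.0, 0.01)), 3)))
        x_factor = 1.0 if is_xx else 0.5
        y_factor = 0.02 if is_xx else 0.5
        rows.append((sample, "X", round(base * x_factor * float(rng.normal(1.0, 0.01)), 3)))
        rows.append((sample, "Y", round(max(0.0, base * y_factor * float(rng.normal(1.0, 0.01))), 3)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "mean_depth"])


def chip_manifest_frames(truth: TruthSet) -> dict[str, pd.DataFrame]:
    """Dense and sparse chip manifests as subsets of the truth SNP loci."""
    loci = truth.snp_matrix.loci
    dense = loci.iloc[::2]
    sparse = loci.iloc[::20]
    out = {}
    for label, subset in (("dense", dense), ("sparse", sparse)):
        out[label] = pd.DataFrame(
            {
                "marker_name": [f"{label}_{i}" for i in range(len(subset))],
                "chrom": subset["chrom"].to_numpy(),
                "pos": subset["pos"].to_numpy(),
            }
        )
    return out


def _write_outputs(truth: TruthSet, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = dict(truth.config.chrom_lengths)
    write_genotype_vcf(truth.snp_matrix, out_dir / "snps.vcf", contigs)
    write_sv_vcf(truth.sv_records, truth.samples, out_dir / "truth_svs.vcf", contigs)
    write_gtf(truth.genes, out_dir / "genes.gtf")
    for label, frame in chip_manifest_frames(truth).items():
        frame.to_csv(out_dir / f"chip_{label}.tsv", sep="\t", index=False)
    depth_summary_table(truth).to_csv(out_dir / "depth.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.sex_labels.items()), columns=["sample", "sex"]
    ).to_csv(out_dir / "sex_truth.tsv", sep="\t", index=False)


def emulate_caller(
    truth: TruthSet,
    profile: CallerProfile,
    path: str | Path | None = None,
) -> list[SVRecord]:
    """Corrupt the truth SV set according to a caller profile.

    Detection, jitter, genotype error and missingness are drawn from streams
    keyed per (profile, truth locus) so per-locus results are stable when
    other loci change. DHFFC values track the true copy-number state.
    """
    profile.validate()
    config = truth.config
    seed = config.seed
    pkey = zlib.crc32(profile.name.encode())
    samples = truth.samples
    n = len(samples)
    emitted: list[SVRecord] = []
    counter = 0
    for k, sv in enumerate(truth.sv_records):
        if sv.svtype == "INS" and not profile.emits_insertions:
            continue
        rng = _rng(seed, _T_CALLER, pkey, k)
        if rng.random() > profile.detection_rate:
            continue
        j = profile.boundary_jitter_bp
        pos = sv.pos
        end = sv.end
        svlen = sv.svlen
        if j > 0:
            pos = max(1, pos + int(rng.integers(-j, j + 1)))
            if sv.svtype != "INS":
                end = max(pos + 2, end + int(rng.integers(-j, j + 1)))
                svlen = (end - pos) * (-1 if sv.svtype == "DEL" else 1)
            else:
                end = pos
        true_dos = sv.dosage_vector(samples).astype(np.int64)
        dos = true_dos.copy()
        err = profile.genotype_error_rate.get(sv.svtype, 0.0)
        if err > 0:
            bad = rng.random(n) < err
            dos[bad] = (dos[bad] + 1 + rng.integers(0, 2, size=int(bad.sum()))) % 3
        if profile.missing_rate > 0:
            dos[rng.random(n) < profile.missing_rate] = -1
        genotypes = {s: int(dos[i]) for i, s in enumerate(samples)}

        dhffc = None
        if sv.svtype in _DHFFC_CENTER:
            centers = _DHFFC_CENTER[sv.svtype]
            noise = rng.normal(0.0, 0.08, size=n)
            dhffc = {
                s: round(max(0.0, centers[int(true_dos[i])] + noise[i]), 4)
                for i, s in enumerate(samples)
            }
        mshq = None
        if (dos == 1).any():
            mshq = float(np.clip(rng.normal(3.5, 0.25), 1.0, 4.0))

        counter += 1
        emitted.append(
            SVRecord(
                id=f"{profile.name}-{counter}",
                chrom=sv.chrom,
                pos=int(pos),
                end=int(end),
                svtype=sv.svtype,
                svlen=svlen,
                ref_allele="N",
                alt_allele=f"<{sv.svtype}>",
                site_quality_mshq=mshq,
                per_sample_dhffc=dhffc,
                genotypes=genotypes,
            )
        )
    if path is not None:
        write_sv_vcf(emitted, samples, path, dict(config.chrom_lengths))
    return emitted


def inject_pseudogene_artifact(
    truth: TruthSet,
    gene: GeneModel,
    carriers: Sequence[str],
) -> tuple[list[SVRecord], dict[tuple[str, str], float]]:
    """Intron-matching heterozygous DELs plus elevated carrier exon coverage.

    Emits one DEL per intron of the gene, heterozygous in every carrier and
    hom-ref elsewhere, and a coverage-track entry of 2.0 (relative to the
    cohort median) for each (gene, carrier).
    """
    introns = gene.all_introns()
    if len(introns) < 2:
        raise UnsupportedInputError(
            f"{gene.gene_id}: pseudogene artifacts need >= 2 introns "
            f"(found {len(introns)})"
        )
    unknown = [c for c in carriers if c not in truth.samples]
    if unknown:
        raise UnsupportedInputError(f"unknown carrier samples: {unknown}")
    records: list[SVRecord] = []
    if not carriers:
        return records, {}
    for i, (s, e) in enumerate(introns, start=1):
        genotypes = {smp: (1 if smp in set(carriers) else 0) for smp in truth.samples}
        records.append(
            SVRecord(
                id=f"pgart-{gene.gene_id}-{i}",
                chrom=gene.chrom,
                pos=s - 1,
                end=e,
                svtype="DEL",
                svlen=-(e - s + 1),
                ref_allele="N",
                alt_allele="<DEL>",
                genotypes=genotypes,
            )
        )
    coverage = {(gene.gene_id, c): 2.0 for c in carriers}
    return records, coverage
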