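import hashlib
from pathlib import Path

import numpy as np
import pytest

from svcohort import simulate
from svcohort.errors import CapacityError, PedigreeError
from svcohort.kinship import king_matrix
from svcohort.ldtags import r2_dosage
from svcohort.vcfio import MISSING


def _dir_digest(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestConfigValidation:
    def test_unknown_parent_rejected(self):
        config = simulate.default_config(n_samples=5, seed=0)
        config.pedigree_spec.append(("bad", "ghost", None))
        with pytest.raises(PedigreeError):
            config.validate()

    def test_parent_after_child_rejected(self):
        config = simulate.default_config(n_samples=5, seed=0)
        names = config.samples
        config.pedigree_spec[0] = (names[0], names[-1], None)
        with pytest.raises(PedigreeError):
            config.validate()

    def test_duplicate_sample_rejected(self):
        config = simulate.default_config(n_samples=5, seed=0)
        config.pedigree_spec.append(config.pedigree_spec[0])
        with pytest.raises(PedigreeError):
            config.validate()

    def test_chromosome_too_small(self):
        config = simulate.default_config(n_samples=5, seed=0)
        config.chrom_lengths = {c: 30_000 for c in config.chrom_lengths}
        with pytest.raises(CapacityError):
            simulate.simulate_cohort(config)

    def test_config_json_round_trip(self, tmp_path):
        config = simulate.default_config(n_samples=5, seed=9)
        config.to_json(tmp_path / "cfg.json")
        back = simulate.CohortConfig.from_json(tmp_path / "cfg.json")
        assert back == config


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            config = simulate.default_config(n_samples=25, seed=17)
            truth = simulate.simulate_cohort(config, out_dir=out)
            simulate.emulate_caller(
                truth, config.caller_profiles[0], out / "calls_alpha.vcf"
            )
            digests.append(_dir_digest(out))
        assert digests[0] == digests[1]

    def test_different_seed_differs(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate.simulate_cohort(simulate.default_config(25, seed=1), out_dir=out1)
        simulate.simulate_cohort(simulate.default_config(25, seed=2), out_dir=out2)
        assert _dir_digest(out1) != _dir_digest(out2)


def _mendelian_compatible(child: int, p1: int, p2: int) -> bool:
    gametes1 = {0: {0}, 1: {0, 1}, 2: {1}}[p1]
    gametes2 = {0: {0}, 1: {0, 1}, 2: {1}}[p2]
    return child in {a + b for a in gametes1 for b in gametes2}


class TestTruthStructure:
    def test_mendelian_consistency(self, small_truth):
        config = small_truth.config
        idx = {s: i for i, s in enumerate(small_truth.samples)}
        dosages = small_truth.snp_matrix.dosages
        for name, sire, dam in config.pedigree_spec:
            if sire is None:
                continue
            c, p1, p2 = idx[name], idx[sire], idx[dam]
            for row in range(0, dosages.shape[0], 37):  # sampled loci
                assert _mendelian_compatible(
                    int(dosages[row, c]), int(dosages[row, p1]), int(dosages[row, p2])
                )

    def test_genotypes_match_haplotypes(self, small_truth):
        chrom = small_truth.config.autosomes[0]
        hap = small_truth.haplotypes[chrom]
        table = small_truth.locus_tables[chrom]
        snp_rows = np.flatnonzero((table["kind"] == "SNP").to_numpy())
        chrom_loci = small_truth.snp_matrix.loci["chrom"] == chrom
        expect = hap[snp_rows].sum(axis=2)
        got = small_truth.snp_matrix.dosages[chrom_loci.to_numpy()]
        assert np.array_equal(expect, got)

    def test_parent_offspring_kinship(self, big_truth):
        phi = king_matrix(big_truth.snp_matrix)
        idx = {s: i for i, s in enumerate(big_truth.samples)}
        values = []
        for name, sire, dam in big_truth.config.pedigree_spec:
            if sire is None:
                continue
            values.append(phi[idx[name], idx[sire]])
            values.append(phi[idx[name], idx[dam]])
        assert np.nanmean(values) == pytest.approx(0.25, abs=0.02)

    def test_ld_target_reached(self, big_truth):
        # each SNP within ld_block_size of its nearest SV co-segregates with
        # that SV at the configured r2 target (n = 300 samples here)
        config = big_truth.config
        sv_by_pos = {
            (r.chrom, r.pos): r.dosage_vector(big_truth.samples)
            for r in big_truth.sv_records
        }
        snp_loci = big_truth.snp_matrix.loci
        snp_row = {
            (c, p): i
            for i, (c, p) in enumerate(zip(snp_loci["chrom"], snp_loci["pos"]))
        }
        r2s = []
        for chrom, table in big_truth.locus_tables.items():
            linked = table[table["linked_sv_pos"] >= 0]
            for row in linked.itertuples(index=False):
                sv_dos = sv_by_pos[(chrom, int(row.linked_sv_pos))]
                snp_dos = big_truth.snp_matrix.dosages[snp_row[(chrom, int(row.pos))]]
                r2 = r2_dosage(sv_dos, snp_dos)
                if r2 is not None:
                    r2s.append(r2)
        assert len(r2s) > 50
        assert np.mean(r2s) == pytest.approx(config.ld_r2_target, abs=0.1)

    def test_founder_af_spectrum_is_polymorphic(self, small_truth):
        freqs = small_truth.snp_matrix.dosages.mean(axis=1) / 2
        assert 0.0 < freqs.mean() < 1.0
        assert freqs.std() > 0.1  # U-ish spread, not a point mass


class TestEmulateCaller:
    def test_identity_profile_reproduces_truth(self, small_truth):
        calls = simulate.emulate_caller(small_truth, simulate.identity_profile())
        assert len(calls) == len(small_truth.sv_records)
        for truth_rec, call in zip(small_truth.sv_records, calls):
            assert call.genotypes == truth_rec.genotypes
            assert (call.pos, call.end) == (truth_rec.pos, truth_rec.end)

    def test_no_insertions_when_disabled(self, small_truth):
        profile = simulate.identity_profile("noins")
        profile.emits_insertions = False
        calls = simulate.emulate_caller(small_truth, profile)
        assert all(c.svtype != "INS" for c in calls)
        expected = sum(1 for r in small_truth.sv_records if r.svtype != "INS")
        assert len(calls) == expected

    def test_detection_rate_drops_loci(self, small_truth):
        profile = simulate.identity_profile("half")
        profile.detection_rate = 0.5
        calls = simulate.emulate_caller(small_truth, profile)
        assert 0 < len(calls) < len(small_truth.sv_records)

    def test_jitter_bounded(self, small_truth):
        profile = simulate.identity_profile("jit")
        profile.boundary_jitter_bp = 25
        calls = simulate.emulate_caller(small_truth, profile)
        truth_by_pos = {
            (r.chrom, r.svtype): r for r in small_truth.sv_records
        }
        for call, truth_rec in zip(calls, small_truth.sv_records):
            assert abs(call.pos - truth_rec.pos) <= 25

    def test_dhffc_tracks_true_copy_number(self, small_truth):
        calls = simulate.emulate_caller(small_truth, simulate.identity_profile())
        for truth_rec, call in zip(small_truth.sv_records, calls):
            if call.svtype != "DEL":
                continue
            for s, dhffc in call.per_sample_dhffc.items():
                d = truth_rec.genotypes[s]
                center = {0: 1.0, 1: 0.5, 2: 0.05}[d]
                assert dhffc == pytest.approx(center, abs=0.5)

    def test_missing_rate_applied(self, small_truth):
        profile = simulate.identity_profile("miss")
        profile.missing_rate = 0.2
        calls = simulate.emulate_caller(small_truth, profile)
        dosages = np.array(
            [c.dosage_vector(small_truth.samples) for c in calls]
        )
        assert (dosages == MISSING).mean() == pytest.approx(0.2, abs=0.05)

    def test_smoove_like_filter_keeps_most_true_sites(self, small_calls):
        from svcohort.filters import filter_smoove_site

        alpha, _ = small_calls
        kept = [r for r in alpha if filter_smoove_site(r)[0]]
        assert len(kept) >= 0.8 * len(alpha)
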