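import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcohort import simulate
from svcohort.errors import UnsupportedInputError
from svcohort.features import (
    GeneModel,
    Transcript,
    flag_pseudogene_artifacts,
    gene_overlaps,
    merge_intervals,
    read_gtf,
    write_gtf,
)
from svcohort.vcfio import SVRecord, affected_interval


def _gene(exons, gene_id="G1", chrom="1", cds=None):
    tx = Transcript("t1", exons=list(exons), cds=list(cds or []))
    return GeneModel(gene_id, gene_id, chrom, {"t1": tx})


def _del(pos, end, gts=None, id="d-1", chrom="1"):
    return SVRecord(id, chrom, pos, end, "DEL", genotypes=gts or {})


class TestGeneModel:
    def test_introns_are_exon_gaps(self):
        tx = Transcript("t", exons=[(100, 199), (300, 399), (500, 599)])
        assert tx.introns == [(200, 299), (400, 499)]

    def test_merge_intervals(self):
        assert merge_intervals([(1, 10), (5, 20), (30, 40)]) == [(1, 20), (30, 40)]

    def test_gtf_round_trip(self, tmp_path):
        gene = _gene([(100, 199), (300, 399)], cds=[(110, 190), (310, 390)])
        path = tmp_path / "genes.gtf"
        write_gtf({"G1": gene}, path)
        back = read_gtf(path)
        assert back["G1"].transcripts["t1"].exons == [(100, 199), (300, 399)]
        assert back["G1"].transcripts["t1"].cds == [(110, 190), (310, 390)]
        assert back["G1"].chrom == "1"


class TestGeneOverlaps:
    def test_ten_bp_boundary(self):
        gene = _gene([(1000, 1999)])
        # DEL interval is pos+1..end; overlap of exactly 9 bp then 10 bp
        sv9 = _del(990, 1009)  # interval 991..1009 -> overlap 1000..1009 = 10?
        # construct precisely: interval stop 1008 -> 9 bp overlap
        sv9 = _del(990, 1008)
        sv10 = _del(990, 1009)
        assert gene_overlaps(sv9, {"G1": gene}) == []
        assert gene_overlaps(sv10, {"G1": gene}) == [("G1", "exon", 10)]

    def test_whole_gene_spanned(self):
        gene = _gene([(1000, 1099), (1200, 1299)], cds=[(1010, 1090)])
        sv = _del(500, 2000)
        result = gene_overlaps(sv, {"G1": gene})
        assert ("G1", "exon", 200) in result
        assert ("G1", "CDS", 81) in result

    def test_intergenic_sv_empty(self):
        gene = _gene([(1000, 1099)])
        assert gene_overlaps(_del(5000, 6000), {"G1": gene}) == []

    def test_union_over_transcripts(self):
        g = GeneModel("G1", "G1", "1", {
            "t1": Transcript("t1", exons=[(1000, 1099)]),
            "t2": Transcript("t2", exons=[(1050, 1199)]),
        })
        sv = _del(999, 1199)  # interval 1000..1199
        assert gene_overlaps(sv, {"G1": g}) == [("G1", "exon", 200)]

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        n_exons = data.draw(st.integers(1, 4))
        exons = []
        cursor = data.draw(st.integers(1, 200))
        for _ in range(n_exons):
            length = data.draw(st.integers(1, 120))
            exons.append((cursor, cursor + length - 1))
            cursor += length + data.draw(st.integers(1, 100))
        gene = _gene(exons)
        pos = data.draw(st.integers(1, cursor + 100))
        end = pos + data.draw(st.integers(1, 400))
        sv = _del(pos, end)
        iv = affected_interval(sv)
        sv_bases = set(range(iv.start, iv.stop + 1))
        exon_bases = {b for s, e in exons for b in range(s, e + 1)}
        expect = len(sv_bases & exon_bases)
        got = gene_overlaps(sv, {"G1": gene}, min_overlap=1)
        got_bp = got[0][2] if got else 0
        assert got_bp == expect


class TestPseudogeneFlags:
    def _gene_with_introns(self, n_introns=4):
        exons = [(1000 + 1500 * i, 1000 + 1500 * i + 199) for i in range(n_introns + 1)]
        return _gene(exons, gene_id="PG1")

    def _artifact_dels(self, gene, carrier="c1", others=("o1", "o2"), dosage=1):
        dels = []
        for k, (s, e) in enumerate(gene.all_introns()):
            gts = {carrier: dosage, **{o: 0 for o in others}}
            dels.append(_del(s - 1, e, gts, id=f"pg-{k}"))
        return dels

    def test_injected_series_flagged_with_evidence(self):
        gene = self._gene_with_introns(4)
        dels = self._artifact_dels(gene)
        flags = flag_pseudogene_artifacts(
            dels, {"PG1": gene}, coverage_track={("PG1", "c1"): 2.0}
        )
        assert len(flags) == 1
        flag = flags[0]
        assert flag.carrier_samples == ["c1"]
        assert set(flag.supporting_deletions) == {d.id for d in dels}
        assert flag.evidence == {
            "intron_match", "multi_intron_series", "het_only",
            "exon_coverage_elevated",
        }

    def test_single_intron_match_not_flagged(self):
        gene = self._gene_with_introns(4)
        dels = self._artifact_dels(gene)[:1]
        assert flag_pseudogene_artifacts(dels, {"PG1": gene}) == []

    def test_far_boundaries_contribute_nothing(self):
        gene = self._gene_with_introns(3)
        introns = gene.all_introns()
        shifted = [
            _del(s - 1 + 200, e + 200, {"c1": 1}, id=f"x-{k}")
            for k, (s, e) in enumerate(introns)
        ]
        assert flag_pseudogene_artifacts(shifted, {"PG1": gene}) == []

    def test_no_shared_carrier_not_flagged(self):
        gene = self._gene_with_introns(3)
        introns = gene.all_introns()
        dels = [
            _del(s - 1, e, {f"c{k}": 1}, id=f"y-{k}")
            for k, (s, e) in enumerate(introns)
        ]
        assert flag_pseudogene_artifacts(dels, {"PG1": gene}) == []

    def test_hom_alt_series_lacks_het_only_evidence(self):
        gene = self._gene_with_introns(4)
        dels = self._artifact_dels(gene, dosage=2)
        flags = flag_pseudogene_artifacts(dels, {"PG1": gene})
        assert len(flags) == 1
        assert "het_only" not in flags[0].evidence

    def test_missing_coverage_downgrades_not_blocks(self):
        gene = self._gene_with_introns(4)
        flags = flag_pseudogene_artifacts(
            self._artifact_dels(gene), {"PG1": gene}, coverage_track=None
        )
        assert len(flags) == 1
        assert "exon_coverage_elevated" not in flags[0].evidence

    def test_boundary_tolerance_window(self):
        gene = self._gene_with_introns(2)
        introns = gene.all_introns()
        within = [
            _del(s - 1 + 15, e - 15, {"c1": 1}, id=f"w-{k}")
            for k, (s, e) in enumerate(introns)
        ]
        flags = flag_pseudogene_artifacts(within, {"PG1": gene}, boundary_tol=20)
        assert len(flags) == 1


class TestClosedLoopInjection:
    def test_injection_and_flagging(self, small_truth):
        gene = next(g for g in small_truth.genes.values()
                    if len(g.all_introns()) >= 2)
        carrier = small_truth.samples[0]
        records, coverage = simulate.inject_pseudogene_artifact(
            small_truth, gene, [carrier]
        )
        assert len(records) == len(gene.all_introns())
        for rec in records:
            assert rec.genotypes[carrier] == 1
            assert all(v == 0 for s, v in rec.genotypes.items() if s != carrier)
        flags = flag_pseudogene_artifacts(
            records, small_truth.genes, coverage_track=coverage
        )
        assert [f.gene_id for f in flags] == [gene.gene_id]
        assert flags[0].evidence >= {
            "intron_match", "multi_intron_series", "het_only",
            "exon_coverage_elevated",
        }

    def test_zero_carriers_zero_records(self, small_truth):
        gene = next(g for g in small_truth.genes.values()
                    if len(g.all_introns()) >= 2)
        records, coverage = simulate.inject_pseudogene_artifact(
            small_truth, gene, []
        )
        assert records == [] and coverage == {}

    def test_too_few_introns_rejected(self, small_truth):
        gene = GeneModel("X1", "X1", "1", {
            "t": Transcript("t", exons=[(100, 200), (300, 400)])
        })
        with pytest.raises(UnsupportedInputError):
            simulate.inject_pseudogene_artifact(small_truth, gene, ["c"])
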