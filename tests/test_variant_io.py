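"""File-format readers and writers: VCF normalization, PED, GMT, reports."""
import json

import numpy as np
import pytest

from digenicscan import (
    GeneSetCollection,
    GenotypeTable,
    VariantRecord,
    read_geneset,
    read_pedigree,
    read_report,
    read_vcf,
    write_report,
)
from digenicscan.digenic import CandidatePair
from digenicscan.records import MISSING, ParseError, ValidationError
from digenicscan.simulate import SimConfig, simulate_cohort, write_cohort
from digenicscan import variant_io

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write_vcf(tmp_path, body, samples=("s1",)):
    path = tmp_path / "test.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(VCF_HEADER + cols + "\t".join(samples) + "\n" + body)
    return path


class TestReadVcf:
    def test_biallelic_het_maps_to_code_one(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        records, gts = read_vcf(path)
        assert [r.variant_id for r in records] == ["1:100:A:G"]
        assert gts.code("1:100:A:G", "s1") == 1

    def test_multiallelic_split_recodes_each_alt(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n")
        records, gts = read_vcf(path)
        assert [r.variant_id for r in records] == ["1:100:A:G", "1:100:A:T"]
        assert gts.code("1:100:A:G", "s1") == 1
        assert gts.code("1:100:A:T", "s1") == 1

    def test_missing_and_phased_genotypes(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t1|0\n",
            samples=("s1", "s2"),
        )
        _, gts = read_vcf(path)
        assert gts.code("1:100:A:G", "s1") == MISSING
        assert gts.code("1:100:A:G", "s2") == 1  # phase separator accepted, ignored

    def test_split_conserves_alt_dosage(self, tmp_path):
        """Total alt dosage per sample is conserved by the multiallelic split."""
        rng = np.random.default_rng(11)
        gt_pool = ["0/0", "0/1", "1/1", "1/2", "2/2", "0/2", "2/3", "3/3"]
        lines, expected = [], {}
        for i in range(25):
            gts = rng.choice(gt_pool, size=3)
            lines.append(
                f"1\t{100 + i}\t.\tA\tG,T,C\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
            for s, gt in zip(("s1", "s2", "s3"), gts):
                expected[(100 + i, s)] = sum(int(a) > 0 for a in gt.split("/"))
        path = _write_vcf(tmp_path, "\n".join(lines) + "\n", samples=("s1", "s2", "s3"))
        records, table = read_vcf(path)
        assert len(records) == 75
        for (pos, sample), want in expected.items():
            got = sum(
                table.code(r.variant_id, sample) for r in records if r.pos == pos
            )
            assert got == want

    def test_quartet_fixture_counts_conserved(self, kindred_files, kindred):
        records, gts = read_vcf(kindred_files["vcf"])
        assert len(records) == len(kindred["records"])
        assert set(gts.sample_ids) == set(kindred["pedigree"].sample_ids)

    def test_no_samples_rejected(self, tmp_path):
        path = tmp_path / "nosamples.vcf"
        path.write_text(
            VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(Exception):
            read_vcf(path)

    def test_malformed_header_raises_parse_error(self, tmp_path):
        path = tmp_path / "broken.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(ParseError):
            read_vcf(path)


class TestSimulatorRoundTrip:
    def test_vcf_round_trip_identity(self, tmp_path):
        """Reading the simulator's VCF reproduces its in-memory state exactly."""
        cohort = simulate_cohort(SimConfig(n_background=120, seed=5))
        paths = write_cohort(cohort, tmp_path)
        records, gts = read_vcf(paths["vcf"])
        assert records == cohort.records
        assert gts.sample_ids == cohort.genotypes.sample_ids
        assert (gts.matrix == cohort.genotypes.matrix).all()

    def test_annotation_round_trip(self, tmp_path):
        cohort = simulate_cohort(SimConfig(n_background=60, seed=9))
        paths = write_cohort(cohort, tmp_path)
        profiles, genes, regions = variant_io.read_annotations(paths["annotations"])
        assert profiles == cohort.profiles
        assert genes == {r.variant_id: r.gene for r in cohort.records}
        assert regions == {r.variant_id: r.region_class for r in cohort.records}


class TestReadPedigree:
    def test_quartet(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text(
            "F1 dad 0 0 1 1\nF1 mom 0 0 2 1\n"
            "F1 kid1 dad mom 2 2\nF1 kid2 dad mom 2 2\n"
        )
        ped = read_pedigree(path)
        affected = ped.affected()
        assert len(affected) == 2
        assert all(m.father_id == "dad" and m.mother_id == "mom" for m in affected)
        assert {m.sample_id for m in ped.founders()} == {"dad", "mom"}

    def test_single_member_valid(self, tmp_path):
        path = tmp_path / "one.ped"
        path.write_text("F1 solo 0 0 1 2\n")
        assert len(read_pedigree(path).members) == 1

    def test_dangling_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.ped"
        path.write_text("F1 kid ghost 0 1 2\n")
        with pytest.raises(ValidationError, match="ghost"):
            read_pedigree(path)

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "dup.ped"
        path.write_text("F1 a 0 0 1 1\nF1 a 0 0 1 1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_pedigree(path)

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "short.ped"
        path.write_text("F1 a 0 0 1\n")
        with pytest.raises(ParseError):
            read_pedigree(path)

    def test_random_cycles_rejected(self, tmp_path):
        """Every randomized cyclic ancestry construction is rejected."""
        from digenicscan.records import Pedigree, PedigreeMember

        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            ids = [f"i{k}" for k in range(n)]
            # chain i0 <- i1 <- ... <- i(n-1), then close the loop
            members = [
                PedigreeMember(ids[k], ids[(k + 1) % n], None, 1, k == 0)
                for k in range(n)
            ]
            rng.shuffle(members)
            with pytest.raises(ValidationError, match="cycle"):
                Pedigree(list(members))


class TestGeneset:
    def test_gmt_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("FGF21_PATHWAY\tdesc\tFGFR1\tKLB\n")
        sets = read_geneset(path)
        assert sets.sets["FGF21_PATHWAY"] == {"FGFR1", "KLB"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert len(read_geneset(path)) == 0

    def test_duplicate_gene_deduplicated(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\td\tA\tA\tB\n")
        assert read_geneset(path).sets["S"] == {"A", "B"}

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "short.gmt"
        path.write_text("S\tdesc\n")
        with pytest.raises(ParseError):
            read_geneset(path)


class TestReport:
    def _pairs(self):
        return [
            CandidatePair(
                "8:1:G:A", "4:2:C:A", "FGFR1", "KLB",
                frozenset({"proband", "sibling"}),
                genesets=("FGF21_PATHWAY",), score=0.75,
            )
        ]

    def test_tsv_header_and_row(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_report(self._pairs(), path, "tsv")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == list(variant_io.REPORT_COLUMNS)
        assert len(lines) == 2
        assert lines[1].split("\t")[1:3] == ["FGFR1", "8:1:G:A"]

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_report([], path, "tsv")
        assert path.read_text().splitlines() == ["\t".join(variant_io.REPORT_COLUMNS)]

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "report.json"
        pairs = self._pairs()
        write_report(pairs, path, "json")
        assert read_report(path) == pairs
        # and the payload is plain JSON
        assert json.loads(path.read_text())[0]["origin_a"] == "maternal"
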