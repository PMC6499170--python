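"""Data model, VCF/FASTA ingestion and candidate extraction."""

from __future__ import annotations

import random
import subprocess

import pytest

from dnsnvkit.core_model import (
    CallSet,
    ConfigurationError,
    DEFAULT_ROLE_MAP,
    ReferenceSequence,
    ReferenceError_,
    SampleCall,
    VariantRecord,
    chrom_sort_key,
    extract_candidate_dnsnvs,
    is_autosome,
    normalize_chrom,
    read_reference,
    read_trio_vcf,
    write_callset_vcf,
)

from .conftest import make_callset, make_record

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##contig=<ID=chrX>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tDAD\tMOM\tKID
"""

ROLE_MAP = {"DAD": "father", "MOM": "mother", "KID": "child"}


def write_vcf(tmp_path, body, name="in.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadTrioVcf:
    def test_minimal_snv(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:AD:GQ\t0/0:20,0:99\t0/0:18,0:99\t0/1:9,11:80\n",
        )
        cs = read_trio_vcf(p, ROLE_MAP)
        assert len(cs) == 1
        r = cs.records[0]
        assert (r.chrom, r.pos, r.ref, r.alt) == ("1", 100, "A", "G")
        assert r.child.genotype == (0, 1)
        assert (r.child.ref_depth, r.child.alt_depth, r.child.gq) == (9, 11, 80)
        assert cs.skip_log.total == 0

    def test_indel_skipped(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tA\tAT\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n")
        cs = read_trio_vcf(p, ROLE_MAP)
        assert len(cs) == 0
        assert cs.skip_log.non_snv == 1

    def test_autosome_restriction(self, tmp_path):
        lines = [
            f"chr1\t{100 + i}\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n" for i in range(3)
        ] + [
            f"chrX\t{200 + i}\t.\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n" for i in range(2)
        ]
        cs = read_trio_vcf(write_vcf(tmp_path, "".join(lines)), ROLE_MAP)
        assert len(cs) == 3
        assert cs.skip_log.non_autosome == 2
        assert all(is_autosome(r.chrom) and len(r.ref) == len(r.alt) == 1 for r in cs)

    def test_multiallelic_skipped_not_split(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n")
        cs = read_trio_vcf(p, ROLE_MAP)
        assert len(cs) == 0
        assert cs.skip_log.multiallelic == 1

    def test_missing_genotype_skips_record(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t./.\t0/0\t0/1\n")
        cs = read_trio_vcf(p, ROLE_MAP)
        assert len(cs) == 0
        assert cs.skip_log.missing_genotype == 1

    def test_missing_ad_retained_unscorable(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:AD\t0/0:.\t0/0:20,0\t0/1:8,9\n"
        )
        cs = read_trio_vcf(p, ROLE_MAP)
        assert len(cs) == 1
        assert not cs.records[0].father.has_depths
        assert cs.records[0].mother.has_depths

    def test_bad_role_map(self, tmp_path):
        p = write_vcf(tmp_path, "")
        with pytest.raises(ConfigurationError):
            read_trio_vcf(p, {"DAD": "father", "MOM": "mother"})
        with pytest.raises(ConfigurationError):
            read_trio_vcf(
                p, {"NOPE": "father", "MOM": "mother", "KID": "child"}
            )


class TestChromLabels:
    @pytest.mark.parametrize(
        "label,expected", [("chr1", "1"), ("1", "1"), ("chr22", "22"), ("CHR3", "3")]
    )
    def test_normalize(self, label, expected):
        assert normalize_chrom(label) == expected

    def test_sort_is_numeric(self):
        labels = ["10", "2", "chr1", "22"]
        assert sorted(labels, key=chrom_sort_key) == ["chr1", "2", "10", "22"]


class TestVariantRecordInvariants:
    def test_rejects_non_snv(self):
        with pytest.raises(ValueError):
            make_record(ref="A", alt="A")
        with pytest.raises(ValueError):
            make_record(ref="N", alt="G")

    def test_rejects_bad_pos_and_depths(self):
        with pytest.raises(ValueError):
            make_record(pos=0)
        with pytest.raises(ValueError):
            SampleCall(genotype=(0, 1), ref_depth=-1, alt_depth=3)

    def test_callset_rejects_duplicates_and_sorts(self):
        a = make_record(chrom="2", pos=50)
        b = make_record(chrom="1", pos=99)
        cs = make_callset([a, b])
        assert [r.chrom for r in cs] == ["1", "2"]
        with pytest.raises(ValueError, match="duplicate"):
            make_callset([a, a])


class TestExtractCandidates:
    def test_canonical_pattern_kept_inherited_excluded(self):
        keep = make_record(pos=10, father=(0, 0), mother=(0, 0), child=(0, 1))
        drop = make_record(pos=20, father=(0, 1), mother=(0, 0), child=(0, 1))
        out = extract_candidate_dnsnvs(make_callset([keep, drop]))
        assert out.keys() == {keep.key}

    def test_matches_bruteforce_scan(self):
        rng = random.Random(42)
        gts = [(0, 0), (0, 1), (1, 1)]
        records = [
            make_record(
                pos=100 + i,
                father=rng.choice(gts),
                mother=rng.choice(gts),
                child=rng.choice(gts),
            )
            for i in range(200)
        ]
        cs = make_callset(records)
        out = extract_candidate_dnsnvs(cs)
        expected = {
            r.key
            for r in records
            if r.father.genotype == (0, 0)
            and r.mother.genotype == (0, 0)
            and 1 in r.child.genotype
        }
        assert out.keys() == expected

    def test_subset_and_idempotent(self, small_sim):
        _, _, callset, _ = small_sim
        once = extract_candidate_dnsnvs(callset)
        assert once.keys() <= callset.keys()
        assert extract_candidate_dnsnvs(once).records == once.records

    def test_missing_genotype_excluded(self):
        r = make_record(father=None, mother=(0, 0), child=(0, 1))
        out = extract_candidate_dnsnvs(make_callset([r]))
        assert len(out) == 0
        assert out.skip_log.missing_genotype == 1


class TestReference:
    def test_lookup(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">1\nACGT\n")
        ref = read_reference(p)
        assert ref.base("1", 3) == "G"
        with pytest.raises(ReferenceError_):
            ref.base("1", 5)
        with pytest.raises(ReferenceError_):
            ref.base("9", 1)

    def test_invalid_base_named(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">1\nACXT\n")
        with pytest.raises(ReferenceError_, match="position 3"):
            read_reference(p)

    def test_roundtrip(self, tmp_path, small_sim):
        _, ref, _, _ = small_sim
        p = tmp_path / "rt.fa"
        ref.write_fasta(p)
        back = read_reference(p)
        assert back.lengths() == ref.lengths()
        assert all(
            back.window(c, 1, ref.length(c)) == ref.window(c, 1, ref.length(c))
            for c in ref.names
        )


class TestVcfRoundTrip:
    def test_empty_callset_header_only(self, tmp_path):
        p = tmp_path / "empty.vcf"
        write_callset_vcf(make_callset([]), p)
        cs = read_trio_vcf(p, DEFAULT_ROLE_MAP)
        assert len(cs) == 0

    def test_single_record(self, tmp_path):
        rec = make_record(gqs={"father": 99, "mother": 98, "child": 70})
        p = tmp_path / "one.vcf"
        write_callset_vcf(make_callset([rec]), p)
        back = read_trio_vcf(p, DEFAULT_ROLE_MAP)
        assert back.records == [rec]

    def test_synthetic_callset_roundtrip_all_fields(self, tmp_path, small_sim):
        _, _, callset, _ = small_sim
        sub = make_callset(callset.records[:100], name="rt")
        p = tmp_path / "hundred.vcf"
        write_callset_vcf(sub, p)
        back = read_trio_vcf(p, DEFAULT_ROLE_MAP, name="rt")
        assert back.records == sub.records
        assert len(back) == 100

    def test_written_vcf_is_valid_per_bcftools(self, tmp_path, small_sim):
        """Independent check: an external VCF parser accepts the writer's output."""
        _, _, callset, _ = small_sim
        p = tmp_path / "check.vcf"
        write_callset_vcf(make_callset(callset.records[:20], name="chk"), p)
        out = subprocess.run(
            ["bcftools", "view", "-H", str(p)], capture_output=True, text=True
        )
        assert out.returncode == 0
        assert len(out.stdout.strip().splitlines()) == 20
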