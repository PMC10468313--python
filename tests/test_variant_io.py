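"""Variant record parsing, classification, normalization, filtering,
and genotype-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonemarker as cm
from clonemarker.variant_io import VariantRecord


def make_rec(ref, alt, pos=5, contig="chr1", qual=200.0, genotypes=None):
    return VariantRecord(
        contig=contig, pos=pos, ref=ref, alt=alt, qual=qual,
        genotypes=genotypes or {},
    )


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("G", "A", "SNV"),  # the readout of an SNV marker like G/A
            ("A", "AT", "InDel"),
            ("ACGT", "A", "InDel"),
            ("AT", "GC", "other"),  # equal-length multi-base substitution
        ],
    )
    def test_classification(self, ref, alt, expected):
        assert cm.classify_variant(make_rec(ref, alt)) == expected

    def test_partition_sums_to_total(self, small_cohort):
        _, _, _, _, records = small_cohort
        kinds = [cm.classify_variant(r) for r in records]
        total = kinds.count("SNV") + kinds.count("InDel") + kinds.count("other")
        assert total == len(records)

    def test_indel_size_from_allele_lengths(self):
        # a 180/190 amplicon pair comes from a 10-bp indel
        assert cm.variant_io.indel_size(make_rec("A" + "C" * 10, "A")) == 10


class TestQualityFilter:
    def test_empty_input(self):
        assert cm.quality_filter([]) == []

    def test_strict_inequality_at_threshold(self):
        recs = [make_rec("A", "G", pos=p, qual=q) for p, q in [(1, 99), (2, 100), (3, 101)]]
        kept = cm.quality_filter(recs, 100)
        assert [r.qual for r in kept] == [101]

    def test_missing_quality_dropped(self):
        recs = [make_rec("A", "G", pos=1, qual=None), make_rec("A", "G", pos=2, qual=150)]
        assert len(cm.quality_filter(recs, 100)) == 1

    def test_matches_brute_force_scan_on_simulated_file(self):
        rng = np.random.default_rng(5)
        recs = [
            make_rec("A", "G", pos=i + 1, qual=float(q))
            for i, q in enumerate(rng.uniform(0, 300, size=1000))
        ]
        kept = cm.quality_filter(recs, 100)
        assert len(kept) == sum(1 for r in recs if r.qual > 100)

    @given(threshold=st.floats(min_value=0, max_value=400))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_subset_and_monotone(self, threshold):
        rng = np.random.default_rng(7)
        recs = [
            make_rec("A", "G", pos=i + 1, qual=float(q))
            for i, q in enumerate(rng.uniform(0, 300, size=200))
        ]
        kept = cm.quality_filter(recs, threshold)
        assert set(id(r) for r in kept) <= set(id(r) for r in recs)
        higher = cm.quality_filter(recs, threshold + 50)
        assert len(higher) <= len(kept)


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]


def oracle_normalize(rec, reference):
    """Independent minimal-representation oracle: compare the reference and
    alternate haplotypes, maximize the common suffix then prefix, and keep a
    left anchor base (maximizing the suffix first forces left alignment)."""
    seq = reference[rec.contig]
    hap = apply_variant(seq, rec.pos, rec.ref, rec.alt)
    s = 0
    while s < min(len(seq), len(hap)) and seq[len(seq) - 1 - s] == hap[len(hap) - 1 - s]:
        s += 1
    p = 0
    while p < min(len(seq), len(hap)) - s and seq[p] == hap[p]:
        p += 1
    ref, alt = seq[p : len(seq) - s], hap[p : len(hap) - s]
    while (not ref or not alt) and p > 0:  # anchor base for pure indels
        p -= 1
        ref, alt = seq[p : len(seq) - s], hap[p : len(hap) - s]
    return (rec.contig, p + 1, ref, alt)


class TestNormalize:
    def test_minimal_snv_unchanged_and_idempotent(self, toy_reference):
        rec = make_rec("A", "G", pos=5)  # chr1[4] == 'A'
        out = cm.normalize_variant(rec, toy_reference)
        assert out.key == rec.key
        assert cm.normalize_variant(out, toy_reference).key == out.key

    def test_right_shifted_deletion_left_aligns_through_repeat(self):
        # 2-bp deletion placed at the right end of a TA repeat tract
        ref = {"c": "GGGCTATATATATAGGGCTACGGATTTCCA"}
        rec = VariantRecord(contig="c", pos=11, ref="TAT", alt="T")
        out = cm.normalize_variant(rec, ref)
        assert out.key == oracle_normalize(rec, ref)

    def test_trailing_shared_base_trimmed_to_one_bp_deletion(self):
        ref = {"c": "TTTTCAGGGGGCTACGGATTTCCAGGCTAA"}
        rec = VariantRecord(contig="c", pos=5, ref="CAG", alt="CG")
        out = cm.normalize_variant(rec, ref)
        assert (out.ref, out.alt) == ("CA", "C")
        assert len(out.ref) - len(out.alt) == 1

    def test_reference_mismatch_raises(self, toy_reference):
        with pytest.raises(cm.ReferenceMismatchError):
            cm.normalize_variant(make_rec("G", "T", pos=5), toy_reference)

    @given(data=st.data())
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_matches_haplotype_oracle_and_preserves_haplotype(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        # repeats make left-alignment nontrivial
        seq = seq[:10] + "ATATATAT" + seq[10:20] + "GGGGG" + seq[20:]
        reference = {"c": seq}
        pos = int(rng.integers(2, len(seq) - 8))
        kind = rng.integers(3)
        if kind == 0:  # SNV
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
        elif kind == 1:  # deletion, possibly unnormalized
            size = int(rng.integers(1, 5))
            ref = seq[pos - 1 : pos + size]
            alt = seq[pos - 1]
        else:  # insertion
            ref = seq[pos - 1]
            alt = ref + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
        rec = VariantRecord(contig="c", pos=pos, ref=ref, alt=alt)
        out = cm.normalize_variant(rec, reference)
        assert out.key == oracle_normalize(rec, reference)
        # the implied alternate haplotype is unchanged
        assert apply_variant(seq, out.pos, out.ref, out.alt) == apply_variant(
            seq, rec.pos, rec.ref, rec.alt
        )


class TestVcfRoundTrip:
    def test_header_only_vcf(self, tmp_path):
        p = tmp_path / "empty.vcf"
        cm.write_vcf(str(p), ["s1"], [], contig_lengths={"chr1": 1000})
        samples, records = cm.read_vcf(str(p))
        assert samples == ["s1"] and records == []

    def test_single_snv_row_parses(self, tmp_path):
        # the locus layout of a validated SNV marker: G>A on a scaffold
        p = tmp_path / "one.vcf"
        rec = VariantRecord(
            contig="scaffold_356", pos=1_788_235, ref="G", alt="A",
            qual=250.0, genotypes={"s1": 1},
        )
        cm.write_vcf(str(p), ["s1"], [rec])
        _, records = cm.read_vcf(str(p))
        assert len(records) == 1
        out = records[0]
        assert out.key == ("scaffold_356", 1_788_235, "G", "A")
        assert cm.classify_variant(out) == "SNV"
        assert out.genotypes["s1"] == 1

    def test_write_read_round_trip_on_simulated_records(self, tmp_path, small_cohort):
        _, _, _, samples, records = small_cohort
        records = records[:50]
        p = tmp_path / "sim.vcf"
        cm.write_vcf(str(p), samples, records)
        rsamples, rrecords = cm.read_vcf(str(p))
        assert rsamples == samples
        assert [r.key for r in rrecords] == [r.key for r in records]
        for a, b in zip(rrecords, records):
            assert a.genotypes == b.genotypes
            assert a.qual == pytest.approx(b.qual, abs=0.01)  # VCF prints 2 decimals

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t10\t.\tA\tG,T\t150\t.\t.\tGT\t0/1\t1/2\n"
        )
        _, records = cm.read_vcf(str(p))
        assert [(r.alt, r.genotypes["s1"], r.genotypes["s2"]) for r in records] == [
            ("G", 1, 1),
            ("T", 0, 1),
        ]

    def test_missing_qual_parses_as_none(self, tmp_path):
        p = tmp_path / "noq.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        _, records = cm.read_vcf(str(p))
        assert records[0].qual is None

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(cm.VcfParseError):
            cm.read_vcf(str(p))


class TestBuildMatrix:
    def test_per_sample_disjoint_sites_merge_as_missing(self):
        r1 = make_rec("A", "G", pos=10, genotypes={"s1": 1})
        r2 = make_rec("C", "T", pos=20, genotypes={"s2": 1})
        m = cm.build_matrix(
            [(["s1"], [r1]), (["s2"], [r2])],
            {"s1": "a", "s2": "b"},
            absent_as="missing",
        )
        assert m.data.shape == (2, 2)
        assert np.isnan(m.data.loc[[r2.key], "s1"]).all()
        assert np.isnan(m.data.loc[[r1.key], "s2"]).all()

    def test_joint_mode_fills_hom_ref(self):
        r1 = make_rec("A", "G", pos=10, genotypes={"s1": 1})
        r2 = make_rec("C", "T", pos=20, genotypes={"s2": 1})
        m = cm.build_matrix(
            [(["s1"], [r1]), (["s2"], [r2])], {"s1": "a", "s2": "b"},
            absent_as="hom_ref",
        )
        assert m.data.loc[[r2.key], "s1"].item() == 0.0

    def test_joint_vcf_cells_equal_simulated_genotypes(self, small_cohort):
        design, _, _, samples, records = small_cohort
        m = cm.build_matrix([(samples, records)], design.sample_to_clone())
        for r in records[:25]:
            for s in samples:
                cell = m.data.loc[[r.key], s].item()
                want = r.genotypes[s]
                assert (np.isnan(cell) and want is None) or cell == want

    def test_conflicting_ref_raises(self):
        r1 = make_rec("A", "G", pos=10, genotypes={"s1": 1})
        r2 = make_rec("AT", "G", pos=10, genotypes={"s2": 1})
        with pytest.raises(cm.MergeConflictError):
            cm.build_matrix(
                [(["s1"], [r1]), (["s2"], [r2])], {"s1": "a", "s2": "b"}
            )

    def test_full_study_design_yields_46_columns(self):
        """Replicate structure of the packaged 18-clone roster: 46 genomes."""
        roster = cm.packaged_design_table()
        s2c, blocks = {}, []
        for _, row in roster.iterrows():
            for i in range(int(row["n_replicates"])):
                s = f"{row['cultivar']}{row['clone_id']}_r{i + 1}"
                s2c[s] = f"{row['cultivar']}{row['clone_id']}"
        rec = make_rec("A", "G", pos=10, genotypes={s: 1 for s in s2c})
        m = cm.build_matrix([(list(s2c), [rec])], s2c)
        assert len(m.samples) == 46

    def test_design_table_exclusion_list(self, tmp_path):
        p = tmp_path / "design.tsv"
        p.write_text(
            "sample_id\tclone_id\tcultivar\texclude\n"
            "s1\tA\tM\t0\n"
            "s2\tA\tM\t1\n"  # e.g. a PCA outlier replicate, dropped explicitly
        )
        df = cm.read_design_table(str(p))
        assert list(df["sample_id"]) == ["s1"]
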