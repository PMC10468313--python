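"""Synthetic cohort generator: reference, truth planting, noisy calls,
amplicon reads."""

import numpy as np
import pytest
from scipy import stats as sps

import clonemarker as cm


class TestReference:
    def test_gc_content_within_binomial_interval(self):
        ref = cm.generate_reference(10_000, 1, gc_fraction=0.345, seed=1)
        seq = ref["contig_001"]
        assert len(seq) == 10_000
        gc = sum(b in "GC" for b in seq)
        lo, hi = sps.binom.interval(0.99, 10_000, 0.345)
        assert lo <= gc <= hi

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in (1, 2):
            ref = cm.generate_reference(2_000, 2, gc_fraction=0.5, seed=7)
            p = tmp_path / f"ref{i}.fasta"
            cm.synthetic.write_fasta(ref, str(p))
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_contig_lengths_sum_to_total(self):
        ref = cm.generate_reference(10_001, 3, seed=0)
        assert sum(len(s) for s in ref.values()) == 10_001
        assert list(ref) == ["contig_001", "contig_002", "contig_003"]

    def test_alphabet(self):
        ref = cm.generate_reference(1_000, 1, seed=3)
        assert set(ref["contig_001"]) <= set("ACGT")

    def test_invalid_design_errors(self):
        with pytest.raises(cm.InvalidDesignError):
            cm.generate_reference(500, 1)
        with pytest.raises(cm.InvalidDesignError):
            cm.generate_reference(10_000, 0)


class TestPlantCohort:
    def test_zero_clone_specific_leaves_only_background(self):
        d = cm.make_design(
            n_clones=2, replicates=2, clone_specific=0,
            genome_length=10_000, background_het_rate=0.003, seed=2,
        )
        ref = cm.generate_reference(d.genome_length, d.n_contigs, seed=2)
        truth = cm.plant_cohort(d, ref)
        assert all(r.clone is None for r in truth.records)
        assert truth.clone_specific_keys() == {}

    def test_exact_planted_counts_and_exclusivity(self, small_cohort):
        design, _, truth, _, _ = small_cohort
        keys = truth.clone_specific_keys()
        for clone in design.clones:
            assert len(keys[clone]) == design.clone_specific_count[clone]
        truth.validate(design.sample_to_clone())  # direct-scan exclusivity

    def test_noiseless_discovery_returns_planted_variants_exactly(self, small_cohort):
        design, _, truth, samples, records = small_cohort
        matrix = cm.build_matrix([(samples, records)], design.sample_to_clone())
        sets = cm.clone_exclusive(matrix)
        assert sets.exclusive == truth.clone_specific_keys()

    def test_background_variants_het_in_every_sample(self, small_cohort):
        _, _, truth, _, _ = small_cohort
        for r in truth.records:
            if r.clone is None:
                assert set(r.genotypes.values()) == {1}

    def test_capacity_error_when_genome_too_small(self):
        d = cm.make_design(
            n_clones=2, replicates=1, clone_specific=900,
            genome_length=1_000, background_het_rate=0.0, seed=0,
        )
        ref = cm.generate_reference(d.genome_length, 1, seed=0)
        with pytest.raises(cm.CapacityError):
            cm.plant_cohort(d, ref)

    def test_planted_tstv_and_het_fraction_match_design_in_expectation(self):
        d = cm.make_design(
            n_clones=2, replicates=1, clone_specific=2_000,
            genome_length=500_000, background_het_rate=0.0,
            indel_fraction=0.0, seed=9,
        )
        ref = cm.generate_reference(d.genome_length, 1, seed=9)
        truth = cm.plant_cohort(d, ref)
        snvs = [r for r in truth.records if len(r.ref) == len(r.alt) == 1]
        n = len(snvs)
        ts = sum(
            (r.ref, r.alt) in cm.discriminate.TRANSITIONS for r in snvs
        )
        p = d.tstv_ratio / (1 + d.tstv_ratio)
        assert abs(ts - n * p) <= 3 * np.sqrt(n * p * (1 - p))
        het = sum(1 in r.genotypes.values() for r in snvs)
        q = d.het_fraction_specific
        assert abs(het - n * q) <= 3 * np.sqrt(n * q * (1 - q))

    def test_indel_fraction_in_expectation(self):
        d = cm.make_design(
            n_clones=1, replicates=1, clone_specific=1_500,
            genome_length=500_000, background_het_rate=0.0, seed=4,
        )
        ref = cm.generate_reference(d.genome_length, 1, seed=4)
        truth = cm.plant_cohort(d, ref)
        n_indel = sum(len(r.ref) != len(r.alt) for r in truth.records)
        p = d.indel_fraction
        n = len(truth.records)
        assert abs(n_indel - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_invalid_rates_rejected(self):
        with pytest.raises(cm.InvalidDesignError):
            cm.make_design(dropout_rate=1.5)
        with pytest.raises(cm.InvalidDesignError):
            cm.CohortDesign(clones=["a", "a"], replicates_per_clone={"a": 2})
        with pytest.raises(cm.InvalidDesignError):
            cm.CohortDesign(clones=["a"], replicates_per_clone={"a": 0})

    def test_single_replicate_clone_is_legal(self):
        d = cm.CohortDesign(
            clones=["a", "b"],
            replicates_per_clone={"a": 1, "b": 3},
            genome_length=10_000,
        )
        assert d.samples[0] == "a_r1"


class TestSimulateCalls:
    def test_noiseless_genotypes_equal_truth(self, small_cohort):
        design, _, truth, samples, records = small_cohort
        by_key = {r.key: r for r in records}
        assert len(records) == len(truth.records)
        for t in truth.records:
            assert by_key[t.key].genotypes == t.genotypes

    def test_same_seed_identical_vcf_bytes(self, tmp_path, small_cohort):
        design, ref, truth, _, _ = small_cohort
        noisy = cm.make_design(
            n_clones=2, replicates=2, clone_specific=5, genome_length=20_000,
            background_het_rate=0.002, dropout_rate=0.1,
            false_positive_rate=1e-4, seed=11,
        )
        paths = []
        for i in (1, 2):
            samples, records = cm.simulate_calls(truth, noisy, seed=13)
            p = tmp_path / f"calls{i}.vcf"
            cm.synthetic.write_calls_vcf(str(p), truth, samples, records)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_dropout_rate_within_binomial_interval(self):
        d = cm.CohortDesign(
            clones=["a"], replicates_per_clone={"a": 1},
            genome_length=300_000, background_het_rate=0.0,
            clone_specific_count={"a": 1_000}, indel_fraction=0.0,
            dropout_rate=0.3, false_positive_rate=0.0, seed=21,
        )
        ref = cm.generate_reference(d.genome_length, 1, seed=21)
        truth = cm.plant_cohort(d, ref)
        _, records = cm.simulate_calls(truth, d)
        by_key = {r.key: r for r in records}
        # a dropped singleton site is not emitted at all
        n_missing = 1_000 - len(records)
        lo, hi = sps.binom.interval(0.99, 1_000, 0.3)
        assert lo <= n_missing <= hi
        assert all(r.genotypes["a_r1"] is not None for r in by_key.values())

    def test_false_positives_are_low_qual_singletons(self):
        d = cm.make_design(
            n_clones=2, replicates=2, clone_specific=0,
            genome_length=100_000, background_het_rate=0.0,
            dropout_rate=0.0, false_positive_rate=5e-4, seed=3,
        )
        ref = cm.generate_reference(d.genome_length, d.n_contigs, seed=3)
        truth = cm.plant_cohort(d, ref)
        _, records = cm.simulate_calls(truth, d)
        assert records, "expected injected false positives"
        for r in records:
            carriers = [s for s, g in r.genotypes.items() if g and g >= 1]
            assert len(carriers) == 1
        # QUAL biased low: the conventional Q>100 filter removes most noise
        share_removed = np.mean([r.qual <= 100 for r in records])
        assert share_removed > 0.5


class TestAmpliconReads:
    def test_zero_depth(self):
        rs = cm.simulate_amplicon_reads("ACGT", "AGGT", "het", depth=0, seed=1)
        assert rs.reads == [] and (rs.n_allele_a, rs.n_allele_b) == (0, 0)

    def test_hom_reference_error_free_reads_all_match(self):
        rs = cm.simulate_amplicon_reads(
            "ACGTACGTAC", "ACGAACGTAC", "hom_a", depth=100,
            per_base_error=0.0, seed=5,
        )
        assert rs.reads == ["ACGTACGTAC"] * 100
        assert (rs.n_allele_a, rs.n_allele_b) == (100, 0)

    def test_het_draws_counted_exactly_by_count_alleles(self):
        marker = cm.MarkerDefinition(
            cultivar="X", clone_id="c1", marker_id="c1_1", variant_type="SNV",
            contig="c", position=50, allele_lengths=(40,),
            snv_alleles=("G", "A"),
            allele_seq_a="G" * 20 + "C" * 20, allele_seq_b="G" * 20 + "A" + "C" * 19,
        )
        rs = cm.simulate_amplicon_reads(
            marker.allele_seq_a, marker.allele_seq_b, "het",
            depth=200, allele_bias=0.5, per_base_error=0.0, seed=3,
        )
        counts = cm.count_alleles(rs.reads, marker, max_mismatches=0)
        assert (counts.count_a, counts.count_b) == (rs.n_allele_a, rs.n_allele_b)

    def test_het_counts_binomial_in_bias(self):
        rs = cm.simulate_amplicon_reads("A" * 30, "C" * 30, "het", depth=1_000,
                                        allele_bias=0.3, seed=8)
        lo, hi = sps.binom.interval(0.99, 1_000, 0.3)
        assert lo <= rs.n_allele_a <= hi
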