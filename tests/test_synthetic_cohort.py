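"""Cohort simulator: genotype sampling, haplotypes, reads and truth."""

import math

import numpy as np
import pytest

from fcgrseq.gene_models import build_isoform
from fcgrseq.synthetic_cohort import (CohortSpec, VariantSpec,
                                      build_haplotypes, emit_reads,
                                      sample_genotypes, simulate_cohort)


def _spec(**kw):
    defaults = dict(n_animals=10, depth=5, error_rate=0.0,
                    indel_error_rate=0.0, seed=1, genes=["FCGR1"])
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSampleGenotypes:
    def test_frequency_zero_gives_no_carriers(self, genes):
        spec = _spec(variant_specs=[VariantSpec(
            "FCGR1", 101378924, "A", "G", allele_frequency=0.0)])
        gts = sample_genotypes(spec, genes)
        assert all(not g for g in gts.values())

    def test_frequency_one_gives_all_hom(self, genes):
        spec = _spec(variant_specs=[VariantSpec(
            "FCGR1", 101378924, "A", "G", allele_frequency=1.0)])
        gts = sample_genotypes(spec, genes)
        assert all(list(g.values()) == [2] for g in gts.values())

    def test_hardy_weinberg_carrier_fraction(self, genes):
        # carrier fraction over replicates ~ 1 - (1-p)^2 (binomial)
        p, n, reps = 0.13, 206, 200
        expected = 1 - (1 - p) ** 2
        fracs = []
        for seed in range(reps):
            spec = _spec(n_animals=n, seed=seed, variant_specs=[
                VariantSpec("FCGR1", 101378924, "A", "G",
                            allele_frequency=p)])
            gts = sample_genotypes(spec, genes)
            fracs.append(sum(bool(g) for g in gts.values()) / n)
        se = math.sqrt(expected * (1 - expected) / (n * reps))
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_carrier_count_mode_is_exact(self, genes):
        spec = _spec(n_animals=206, variant_specs=[VariantSpec(
            "FCGR1", 101378924, "A", "G", carrier_count=52)])
        gts = sample_genotypes(spec, genes)
        assert sum(bool(g) for g in gts.values()) == 52

    def test_both_or_neither_mode_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec("FCGR1", 1, "A", "G")
        with pytest.raises(ValueError):
            VariantSpec("FCGR1", 1, "A", "G", allele_frequency=0.1,
                        carrier_count=3)


class TestBuildHaplotypes:
    def test_no_variants_returns_isoform_transcript(self, fcgr1):
        iso = build_isoform(fcgr1, [])
        h1, h2 = build_haplotypes(fcgr1, iso, ([], []))
        assert h1 == h2 == iso.transcript_seq

    def test_single_snp_hamming_distance_one(self, fcgr1):
        iso = build_isoform(fcgr1, [])
        h1, h2 = build_haplotypes(fcgr1, iso, ([("snv", 134, "C")], []))
        assert h2 == iso.transcript_seq
        diffs = [i for i, (a, b) in enumerate(zip(h1, h2)) if a != b]
        assert diffs == [133]

    def test_three_nt_insertion_preserves_flanks(self, fcgr2a):
        iso = build_isoform(fcgr2a, [])
        h1, _ = build_haplotypes(fcgr2a, iso, ([("ins", 894, "GAT")], []))
        ref = iso.transcript_seq
        assert len(h1) == len(ref) + 3
        assert h1[:894] == ref[:894] and h1[897:] == ref[894:]

    def test_variant_coordinates_shift_for_isoform_edits(self, fcgr2b):
        # the cassette sits upstream-of-nothing relevant here: a variant
        # past the insertion point must shift by the cassette length
        iso = build_isoform(fcgr2b, [{"type": "include_exon", "exon": "6"}])
        ref = fcgr2b.reference_transcript
        alt = "A" if ref[909] != "A" else "C"
        h1, _ = build_haplotypes(fcgr2b, iso, ([("snv", 910, alt)], []))
        assert h1[910 + 57 - 1] == alt

    def test_conflicting_variants_rejected(self, fcgr1):
        iso = build_isoform(fcgr1, [])
        with pytest.raises(ValueError, match="conflicting"):
            build_haplotypes(fcgr1, iso,
                             ([("snv", 134, "C"), ("snv", 134, "G")], []))


class TestEmitReads:
    def test_error_free_reads_are_exact_copies(self):
        rng = np.random.default_rng(0)
        reads, counts = emit_reads(["ACGT" * 30], [1.0], 20, 0.0, 0.0, rng)
        assert counts.tolist() == [20]
        assert all(seq == "ACGT" * 30 for _, seq in reads)

    def test_substitution_rate_matches_expectation(self):
        rng = np.random.default_rng(1)
        template = "ACGT" * 250
        reads, _ = emit_reads([template], [1.0], 400, 0.002, 0.0, rng)
        mismatches = sum(sum(a != b for a, b in zip(seq, template))
                         for _, seq in reads)
        expected = 0.002 * len(template) * 400
        assert abs(mismatches - expected) < 4 * math.sqrt(expected)

    def test_degenerate_mixture_uses_single_template(self):
        rng = np.random.default_rng(2)
        reads, counts = emit_reads(["AAAA", "CCCC"], [1.0, 0.0], 15,
                                   0.0, 0.0, rng)
        assert counts.tolist() == [15, 0]

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            emit_reads(["ACGT"], [1.0], 0, 0.0, 0.0,
                       np.random.default_rng(0))


class TestSimulateCohort:
    def test_single_animal_single_read(self, genes):
        spec = _spec(n_animals=1, depth=1)
        reads, truth = simulate_cohort(spec, genes)
        assert len(reads) == 1
        assert len(reads["RM001"]["FCGR1"]) == 1

    def test_same_seed_identical_output(self, genes, tmp_path):
        spec = _spec(n_animals=3, depth=4, error_rate=0.01, seed=5)
        simulate_cohort(spec, genes, out_dir=tmp_path / "a")
        simulate_cohort(spec, genes, out_dir=tmp_path / "b")
        fa = (tmp_path / "a" / "RM001_FCGR1.fastq").read_bytes()
        fb = (tmp_path / "b" / "RM001_FCGR1.fastq").read_bytes()
        assert fa == fb

    def test_different_seeds_differ(self, genes):
        r1, _ = simulate_cohort(_spec(seed=1, error_rate=0.01), genes)
        r2, _ = simulate_cohort(_spec(seed=2, error_rate=0.01), genes)
        assert r1 != r2

    def test_table_scale_carrier_counts(self, genes):
        # carrier-count mode reproduces a published carrier count exactly
        spec = _spec(n_animals=206, variant_specs=[VariantSpec(
            "FCGR1", 101378924, "A", "G", carrier_count=52)])
        _, truth = simulate_cohort(spec, genes)
        assert truth.variant_carrier_counts() == {
            "chr1:101378924:A>G": 52}

    def test_truth_consistent_with_error_free_reads(self, genes):
        """Genotypes re-derived from error-free reads equal the truth."""
        from fcgrseq.amplicon_caller import call_animal
        spec = _spec(n_animals=6, depth=24, variant_specs=[
            VariantSpec("FCGR1", 101378924, "A", "G",
                        allele_frequency=0.5),
            VariantSpec("FCGR1", 101378991, "C", "CT",
                        allele_frequency=0.3),
        ], seed=21)
        reads, truth = simulate_cohort(spec, genes)
        for animal in truth.animals:
            calls = call_animal(reads[animal]["FCGR1"], genes["FCGR1"])
            assert {c.genomic_key: c.zygosity for c in calls} == \
                truth.genotypes[animal]

    def test_isoform_proportions_sum_to_one(self, genes):
        spec = _spec(genes=["FCGR2B"], isoform_mixture={
            "FCGR2B": {"dirichlet": 1.5}}, n_animals=4)
        _, truth = simulate_cohort(spec, genes)
        for animal in truth.animals:
            props = truth.isoform_props[animal]["FCGR2B"]
            assert len(props) == 4
            assert abs(sum(props.values()) - 1.0) < 1e-12
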