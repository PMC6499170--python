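"""Generator determinism, Mendelian consistency, and parameter recovery."""

from __future__ import annotations

import dataclasses
import math

import pytest
from scipy import stats

from dnsnvkit.context_metrics import TRANSITION, gc_content, titv_summary
from dnsnvkit.core_model import extract_candidate_dnsnvs
from dnsnvkit.denovo_filter import RATIO, apply_filter
from dnsnvkit.callset_comparison import gq_summary
from dnsnvkit.synthetic_trio import (
    ORIGIN_DENOVO,
    ORIGIN_INHERITED,
    ORIGIN_SPURIOUS,
    SyntheticTrioConfig,
    generate_reference,
    generate_trio,
    subsample_callset,
)

from .conftest import SMALL_CONFIG


def binom_bounds(n, p, level=0.99):
    lo = stats.binom.ppf((1 - level) / 2, n, p)
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, p)
    return lo, hi


class TestConfig:
    def test_segment_lengths_must_sum(self):
        with pytest.raises(ValueError):
            SyntheticTrioConfig(chrom_length=100, gc_segments=((60, 0.4),))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticTrioConfig(ti_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticTrioConfig(spurious_rate=1.0)

    def test_spurious_count_realises_requested_rate(self):
        cfg = dataclasses.replace(SMALL_CONFIG, n_denovo=300, spurious_rate=0.10)
        n_s = cfg.n_spurious
        assert n_s / (n_s + cfg.n_denovo) == pytest.approx(0.10, abs=0.01)
        assert dataclasses.replace(cfg, spurious_rate=0.0).n_spurious == 0


class TestReference:
    def test_gc_zero_segment_has_no_gc(self):
        cfg = SyntheticTrioConfig(
            n_chrom=1, chrom_length=5000, gc_segments=((5000, 0.0),), seed=1,
            n_inherited=0, n_denovo=0,
        )
        ref = generate_reference(cfg)
        seq = ref.window("1", 1, 5000)
        assert set(seq) <= {"A", "T"}

    def test_gc_one_segment_is_all_gc(self):
        cfg = SyntheticTrioConfig(
            n_chrom=1, chrom_length=5000, gc_segments=((5000, 1.0),), seed=1,
            n_inherited=0, n_denovo=0,
        )
        seq = generate_reference(cfg).window("1", 1, 5000)
        assert set(seq) <= {"G", "C"}

    def test_realised_gc_within_binomial_bounds(self):
        cfg = SyntheticTrioConfig(
            n_chrom=1, chrom_length=10_000, gc_segments=((10_000, 0.6),), seed=5,
            n_inherited=0, n_denovo=0,
        )
        seq = generate_reference(cfg).window("1", 1, 10_000)
        n_gc = sum(1 for b in seq if b in "GC")
        lo, hi = binom_bounds(10_000, 0.6)
        assert lo <= n_gc <= hi

    def test_deterministic_under_seed(self):
        a = generate_reference(SMALL_CONFIG)
        b = generate_reference(SMALL_CONFIG)
        assert all(
            a.window(c, 1, a.length(c)) == b.window(c, 1, b.length(c))
            for c in a.names
        )


class TestTrioGeneration:
    def test_nothing_planted_gives_no_candidates(self):
        cfg = dataclasses.replace(SMALL_CONFIG, n_denovo=0, spurious_rate=0.0)
        ref = generate_reference(cfg)
        callset, truth = generate_trio(cfg, ref)
        assert len(extract_candidate_dnsnvs(callset)) == 0
        assert truth.keys(ORIGIN_DENOVO) == set()

    def test_seeded_rerun_is_byte_identical(self, tmp_path):
        ref = generate_reference(SMALL_CONFIG)
        for i in (1, 2):
            generate_trio(
                SMALL_CONFIG, ref,
                vcf_path=tmp_path / f"t{i}.vcf", truth_path=tmp_path / f"t{i}.tsv",
            )
        assert (tmp_path / "t1.vcf").read_bytes() == (tmp_path / "t2.vcf").read_bytes()
        assert (tmp_path / "t1.tsv").read_bytes() == (tmp_path / "t2.tsv").read_bytes()

    def test_mendelian_consistency_of_inherited_truth(self, small_sim):
        _, _, _, truth = small_sim
        for t in truth:
            if t.origin != ORIGIN_INHERITED:
                continue
            child = t.true_genotypes["child"]
            parents = (t.true_genotypes["father"], t.true_genotypes["mother"])
            for allele in child:
                assert any(allele in p for p in parents)

    def test_truth_and_vcf_agree(self, small_sim):
        _, _, callset, truth = small_sim
        assert callset.keys() == truth.keys()

    def test_candidates_are_exactly_planted_denovo_plus_spurious(self, small_sim):
        _, _, callset, truth = small_sim
        cands = extract_candidate_dnsnvs(callset)
        assert cands.keys() == truth.keys(ORIGIN_DENOVO) | truth.keys(ORIGIN_SPURIOUS)

    def test_ref_alleles_match_reference(self, small_sim):
        _, ref, callset, _ = small_sim
        for r in callset.records[::37]:
            assert ref.base(r.chrom, r.pos) == r.ref

    def test_too_many_variants_errors(self):
        cfg = SyntheticTrioConfig(
            n_chrom=1, chrom_length=200, gc_segments=((200, 0.5),),
            n_inherited=500, n_denovo=0, spurious_rate=0.0,
        )
        ref = generate_reference(cfg)
        with pytest.raises(ValueError, match="cannot place"):
            generate_trio(cfg, ref)


class TestParameterRecovery:
    def test_planted_transition_fraction_recovered(self, recovery_sim):
        cfg, _, _, truth = recovery_sim
        denovo = [t for t in truth if t.origin == ORIGIN_DENOVO]
        assert len(denovo) == 300
        n_ti = sum(1 for t in denovo if t.substitution_class == TRANSITION)
        lo, hi = binom_bounds(len(denovo), cfg.ti_fraction)
        assert lo <= n_ti <= hi

    def test_titv_of_recovered_true_dnsnvs_estimates_planted_ratio(self, recovery_sim):
        cfg, _, callset, truth = recovery_sim
        cands = extract_candidate_dnsnvs(callset)
        true_cands = cands.subset(truth.keys(ORIGIN_DENOVO))
        s = titv_summary(true_cands)
        lo, hi = binom_bounds(s.n_classified, cfg.ti_fraction)
        assert lo <= s.n_transitions <= hi

    def test_segment_gc_recovered_from_variant_windows(self, small_sim):
        cfg, ref, _, truth = small_sim
        for target in {t.segment_gc for t in truth}:
            keys = [t.key for t in truth if t.segment_gc == target]
            gcs = [
                gc_content(ref, c, p) for (c, p, _, _) in keys
            ]
            gcs = [g for g in gcs if g is not None]
            # mean of k windows of 100 i.i.d. bases: binomial(100k, target)
            n = 100 * len(gcs)
            lo, hi = binom_bounds(n, target, level=0.999)
            total_gc = sum(g for g in gcs)  # each g is a count over 100 bases
            assert lo <= total_gc <= hi

    def test_filter_retains_true_dnsnvs_at_depth_30(self, recovery_sim):
        cfg, _, callset, truth = recovery_sim
        assert cfg.mean_depth >= 30 and cfg.seq_error <= 0.01
        cands = extract_candidate_dnsnvs(callset)
        kept = apply_filter(cands, 0.0)
        true_kept = kept.keys() & truth.keys(ORIGIN_DENOVO)
        assert len(true_kept) >= 0.9 * cfg.n_denovo

    def test_ratio_score_separates_true_from_spurious(self, recovery_sim):
        """Under this generator, spurious candidates have a nearly homozygous
        child depth profile; the ratio-form score is the one that penalises
        that, so discrimination is asserted for it (see the methods note)."""
        cfg, _, callset, truth = recovery_sim
        cands = extract_candidate_dnsnvs(callset)
        kept = apply_filter(cands, 0.0, RATIO)
        spurious = truth.keys(ORIGIN_SPURIOUS)
        true_keys = truth.keys(ORIGIN_DENOVO)
        assert len(kept.keys() & spurious) < 0.5 * len(spurious)
        assert len(kept.keys() & true_keys) >= 0.9 * cfg.n_denovo

    def test_titv_preserved_by_filtering(self, recovery_sim):
        cfg, _, callset, truth = recovery_sim
        cands = extract_candidate_dnsnvs(callset)
        kept = apply_filter(cands, 0.0)
        before, after = titv_summary(cands), titv_summary(kept)
        # The filter is substitution-blind, so the kept transition fraction
        # stays within binomial sampling error of the input fraction.
        p = before.n_transitions / before.n_classified
        lo, hi = binom_bounds(after.n_classified, p)
        assert lo <= after.n_transitions <= hi

    def test_gq_medians_improve_after_ratio_filtering(self, recovery_sim):
        cfg, _, callset, truth = recovery_sim
        cands = extract_candidate_dnsnvs(callset)
        kept = apply_filter(cands, 0.0, RATIO)
        before, after = gq_summary(cands), gq_summary(kept)
        for role in ("father", "mother", "child"):
            assert after[role].median >= before[role].median


class TestSubsample:
    def test_fraction_bounds(self, small_sim):
        _, _, callset, _ = small_sim
        with pytest.raises(ValueError):
            subsample_callset(callset, 1.5, seed=1)

    def test_subset_and_deterministic(self, small_sim):
        _, _, callset, _ = small_sim
        a = subsample_callset(callset, 0.6, seed=3)
        b = subsample_callset(callset, 0.6, seed=3)
        assert a.keys() <= callset.keys()
        assert a.records == b.records
        assert 0 < len(a) < len(callset)
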