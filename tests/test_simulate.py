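"""Synthetic-data generator: determinism, planted truth, read errors."""

import math
from itertools import product

import edlib
import numpy as np
import pytest

from tetrasnp import io as io_mod
from tetrasnp.errors import ConfigurationError
from tetrasnp.simulate import (SimulationConfig, apply_homopolymer_indels,
                               audit_allele_support,
                               generate_reference_transcripts,
                               genotype_of_read, plant_variants,
                               reverse_complement, simulate_dataset,
                               simulate_reads)

from test_classify import oracle_classify


def config(**kw):
    base = dict(n_loci=10, seed=42, sub_error_rate=0.0,
                homopolymer_indel_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_zero_loci_rejected(self):
        with pytest.raises(ConfigurationError):
            config(n_loci=0)

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ConfigurationError):
            config(locus_length_range=(2000, 300))

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            config(within_het_rate=1.5)

    def test_dosage_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            config(dosage_weights=(0.5, 0.5, 0.5))

    def test_read_min_below_100_rejected(self):
        with pytest.raises(ConfigurationError):
            config(read_length_model={"min": 50, "max": 600, "mean": 300,
                                      "sd": 50})


class TestTranscripts:
    def test_lengths_and_alphabet(self):
        cfg = config(n_loci=200, locus_length_range=(300, 2000))
        transcripts = generate_reference_transcripts(cfg)
        assert len(transcripts) == 200
        for seq in transcripts.values():
            assert 300 <= len(seq) <= 2000
            assert set(seq) <= set("ACGT")

    def test_seed_determinism_byte_identical(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            ds = simulate_dataset(config(seed=7))
            out = tmp_path / name
            io_mod.write_dataset(ds, out)
            paths.append(out)
        for fname in ("transcripts.fasta", "reads.fasta", "placements.tsv",
                      "truth.tsv"):
            assert (paths[0] / fname).read_bytes() == \
                (paths[1] / fname).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_reference_transcripts(config(seed=1))
        b = generate_reference_transcripts(config(seed=2))
        assert a != b


class TestPlantedVariants:
    def test_null_simulation_is_monomorphic(self):
        cfg = config(within_het_rate=0.0, between_div_rate=0.0)
        transcripts = generate_reference_transcripts(cfg)
        ga, gb, truth = plant_variants(transcripts, cfg)
        assert truth == []
        for locus, ref in transcripts.items():
            for hap in ga.haplotypes[locus] + gb.haplotypes[locus]:
                assert hap == ref

    def test_pure_between_divergence_is_category_1(self):
        cfg = config(within_het_rate=0.0, between_div_rate=0.01)
        transcripts = generate_reference_transcripts(cfg)
        _, _, truth = plant_variants(transcripts, cfg)
        assert truth
        assert all(v.expected_category == 1 for v in truth)

    def test_het_in_one_homozygous_in_other_is_category_2(self):
        # dosage-2 heterozygosity in one genotype, the other unchanged
        cfg = config()
        var = None
        transcripts = generate_reference_transcripts(
            config(within_het_rate=0.01, between_div_rate=0.0))
        _, _, truth = plant_variants(
            transcripts, config(within_het_rate=0.01, between_div_rate=0.0))
        for v in truth:
            sets = [frozenset(v.alleles[g]) for g in cfg.genotype_ids]
            if len(sets[0]) == 2 and len(sets[1]) == 1:
                var = v
                break
        assert var is not None
        assert var.expected_category == 2

    def test_truth_categories_match_oracle_exhaustively(self):
        cfg = config(n_loci=30, within_het_rate=0.01, between_div_rate=0.005)
        ds = simulate_dataset(cfg)
        assert ds.truth
        for v in ds.truth:
            a, b = (v.alleles[g] for g in cfg.genotype_ids)
            assert v.expected_category == oracle_classify(a, b)
            for g in cfg.genotype_ids:
                assert sum(v.alleles[g].values()) == 4
                counts = {x: v.hap_alleles[g].count(x) for x in set(v.hap_alleles[g])}
                assert counts == v.alleles[g]

    def test_one_variant_per_position_and_haplotype_consistency(self):
        cfg = config(n_loci=20, within_het_rate=0.01, between_div_rate=0.005)
        ds = simulate_dataset(cfg)
        seen = set()
        planted = {}
        for v in ds.truth:
            assert (v.locus_id, v.position) not in seen
            seen.add((v.locus_id, v.position))
            planted.setdefault(v.locus_id, set()).add(v.position)
        # haplotypes differ from the reference only at planted positions
        for genotype in ds.genotypes:
            for locus, haps in genotype.haplotypes.items():
                ref = ds.transcripts[locus]
                for hap in haps:
                    diffs = {i for i, (x, y) in enumerate(zip(ref, hap))
                             if x != y}
                    assert diffs <= planted.get(locus, set())


def site_category_distribution(w, b):
    """Exact category probabilities by enumerating the site-state space.

    The background of genotype A is the reference; genotype B's background
    diverges with probability b (uniform over the 3 other bases); each
    genotype is independently heterozygous with probability w, its second
    allele uniform over the 3 bases other than its background.
    """
    ref = "A"
    probs = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    bg_b_states = [(ref, 1 - b)] + [(x, b / 3) for x in "CGT"]
    for bg_b, p_bg in bg_b_states:
        het_a_states = [(None, 1 - w)] + [
            (x, w / 3) for x in "ACGT" if x != ref]
        het_b_states = [(None, 1 - w)] + [
            (x, w / 3) for x in "ACGT" if x != bg_b]
        for (ha, pa), (hb, pb) in product(het_a_states, het_b_states):
            set_a = {ref} | ({ha} if ha else set())
            set_b = {bg_b} | ({hb} if hb else set())
            cat = oracle_classify(set_a, set_b)
            if cat is not None:
                probs[cat] += p_bg * pa * pb
    total = sum(probs.values())
    return {c: p / total for c, p in probs.items()}, total


class TestCategoryFrequencies:
    def test_truth_frequencies_match_enumeration_3_sigma(self):
        w, b = 0.004, 0.002
        cfg = config(n_loci=150, locus_length_range=(500, 1500),
                     within_het_rate=w, between_div_rate=b)
        ds = simulate_dataset(cfg)
        dist, _ = site_category_distribution(w, b)
        n = len(ds.truth)
        assert n > 300
        for cat, p in dist.items():
            observed = sum(1 for v in ds.truth if v.expected_category == cat)
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sigma, (cat, observed, n * p)


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, clean_dataset):
        haps = {g.genotype_id: g.haplotypes for g in clean_dataset.genotypes}
        for read in clean_dataset.reads:
            source = haps[read.genotype_id][read.locus_id][
                read.haplotype_index - 1]
            fragment = (read.sequence if read.strand == "+"
                        else reverse_complement(read.sequence))
            assert fragment == source[read.start:read.end]
            assert 100 <= len(fragment) <= 636

    def test_genotype_recoverable_from_read_id(self, clean_dataset):
        cfg = clean_dataset.config
        for read in clean_dataset.reads[:50]:
            assert genotype_of_read(read.read_id, cfg) == read.genotype_id

    def test_per_locus_counts_poisson_3_sigma(self):
        depth = 10.0
        cfg = config(n_loci=20, depth_per_genotype=depth)
        ds = simulate_dataset(cfg)
        counts = {}
        for read in ds.reads:
            key = (read.genotype_id, read.locus_id)
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        n_cells = 2 * cfg.n_loci
        sigma = math.sqrt(n_cells * depth)
        assert abs(total - n_cells * depth) <= 3 * sigma
        # no single locus wildly off (3 sigma with a small slack for the
        # 40-cell multiplicity)
        for key in counts:
            assert abs(counts[key] - depth) <= 4 * math.sqrt(depth)

    def test_homopolymer_indels_detected_by_alignment(self):
        cfg = config(n_loci=5, homopolymer_indel_rate=0.05, seed=9)
        ds = simulate_dataset(cfg)
        haps = {g.genotype_id: g.haplotypes for g in ds.genotypes}
        n_indel_reads = 0
        for read in ds.reads:
            source = haps[read.genotype_id][read.locus_id][
                read.haplotype_index - 1][read.start:read.end]
            fragment = (read.sequence if read.strand == "+"
                        else reverse_complement(read.sequence))
            result = edlib.align(fragment, source, task="path")
            ops = result["cigar"]
            if "I" in ops or "D" in ops:
                n_indel_reads += 1
                assert read.n_indel > 0
        assert n_indel_reads >= 1

    def test_homopolymer_edit_changes_one_run_unit(self):
        rng = np.random.default_rng(0)
        seq = "ACGTAAAACGTT"
        out, n = apply_homopolymer_indels(seq, 1.0, rng)
        # every run of length >= 2 gained or lost exactly one unit
        assert n == 2
        assert abs(len(out) - len(seq)) <= n


class TestAudit:
    def test_support_counts_match_direct_scan(self, clean_dataset):
        audit = audit_allele_support(clean_dataset.truth, clean_dataset.reads)
        for entry in audit[:40]:
            var = entry["variant"]
            for read in clean_dataset.reads:
                if read.locus_id != var.locus_id:
                    continue
                covered = read.start <= var.position < read.end
                if covered:
                    allele = var.hap_alleles[read.genotype_id][
                        read.haplotype_index - 1]
                    assert entry["support"][read.genotype_id][allele] >= 1
            total = sum(sum(d.values()) for d in entry["support"].values())
            n_cover = sum(
                1 for read in clean_dataset.reads
                if read.locus_id == var.locus_id
                and read.start <= var.position < read.end)
            assert total == n_cover
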