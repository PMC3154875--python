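"""Candidate SNP caller: support filtering, confidence, remap QC."""

import pytest
from hypothesis import given, settings, strategies as st

from tetrasnp.discovery import (CallerConfig, call_contigs,
                                classify_candidates, confidence_score,
                                detect_variant_columns, remap_qc,
                                summarize_column, STATUS_CALLED,
                                STATUS_INDEL, STATUS_LOW_CONFIDENCE,
                                STATUS_UNCOVERED)
from tetrasnp.errors import ConfigurationError, InputError

from conftest import make_contig

TEMPLATE = "ACGTACGTACGACGTACGTAC"  # 21 columns; variant column is 10


def variant_contig(chi_bases="AA", wis_bases="CC", wis_extra_mismatches=0):
    """Four full-length reads with a variant column at position 10.

    ``wis_extra_mismatches`` flanking columns of the second Wisfal read are
    mutated away from the 3-read majority consensus (paralog-like noise).
    """
    def with_base(base):
        return TEMPLATE[:10] + base + TEMPLATE[11:]

    reads = [
        ("CHI|r1", "Chilean", 0, with_base(chi_bases[0])),
        ("CHI|r2", "Chilean", 0, with_base(chi_bases[1])),
        ("WIS|r1", "Wisfal", 0, with_base(wis_bases[0])),
    ]
    noisy = list(with_base(wis_bases[1]))
    flank_cols = [c for c in range(21) if c != 10]
    for col in flank_cols[:wis_extra_mismatches]:
        noisy[col] = {"A": "G", "C": "T", "G": "A", "T": "C"}[noisy[col]]
    reads.append(("WIS|r2", "Wisfal", 0, "".join(noisy)))
    return make_contig("ctg", reads)


class TestSummarizeColumn:
    def test_counts_per_genotype(self):
        contig = variant_contig()
        col = summarize_column(contig, 10)
        assert col.base_counts == {"Chilean": {"A": 2}, "Wisfal": {"C": 2}}
        assert col.gap_counts == {"Chilean": 0, "Wisfal": 0}

    def test_non_spanning_read_contributes_nothing(self):
        contig = make_contig("c", [("CHI|a", "Chilean", 0, "ACGT"),
                                   ("WIS|b", "Wisfal", 6, "ACGT")])
        col = summarize_column(contig, 2)
        assert col.base_counts["Chilean"] == {"G": 1}
        assert col.base_counts.get("Wisfal", {}) == {}

    def test_mixed_case_counted_case_insensitively(self):
        contig = make_contig("c", [("CHI|a", "Chilean", 0, "acgt"),
                                   ("CHI|b", "Chilean", 0, "ACGT")])
        col = summarize_column(contig, 0)
        assert col.base_counts["Chilean"] == {"A": 2}

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            summarize_column(variant_contig(), 99)


class TestDetect:
    def test_clean_between_genotype_column_called(self):
        snps = detect_variant_columns(variant_contig())
        [snp] = snps
        assert snp.padded_pos == 10
        assert snp.status == STATUS_CALLED
        assert snp.alleles == {"Chilean": frozenset("A"),
                               "Wisfal": frozenset("C")}

    def test_singleton_allele_dropped(self):
        # C seen once in Chilean: not a form of the SNP
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("CHI|3", "Chilean", 0, TEMPLATE[:10] + "C" + TEMPLATE[11:]),
            ("WIS|1", "Wisfal", 0, TEMPLATE),
            ("WIS|2", "Wisfal", 0, TEMPLATE),
        ])
        assert detect_variant_columns(contig) == []

    def test_gap_only_variation_never_candidate(self):
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("CHI|3", "Chilean", 0, TEMPLATE[:10] + "-" + TEMPLATE[11:]),
            ("CHI|4", "Chilean", 0, TEMPLATE[:10] + "-" + TEMPLATE[11:]),
            ("WIS|1", "Wisfal", 0, TEMPLATE),
            ("WIS|2", "Wisfal", 0, TEMPLATE),
        ])
        assert detect_variant_columns(contig) == []

    def test_pad_consensus_column_filtered_as_indel(self):
        # most reads carry an insertion column; two reads of each genotype
        # show bases at the pad -> would be a candidate but is voided
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, "ACGTA-ACGT"),
            ("CHI|2", "Chilean", 0, "ACGTAAACGT"),
            ("CHI|3", "Chilean", 0, "ACGTAAACGT"),
            ("WIS|1", "Wisfal", 0, "ACGTA-ACGT"),
            ("WIS|2", "Wisfal", 0, "ACGTA-ACGT"),
            ("WIS|3", "Wisfal", 0, "ACGTACACGT"),
            ("WIS|4", "Wisfal", 0, "ACGTACACGT"),
        ])
        assert contig.consensus[5] == "-"
        snps = detect_variant_columns(contig)
        statuses = {s.padded_pos: s.status for s in snps}
        assert statuses.get(5) == STATUS_INDEL

    def test_single_genotype_coverage_filtered(self):
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("CHI|3", "Chilean", 0, TEMPLATE[:10] + "C" + TEMPLATE[11:]),
            ("CHI|4", "Chilean", 0, TEMPLATE[:10] + "C" + TEMPLATE[11:]),
        ])
        [snp] = detect_variant_columns(contig)
        assert snp.status == STATUS_UNCOVERED
        relaxed = CallerConfig(require_both_genotypes_covered=False)
        [snp] = detect_variant_columns(contig, relaxed)
        assert snp.status == STATUS_CALLED

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CallerConfig(min_reads_per_allele=0)
        with pytest.raises(ConfigurationError):
            CallerConfig(min_confidence=150)


class TestConfidence:
    def test_all_matching_is_100(self):
        assert confidence_score(variant_contig(), 10, 10) == 100.0

    def test_hand_counted_85_percent(self):
        # 3 identical reads and one with 9 flank mismatches: 60 flanking
        # observations per... 3 reads match everywhere (51 of 60 match)
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("WIS|1", "Wisfal", 0, TEMPLATE),
        ])
        noisy = list(TEMPLATE)
        flank_cols = [c for c in range(21) if c != 10]
        for col in flank_cols[:9]:
            noisy[col] = {"A": "G", "C": "T", "G": "A", "T": "C"}[noisy[col]]
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("WIS|1", "Wisfal", 0, "".join(noisy)),
        ])
        assert confidence_score(contig, 10, 10) == pytest.approx(85.0)

    def test_exact_90_boundary_retained(self):
        # 8 mismatches of 80 flanking observations -> exactly 90.0
        contig = variant_contig(wis_extra_mismatches=8)
        [snp] = [s for s in detect_variant_columns(contig)
                 if s.padded_pos == 10]
        assert snp.confidence == pytest.approx(90.0)
        assert snp.status == STATUS_CALLED

    def test_below_90_filtered(self):
        contig = variant_contig(wis_extra_mismatches=9)
        [snp] = [s for s in detect_variant_columns(contig)
                 if s.padded_pos == 10]
        assert snp.confidence < 90.0
        assert snp.status == STATUS_LOW_CONFIDENCE

    def test_gaps_excluded_from_both_sides_of_ratio(self):
        gappy = TEMPLATE[:5] + "-" + TEMPLATE[6:]
        contig = make_contig("c", [
            ("CHI|1", "Chilean", 0, TEMPLATE),
            ("CHI|2", "Chilean", 0, TEMPLATE),
            ("WIS|1", "Wisfal", 0, gappy),
        ])
        assert confidence_score(contig, 10, 10) == 100.0


def oracle_scan(contig, config):
    """Independent brute-force caller over the raw padded strings."""
    genotypes = sorted({r.genotype_id for r in contig.reads})
    length = len(contig.consensus)

    def counts_at(col):
        out = {g: {b: 0 for b in "ACGT-"} for g in genotypes}
        for r in contig.reads:
            if r.offset <= col < r.offset + len(r.padded_seq):
                ch = r.padded_seq[col - r.offset].upper()
                if ch in "ACGT-":
                    out[r.genotype_id][ch] += 1
        return out

    def oracle_confidence(pos):
        cols, i = [], pos - 1
        while i >= 0 and len(cols) < config.confidence_window:
            if contig.consensus[i] in "ACGT":
                cols.append(i)
            i -= 1
        right, i = 0, pos + 1
        while i < length and right < config.confidence_window:
            if contig.consensus[i] in "ACGT":
                cols.append(i)
                right += 1
            i += 1
        match = total = 0
        for col in cols:
            d = counts_at(col)
            for g in genotypes:
                for b in "ACGT":
                    total += d[g][b]
                    if b == contig.consensus[col]:
                        match += d[g][b]
        return 100.0 * match / total if total else 100.0

    results = {}
    for col in range(length):
        d = counts_at(col)
        retained = {g: {b for b in "ACGT"
                        if d[g][b] >= config.min_reads_per_allele}
                    for g in genotypes}
        pooled = set().union(*retained.values()) if retained else set()
        if len(pooled) < 2:
            continue
        if contig.consensus[col] == "-":
            status = STATUS_INDEL
        elif config.require_both_genotypes_covered and (
                len(genotypes) < 2 or any(
                    sum(d[g][b] for b in "ACGT") < config.min_reads_per_allele
                    for g in genotypes)):
            status = STATUS_UNCOVERED
        elif oracle_confidence(col) < config.min_confidence:
            status = STATUS_LOW_CONFIDENCE
        else:
            status = STATUS_CALLED
        results[col] = (status, {g: frozenset(retained[g])
                                 for g in genotypes})
    return results


@st.composite
def small_contigs(draw):
    n_cols = draw(st.integers(min_value=5, max_value=30))
    n_reads = draw(st.integers(min_value=2, max_value=12))
    reads = []
    for i in range(n_reads):
        offset = draw(st.integers(min_value=0, max_value=n_cols - 3))
        length = draw(st.integers(min_value=3, max_value=n_cols - offset))
        seq = draw(st.text(alphabet=["A", "C", "G", "T", "-"],
                           min_size=length, max_size=length))
        genotype = draw(st.sampled_from(["Chilean", "Wisfal"]))
        reads.append((f"{genotype[:3].upper()}|r{i}", genotype, offset, seq))
    return make_contig("contig", reads)


@given(contig=small_contigs(),
       min_reads=st.integers(min_value=1, max_value=3))
@settings(max_examples=80, derandomize=True, deadline=None)
def test_detect_agrees_with_brute_force_oracle(contig, min_reads):
    config = CallerConfig(min_reads_per_allele=min_reads)
    expected = oracle_scan(contig, config)
    observed = {s.padded_pos: (s.status, s.alleles)
                for s in detect_variant_columns(contig, config)}
    assert observed == expected


class TestMonotonicity:
    def test_raising_support_threshold_never_adds_calls(self, clean_contigs):
        counts = []
        for min_reads in (2, 3, 4):
            config = CallerConfig(min_reads_per_allele=min_reads)
            snps = call_contigs(clean_contigs, config, run_remap_qc=False)
            counts.append(sum(1 for s in snps if s.status == STATUS_CALLED))
        assert counts[0] >= counts[1] >= counts[2]

    def test_raising_confidence_threshold_never_adds_calls(self,
                                                           noisy_dataset):
        from tetrasnp.alignment import build_contig_alignment

        contigs = build_contig_alignment(noisy_dataset.reads,
                                         noisy_dataset.transcripts)
        counts = []
        for min_conf in (50.0, 90.0, 99.0):
            config = CallerConfig(min_confidence=min_conf)
            snps = call_contigs(contigs, config, run_remap_qc=False)
            counts.append(sum(1 for s in snps if s.status == STATUS_CALLED))
        assert counts[0] >= counts[1] >= counts[2]


class TestRemapQC:
    def test_untouched_alignment_passes(self):
        contig = variant_contig()
        [snp] = detect_variant_columns(contig)
        assert remap_qc(contig, snp) is True
        assert snp.remap_ok is True

    def test_shifted_read_offset_fails(self):
        contig = variant_contig()
        [snp] = detect_variant_columns(contig)
        reads = [("CHI|r1", "Chilean", 0, contig.reads[0].padded_seq[:-1])]
        for r in contig.reads[1:]:
            reads.append((r.read_id, r.genotype_id, r.offset + 1,
                          r.padded_seq[:-1]))
        perturbed = make_contig("ctg", reads)
        assert remap_qc(perturbed, snp) is False

    def test_contig_mismatch_rejected(self):
        contig = variant_contig()
        [snp] = detect_variant_columns(contig)
        other = make_contig("other", [("CHI|x", "Chilean", 0, "ACGT"),
                                      ("WIS|y", "Wisfal", 0, "ACGT")])
        with pytest.raises(InputError):
            remap_qc(other, snp)


class TestClassifyCandidates:
    def test_categories_assigned_from_filtered_sets(self):
        contig = variant_contig()
        snps = detect_variant_columns(contig)
        classify_candidates(snps, genotype_order=["Chilean", "Wisfal"])
        assert snps[0].category == 1

    def test_filtered_records_left_unclassified(self):
        contig = variant_contig(wis_extra_mismatches=9)
        snps = detect_variant_columns(contig)
        classify_candidates(snps, genotype_order=["Chilean", "Wisfal"])
        assert all(s.category is None for s in snps
                   if s.status != STATUS_CALLED)
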