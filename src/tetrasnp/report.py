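"""Run summaries: length distributions, category tables, truth comparison.

Length tables mirror the conventional pre-/post-assembly presentation of an
EST sequencing project: raw reads binned in 100 bp steps, assembled
sequences in coarser bins (100-500, 501-1000, ... , >2000 bp), each with
count, min/max and average length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: (label, lower, upper) with lower <= x <= upper (inclusive edges as the
#: labels read); pre-assembly bins are closed-open 100 bp steps
PRE_BINS = [(f"{lo}-{lo + 100} bp", lo, lo + 100 - 1)
            for lo in range(100, 700, 100)]
POST_BINS = [("100-500 bp", 100, 500), ("501-1000 bp", 501, 1000),
             ("1001-1500 bp", 1001, 1500), ("1501-2000 bp", 1501, 2000),
             ("> 2000 bp", 2001, None)]


def length_summary(lengths, kind: str = "pre") -> pd.DataFrame:
    """Bin sequence lengths into the standard pre- or post-assembly table."""
    bins = PRE_BINS if kind == "pre" else POST_BINS
    lengths = sorted(int(x) for x in lengths)
    rows = []
    for label, lo, hi in bins:
        n = sum(1 for x in lengths
                if x >= lo and (hi is None or x <= hi))
        rows.append({"bin": label, "count": n})
    rows.append({"bin": "Total base count (bp)", "count": sum(lengths)})
    rows.append({"bin": "Sequence count", "count": len(lengths)})
    rows.append({"bin": "Minimum length (bp)",
                 "count": lengths[0] if lengths else 0})
    rows.append({"bin": "Maximum length (bp)",
                 "count": lengths[-1] if lengths else 0})
    rows.append({"bin": "Average length (bp)",
                 "count": round(sum(lengths) / len(lengths)) if lengths else 0})
    return pd.DataFrame(rows, columns=["bin", "count"])


@dataclass
class TruthEvaluation:
    """Comparison of called SNPs against the planted-variant truth table."""

    n_planted: int
    n_supported: int  # planted variants with every allele at >= 2 reads
    n_called: int
    n_true_positive: int  # called columns matching a planted variant
    n_false_positive: int
    n_supported_called: int  # supported planted variants that were called
    #: (expected_category, called_category) -> count over matched calls
    confusion: dict = field(default_factory=dict)
    #: same, restricted to fully supported planted variants
    confusion_supported: dict = field(default_factory=dict)

    @property
    def sensitivity_supported(self) -> float:
        """Fraction of fully supported planted variants that were called."""
        if self.n_supported == 0:
            return 1.0
        return self.n_supported_called / self.n_supported

    @property
    def precision(self) -> float:
        if self.n_called == 0:
            return 1.0
        return self.n_true_positive / self.n_called

    def category_agreement(self, supported_only: bool = False) -> float:
        """Fraction of matched calls whose category equals the planted one.

        With ``supported_only`` the fraction is computed over planted
        variants whose every allele met the read-support threshold — the
        subset where the observed allele profile can equal the planted one.
        """
        confusion = self.confusion_supported if supported_only else self.confusion
        total = sum(confusion.values())
        if total == 0:
            return 1.0
        agree = sum(n for (exp, got), n in confusion.items() if exp == got)
        return agree / total


def planted_column(contig, variant):
    """Padded column of a planted variant on a backbone-built contig."""
    if contig.ref_column_map is None:
        return None
    idx = variant.position - contig.ref_offset
    if not 0 <= idx < len(contig.ref_column_map):
        return None
    return int(contig.ref_column_map[idx])


def evaluate_against_truth(contigs, truth, snps, reads=None,
                           min_reads: int = 2) -> TruthEvaluation:
    """Match called SNP columns to planted variants and tally agreement.

    ``contigs`` must come from :func:`~tetrasnp.alignment.build_contig_alignment`
    (they carry the backbone coordinate map). When ``reads`` is given, the
    truth-projected allele support determines which planted variants were
    fully supported (every planted allele covered by >= ``min_reads`` reads
    of its genotype).
    """
    from .simulate import audit_allele_support

    contig_map = {c.contig_id: c for c in contigs}
    planted_by_col = {}
    for var in truth:
        contig = contig_map.get(var.locus_id)
        if contig is None:
            continue
        col = planted_column(contig, var)
        if col is not None:
            planted_by_col[(var.locus_id, col)] = var

    called = {(s.contig_id, s.padded_pos): s
              for s in snps if s.status == "called"}

    supported_keys = set()
    if reads is not None:
        audit = audit_allele_support(truth, reads, min_reads=min_reads)
        for entry in audit:
            if entry["fully_supported"]:
                var = entry["variant"]
                supported_keys.add((var.locus_id, var.position))

    confusion: dict = {}
    confusion_supported: dict = {}
    n_tp = 0
    n_supported_called = 0
    for key, snp in called.items():
        var = planted_by_col.get(key)
        if var is None:
            continue
        n_tp += 1
        pair = (var.expected_category, snp.category)
        confusion[pair] = confusion.get(pair, 0) + 1
        if (var.locus_id, var.position) in supported_keys:
            confusion_supported[pair] = confusion_supported.get(pair, 0) + 1
    for (locus_id, col), var in planted_by_col.items():
        if (locus_id, var.position) in supported_keys and \
                (locus_id, col) in called:
            n_supported_called += 1

    return TruthEvaluation(
        n_planted=len(truth),
        n_supported=len(supported_keys),
        n_called=len(called),
        n_true_positive=n_tp,
        n_false_positive=len(called) - n_tp,
        n_supported_called=n_supported_called,
        confusion=confusion,
        confusion_supported=confusion_supported,
    )


def format_report(read_lengths=None, contig_lengths=None, summary=None,
                  chromosome_table=None, evaluation=None) -> str:
    """Human-readable run report; every section is optional."""
    parts = []
    if read_lengths is not None:
        parts.append("== Read length distribution (pre-assembly) ==")
        parts.append(length_summary(read_lengths, "pre").to_string(index=False))
    if contig_lengths is not None:
        parts.append("== Contig length distribution (post-assembly) ==")
        parts.append(length_summary(contig_lengths, "post")
                     .to_string(index=False))
    if summary is not None:
        parts.append("== Candidate SNP categories ==")
        parts.append(summary.to_frame().to_string(index=False))
        parts.append(f"Total SNPs: {summary.total_snps}   "
                     f"contigs with SNPs: {summary.contigs_with_snps}")
    if chromosome_table is not None and len(chromosome_table):
        parts.append("== SNP-bearing contigs per chromosome ==")
        parts.append(chromosome_table.to_string(index=False))
    if evaluation is not None:
        parts.append("== Truth comparison (simulation) ==")
        parts.append(
            f"planted variants: {evaluation.n_planted}\n"
            f"fully supported (>=2 reads per allele): "
            f"{evaluation.n_supported}\n"
            f"called: {evaluation.n_called}   "
            f"true positives: {evaluation.n_true_positive}   "
            f"false positives: {evaluation.n_false_positive}\n"
            f"sensitivity (supported subset): "
            f"{100 * evaluation.sensitivity_supported:.1f}%   "
            f"precision: {100 * evaluation.precision:.1f}%   "
            f"category agreement: "
            f"{100 * evaluation.category_agreement():.1f}%")
    return "\n\n".join(parts) + "\n"
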