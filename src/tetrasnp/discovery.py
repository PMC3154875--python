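"""Candidate SNP calling on padded contig alignments.

The caller scans every consensus column of a two-genotype contig and applies
the classic stringent EST-SNP rules:

* an allele counts as a "form" of the SNP only with a minimum number of
  supporting reads (default 2) in its genotype;
* gap observations are never alleles and pad-consensus columns are never
  candidates — indels are ignored, they are treated as sequencing artifacts;
* a windowed confidence score (percent of flanking read bases matching the
  consensus) guards against misassembled or paralogous regions, with calls
  below the cutoff (default 90%, inclusive boundary retained) discarded;
* optionally both genotypes must be covered at the column, avoiding phantom
  between-genotype calls where one genotype was simply not sequenced.

Called columns carry per-genotype allele support and can be quality
controlled by remapping: serializing the contig through the ACE format and
re-extracting every supporting base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np

from . import ace as ace_mod
from .alignment import PAD, BASES, _CODE_LUT, ContigAlignment
from .classify import classify_allele_sets
from .errors import ConfigurationError, InputError


@dataclass
class CallerConfig:
    """Thresholds of the candidate-SNP caller."""

    min_reads_per_allele: int = 2
    confidence_window: int = 10  # non-pad consensus columns per side
    min_confidence: float = 90.0  # percent; inclusive boundary
    require_both_genotypes_covered: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.min_reads_per_allele < 1:
            raise ConfigurationError("min_reads_per_allele must be >= 1")
        if not 0.0 <= self.min_confidence <= 100.0:
            raise ConfigurationError("min_confidence outside [0, 100]")
        if self.confidence_window < 1:
            raise ConfigurationError("confidence_window must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "CallerConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown caller keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Column:
    """Exact per-genotype observation counts at one padded column."""

    padded_pos: int
    base_counts: dict  # genotype -> {A/C/G/T: count}, zero counts omitted
    gap_counts: dict  # genotype -> count
    consensus_base: str


STATUS_CALLED = "called"
STATUS_LOW_CONFIDENCE = "filtered_low_confidence"
STATUS_SUPPORT = "filtered_support"
STATUS_INDEL = "filtered_indel_column"
STATUS_UNCOVERED = "filtered_uncovered"


@dataclass
class CandidateSNP:
    """A variant column with per-genotype allele support."""

    contig_id: str
    padded_pos: int
    unpadded_pos: int  # 0-based on the unpadded consensus; -1 at pad columns
    support: dict  # genotype -> {allele: raw read count}
    alleles: dict  # genotype -> frozenset of support-filtered alleles
    confidence: float | None
    status: str
    remap_ok: bool | None = None
    category: int | None = None

    @property
    def position(self) -> int:
        """1-based position on the unpadded consensus (report convention)."""
        return self.unpadded_pos + 1


def summarize_column(contig: ContigAlignment, padded_pos: int) -> Column:
    """Per-genotype A/C/G/T and gap counts among reads covering a column.

    Bases are counted case-insensitively; a read whose padded span does not
    include the column contributes nothing.
    """
    if not 0 <= padded_pos < len(contig.consensus):
        raise InputError(
            f"column {padded_pos} outside contig {contig.contig_id} "
            f"(length {len(contig.consensus)})")
    counts = contig.count_matrix()
    base_counts = {}
    gap_counts = {}
    for genotype, mat in counts.items():
        col = mat[:, padded_pos]
        base_counts[genotype] = {
            BASES[i]: int(col[i]) for i in range(4) if col[i] > 0
        }
        gap_counts[genotype] = int(col[4])
    return Column(padded_pos, base_counts, gap_counts,
                  contig.consensus[padded_pos])


def confidence_score(contig: ContigAlignment, padded_pos: int,
                     window: int = 10) -> float:
    """Percent of flanking read bases matching the consensus.

    Over up to ``window`` non-pad consensus columns on each side of the
    column (the column itself excluded, truncated silently at contig ends),
    counts read-base observations pooled over all reads; gap observations
    enter neither numerator nor denominator. Returns 100.0 when no flanking
    observation exists.
    """
    if not 0 <= padded_pos < len(contig.consensus):
        raise InputError(f"column {padded_pos} outside contig")
    pooled = contig.pooled_counts()
    cons = np.frombuffer(contig.consensus.encode("ascii"), dtype=np.uint8)
    cons_codes = _CODE_LUT[cons]
    valid = cons_codes < 4  # A/C/G/T consensus only (not pad, not N)

    cols = []
    i, taken = padded_pos - 1, 0
    while i >= 0 and taken < window:
        if valid[i]:
            cols.append(i)
            taken += 1
        i -= 1
    i, taken = padded_pos + 1, 0
    while i < len(cons) and taken < window:
        if valid[i]:
            cols.append(i)
            taken += 1
        i += 1
    if not cols:
        return 100.0
    cols = np.array(cols)
    matches = pooled[cons_codes[cols], cols].sum()
    total = pooled[:4, cols].sum()
    if total == 0:
        return 100.0
    return 100.0 * float(matches) / float(total)


def detect_variant_columns(contig: ContigAlignment,
                           config: CallerConfig | None = None) -> list:
    """Scan all consensus columns of a contig for candidate SNPs.

    A column is a candidate iff, after dropping alleles supported by fewer
    than ``min_reads_per_allele`` reads within their genotype and dropping
    gap observations, at least two distinct alleles remain pooled across
    genotypes. Candidates at pad-consensus columns are voided
    (``filtered_indel_column``); with ``require_both_genotypes_covered``,
    columns where either genotype shows fewer than ``min_reads_per_allele``
    base observations are voided (``filtered_uncovered``); remaining
    candidates below ``min_confidence`` become ``filtered_low_confidence``,
    the rest are ``called``.
    """
    config = config or CallerConfig()
    counts = contig.count_matrix()
    genotypes = contig.genotypes
    if not genotypes:
        return []
    n = len(contig.consensus)
    retained_mask = {
        g: counts[g][:4] >= config.min_reads_per_allele for g in genotypes
    }
    pooled_retained = np.zeros((4, n), dtype=bool)
    for g in genotypes:
        pooled_retained |= retained_mask[g]
    candidate_cols = np.nonzero(pooled_retained.sum(axis=0) >= 2)[0]

    unpadded = contig.padded_to_unpadded()
    out = []
    for col in candidate_cols:
        col = int(col)
        support = {}
        alleles = {}
        for g in genotypes:
            col_counts = counts[g][:, col]
            support[g] = {BASES[i]: int(col_counts[i])
                          for i in range(4) if col_counts[i] > 0}
            alleles[g] = frozenset(
                BASES[i] for i in range(4) if retained_mask[g][i, col])
        snp = CandidateSNP(
            contig_id=contig.contig_id,
            padded_pos=col,
            unpadded_pos=int(unpadded[col]),
            support=support,
            alleles=alleles,
            confidence=None,
            status=STATUS_CALLED,
        )
        if contig.consensus[col] == PAD:
            snp.status = STATUS_INDEL
        elif config.require_both_genotypes_covered and (
                len(genotypes) < 2 or any(
                    sum(support[g].values()) < config.min_reads_per_allele
                    for g in genotypes)):
            snp.status = STATUS_UNCOVERED
        else:
            snp.confidence = confidence_score(
                contig, col, config.confidence_window)
            if snp.confidence < config.min_confidence:
                snp.status = STATUS_LOW_CONFIDENCE
        out.append(snp)
    return out


def _ace_roundtrip(contig: ContigAlignment) -> ContigAlignment:
    buf = io.StringIO()
    ace_mod.dump_ace([contig], buf)
    buf.seek(0)
    return ace_mod.load_ace(buf)[0]


def _check_remap(remapped: ContigAlignment, snp: CandidateSNP) -> bool:
    try:
        column = summarize_column(remapped, snp.padded_pos)
    except InputError:
        snp.remap_ok = False
        return False
    snp.remap_ok = (column.base_counts == snp.support)
    return snp.remap_ok


def remap_qc(contig: ContigAlignment, snp: CandidateSNP) -> bool:
    """Re-extract the SNP column after an ACE round trip.

    The contig is serialized to ACE and parsed back; the column is
    re-summarized and must reproduce the recorded per-genotype allele counts
    exactly. Sets and returns ``snp.remap_ok``.
    """
    if snp.contig_id != contig.contig_id:
        raise InputError(
            f"SNP belongs to contig {snp.contig_id!r}, got "
            f"{contig.contig_id!r}")
    return _check_remap(_ace_roundtrip(contig), snp)


def classify_candidates(snps, genotype_order=None) -> list:
    """Assign the four-way category to every called SNP in place.

    The category is computed from the support-filtered allele sets; called
    SNPs where either genotype retains no allele are left unclassified.
    Returns the input list.
    """
    for snp in snps:
        if snp.status != STATUS_CALLED:
            snp.category = None
            continue
        order = genotype_order or sorted(snp.alleles)
        sets = [snp.alleles.get(g, frozenset()) for g in order]
        if len(sets) != 2 or any(not s for s in sets):
            snp.category = None
            continue
        snp.category = classify_allele_sets(sets[0], sets[1])
    return snps


def call_contigs(contigs, config: CallerConfig | None = None,
                 run_remap_qc: bool = True) -> list:
    """Run the caller over many contigs; returns all candidate records."""
    config = config or CallerConfig()
    out = []
    for contig in contigs:
        snps = detect_variant_columns(contig, config)
        called = [s for s in snps if s.status == STATUS_CALLED]
        if run_remap_qc and called:
            remapped = _ace_roundtrip(contig)
            for snp in called:
                _check_remap(remapped, snp)
        out.extend(snps)
    return out
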