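"""Small-amplicon melting-assay design around candidate SNPs.

Validation of EST SNPs by high-resolution melting (HRM) uses short PCR
amplicons spanning a single variant: both primers must sit in conserved
flanks, hit a narrow annealing-temperature band, and the amplicon should
contain no additional variant (extra SNPs distort the melt profile). The
default criteria — primer Tm 59-61 degC, primer length 18-24 bp, amplicon
40-200 bp, no other variant in the amplicon — reflect standard
small-amplicon HRM design.

Melting temperatures come from the nearest-neighbor thermodynamic model
(Allawi & SantaLucia 1997 unified parameters with the SantaLucia 1998 salt
correction) at fixed ionic conditions: 50 mM monovalent cation, 50 nM
primer, excess over template. The expected melt profile is summarized as a
categorical class: a fixed difference between two homozygous genotypes gives
two distinct homoduplex peaks, while a heterozygous genotype gives the
broadened het-versus-hom peak contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from Bio.SeqUtils import MeltingTemp

from .alignment import ContigAlignment
from .errors import ConfigurationError, InputError
from .simulate import reverse_complement

#: fixed ionic conditions for the nearest-neighbor Tm model
TM_CONDITIONS = {"Na": 50.0, "dnac1": 50.0, "dnac2": 0.0}

MELT_CLASS_CATEGORY1 = "category1_like"  # two distinct homoduplex peaks
MELT_CLASS_CATEGORY2 = "category2_like"  # het vs hom peak shapes

REASON_FLANK = "insufficient_flank"
REASON_TM = "tm_infeasible"
REASON_VARIANTS = "too_many_variants"


@dataclass
class AssayCriteria:
    tm_range: tuple = (59.0, 61.0)
    primer_length_range: tuple = (18, 24)
    amplicon_length_range: tuple = (40, 200)
    max_other_variants_in_amplicon: int = 0

    def __post_init__(self):
        for key in ("tm_range", "primer_length_range",
                    "amplicon_length_range"):
            v = getattr(self, key)
            if isinstance(v, list):
                setattr(self, key, tuple(v))
        self.validate()

    def validate(self):
        for name in ("tm_range", "primer_length_range",
                     "amplicon_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} exceeds max {hi}")
        lo, hi = self.primer_length_range
        if lo < 10 or hi > 40:
            raise ConfigurationError(
                "primer lengths must lie within 10-40 bp")
        if self.max_other_variants_in_amplicon < 0:
            raise ConfigurationError(
                "max_other_variants_in_amplicon must be >= 0")

    def amplicon_ok(self, length: int) -> bool:
        lo, hi = self.amplicon_length_range
        return lo <= length <= hi

    @classmethod
    def from_dict(cls, d: dict) -> "AssayCriteria":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown assay keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_tm(primer: str) -> float:
    """Nearest-neighbor melting temperature (degC) at fixed conditions.

    Deterministic for a given sequence; 10-40 bp ACGT only. The duplex is
    symmetric, so a primer and its reverse complement share one Tm.
    """
    primer = primer.upper()
    if not 10 <= len(primer) <= 40:
        raise InputError(f"primer length {len(primer)} outside 10-40 bp")
    if not set(primer) <= set("ACGT"):
        raise InputError("primer must contain only A/C/G/T")
    return float(MeltingTemp.Tm_NN(primer, **TM_CONDITIONS))


@dataclass
class AssayTarget:
    """A feasible small-amplicon design for one candidate SNP."""

    contig_id: str
    snp_position: int  # 1-based on the unpadded consensus
    amplicon_start: int  # 0-based half-open on the unpadded consensus
    amplicon_end: int
    forward_primer: str
    reverse_primer: str
    forward_tm: float
    reverse_tm: float
    melting_class: str
    snp: object = None  # the CandidateSNP record, when available

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass
class AssayRejection:
    contig_id: str
    snp_position: int
    reason: str
    snp: object = None


def _melting_class(snp) -> str:
    category = getattr(snp, "category", None)
    return MELT_CLASS_CATEGORY1 if category == 1 else MELT_CLASS_CATEGORY2


def design_for_position(seq: str, pos: int, criteria: AssayCriteria,
                        other_variants=(), tm_cache: dict | None = None):
    """Search primer windows flanking ``pos`` on ``seq``.

    Returns ``(design, reason)`` where exactly one is not None. ``design``
    is ``(amp_start, amp_end, fwd_primer, fwd_tm, rev_primer, rev_tm)`` for
    the first feasible placement in deterministic order: smallest amplicon,
    then leftmost start, then shortest primers. Both primers must satisfy
    the length and Tm criteria and sit strictly off the SNP base.
    """
    n = len(seq)
    pl_min, pl_max = criteria.primer_length_range
    a_min, a_max = criteria.amplicon_length_range
    tm_lo, tm_hi = criteria.tm_range
    others = sorted(set(int(v) for v in other_variants) - {pos})
    cache = tm_cache if tm_cache is not None else {}

    def tm_of(start, length, reverse):
        key = (start, length, reverse)
        if key not in cache:
            window = seq[start:start + length]
            if set(window) <= set("ACGT"):
                primer = reverse_complement(window) if reverse else window
                cache[key] = estimate_tm(primer)
            else:
                cache[key] = None
        return cache[key]

    any_geometry = False
    tm_feasible_blocked_by_variants = False
    for amp_len in range(a_min, min(a_max, n) + 1):
        f_lo = max(0, pos + 1 + pl_min - amp_len)
        f_hi = min(n - amp_len, pos - pl_min)
        for f in range(f_lo, f_hi + 1):
            any_geometry = True
            fwd = None
            for lf in range(pl_min, min(pl_max, pos - f) + 1):
                tm = tm_of(f, lf, reverse=False)
                if tm is not None and tm_lo <= tm <= tm_hi:
                    fwd = (lf, tm)
                    break
            if fwd is None:
                continue
            amp_end = f + amp_len
            rev = None
            for lr in range(pl_min, min(pl_max, amp_end - pos - 1) + 1):
                tm = tm_of(amp_end - lr, lr, reverse=True)
                if tm is not None and tm_lo <= tm <= tm_hi:
                    rev = (lr, tm)
                    break
            if rev is None:
                continue
            n_other = sum(1 for v in others if f <= v < amp_end)
            if n_other > criteria.max_other_variants_in_amplicon:
                tm_feasible_blocked_by_variants = True
                continue
            lf, fwd_tm = fwd
            lr, rev_tm = rev
            return (f, amp_end, seq[f:f + lf], fwd_tm,
                    reverse_complement(seq[amp_end - lr:amp_end]),
                    rev_tm), None
    if not any_geometry:
        return None, REASON_FLANK
    if tm_feasible_blocked_by_variants:
        return None, REASON_VARIANTS
    return None, REASON_TM


def select_assayable(snps, contigs: dict, criteria: AssayCriteria | None = None,
                     variant_positions: dict | None = None):
    """Design at most one small-amplicon target per candidate SNP.

    Parameters
    ----------
    snps
        Candidate SNP records (only ``status == 'called'`` ones are
        designed; others are ignored).
    contigs
        ``{contig_id: ContigAlignment or unpadded consensus string}``.
    variant_positions
        ``{contig_id: iterable of 0-based positions}`` of *all* known
        variant columns, used for the other-variants-in-amplicon rule.
        Defaults to the positions of the supplied SNPs themselves.

    Returns ``(targets, rejections)``.
    """
    criteria = criteria or AssayCriteria()
    if variant_positions is None:
        variant_positions = {}
        for snp in snps:
            if snp.status == "called":
                variant_positions.setdefault(snp.contig_id, []).append(
                    snp.unpadded_pos)

    seqs = {}
    for contig_id, contig in contigs.items():
        if isinstance(contig, ContigAlignment):
            seqs[contig_id] = contig.unpadded_consensus()
        else:
            seqs[contig_id] = str(contig)

    targets, rejections = [], []
    caches: dict[str, dict] = {}
    for snp in snps:
        if snp.status != "called":
            continue
        if snp.contig_id not in seqs:
            raise InputError(
                f"SNP at {snp.contig_id}:{snp.position}: unknown contig")
        seq = seqs[snp.contig_id]
        if not 0 <= snp.unpadded_pos < len(seq):
            raise InputError(
                f"SNP position {snp.position} outside contig "
                f"{snp.contig_id}")
        design, reason = design_for_position(
            seq, snp.unpadded_pos, criteria,
            other_variants=variant_positions.get(snp.contig_id, ()),
            tm_cache=caches.setdefault(snp.contig_id, {}),
        )
        if design is None:
            rejections.append(AssayRejection(
                snp.contig_id, snp.position, reason, snp))
            continue
        start, end, fwd, fwd_tm, rev, rev_tm = design
        targets.append(AssayTarget(
            contig_id=snp.contig_id,
            snp_position=snp.position,
            amplicon_start=start,
            amplicon_end=end,
            forward_primer=fwd,
            reverse_primer=rev,
            forward_tm=fwd_tm,
            reverse_tm=rev_tm,
            melting_class=_melting_class(snp),
            snp=snp,
        ))
    return targets, rejections


def write_assay_table(targets, rejections, path):
    """Assay targets and rejection reasons as one TSV (1-based coords)."""
    import csv

    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "snp_position", "amplicon_start",
                    "amplicon_end", "amplicon_length", "forward_primer",
                    "reverse_primer", "forward_tm", "reverse_tm",
                    "melting_class", "status"])
        for t in targets:
            w.writerow([t.contig_id, t.snp_position, t.amplicon_start + 1,
                        t.amplicon_end, t.amplicon_length, t.forward_primer,
                        t.reverse_primer, f"{t.forward_tm:.2f}",
                        f"{t.reverse_tm:.2f}", t.melting_class, "designed"])
        for r in rejections:
            w.writerow([r.contig_id, r.snp_position, ".", ".", ".", ".",
                        ".", ".", ".", ".", r.reason])
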