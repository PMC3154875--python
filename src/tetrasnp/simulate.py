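"""Synthetic tetraploid transcriptome reads with a planted-variant truth table.

The generator emulates the data underlying two-genotype EST SNP discovery in
an autotetraploid crop: a set of reference transcripts (loci), two genotypes
each carrying exactly four haplotypes per locus, heterozygous sites within a
genotype (alternate-allele dosage 1-3 of 4), fixed differences between the
genotypes, and single-pass pyrosequencing-style reads with substitution
errors and homopolymer-associated indel errors. Every planted variant is
recorded in a machine-readable truth table together with the category the
allele-profile classifier must assign to it, so the discovery pipeline can be
audited base by base.

Site model
----------
Positions are independent. At each reference position:

* with probability ``between_div_rate`` the second genotype's background
  allele is replaced by one of the three other bases (a fixed difference);
* independently, with probability ``within_het_rate`` per genotype, that
  genotype becomes heterozygous: a second allele (distinct from its
  background) is planted on ``d`` of its four haplotypes, ``d`` drawn from
  ``dosage_weights`` over {1, 2, 3} (simplex/duplex/triplex).

Variants are substitutions only; indels enter solely as sequencing errors,
matching a discovery target restricted to base substitutions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify import classify_allele_sets
from .errors import ConfigurationError, InputError

BASES = "ACGT"
_OTHER = {b: [x for x in BASES if x != b] for b in BASES}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadLengthModel:
    """Truncated-normal read length model (bp)."""

    min: int = 100
    max: int = 636
    mean: float = 379.0
    sd: float = 60.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults reflect a two-genotype pyrosequencing experiment: read lengths
    of 100-636 bp averaging ~379 bp, mean 10 reads per locus per genotype,
    and low per-base substitution error with homopolymer-run indel errors.
    """

    n_loci: int = 200
    locus_length_range: tuple = (300, 2000)
    within_het_rate: float = 0.002
    between_div_rate: float = 0.001
    dosage_weights: tuple = (0.5, 0.3, 0.2)
    depth_per_genotype: float = 10.0
    read_length_model: ReadLengthModel = field(default_factory=ReadLengthModel)
    sub_error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.02
    seed: int = 1
    genotype_ids: tuple = ("Chilean", "Wisfal")

    def __post_init__(self):
        if isinstance(self.read_length_model, dict):
            self.read_length_model = ReadLengthModel(**self.read_length_model)
        self.validate()

    def validate(self):
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        lo, hi = self.locus_length_range
        if lo > hi:
            raise ConfigurationError(
                f"locus_length_range min {lo} exceeds max {hi}"
            )
        if lo < 1:
            raise ConfigurationError("locus lengths must be positive")
        for name in ("within_het_rate", "between_div_rate",
                     "sub_error_rate", "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if len(self.dosage_weights) != 3:
            raise ConfigurationError("dosage_weights must have 3 entries")
        if any(w < 0 for w in self.dosage_weights):
            raise ConfigurationError("dosage_weights must be non-negative")
        if abs(sum(self.dosage_weights) - 1.0) > 1e-9:
            raise ConfigurationError("dosage_weights must sum to 1")
        if self.depth_per_genotype <= 0:
            raise ConfigurationError("depth_per_genotype must be > 0")
        m = self.read_length_model
        if m.min < 100:
            raise ConfigurationError("read length min must be >= 100 bp")
        if m.min > m.max:
            raise ConfigurationError("read length min exceeds max")
        if len(self.genotype_ids) != 2:
            raise ConfigurationError("exactly two genotype_ids required")

    @property
    def genotype_prefixes(self) -> tuple:
        return tuple(g[:3].upper() for g in self.genotype_ids)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("locus_length_range", "dosage_weights", "genotype_ids"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedVariant:
    """One planted variant column with its per-genotype allele dosages."""

    locus_id: str
    position: int  # 0-based on the reference transcript
    ref: str
    #: genotype_id -> {allele: dosage}; dosages sum to 4 per genotype
    alleles: dict
    #: genotype_id -> string of 4 allele chars, one per haplotype
    hap_alleles: dict
    expected_category: int

    def allele_sets(self):
        return tuple(frozenset(self.alleles[g]) for g in self.alleles)


@dataclass
class TetraploidGenotype:
    """Four haplotype sequences per locus for one genotype."""

    genotype_id: str
    haplotypes: dict  # locus_id -> list of 4 sequences


@dataclass
class ReadRecord:
    """A simulated single-pass read and its true origin.

    ``start``/``end`` are 0-based half-open coordinates on the source
    haplotype before sequencing errors; ``sequence`` is the read as
    sequenced (reverse-complemented when ``strand`` is '-').
    """

    read_id: str
    genotype_id: str
    locus_id: str
    haplotype_index: int  # 1..4
    start: int
    end: int
    strand: str
    sequence: str
    n_sub: int = 0
    n_indel: int = 0


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    transcripts: dict  # locus_id -> sequence
    genotypes: tuple  # (TetraploidGenotype, TetraploidGenotype)
    truth: list  # list[PlantedVariant]
    reads: list  # list[ReadRecord]


def generate_reference_transcripts(config: SimulationConfig,
                                   rng: np.random.Generator | None = None) -> dict:
    """Random uppercase-ACGT reference transcripts, one per locus.

    Lengths are uniform over ``locus_length_range`` (inclusive).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.locus_length_range
    width = len(str(config.n_loci))
    out = {}
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        out[f"L{i + 1:0{max(width, 4)}d}"] = seq
    return out


def _draw_dosage(rng, weights) -> int:
    return int(rng.choice([1, 2, 3], p=list(weights)))


def plant_variants(transcripts: dict, config: SimulationConfig,
                   rng: np.random.Generator | None = None):
    """Plant within- and between-genotype variation on two tetraploid genotypes.

    Returns ``(genotype_a, genotype_b, truth)`` where ``truth`` is the list of
    :class:`PlantedVariant` records. Haplotypes differ from the reference only
    at planted positions, at most one variant per position, and
    ``expected_category`` is computed with the same classifier used by the
    discovery pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ga_id, gb_id = config.genotype_ids
    haps_a, haps_b = {}, {}
    truth: list[PlantedVariant] = []
    w = config.within_het_rate
    b = config.between_div_rate
    for locus_id, ref_seq in transcripts.items():
        L = len(ref_seq)
        fire_b = rng.random(L) < b
        fire_ha = rng.random(L) < w
        fire_hb = rng.random(L) < w
        hap_a = [bytearray(ref_seq, "ascii") for _ in range(4)]
        hap_b = [bytearray(ref_seq, "ascii") for _ in range(4)]
        sites = np.nonzero(fire_b | fire_ha | fire_hb)[0]
        for pos in sites:
            pos = int(pos)
            ref = ref_seq[pos]
            bg_a = ref
            bg_b = str(rng.choice(_OTHER[ref])) if fire_b[pos] else ref
            per_geno = {}
            hap_strings = {}
            for gid, bg, fired, haps in (
                (ga_id, bg_a, bool(fire_ha[pos]), hap_a),
                (gb_id, bg_b, bool(fire_hb[pos]), hap_b),
            ):
                hap_bases = [bg] * 4
                if fired:
                    alt = str(rng.choice(_OTHER[bg]))
                    dosage = _draw_dosage(rng, config.dosage_weights)
                    carriers = sorted(
                        int(i) for i in rng.choice(4, size=dosage, replace=False)
                    )
                    for i in carriers:
                        hap_bases[i] = alt
                    per_geno[gid] = {bg: 4 - dosage, alt: dosage}
                else:
                    per_geno[gid] = {bg: 4}
                for i, base in enumerate(hap_bases):
                    haps[i][pos] = ord(base)
                hap_strings[gid] = "".join(hap_bases)
            category = classify_allele_sets(per_geno[ga_id], per_geno[gb_id])
            if category is None:
                # both genotypes ended up identical and homozygous for the
                # reference; nothing was actually planted
                continue
            truth.append(PlantedVariant(
                locus_id=locus_id, position=pos, ref=ref,
                alleles=per_geno, hap_alleles=hap_strings,
                expected_category=category,
            ))
        haps_a[locus_id] = [h.decode("ascii") for h in hap_a]
        haps_b[locus_id] = [h.decode("ascii") for h in hap_b]
    return (
        TetraploidGenotype(ga_id, haps_a),
        TetraploidGenotype(gb_id, haps_b),
        truth,
    )


_HOMOPOLYMER = re.compile(r"(.)\1+")


def apply_homopolymer_indels(seq: str, rate: float, rng) -> tuple[str, int]:
    """Insert or delete one repeat unit in homopolymer runs (length >= 2).

    Each run independently suffers an indel with probability ``rate``;
    insertion or deletion is chosen with equal probability. Returns the
    edited sequence and the number of indels applied.
    """
    if rate <= 0.0:
        return seq, 0
    edits = []  # (run_start, run_end, +1 | -1)
    for m in _HOMOPOLYMER.finditer(seq):
        if rng.random() < rate:
            edits.append((m.start(), m.end(), 1 if rng.random() < 0.5 else -1))
    if not edits:
        return seq, 0
    out = seq
    for start, end, delta in reversed(edits):
        if delta > 0:
            out = out[:end] + seq[start] + out[end:]
        else:
            out = out[:start] + out[start + 1:]
    return out, len(edits)


def apply_substitutions(seq: str, rate: float, rng) -> tuple[str, int]:
    """I.i.d. per-base substitutions at ``rate``; never the original base."""
    if rate <= 0.0 or not seq:
        return seq, 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=int(n), replace=False)
    out = bytearray(seq, "ascii")
    for pos in sorted(int(p) for p in positions):
        out[pos] = ord(str(rng.choice(_OTHER.get(chr(out[pos]), list(BASES)))))
    return out.decode("ascii"), int(n)


def simulate_reads(genotypes, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> list:
    """Draw single-pass reads uniformly over each locus's four haplotypes.

    Per locus and genotype the read count is Poisson with mean
    ``depth_per_genotype``; lengths follow the truncated-normal read length
    model, further truncated to the locus length; strand is uniform.
    Substitution and homopolymer-indel errors are applied per read.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.read_length_model
    reads: list[ReadRecord] = []
    for genotype, prefix in zip(genotypes, config.genotype_prefixes):
        serial = 0
        for locus_id, haps in genotype.haplotypes.items():
            L = len(haps[0])
            n = int(rng.poisson(config.depth_per_genotype))
            for _ in range(n):
                hap = int(rng.integers(0, 4))
                length = int(round(rng.normal(model.mean, model.sd)))
                length = max(model.min, min(model.max, length))
                length = min(length, L)
                start = int(rng.integers(0, L - length + 1))
                frag = haps[hap][start:start + length]
                frag, n_indel = apply_homopolymer_indels(
                    frag, config.homopolymer_indel_rate, rng)
                frag, n_sub = apply_substitutions(
                    frag, config.sub_error_rate, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                seq = frag if strand == "+" else reverse_complement(frag)
                serial += 1
                reads.append(ReadRecord(
                    read_id=f"{prefix}|{locus_id}|{serial:06d}",
                    genotype_id=genotype.genotype_id,
                    locus_id=locus_id,
                    haplotype_index=hap + 1,
                    start=start, end=start + length,
                    strand=strand, sequence=seq,
                    n_sub=n_sub, n_indel=n_indel,
                ))
    return reads


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the three generator stages with one seeded generator.

    The stage order (transcripts, variants, reads) is fixed, so an identical
    config — including the seed — reproduces every output byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    transcripts = generate_reference_transcripts(config, rng)
    ga, gb, truth = plant_variants(transcripts, config, rng)
    reads = simulate_reads((ga, gb), config, rng)
    return SimulatedDataset(config, transcripts, (ga, gb), truth, reads)


def genotype_of_read(read_id: str, config: SimulationConfig | None = None) -> str:
    """Recover the genotype from the read-id prefix (e.g. ``CHI|...``)."""
    prefix = read_id.split("|", 1)[0]
    if config is not None:
        mapping = dict(zip(config.genotype_prefixes, config.genotype_ids))
        if prefix not in mapping:
            raise InputError(f"read id {read_id!r}: unknown genotype prefix")
        return mapping[prefix]
    return prefix


# ---------------------------------------------------------------------------
# truth auditing


def audit_allele_support(truth, reads, min_reads: int = 2):
    """Project read placements onto planted variants.

    For every planted variant, count the reads of each genotype whose span
    covers the variant position, keyed by the allele their source haplotype
    carries (sequencing errors are ignored: support is counted by origin).

    Returns a list of dicts with keys ``variant``, ``support``
    (genotype -> allele -> read count), ``fully_supported`` (every planted
    allele has >= ``min_reads`` support), and ``observed_sets``
    (genotype -> frozenset of alleles with >= ``min_reads`` support).
    """
    by_locus: dict[str, list] = {}
    for read in reads:
        by_locus.setdefault(read.locus_id, []).append(read)
    out = []
    for var in truth:
        support = {g: {a: 0 for a in var.alleles[g]} for g in var.alleles}
        for read in by_locus.get(var.locus_id, ()):
            if read.start <= var.position < read.end:
                allele = var.hap_alleles[read.genotype_id][read.haplotype_index - 1]
                support[read.genotype_id][allele] = (
                    support[read.genotype_id].get(allele, 0) + 1)
        fully = all(
            support[g][a] >= min_reads
            for g in var.alleles for a in var.alleles[g]
        )
        observed = {
            g: frozenset(a for a, n in support[g].items() if n >= min_reads)
            for g in support
        }
        out.append({
            "variant": var,
            "support": support,
            "fully_supported": fully,
            "observed_sets": observed,
        })
    return out
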