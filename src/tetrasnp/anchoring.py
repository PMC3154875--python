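"""Anchoring transcript contigs to a related reference genome.

Transcript-to-genome alignments arrive as 21-column PSL records (BLAT's
native tab-separated format, 0-based half-open coordinates). A record
anchors its query to a chromosome when it passes identity and coverage
thresholds (defaults 95% and 90%, boundaries inclusive), and passing
anchors can be reduced to one best hit per query and tallied per chromosome
together with the SNP catalog.

Identity here is the pure match ratio ``(matches + repMatches) /
(matches + repMatches + misMatches)`` — N bases and query gaps excluded —
and coverage defaults to the aligned query span ``(qEnd - qStart) / qSize``.
Both definitions are configurable because "percent identity" and "coverage"
are reported differently across aligner front ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import pandas as pd

from .errors import ConfigurationError, PslParseError

PSL_N_COLUMNS = 21


@dataclass
class PslRecord:
    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: list
    qStarts: list
    tStarts: list


@dataclass
class AnchorConfig:
    min_identity: float = 95.0
    min_coverage: float = 90.0
    best_hit_policy: str = "keep-all"  # or "keep-best"
    coverage_mode: str = "span"  # or "blocks"

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(f"{name}={v} outside [0, 100]")
        if self.best_hit_policy not in ("keep-all", "keep-best"):
            raise ConfigurationError(
                f"unknown best_hit_policy {self.best_hit_policy!r}")
        if self.coverage_mode not in ("span", "blocks"):
            raise ConfigurationError(
                f"unknown coverage_mode {self.coverage_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown anchor keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Anchor:
    """Anchoring verdict for one PSL record."""

    qName: str
    tName: str
    tStart: int
    tEnd: int
    identity: float
    coverage: float
    passed: bool
    matches: int = 0
    reason: str | None = None


def _int_list(text: str, lineno: int, column: str) -> list:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x != ""]
    except ValueError:
        raise PslParseError(f"non-integer value in column {column!r}", lineno)


def read_psl(path) -> list:
    """Parse a PSL file (21 columns; the optional 5-line header is skipped)."""
    records = []
    with open(path) as handle:
        lines = handle.read().splitlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        # header ends with a row of dashes
        for i, line in enumerate(lines[:10]):
            if set(line.strip()) == {"-"}:
                start = i + 1
                break
        else:
            raise PslParseError("psLayout header without dashed terminator", 1)
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_N_COLUMNS:
            raise PslParseError(
                f"expected {PSL_N_COLUMNS} tab-separated columns, got "
                f"{len(fields)}", lineno)
        try:
            ints = [int(fields[i]) for i in range(8)]
            qSize, qStart, qEnd = (int(fields[i]) for i in (10, 11, 12))
            tSize, tStart, tEnd = (int(fields[i]) for i in (14, 15, 16))
            blockCount = int(fields[17])
        except ValueError:
            raise PslParseError("non-integer numeric field", lineno)
        rec = PslRecord(
            matches=ints[0], misMatches=ints[1], repMatches=ints[2],
            nCount=ints[3], qNumInsert=ints[4], qBaseInsert=ints[5],
            tNumInsert=ints[6], tBaseInsert=ints[7], strand=fields[8],
            qName=fields[9], qSize=qSize, qStart=qStart, qEnd=qEnd,
            tName=fields[13], tSize=tSize, tStart=tStart, tEnd=tEnd,
            blockCount=blockCount,
            blockSizes=_int_list(fields[18], lineno, "blockSizes"),
            qStarts=_int_list(fields[19], lineno, "qStarts"),
            tStarts=_int_list(fields[20], lineno, "tStarts"),
        )
        if not (0 <= rec.qStart < rec.qEnd <= rec.qSize):
            raise PslParseError(
                f"inconsistent query coordinates for {rec.qName!r}", lineno)
        records.append(rec)
    return records


def compute_anchor(rec: PslRecord, config: AnchorConfig | None = None) -> Anchor:
    """Identity/coverage verdict for one alignment record.

    ``identity = 100 * (matches + repMatches) / (matches + repMatches +
    misMatches)``; coverage is the aligned query span (or summed block
    lengths under ``coverage_mode='blocks'``) over the query size. A record
    passes iff both values meet their thresholds (boundaries inclusive).
    """
    config = config or AnchorConfig()
    denom = rec.matches + rec.repMatches + rec.misMatches
    if denom == 0 or rec.qSize == 0:
        return Anchor(rec.qName, rec.tName, rec.tStart, rec.tEnd,
                      identity=0.0, coverage=0.0, passed=False,
                      matches=rec.matches, reason="zero_denominator")
    identity = 100.0 * (rec.matches + rec.repMatches) / denom
    if config.coverage_mode == "span":
        covered = rec.qEnd - rec.qStart
    else:
        covered = sum(rec.blockSizes)
    coverage = 100.0 * covered / rec.qSize
    passed = identity >= config.min_identity and coverage >= config.min_coverage
    reason = None
    if not passed:
        parts = []
        if identity < config.min_identity:
            parts.append("low_identity")
        if coverage < config.min_coverage:
            parts.append("low_coverage")
        reason = "+".join(parts)
    return Anchor(rec.qName, rec.tName, rec.tStart, rec.tEnd,
                  identity=identity, coverage=coverage, passed=passed,
                  matches=rec.matches, reason=reason)


def compute_anchors(records, config: AnchorConfig | None = None) -> list:
    config = config or AnchorConfig()
    return [compute_anchor(rec, config) for rec in records]


def resolve_best_hits(anchors, policy: str = "keep-best") -> list:
    """Reduce passing anchors per query.

    ``keep-best`` keeps, for each query, the passing anchor with the most
    matching bases; ties break by higher identity, then lexicographically
    smallest target name, then smallest target start. ``keep-all`` keeps
    every passing anchor.
    """
    passing = [a for a in anchors if a.passed]
    if policy == "keep-all":
        return passing
    if policy != "keep-best":
        raise ConfigurationError(f"unknown best-hit policy {policy!r}")
    best: dict[str, Anchor] = {}
    for anchor in passing:
        key = (-anchor.matches, -anchor.identity, anchor.tName, anchor.tStart)
        incumbent = best.get(anchor.qName)
        if incumbent is None or key < (-incumbent.matches,
                                       -incumbent.identity,
                                       incumbent.tName, incumbent.tStart):
            best[anchor.qName] = anchor
    return [best[q] for q in sorted(best)]


_CHROM_RE = re.compile(r"^chr(\d+)$", re.IGNORECASE)

UNPLACED = "Chr0"


def normalize_chromosome(tName: str) -> str:
    """Map a target name to ``ChrN``; unrecognized names pool into Chr0."""
    m = _CHROM_RE.match(tName)
    if m:
        return f"Chr{int(m.group(1))}"
    return UNPLACED


def tally_by_chromosome(anchors, snps=None) -> pd.DataFrame:
    """Per-chromosome counts of anchored contigs, SNP contigs, and SNPs.

    ``snps`` is an optional iterable with ``contig_id`` and ``category``
    attributes; only classified records (``category`` not None) are
    counted. A contig with several anchors on different chromosomes counts
    once per chromosome; totals over rows therefore equal the number of
    distinct (contig, chromosome) anchor pairs.
    """
    snp_counts: dict[str, int] = {}
    if snps is not None:
        for snp in snps:
            if getattr(snp, "category", None) is None:
                continue
            snp_counts[snp.contig_id] = snp_counts.get(snp.contig_id, 0) + 1

    placements = {}  # chrom -> set of qNames
    for anchor in anchors:
        chrom = normalize_chromosome(anchor.tName)
        placements.setdefault(chrom, set()).add(anchor.qName)

    def sort_key(chrom):
        return (chrom == UNPLACED, int(chrom[3:]))

    rows = []
    for chrom in sorted(placements, key=sort_key):
        contigs = placements[chrom]
        with_snps = [c for c in contigs if snp_counts.get(c, 0) > 0]
        rows.append({
            "chromosome": chrom,
            "contigs": len(contigs),
            "contigs_with_snps": len(with_snps),
            "n_snps": sum(snp_counts[c] for c in with_snps),
        })
    return pd.DataFrame(
        rows, columns=["chromosome", "contigs", "contigs_with_snps", "n_snps"])


def write_anchors(anchors, path):
    """Anchors as TSV with 1-based inclusive target coordinates."""
    rows = [{
        "qName": a.qName, "tName": a.tName,
        "tStart": a.tStart + 1, "tEnd": a.tEnd,
        "identity": round(a.identity, 2), "coverage": round(a.coverage, 2),
        "passed": int(a.passed), "reason": a.reason or ".",
    } for a in anchors]
    pd.DataFrame(rows, columns=["qName", "tName", "tStart", "tEnd",
                                "identity", "coverage", "passed",
                                "reason"]).to_csv(path, sep="\t", index=False)
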