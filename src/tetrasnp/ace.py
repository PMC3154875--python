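"""ACE (consed/phrap) assembly file reader and writer.

The dialect written here is the common single-pass one: an ``AS`` header,
then per contig a ``CO`` record with the padded consensus (``*`` pads), a
``BQ`` consensus-quality segment, the ``AF`` read-placement lines, and one
``RD`` block per read followed by ``QA`` and ``DS`` lines. Base qualities
are not modeled, so ``BQ`` carries a constant placeholder value (consumers
such as consed require the segment to be present); the reader skips ``BQ``
and ``BS`` records.

The genotype of each read is recorded as a ``GENOTYPE:`` tag on the ``DS``
line (and recovered from the read-name prefix for files produced by other
tools), so a write -> read round trip preserves a
:class:`~tetrasnp.alignment.ContigAlignment` exactly.
"""

from __future__ import annotations

from .alignment import AlignedRead, ContigAlignment, PAD
from .errors import AceParseError

ACE_PAD = "*"
_WRAP = 50


def _wrap(seq: str) -> str:
    return "\n".join(seq[i:i + _WRAP] for i in range(0, len(seq), _WRAP))


def dump_ace(contigs, handle):
    """Write contigs to an open text handle in ACE format."""
    n_reads = sum(len(c.reads) for c in contigs)
    handle.write(f"AS {len(contigs)} {n_reads}\n\n")
    for contig in contigs:
        consensus = contig.consensus.replace(PAD, ACE_PAD)
        handle.write(
            f"CO {contig.contig_id} {len(consensus)} {len(contig.reads)} 0 U\n")
        handle.write(_wrap(consensus) + "\n\n")
        # placeholder consensus qualities (one per unpadded base)
        n_unpadded_co = len(contig.consensus.replace(PAD, ""))
        handle.write("BQ\n")
        quals = ["30"] * n_unpadded_co
        for i in range(0, len(quals), _WRAP):
            handle.write(" ".join(quals[i:i + _WRAP]) + "\n")
        handle.write("\n")
        for read in contig.reads:
            orient = "C" if read.is_reverse else "U"
            handle.write(f"AF {read.read_id} {orient} {read.offset + 1}\n")
        handle.write("\n")
        for read in contig.reads:
            seq = read.padded_seq.replace(PAD, ACE_PAD)
            n_unpadded = len(read.padded_seq.replace(PAD, ""))
            handle.write(f"RD {read.read_id} {len(seq)} 0 0\n")
            handle.write(_wrap(seq) + "\n\n")
            handle.write(f"QA 1 {n_unpadded} 1 {n_unpadded}\n")
            handle.write(
                f"DS CHROMAT_FILE: {read.read_id} PHD_FILE: "
                f"{read.read_id}.phd GENOTYPE: {read.genotype_id} "
                f"TIME: n/a\n\n")


def write_ace(contigs, path):
    with open(path, "w") as handle:
        dump_ace(contigs, handle)


class _Lines:
    """Line iterator that tracks the current 1-based line number."""

    def __init__(self, handle):
        self.lines = handle.read().splitlines()
        self.idx = 0

    @property
    def lineno(self) -> int:
        return self.idx

    def peek(self):
        return self.lines[self.idx] if self.idx < len(self.lines) else None

    def next(self):
        line = self.peek()
        if line is not None:
            self.idx += 1
        return line


def _read_sequence(lines: _Lines, expected: int, what: str) -> str:
    parts = []
    total = 0
    while total < expected:
        line = lines.peek()
        if line is None or not line.strip() or line.split()[0] in (
                "CO", "AF", "BS", "RD", "QA", "DS", "BQ", "AS"):
            raise AceParseError(
                f"truncated {what}: got {total} of {expected} bases",
                lines.lineno + 1)
        lines.next()
        chunk = line.strip()
        parts.append(chunk)
        total += len(chunk)
    if total != expected:
        raise AceParseError(
            f"{what}: got {total} bases, expected {expected}", lines.lineno)
    return "".join(parts)


def load_ace(handle, genotype_map: dict | None = None) -> list:
    """Parse an ACE stream into :class:`ContigAlignment` objects.

    ``genotype_map`` maps read-name prefixes (text before the first ``|``)
    to genotype labels; it is consulted when a read's ``DS`` line carries no
    ``GENOTYPE:`` tag.
    """
    lines = _Lines(handle)
    contigs = []
    current = None  # (contig_id, consensus, af_by_read, reads)
    reads_seen = {}

    def finish():
        if current is None:
            return
        contig_id, consensus, af, rd_list = current
        aligned = []
        for read_id, padded_seq, genotype in rd_list:
            if read_id not in af:
                raise AceParseError(
                    f"read {read_id!r} has RD but no AF record in contig "
                    f"{contig_id!r}")
            orient, start = af[read_id]
            if genotype is None:
                prefix = read_id.split("|", 1)[0]
                genotype = (genotype_map or {}).get(prefix, prefix)
            aligned.append(AlignedRead(
                read_id=read_id,
                genotype_id=genotype,
                offset=start - 1,
                is_reverse=(orient == "C"),
                padded_seq=padded_seq,
            ))
        contig = ContigAlignment(contig_id, consensus, aligned)
        contig.validate()
        contigs.append(contig)

    while True:
        line = lines.next()
        if line is None:
            break
        if not line.strip():
            continue
        fields = line.split()
        tag = fields[0]
        if tag == "AS":
            continue
        elif tag == "CO":
            finish()
            if len(fields) < 5:
                raise AceParseError("malformed CO record", lines.lineno)
            try:
                n_bases = int(fields[2])
            except ValueError:
                raise AceParseError("CO base count is not an integer",
                                    lines.lineno)
            consensus = _read_sequence(lines, n_bases, "CO consensus")
            current = (fields[1], consensus.upper().replace(ACE_PAD, PAD),
                       {}, [])
        elif tag == "BQ":
            while lines.peek() is not None and lines.peek().strip() and \
                    lines.peek().split()[0] not in (
                        "CO", "AF", "BS", "RD", "QA", "DS"):
                lines.next()
        elif tag == "AF":
            if current is None:
                raise AceParseError("AF record before any CO", lines.lineno)
            if len(fields) != 4 or fields[2] not in ("U", "C"):
                raise AceParseError("malformed AF record", lines.lineno)
            try:
                start = int(fields[3])
            except ValueError:
                raise AceParseError("AF padded start is not an integer",
                                    lines.lineno)
            current[2][fields[1]] = (fields[2], start)
        elif tag == "BS":
            continue
        elif tag == "RD":
            if current is None:
                raise AceParseError("RD record before any CO", lines.lineno)
            if len(fields) < 2:
                raise AceParseError("malformed RD record", lines.lineno)
            try:
                n_bases = int(fields[2]) if len(fields) > 2 else None
            except ValueError:
                raise AceParseError("RD base count is not an integer",
                                    lines.lineno)
            if n_bases is None:
                raise AceParseError("RD record missing base count",
                                    lines.lineno)
            seq = _read_sequence(lines, n_bases, f"RD block for {fields[1]!r}")
            entry = [fields[1], seq.upper().replace(ACE_PAD, PAD), None]
            current[3].append(entry)
            reads_seen[fields[1]] = entry
        elif tag == "QA":
            continue
        elif tag == "DS":
            if "GENOTYPE:" in fields:
                genotype = fields[fields.index("GENOTYPE:") + 1]
                if current is not None and current[3]:
                    current[3][-1][2] = genotype
        else:
            raise AceParseError(f"unknown record tag {tag!r}", lines.lineno)
    finish()
    return contigs


def read_ace(path, genotype_map: dict | None = None) -> list:
    with open(path) as handle:
        return load_ace(handle, genotype_map=genotype_map)
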