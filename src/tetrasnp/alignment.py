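"""Padded contig multiple alignments of genotype-tagged reads.

Contigs are represented the way assembly viewers store them: a padded
consensus string over columns, and per read a padded offset, an orientation
flag, and the read sequence in contig orientation with ``-`` pads at
deletion/insertion columns. This is the unit on which per-column SNP rules
operate, and it round-trips through the ACE assembly format
(:mod:`tetrasnp.ace`).

The de novo assembler is intentionally not re-implemented: contigs are built
either from truth placements (simulation) or refined with the semi-global
pairwise aligner against a reference backbone, or loaded from external ACE
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import InputError
from .simulate import reverse_complement

PAD = "-"
BASES = "ACGT"
#: row order of count matrices: A, C, G, T, pad
CODES = "ACGT" + PAD

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(CODES):
    _CODE_LUT[ord(_c)] = _i
    _CODE_LUT[ord(_c.lower())] = _i


@dataclass
class PairwiseAlignment:
    """A semi-global alignment of a read against a target.

    ``aligned_read`` and ``aligned_target`` have equal length and cover the
    target interval ``[target_start, target_end)``; stripping pads from
    ``aligned_read`` recovers the full read, and from ``aligned_target`` the
    target slice.
    """

    aligned_read: str
    aligned_target: str
    score: float
    target_start: int
    target_end: int


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on the target side: the read aligns fully, locally in
    # the target ("end deletions" are target bases aligned to nothing)
    aligner.end_deletion_score = 0
    return aligner


def semiglobal_align(read: str, target: str, match: float = 1.0,
                     mismatch: float = -1.0, gap_open: float = -2.0,
                     gap_extend: float = -1.0) -> PairwiseAlignment:
    """Optimal alignment of ``read`` fully contained within ``target``.

    End gaps on the target are free; gaps use affine scores (``gap_open``
    for the first base of a gap, ``gap_extend`` thereafter). The traceback
    is deterministic (first optimal path of the underlying aligner).
    """
    read = read.upper()
    target = target.upper()
    if not read or not target:
        raise InputError("semiglobal_align: empty sequence")
    if not set(read) <= set("ACGTN") or not set(target) <= set("ACGTN"):
        raise InputError("semiglobal_align: sequences must be ACGT(N)")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    best = aligner.align(target, read)[0]
    t_row, r_row = str(best[0]), str(best[1])
    left = 0
    while left < len(r_row) and r_row[left] == PAD:
        left += 1
    right = len(r_row)
    while right > left and r_row[right - 1] == PAD:
        right -= 1
    t_start = sum(1 for c in t_row[:left] if c != PAD)
    t_end = t_start + sum(1 for c in t_row[left:right] if c != PAD)
    return PairwiseAlignment(
        aligned_read=r_row[left:right],
        aligned_target=t_row[left:right],
        score=float(best.score),
        target_start=t_start,
        target_end=t_end,
    )


@dataclass
class AlignedRead:
    """A read placed in a contig: padded sequence in contig orientation."""

    read_id: str
    genotype_id: str
    offset: int  # 0-based padded column of the read's first column
    is_reverse: bool
    padded_seq: str

    @property
    def end(self) -> int:
        return self.offset + len(self.padded_seq)


@dataclass
class ContigAlignment:
    """Padded multiple alignment of reads over a consensus."""

    contig_id: str
    consensus: str  # padded; PAD at pad-consensus columns, N if uncovered
    reads: list = field(default_factory=list)

    def __post_init__(self):
        self._counts = None
        # set by build_contig_alignment: reference position of the first
        # backbone column, and the padded column of each reference position
        # (both lost over an ACE round trip, which carries no backbone)
        self.ref_offset = 0
        self.ref_column_map = None

    def validate(self):
        n = len(self.consensus)
        for read in self.reads:
            if not read.genotype_id:
                raise InputError(
                    f"contig {self.contig_id}: read {read.read_id} has "
                    "no genotype")
            if read.offset < 0 or read.end > n:
                raise InputError(
                    f"contig {self.contig_id}: read {read.read_id} extends "
                    "outside the consensus")

    @property
    def genotypes(self) -> list:
        return sorted({r.genotype_id for r in self.reads})

    def count_matrix(self) -> dict:
        """Per-genotype 5xL count matrices (rows A, C, G, T, pad)."""
        if self._counts is None:
            n = len(self.consensus)
            counts = {g: np.zeros((5, n), dtype=np.int32)
                      for g in self.genotypes}
            for read in self.reads:
                arr = np.frombuffer(read.padded_seq.encode("ascii"),
                                    dtype=np.uint8)
                codes = _CODE_LUT[arr]
                mask = codes < 5
                pos = np.arange(read.offset, read.end)[mask]
                np.add.at(counts[read.genotype_id], (codes[mask], pos), 1)
            self._counts = counts
        return self._counts

    def pooled_counts(self) -> np.ndarray:
        mats = list(self.count_matrix().values())
        if not mats:
            return np.zeros((5, len(self.consensus)), dtype=np.int32)
        return np.sum(mats, axis=0)

    def invalidate_counts(self):
        self._counts = None

    # --- padded/unpadded coordinate maps -------------------------------

    def unpadded_consensus(self) -> str:
        return self.consensus.replace(PAD, "")

    def padded_to_unpadded(self) -> np.ndarray:
        """For each padded column, its 0-based unpadded position (-1 at pads)."""
        is_base = np.frombuffer(self.consensus.encode("ascii"),
                                dtype=np.uint8) != ord(PAD)
        out = np.cumsum(is_base) - 1
        out[~is_base] = -1
        return out

    @classmethod
    def from_padded_reads(cls, contig_id: str, reads) -> "ContigAlignment":
        """Build a contig from (read_id, genotype_id, offset, padded_seq)
        tuples (or AlignedRead objects) and call its consensus."""
        aligned = []
        for r in reads:
            if isinstance(r, AlignedRead):
                aligned.append(r)
            else:
                read_id, genotype_id, offset, seq = r
                aligned.append(AlignedRead(read_id, genotype_id, offset,
                                           False, seq))
        n = max((a.end for a in aligned), default=0)
        contig = cls(contig_id, "N" * n, aligned)
        contig.consensus = call_consensus(contig)
        contig.invalidate_counts()
        contig.validate()
        return contig


def call_consensus(contig: ContigAlignment) -> str:
    """Majority-vote padded consensus over all reads, genotypes pooled.

    Ties between bases break alphabetically (A < C < G < T); a pad wins a
    column only with a strict majority over the best base. Columns covered
    by no read are called ``N``.
    """
    if not contig.reads:
        raise InputError(f"contig {contig.contig_id}: no reads")
    pooled = contig.pooled_counts()
    base_counts = pooled[:4]
    best_idx = np.argmax(base_counts, axis=0)  # first max = alphabetical
    best_cnt = base_counts[best_idx, np.arange(pooled.shape[1])]
    gap_cnt = pooled[4]
    out = np.array(list(BASES))[best_idx]
    out[gap_cnt > best_cnt] = PAD
    out[(best_cnt == 0) & (gap_cnt == 0)] = "N"
    return "".join(out)


# ---------------------------------------------------------------------------
# contig construction from reads + placements


def _alignment_ops(aln: PairwiseAlignment, ref_offset: int):
    """Decompose a pairwise alignment into per-reference-position ops.

    Returns ``(span, deletions, insertions)`` where ``span`` is the
    half-open reference interval covered, ``deletions`` the set of reference
    positions aligned to a read gap, and ``insertions`` maps a reference
    position ``i`` to read bases inserted *before* ``i``.
    """
    ref_pos = ref_offset + aln.target_start
    first = ref_pos
    deletions = set()
    insertions: dict[int, str] = {}
    for rc, tc in zip(aln.aligned_read, aln.aligned_target):
        if tc == PAD:
            insertions[ref_pos] = insertions.get(ref_pos, "") + rc
        else:
            if rc == PAD:
                deletions.add(ref_pos)
            ref_pos += 1
    return (first, ref_pos), deletions, insertions


def build_contig_alignment(reads, references: dict,
                           aligner_scores: dict | None = None,
                           realign_window: int = 16) -> list:
    """Build one padded contig per locus from placed reads.

    Reads whose recorded span matches their length (no indel errors) are
    placed directly from their true coordinates; reads containing indels are
    refined against the reference backbone with the semi-global aligner and
    contribute pad columns. Reverse-strand reads are stored
    reverse-complemented (contig orientation) with the orientation flag set.

    Parameters
    ----------
    reads
        :class:`~tetrasnp.simulate.ReadRecord` iterable (sequence required).
    references
        ``{locus_id: reference sequence}`` used as the alignment backbone;
        the consensus itself is still called from the reads.
    """
    scores = aligner_scores or {}
    by_locus: dict[str, list] = {}
    for read in reads:
        if read.locus_id not in references:
            raise InputError(
                f"read {read.read_id}: unknown locus {read.locus_id!r}")
        by_locus.setdefault(read.locus_id, []).append(read)

    contigs = []
    for locus_id in sorted(by_locus):
        ref = references[locus_id]
        L = len(ref)
        placed = []  # (read, oriented_seq, span, deletions, insertions)
        for read in by_locus[locus_id]:
            oriented = (read.sequence if read.strand == "+"
                        else reverse_complement(read.sequence))
            if read.n_indel == 0 and len(oriented) == read.end - read.start:
                placed.append((read, oriented, (read.start, read.end),
                               set(), {}))
                continue
            w0 = max(0, read.start - realign_window)
            w1 = min(L, read.end + realign_window)
            aln = semiglobal_align(oriented, ref[w0:w1], **scores)
            span, dels, ins = _alignment_ops(aln, w0)
            placed.append((read, oriented, span, dels, ins))

        cmin = min(p[2][0] for p in placed)
        cmax = max(p[2][1] for p in placed)
        # maximum insertion length before each reference position
        ins_len = np.zeros(cmax - cmin + 1, dtype=np.int64)
        for _, _, _, _, ins in placed:
            for pos, bases in ins.items():
                idx = pos - cmin
                ins_len[idx] = max(ins_len[idx], len(bases))
        # padded column of the insertion slot before each reference position
        slot_start = np.zeros(cmax - cmin + 1, dtype=np.int64)
        acc = 0
        for i in range(cmax - cmin + 1):
            slot_start[i] = acc
            acc += int(ins_len[i]) + (1 if i < cmax - cmin else 0)
        total_cols = acc

        aligned_reads = []
        for read, oriented, (rs, re_), dels, ins in placed:
            parts = []
            offset = None
            ri = 0  # index into oriented read
            for i in range(rs, re_ + 1):
                slot = int(ins_len[i - cmin])
                inserted = ins.get(i, "")
                if i == rs:
                    if inserted:
                        offset = int(slot_start[i - cmin])
                        parts.append(inserted + PAD * (slot - len(inserted)))
                        ri += len(inserted)
                    else:
                        offset = int(slot_start[i - cmin]) + slot
                elif i == re_:
                    if inserted:
                        parts.append(inserted)
                        ri += len(inserted)
                    break
                else:
                    parts.append(inserted + PAD * (slot - len(inserted)))
                    ri += len(inserted)
                if i < re_:
                    if i in dels:
                        parts.append(PAD)
                    else:
                        parts.append(oriented[ri])
                        ri += 1
            aligned_reads.append(AlignedRead(
                read_id=read.read_id,
                genotype_id=read.genotype_id,
                offset=offset,
                is_reverse=(read.strand == "-"),
                padded_seq="".join(parts),
            ))

        contig = ContigAlignment(locus_id, "N" * total_cols, aligned_reads)
        contig.consensus = call_consensus(contig)
        contig.invalidate_counts()
        contig.validate()
        contig.ref_offset = cmin
        contig.ref_column_map = slot_start[:cmax - cmin] + ins_len[:cmax - cmin]
        contigs.append(contig)
    return contigs
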