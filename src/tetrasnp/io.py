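"""FASTA / TSV serialization for simulated datasets and pipeline tables."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .errors import InputError
from .simulate import PlantedVariant, ReadRecord

FASTA_WRAP = 80

PLACEMENT_COLUMNS = [
    "read_id", "genotype_id", "locus_id", "haplotype_index",
    "start", "end", "strand", "n_sub", "n_indel",
]

TRUTH_COLUMNS = [
    "locus_id", "position", "ref",
    "genotype_a", "alleles_a", "haps_a",
    "genotype_b", "alleles_b", "haps_b",
    "expected_category",
]


def write_fasta(records, path):
    """Write (id, sequence) pairs as FASTA wrapped at 80 columns."""
    seq_records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(seq_records)


def read_fasta(path) -> dict:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` dict."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_reads_fasta(reads, path):
    write_fasta(((r.read_id, r.sequence) for r in reads), path)


def write_placements(reads, path):
    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(PLACEMENT_COLUMNS)
        for r in reads:
            w.writerow([r.read_id, r.genotype_id, r.locus_id,
                        r.haplotype_index, r.start, r.end, r.strand,
                        r.n_sub, r.n_indel])


def read_placements(path, sequences: dict | None = None) -> list:
    """Read a placement TSV back into :class:`ReadRecord` objects.

    ``sequences`` (read_id -> sequence) fills in the read sequences when
    available; otherwise sequences are left empty.
    """
    reads = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(PLACEMENT_COLUMNS[:7]) - set(reader.fieldnames or ())
        if missing:
            raise InputError(
                f"{path}: placement TSV missing columns {sorted(missing)}")
        for row in reader:
            reads.append(ReadRecord(
                read_id=row["read_id"],
                genotype_id=row["genotype_id"],
                locus_id=row["locus_id"],
                haplotype_index=int(row["haplotype_index"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                sequence=(sequences or {}).get(row["read_id"], ""),
                n_sub=int(row.get("n_sub") or 0),
                n_indel=int(row.get("n_indel") or 0),
            ))
    return reads


def _format_alleles(alleles: dict) -> str:
    return "/".join(f"{a}:{d}" for a, d in sorted(alleles.items()))


def _parse_alleles(text: str) -> dict:
    out = {}
    for part in text.split("/"):
        allele, dosage = part.split(":")
        out[allele] = int(dosage)
    return out


def write_truth_table(truth, path):
    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for v in truth:
            (ga, gb) = v.alleles.keys()
            w.writerow([
                v.locus_id, v.position, v.ref,
                ga, _format_alleles(v.alleles[ga]), v.hap_alleles[ga],
                gb, _format_alleles(v.alleles[gb]), v.hap_alleles[gb],
                v.expected_category,
            ])


def read_truth_table(path) -> list:
    truth = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            ga, gb = row["genotype_a"], row["genotype_b"]
            truth.append(PlantedVariant(
                locus_id=row["locus_id"],
                position=int(row["position"]),
                ref=row["ref"],
                alleles={ga: _parse_alleles(row["alleles_a"]),
                         gb: _parse_alleles(row["alleles_b"])},
                hap_alleles={ga: row["haps_a"], gb: row["haps_b"]},
                expected_category=int(row["expected_category"]),
            ))
    return truth


SNP_COLUMNS = [
    "contig_id", "position", "padded_pos",
    "genotype_a", "alleles_a", "support_a",
    "genotype_b", "alleles_b", "support_b",
    "confidence", "status", "category", "remap_ok",
]


def _slash(alleles) -> str:
    return "/".join(sorted(alleles)) if alleles else "."


def _support_str(support: dict) -> str:
    return ",".join(f"{a}:{n}" for a, n in sorted(support.items())) or "."


def _parse_support(text: str) -> dict:
    if text in (".", ""):
        return {}
    return {a: int(n) for a, n in
            (part.split(":") for part in text.split(","))}


def write_snp_table(snps, path):
    """Candidate-SNP table as TSV (positions 1-based on unpadded consensus)."""
    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(SNP_COLUMNS)
        for s in snps:
            genos = sorted(s.support)
            ga = genos[0]
            gb = genos[1] if len(genos) > 1 else "."
            w.writerow([
                s.contig_id, s.position, s.padded_pos,
                ga, _slash(s.alleles.get(ga, ())),
                _support_str(s.support.get(ga, {})),
                gb, _slash(s.alleles.get(gb, ())),
                _support_str(s.support.get(gb, {})),
                "." if s.confidence is None else f"{s.confidence:.2f}",
                s.status,
                "." if s.category is None else s.category,
                "." if s.remap_ok is None else int(s.remap_ok),
            ])


def read_snp_table(path) -> list:
    from .discovery import CandidateSNP

    snps = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(SNP_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise InputError(
                f"{path}: SNP table missing columns {sorted(missing)}")
        for row in reader:
            support, alleles = {}, {}
            for geno_key, allele_key, supp_key in (
                    ("genotype_a", "alleles_a", "support_a"),
                    ("genotype_b", "alleles_b", "support_b")):
                geno = row[geno_key]
                if geno == ".":
                    continue
                support[geno] = _parse_support(row[supp_key])
                alleles[geno] = (frozenset() if row[allele_key] == "."
                                 else frozenset(row[allele_key].split("/")))
            snps.append(CandidateSNP(
                contig_id=row["contig_id"],
                padded_pos=int(row["padded_pos"]),
                unpadded_pos=int(row["position"]) - 1,
                support=support,
                alleles=alleles,
                confidence=(None if row["confidence"] == "."
                            else float(row["confidence"])),
                status=row["status"],
                remap_ok=(None if row["remap_ok"] == "."
                          else bool(int(row["remap_ok"]))),
                category=(None if row["category"] == "."
                          else int(row["category"])),
            ))
    return snps


def write_dataset(dataset, outdir):
    """Serialize a simulated dataset into its canonical per-file artifacts.

    Returns a dict of artifact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "reads": outdir / "reads.fasta",
        "placements": outdir / "placements.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.transcripts.items(), paths["transcripts"])
    write_reads_fasta(dataset.reads, paths["reads"])
    write_placements(dataset.reads, paths["placements"])
    write_truth_table(dataset.truth, paths["truth"])
    for genotype in dataset.genotypes:
        p = outdir / f"haplotypes_{genotype.genotype_id}.fasta"
        paths[f"haplotypes_{genotype.genotype_id}"] = p
        write_fasta(
            ((f"{locus}|hap{i + 1}", seq)
             for locus, haps in genotype.haplotypes.items()
             for i, seq in enumerate(haps)),
            p,
        )
    return paths
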