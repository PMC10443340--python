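"""Reading and writing the pipeline's file formats.

FASTA and FASTQ go through Biopython's SeqIO; GFF3 gene features are read
column-wise (seqid, start, end, strand, ID/product attributes), which is all
the pipeline consumes.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Gene, GenomeRecord


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig_id, description="")
        for contig_id, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genome_gff3(genome: GenomeRecord, path: str | Path) -> None:
    """Emit gene features; coordinates converted to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};product={g.product}"
            fh.write(
                f"{g.contig_id}\tmicrodiv\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_genome(
    fasta_path: str | Path, gff3_path: str | Path, genome_id: str | None = None
) -> GenomeRecord:
    """Load one strain from a FASTA + GFF3 pair (gene features only)."""
    fasta_path = Path(fasta_path)
    contigs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    genes: list[Gene] = []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = _parse_gff_attributes(fields[8])
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}"),
                    contig_id=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                    product=attrs.get("product", "hypothetical protein"),
                )
            )
    return GenomeRecord(
        genome_id=genome_id or fasta_path.stem, contigs=contigs, genes=genes
    )


def read_genome_dir(directory: str | Path) -> list[GenomeRecord]:
    """Load every `<strain>.fasta` + `<strain>.gff3` pair in a directory."""
    directory = Path(directory)
    genomes = []
    for fasta in sorted(directory.glob("*.fasta")):
        gff = fasta.with_suffix(".gff3")
        if gff.exists():
            genomes.append(read_genome(fasta, gff))
    if not genomes:
        raise FileNotFoundError(f"no FASTA/GFF3 pairs under {directory}")
    return genomes


def write_fastq(
    reads: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (read_id, sequence, quality-string) triples."""
    with _open_text(Path(path), "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence); gzip transparent."""
    with _open_text(Path(path)) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_marker_fasta(
    markers: Iterable[tuple[str, str]], path: str | Path
) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in markers),
        str(path),
        "fasta",
    )
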