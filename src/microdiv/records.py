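"""Shared in-memory containers for genomes, gene families and alignments.

Coordinates are 0-based half-open throughout the library; GFF3 emission
converts to 1-based inclusive at the file boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene feature on a contig.

    ``start``/``end`` are 0-based half-open on the forward strand.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = "hypothetical protein"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One strain: contig sequences plus annotated gene features."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene]
    source: str = ""

    def gene_sequence(self, gene: Gene) -> str:
        seq = self.contigs[gene.contig_id][gene.start : gene.end]
        return seq if gene.strand == "+" else reverse_complement(seq)

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def gene_sequences(self) -> dict[str, str]:
        return {g.gene_id: self.gene_sequence(g) for g in self.genes}


@dataclass
class GeneFamilyTable:
    """Clusters of orthologous genes (COGs) across a genome set.

    ``members`` maps family ID -> {genome ID -> list of member gene IDs};
    paralogs are kept as multiple entries for the same genome.
    """

    genome_ids: list[str]
    members: dict[str, dict[str, list[str]]]

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.members)

    def presence_matrix(self) -> pd.DataFrame:
        """Family x genome matrix of member counts (0/1/paralog count)."""
        mat = pd.DataFrame(
            0, index=self.family_ids, columns=self.genome_ids, dtype=int
        )
        for fam, per_genome in self.members.items():
            for gid, genes in per_genome.items():
                mat.loc[fam, gid] = len(genes)
        return mat

    def carriers(self, family_id: str) -> set[str]:
        return {g for g, members in self.members[family_id].items() if members}

    def n_genes(self, genome_id: str) -> int:
        return sum(
            len(per_genome.get(genome_id, []))
            for per_genome in self.members.values()
        )


@dataclass
class CoreAlignment:
    """Aligned nucleotide sequences of one core family over all genomes.

    Rows are equal length and ordered as ``genome_ids``; '-' is the gap
    character. Concatenating families in a fixed order preserves per-family
    column offsets.
    """

    family_id: str
    genome_ids: list[str]
    rows: list[str]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.genome_ids):
            raise ValueError("row count must match genome list")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must be equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_for(self, genome_id: str) -> str:
        return self.rows[self.genome_ids.index(genome_id)]


def concatenate_alignments(
    alignments: list[CoreAlignment],
) -> CoreAlignment:
    """Concatenate per-family alignments (same genome order) column-wise."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    genome_ids = alignments[0].genome_ids
    for aln in alignments[1:]:
        if aln.genome_ids != genome_ids:
            raise ValueError("genome order differs between alignments")
    rows = [
        "".join(aln.rows[i] for aln in alignments)
        for i in range(len(genome_ids))
    ]
    return CoreAlignment(
        family_id="+".join(a.family_id for a in alignments),
        genome_ids=genome_ids,
        rows=rows,
    )


def seq_to_array(seq: str) -> np.ndarray:
    """Encode A/C/G/T/-/N as uint8 codes 0..5 for vectorised column scans."""
    table = np.full(256, 5, dtype=np.uint8)
    for i, base in enumerate("ACGT-"):
        table[ord(base)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
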