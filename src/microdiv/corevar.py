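"""Core-gene alignments, occurrence-filtered SNP sites, SNPs/Mbp,
reference-based pairwise SNP counts and synonymous/non-synonymous
classification.

A column is a SNP site when, after dropping gap-containing columns, at
least two bases occur and the summed occurrence of all non-majority bases
reaches the occurrence threshold (default 20% of the genome collection) —
the filter that separates real variants, seen in many independent
assemblies, from isolated sequencing errors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable

from .records import (
    CoreAlignment,
    GenomeRecord,
    GeneFamilyTable,
    concatenate_alignments,
    seq_to_array,
)

_EPS = 1e-9

# translation table 11 (bacterial); stops rendered as '*'
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _TABLE11.stop_codons})


@dataclass
class SnpCallingConfig:
    min_occurrence: float = 0.20
    drop_gap_columns: bool = True

    def validate(self) -> None:
        if not 0 <= self.min_occurrence <= 1:
            raise ValueError("min_occurrence: must lie in [0, 1]")


@dataclass
class SnpSite:
    family_id: str
    column: int  # 0-based within the family alignment
    allele_counts: dict[str, int]
    minor_occurrence: float  # summed non-majority fraction of genomes


def align_family(
    members: dict[str, str], reference: str, family_id: str = ""
) -> CoreAlignment:
    """Align one core family's members, projected onto the reference.

    Equal-length members are stacked positionally (the default, indel-free
    case). Otherwise each member is globally aligned to the reference
    member and its characters are projected onto reference coordinates, so
    the reference row is always gap-free.
    """
    if reference not in members:
        raise ValueError(f"missing reference member {reference}: not a core family")
    genome_ids = sorted(members)
    seqs = [members[g] for g in genome_ids]
    if len({len(s) for s in seqs}) == 1:
        return CoreAlignment(
            family_id=family_id, genome_ids=genome_ids, rows=list(seqs)
        )
    ref_seq = members[reference]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    rows = []
    for g in genome_ids:
        if g == reference:
            rows.append(ref_seq)
            continue
        alignment = aligner.align(ref_seq, members[g])[0]
        projected = ["-"] * len(ref_seq)
        for (t0, t1), (q0, q1) in zip(*alignment.aligned):
            projected[t0:t1] = members[g][q0:q1]
        rows.append("".join(projected))
    return CoreAlignment(family_id=family_id, genome_ids=genome_ids, rows=rows)


def build_core_alignments(
    genomes: list[GenomeRecord],
    members: dict[str, dict[str, list[str]]] | GeneFamilyTable,
    reference: str,
    core_families: set[str] | None = None,
) -> list[CoreAlignment]:
    """Build one alignment per core family from genome records.

    ``members`` is family -> genome -> gene IDs (a GeneFamilyTable works);
    families not carried by every genome are skipped unless explicitly
    listed in ``core_families``. Paralogs: the first gene ID is used.
    """
    if isinstance(members, GeneFamilyTable):
        members = members.members
    by_id = {g.genome_id: g for g in genomes}
    n = len(by_id)
    out = []
    for fam in sorted(members):
        per_genome = members[fam]
        carriers = {g for g, lst in per_genome.items() if lst}
        if core_families is not None:
            if fam not in core_families:
                continue
        elif len(carriers) < n:
            continue
        seqs = {}
        for g in sorted(carriers):
            genome = by_id[g]
            gene = genome.gene_by_id(sorted(per_genome[g])[0])
            seqs[g] = genome.gene_sequence(gene)
        out.append(align_family(seqs, reference, family_id=fam))
    return out


def extract_snp_sites(
    alignment: CoreAlignment, config: SnpCallingConfig | None = None
) -> list[SnpSite]:
    """Scan alignment columns for occurrence-filtered SNP sites."""
    config = config or SnpCallingConfig()
    config.validate()
    if len(alignment.rows) < 2:
        raise ValueError("need >= 2 rows")
    mat = np.stack([seq_to_array(row) for row in alignment.rows])
    n_rows = mat.shape[0]
    counts = np.stack([(mat == i).sum(axis=0) for i in range(4)])  # ACGT
    has_gap = (mat == 4).any(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    major = counts.max(axis=0)
    minor_total = counts.sum(axis=0) - major
    keep = (n_alleles >= 2) & (
        minor_total + _EPS >= config.min_occurrence * n_rows
    )
    if config.drop_gap_columns:
        keep &= ~has_gap
    sites = []
    for col in np.nonzero(keep)[0]:
        allele_counts = {
            base: int(counts[i, col])
            for i, base in enumerate("ACGT")
            if counts[i, col] > 0
        }
        sites.append(
            SnpSite(
                family_id=alignment.family_id,
                column=int(col),
                allele_counts=allele_counts,
                minor_occurrence=float(minor_total[col]) / n_rows,
            )
        )
    return sites


def snps_per_mbp(snp_count: int, normalization_length: int) -> float:
    """Normalise a SNP count to a per-megabase rate."""
    if normalization_length <= 0:
        raise ValueError("normalization_length must be > 0")
    return snp_count * 1e6 / normalization_length


def pairwise_snp_count(row: str, reference_row: str) -> int:
    """Differing unambiguous-base columns between two aligned rows;
    columns containing a gap in either row are skipped."""
    if len(row) != len(reference_row):
        raise ValueError("aligned rows must have equal length")
    a = seq_to_array(row)
    b = seq_to_array(reference_row)
    comparable = (a < 4) & (b < 4)
    return int(np.sum(comparable & (a != b)))


def classify_substitution(
    reference_codon: str, variant_codon: str
) -> dict[int, str]:
    """Classify each differing codon position as synonymous or not.

    Each differing position is judged by mutating the reference codon at
    that position alone (standard bacterial code, table 11); stop gain or
    loss counts as non-synonymous. Positions with ambiguous bases are
    reported ``unclassifiable``.
    """
    if len(reference_codon) != 3 or len(variant_codon) != 3:
        raise ValueError("codons must be length 3")
    reference_codon = reference_codon.upper()
    variant_codon = variant_codon.upper()
    out: dict[int, str] = {}
    for pos in range(3):
        if reference_codon[pos] == variant_codon[pos]:
            continue
        mutated = (
            reference_codon[:pos]
            + variant_codon[pos]
            + reference_codon[pos + 1 :]
        )
        if reference_codon not in _CODON_TO_AA or mutated not in _CODON_TO_AA:
            out[pos] = "unclassifiable"
            continue
        same = _CODON_TO_AA[reference_codon] == _CODON_TO_AA[mutated]
        out[pos] = "synonymous" if same else "non_synonymous"
    return out


def genomewide_snp_summary(
    alignments: list[CoreAlignment],
    reference: str,
    config: SnpCallingConfig | None = None,
) -> pd.DataFrame:
    """Per-genome SNP totals against the reference over all core families.

    For each non-reference genome: total differing sites on the
    concatenated core genes, synonymous/non-synonymous tallies for sites in
    complete unambiguous codons (frame 0 of each gene), and the
    non-synonymous percentage (exact, plus the integer part as printed).
    """
    totals: dict[str, int] = {}
    syn: dict[str, int] = {}
    nonsyn: dict[str, int] = {}
    for aln in alignments:
        if reference not in aln.genome_ids:
            raise ValueError(f"reference {reference} missing from {aln.family_id}")
        ref_row = aln.row_for(reference)
        for g, row in zip(aln.genome_ids, aln.rows):
            if g == reference:
                continue
            totals.setdefault(g, 0)
            syn.setdefault(g, 0)
            nonsyn.setdefault(g, 0)
            totals[g] += pairwise_snp_count(row, ref_row)
            a = seq_to_array(row)
            b = seq_to_array(ref_row)
            diff_cols = np.nonzero((a < 4) & (b < 4) & (a != b))[0]
            for col in diff_cols:
                start = 3 * (col // 3)
                ref_codon = ref_row[start : start + 3]
                if len(ref_codon) < 3 or any(c not in "ACGT" for c in ref_codon):
                    continue
                var_base = row[col]
                labels = classify_substitution(
                    ref_codon,
                    ref_codon[: col - start]
                    + var_base
                    + ref_codon[col - start + 1 :],
                )
                label = labels.get(col - start)
                if label == "synonymous":
                    syn[g] += 1
                elif label == "non_synonymous":
                    nonsyn[g] += 1
    rows = []
    for g in sorted(totals):
        classified = syn[g] + nonsyn[g]
        pct = 100.0 * nonsyn[g] / classified if classified else 0.0
        rows.append(
            {
                "genome": g,
                "total_snps": totals[g],
                "synonymous": syn[g],
                "non_synonymous": nonsyn[g],
                "percent_non_synonymous": pct,
                "percent_non_synonymous_printed": int(pct),
            }
        )
    return pd.DataFrame(rows)


def concatenated_snp_analysis(
    alignments: list[CoreAlignment],
    config: SnpCallingConfig | None = None,
) -> tuple[list[SnpSite], int, float]:
    """Occurrence-filtered SNP sites on the concatenated core alignment.

    Returns (sites, alignment length, SNPs per Mbp under the
    alignment-length convention).
    """
    concat = concatenate_alignments(alignments)
    sites = extract_snp_sites(concat, config)
    length = concat.n_columns
    return sites, length, snps_per_mbp(len(sites), length)
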