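"""Strain-specific marker genes and RPKM-based strain deconvolution.

Markers are genes unique to one strain that survive three filters: no
sufficiently long, sufficiently similar alignment to any other strain's
genome (k-mer seeded, ungapped extension), no mobile-element-like
annotation (transposase/phage/integrase by default), and not located near
a contig end. Reads are counted against markers only on full-length exact
identity on either strand ("perfect mode"); reads matching markers of more
than one strain are discarded and tallied. Strain abundance is the mean
RPKM over that strain's markers, normalised to proportions per time point.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .pangenome import classify_families
from .records import GenomeRecord, GeneFamilyTable, reverse_complement


@dataclass(frozen=True)
class Marker:
    strain: str
    gene_id: str
    length: int
    sequence: str


@dataclass
class MarkerGeneSet:
    markers: dict[str, list[Marker]]  # strain -> kept markers
    audit: pd.DataFrame  # candidate -> kept/rejected + reason

    def all_markers(self) -> list[Marker]:
        return [m for lst in self.markers.values() for m in lst]


@dataclass
class MarkerFilters:
    end_distance: int = 500  # bp from a contig end
    blacklist: tuple[str, ...] = ("transposase", "phage", "integrase")
    min_hit_length: int = 100  # bp of cross-genome alignment that disqualifies
    min_hit_identity: float = 0.90
    seed_k: int = 21
    ani_warn_threshold: float = 98.0  # percent


def _kmer_index(contigs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((cid, i))
    return index


def _extend_hit(
    gene: str, contig: str, gp: int, cp: int, k: int, id_min: float
) -> int:
    """Greedy ungapped extension of an exact k-mer seed; returns the length
    of the extended segment while identity stays >= id_min."""
    matches = k
    left_g, left_c = gp, cp
    right_g, right_c = gp + k, cp + k
    # extend right, then left, accepting mismatches while identity holds
    while right_g < len(gene) and right_c < len(contig):
        m = matches + (gene[right_g] == contig[right_c])
        length = (right_g - left_g) + 1
        if m / length < id_min:
            break
        matches = m
        right_g += 1
        right_c += 1
    while left_g > 0 and left_c > 0:
        m = matches + (gene[left_g - 1] == contig[left_c - 1])
        length = (right_g - left_g) + 1
        if m / length < id_min:
            break
        matches = m
        left_g -= 1
        left_c -= 1
    return right_g - left_g


def _has_cross_hit(
    gene_seq: str,
    other: GenomeRecord,
    other_index: dict[str, list[tuple[str, int]]],
    filters: MarkerFilters,
) -> bool:
    k = filters.seed_k
    for query in (gene_seq, reverse_complement(gene_seq)):
        seen_diagonals: set[tuple[str, int]] = set()
        for gp in range(0, len(query) - k + 1):
            for cid, cp in other_index.get(query[gp : gp + k], ()):
                diag = (cid, cp - gp)
                if diag in seen_diagonals:
                    continue
                seen_diagonals.add(diag)
                length = _extend_hit(
                    query, other.contigs[cid], gp, cp, k,
                    filters.min_hit_identity,
                )
                if length >= filters.min_hit_length:
                    return True
    return False


def select_marker_genes(
    table: GeneFamilyTable,
    genomes: list[GenomeRecord],
    filters: MarkerFilters | None = None,
    max_markers: int = 10,
    ani: pd.DataFrame | None = None,
) -> MarkerGeneSet:
    """Pick up to ``max_markers`` strain-specific marker genes per strain.

    Candidates are the families unique to each strain; survivors of the
    annotation-blacklist, contig-end and cross-genome-similarity filters
    are kept longest-first. The audit trail lists every candidate with its
    outcome. If an ANI matrix is given, strain pairs at or above the warn
    threshold (default 98%) trigger a multi-mapping warning.
    """
    filters = filters or MarkerFilters()
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    by_id = {g.genome_id: g for g in genomes}
    partition = classify_families(table)

    if ani is not None:
        for i, ga in enumerate(ani.index):
            for gb in ani.columns[i + 1 :]:
                if ani.loc[ga, gb] >= filters.ani_warn_threshold:
                    warnings.warn(
                        f"strains {ga} and {gb} have ANI "
                        f"{ani.loc[ga, gb]:.2f}% >= "
                        f"{filters.ani_warn_threshold}%: marker uniqueness "
                        "and read assignment may be unreliable"
                    )

    indexes = {
        g.genome_id: _kmer_index(g.contigs, filters.seed_k) for g in genomes
    }
    audit_rows = []
    markers: dict[str, list[Marker]] = {g.genome_id: [] for g in genomes}
    for fam in sorted(partition.unique):
        strain = next(iter(table.carriers(fam)))
        genome = by_id[strain]
        for gene_id in sorted(table.members[fam][strain]):
            gene = genome.gene_by_id(gene_id)
            seq = genome.gene_sequence(gene)
            reason = None
            if any(w in gene.product.lower() for w in filters.blacklist):
                reason = "blacklist"
            if reason is None:
                contig_len = len(genome.contigs[gene.contig_id])
                if (
                    gene.start < filters.end_distance
                    or contig_len - gene.end < filters.end_distance
                ):
                    reason = "contig_end"
            if reason is None:
                for other in genomes:
                    if other.genome_id == strain:
                        continue
                    if _has_cross_hit(
                        seq, other, indexes[other.genome_id], filters
                    ):
                        reason = "cross_hit"
                        break
            audit_rows.append(
                {
                    "strain": strain,
                    "gene_id": gene_id,
                    "family": fam,
                    "length": gene.length,
                    "status": "rejected" if reason else "candidate_kept",
                    "reason": reason or "",
                }
            )
            if reason is None:
                markers[strain].append(
                    Marker(
                        strain=strain,
                        gene_id=gene_id,
                        length=gene.length,
                        sequence=seq,
                    )
                )
    # keep the longest survivors, capped at max_markers
    audit = pd.DataFrame(audit_rows)
    for strain in markers:
        survivors = sorted(
            markers[strain], key=lambda m: (-m.length, m.gene_id)
        )
        kept = survivors[:max_markers]
        dropped = {m.gene_id for m in survivors[max_markers:]}
        markers[strain] = kept
        if len(audit):
            over = audit["gene_id"].isin(dropped)
            audit.loc[over, "status"] = "rejected"
            audit.loc[over, "reason"] = "over_max_markers"
            is_kept = audit["status"] == "candidate_kept"
            audit.loc[is_kept, "status"] = "kept"
        if not kept:
            warnings.warn(f"strain {strain}: no surviving marker candidates")
    return MarkerGeneSet(markers=markers, audit=audit)


@dataclass
class MappingResult:
    counts: dict[str, int]  # marker gene_id -> perfect-match read count
    total_mapped: int  # reads assigned to exactly one strain
    ambiguous: int  # reads matching markers of > 1 strain (discarded)
    total_reads: int


def map_reads_perfect(
    reads: Iterable[tuple[str, str]], markers: MarkerGeneSet
) -> MappingResult:
    """Count reads matching a marker exactly over their full length.

    A read counts for a marker iff it equals a contiguous stretch of the
    marker on either strand. Reads hitting markers of more than one strain
    are discarded and tallied separately.
    """
    all_markers = markers.all_markers()
    counts = {m.gene_id: 0 for m in all_markers}
    # substring index per read length, built lazily
    index_by_len: dict[int, dict[str, set[tuple[str, str]]]] = {}

    def index_for(L: int) -> dict[str, set[tuple[str, str]]]:
        if L not in index_by_len:
            idx: dict[str, set[tuple[str, str]]] = {}
            for m in all_markers:
                for i in range(len(m.sequence) - L + 1):
                    idx.setdefault(m.sequence[i : i + L], set()).add(
                        (m.strain, m.gene_id)
                    )
            index_by_len[L] = idx
        return index_by_len[L]

    total_mapped = 0
    ambiguous = 0
    total_reads = 0
    for _, seq in reads:
        total_reads += 1
        idx = index_for(len(seq))
        hits = idx.get(seq, set()) | idx.get(reverse_complement(seq), set())
        if not hits:
            continue
        strains = {s for s, _ in hits}
        if len(strains) > 1:
            ambiguous += 1
            continue
        total_mapped += 1
        for _, gene_id in hits:
            counts[gene_id] += 1
    return MappingResult(
        counts=counts,
        total_mapped=total_mapped,
        ambiguous=ambiguous,
        total_reads=total_reads,
    )


def rpkm(mapped_reads: int, gene_length: int, total_mapped_reads: int) -> float:
    """Reads per kilobase per million mapped reads:
    (10^9 * mapped reads to the gene) / (total mapped reads * gene length)."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if total_mapped_reads == 0:
        warnings.warn("no mapped reads: RPKM reported as 0")
        return 0.0
    if total_mapped_reads < mapped_reads:
        raise ValueError("total_mapped_reads must be >= mapped_reads")
    return 1e9 * mapped_reads / (total_mapped_reads * gene_length)


@dataclass
class AbundanceProfile:
    """Per strain x time point abundances with per-time library sizes."""

    table: pd.DataFrame  # time, strain, mapped_reads, mean_rpkm, proportion
    library_sizes: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)


def profile_timeseries(
    reads_by_time: dict[str, Iterable[tuple[str, str]]],
    markers: MarkerGeneSet,
    aggregate: str = "mean",
) -> AbundanceProfile:
    """Strain proportions over a time series of read sets.

    Per time point and strain: perfect-match counts on that strain's
    markers, the mean (or median) marker RPKM, and the proportion
    strain-RPKM / sum of strain-RPKMs. Time points with no mapped reads
    report NaN proportions.
    """
    if not any(markers.markers.values()):
        raise ValueError("no markers for any strain")
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    rows = []
    library_sizes: dict[str, int] = {}
    ambiguous: dict[str, int] = {}
    for tp in sorted(reads_by_time):
        result = map_reads_perfect(reads_by_time[tp], markers)
        library_sizes[tp] = result.total_mapped
        ambiguous[tp] = result.ambiguous
        strain_rpkm = {}
        strain_reads = {}
        for strain, strain_markers in markers.markers.items():
            if not strain_markers:
                continue
            rpkms = [
                rpkm(
                    result.counts[m.gene_id], m.length, result.total_mapped
                )
                if result.total_mapped
                else 0.0
                for m in strain_markers
            ]
            strain_rpkm[strain] = float(agg(rpkms))
            strain_reads[strain] = sum(
                result.counts[m.gene_id] for m in strain_markers
            )
        total_rpkm = sum(strain_rpkm.values())
        for strain in sorted(strain_rpkm):
            proportion = (
                strain_rpkm[strain] / total_rpkm if total_rpkm > 0 else np.nan
            )
            rows.append(
                {
                    "time": tp,
                    "strain": strain,
                    "mapped_reads": strain_reads[strain],
                    "mean_rpkm": strain_rpkm[strain],
                    "proportion": proportion,
                }
            )
    return AbundanceProfile(
        table=pd.DataFrame(rows),
        library_sizes=library_sizes,
        ambiguous=ambiguous,
    )
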