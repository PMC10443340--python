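"""Gene-family clustering, core/accessory partitioning, accumulation
curves, ANI and dereplication.

Genes are clustered into families (COGs) by thresholding exact global
pairwise alignments (default: identity >= 50% over >= 80% coverage of the
longer sequence) and taking connected components of the resulting graph; a
shared-k-mer prefilter bounds the all-vs-all cost and, at these thresholds,
cannot discard a passing pair of non-pathological gene sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align

from .records import GenomeRecord, GeneFamilyTable


@dataclass
class ClusteringConfig:
    min_identity: float = 0.50
    min_coverage: float = 0.80
    match_score: float = 2.0
    mismatch_score: float = -3.0
    open_gap_score: float = -5.0
    extend_gap_score: float = -2.0
    prefilter_k: int = 15

    def validate(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity: must lie in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage: must lie in (0, 1]")


@dataclass
class DereplicationConfig:
    ani_threshold: float = 99.0  # percent

    def validate(self) -> None:
        if not 0 < self.ani_threshold <= 100:
            raise ValueError("ani_threshold: must lie in (0, 100]")


def _make_aligner(config: ClusteringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.open_gap_score
    aligner.extend_gap_score = config.extend_gap_score
    # end gaps are free: fragments align without being forced to stretch
    new_names = (
        "open_end_insertion_score",
        "extend_end_insertion_score",
        "open_end_deletion_score",
        "extend_end_deletion_score",
    )
    old_names = (
        "target_end_open_gap_score",
        "target_end_extend_gap_score",
        "query_end_open_gap_score",
        "query_end_extend_gap_score",
    )
    names = new_names if hasattr(aligner, new_names[0]) else old_names
    for name in names:
        setattr(aligner, name, 0.0)
    return aligner


def pairwise_gene_identity(
    a: str, b: str, config: ClusteringConfig | None = None
) -> tuple[float, float]:
    """Identity and coverage of the optimal global alignment of two genes.

    Identity = matching columns / aligned columns (end gaps excluded, N never
    matches); coverage = aligned span / length of the longer sequence.
    """
    config = config or ClusteringConfig()
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0, 1.0
    aligner = _make_aligner(config)
    alignment = aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    both = [
        i
        for i, (x, y) in enumerate(zip(row_a, row_b))
        if x != "-" and y != "-"
    ]
    if not both:
        return 0.0, 0.0
    c0, c1 = both[0], both[-1]
    span = c1 - c0 + 1
    matches = sum(
        1
        for x, y in zip(row_a[c0 : c1 + 1], row_b[c0 : c1 + 1])
        if x == y and x in "ACGT"
    )
    identity = matches / span
    coverage = span / max(len(a), len(b))
    return identity, coverage


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def cluster_gene_families(
    genomes: list[GenomeRecord],
    config: ClusteringConfig | None = None,
    use_prefilter: bool = True,
) -> GeneFamilyTable:
    """Group genes into families by thresholded pairwise similarity.

    Families are connected components of the graph with an edge wherever
    identity >= min_identity and coverage >= min_coverage; the family ID is
    the lexicographically smallest member gene ID, making the output
    invariant to input order.
    """
    config = config or ClusteringConfig()
    config.validate()
    if not genomes or all(not g.genes for g in genomes):
        raise ValueError("need at least one genome with at least one gene")

    entries: list[tuple[str, str, str]] = []  # (gene_id, genome_id, seq)
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for gene in genome.genes:
            entries.append(
                (gene.gene_id, genome.genome_id, genome.gene_sequence(gene))
            )
    entries.sort()
    gene_ids = [e[0] for e in entries]
    seq_of = {e[0]: e[2] for e in entries}
    genome_of = {e[0]: e[1] for e in entries}

    if use_prefilter:
        index: dict[str, list[str]] = {}
        for gid, _, seq in entries:
            for kmer in _kmer_set(seq, config.prefilter_k):
                index.setdefault(kmer, []).append(gid)
        candidate_pairs = set()
        for bucket in index.values():
            if len(bucket) > 1:
                candidate_pairs.update(combinations(sorted(set(bucket)), 2))
    else:
        candidate_pairs = set(combinations(gene_ids, 2))

    uf = _UnionFind(gene_ids)
    for ga, gb in sorted(candidate_pairs):
        if seq_of[ga] == seq_of[gb]:
            uf.union(ga, gb)
            continue
        identity, coverage = pairwise_gene_identity(
            seq_of[ga], seq_of[gb], config
        )
        if identity >= config.min_identity and coverage >= config.min_coverage:
            uf.union(ga, gb)

    members: dict[str, dict[str, list[str]]] = {}
    for gid in gene_ids:
        fam = uf.find(gid)
        members.setdefault(fam, {}).setdefault(genome_of[gid], []).append(gid)
    genome_ids = sorted(g.genome_id for g in genomes)
    return GeneFamilyTable(genome_ids=genome_ids, members=members)


@dataclass
class FamilyPartition:
    core: set[str]
    accessory: set[str]
    unique: set[str]
    unique_counts: dict[str, int] = field(default_factory=dict)


def classify_families(table: GeneFamilyTable) -> FamilyPartition:
    """Partition families into core / accessory / unique.

    Core = present in all genomes; unique = present in exactly one;
    accessory = the remainder. Also counts unique families per genome.
    """
    if not table.members:
        raise ValueError("empty family table")
    n = len(table.genome_ids)
    core, accessory, unique = set(), set(), set()
    unique_counts = {g: 0 for g in table.genome_ids}
    for fam in table.family_ids:
        carriers = table.carriers(fam)
        if len(carriers) == n:
            core.add(fam)
        elif len(carriers) == 1:
            unique.add(fam)
            unique_counts[next(iter(carriers))] += 1
        else:
            accessory.add(fam)
    return FamilyPartition(
        core=core, accessory=accessory, unique=unique,
        unique_counts=unique_counts,
    )


def accumulation_curves(
    table: GeneFamilyTable, n_permutations: int, seed: int = 0
) -> pd.DataFrame:
    """Pangenome (cumulative union) and core (cumulative intersection)
    sizes as genomes are added in random order; median and quartiles over
    permutations of the genome ordering."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(table.genome_ids) < 2:
        raise ValueError("need >= 2 genomes")
    presence = (table.presence_matrix().to_numpy() > 0)  # families x genomes
    n_genomes = presence.shape[1]
    rng = np.random.default_rng(seed)
    pan = np.empty((n_permutations, n_genomes), dtype=int)
    core = np.empty((n_permutations, n_genomes), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        union = np.zeros(presence.shape[0], dtype=bool)
        inter = np.ones(presence.shape[0], dtype=bool)
        for step, g in enumerate(order):
            union |= presence[:, g]
            inter &= presence[:, g]
            pan[p, step] = union.sum()
            core[p, step] = inter.sum()
    rows = []
    for step in range(n_genomes):
        rows.append(
            {
                "n_genomes": step + 1,
                "pangenome_q1": float(np.quantile(pan[:, step], 0.25)),
                "pangenome_median": float(np.median(pan[:, step])),
                "pangenome_q3": float(np.quantile(pan[:, step], 0.75)),
                "core_q1": float(np.quantile(core[:, step], 0.25)),
                "core_median": float(np.median(core[:, step])),
                "core_q3": float(np.quantile(core[:, step], 0.75)),
            }
        )
    return pd.DataFrame(rows)


def compute_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    table: GeneFamilyTable,
    config: ClusteringConfig | None = None,
) -> float:
    """Average nucleotide identity (percent) over shared gene families.

    One member per genome per family; with paralogs the best-scoring pair
    is used.
    """
    config = config or ClusteringConfig()
    seqs_a = a.gene_sequences()
    seqs_b = b.gene_sequences()
    identities = []
    for fam in table.family_ids:
        mem_a = table.members[fam].get(a.genome_id, [])
        mem_b = table.members[fam].get(b.genome_id, [])
        if not mem_a or not mem_b:
            continue
        best = max(
            pairwise_gene_identity(seqs_a[ga], seqs_b[gb], config)[0]
            for ga in mem_a
            for gb in mem_b
        )
        identities.append(best)
    if not identities:
        raise ValueError(
            f"genomes {a.genome_id} and {b.genome_id} share no gene family"
        )
    return 100.0 * float(np.mean(identities))


def ani_matrix(
    genomes: list[GenomeRecord],
    table: GeneFamilyTable,
    config: ClusteringConfig | None = None,
) -> pd.DataFrame:
    ids = sorted(g.genome_id for g in genomes)
    by_id = {g.genome_id: g for g in genomes}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for ga, gb in combinations(ids, 2):
        ani = compute_ani(by_id[ga], by_id[gb], table, config)
        mat.loc[ga, gb] = ani
        mat.loc[gb, ga] = ani
    return mat


def dereplicate(
    genomes: list[GenomeRecord],
    config: DereplicationConfig | None = None,
    table: GeneFamilyTable | None = None,
    ani: pd.DataFrame | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Collapse near-identical genomes: single-linkage clusters at
    ANI > threshold, one representative per cluster (largest gene count,
    ties broken lexicographically).

    Returns (representative IDs, representative -> cluster members).
    """
    config = config or DereplicationConfig()
    config.validate()
    if ani is None:
        if table is None:
            raise ValueError("need a GeneFamilyTable or a precomputed ANI matrix")
        ani = ani_matrix(genomes, table)
    ids = list(ani.index)
    uf = _UnionFind(ids)
    for ga, gb in combinations(ids, 2):
        if ani.loc[ga, gb] > config.ani_threshold:
            uf.union(ga, gb)
    clusters: dict[str, list[str]] = {}
    for gid in ids:
        clusters.setdefault(uf.find(gid), []).append(gid)
    n_genes = {g.genome_id: len(g.genes) for g in genomes}
    representatives: dict[str, list[str]] = {}
    for members in clusters.values():
        rep = sorted(members, key=lambda g: (-n_genes.get(g, 0), g))[0]
        representatives[rep] = sorted(members)
    reps = sorted(representatives)
    return reps, representatives
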