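"""Per-gene variability, highly-variable-gene (HVG) detection, p-distance
matrices, neighbor-joining trees with bootstrap and reference-strain
selection.

A core gene's variability is the mean pairwise SNP count of every
non-reference genome against the reference; HVGs are the upper outliers of
that distribution under the Tukey rule (mean > Q3 + 1.5*IQR, quartiles by
linear interpolation of order statistics), conserved genes sit below Q1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corevar import pairwise_snp_count
from .records import CoreAlignment, concatenate_alignments, seq_to_array
from .simulate import TreeNode


@dataclass
class GeneVariabilityStats:
    family_id: str
    counts: dict[str, int]  # non-reference genome -> SNPs vs reference
    mean: float
    sd: float
    rate_class: str = "typical"  # conserved | typical | HVG


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match id list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m

    def mean_distances(self) -> dict[str, float]:
        n = len(self.ids)
        if n < 2:
            return {g: 0.0 for g in self.ids}
        sums = self.matrix.sum(axis=1)
        return {g: float(sums[i]) / (n - 1) for i, g in enumerate(self.ids)}


def per_gene_snp_stats(
    alignments: list[CoreAlignment],
    reference: str,
    all_vs_all: bool = False,
) -> list[GeneVariabilityStats]:
    """Mean and SD of pairwise SNP counts per core family.

    Default: every non-reference row against the reference row (the
    reference is excluded from its own statistics). ``all_vs_all`` averages
    over every unordered row pair instead.
    """
    out = []
    for aln in alignments:
        if reference not in aln.genome_ids:
            raise ValueError(f"reference {reference} missing from {aln.family_id}")
        if all_vs_all:
            counts = {}
            vals = []
            for i in range(len(aln.genome_ids)):
                for j in range(i + 1, len(aln.genome_ids)):
                    vals.append(pairwise_snp_count(aln.rows[i], aln.rows[j]))
        else:
            ref_row = aln.row_for(reference)
            counts = {
                g: pairwise_snp_count(row, ref_row)
                for g, row in zip(aln.genome_ids, aln.rows)
                if g != reference
            }
            vals = list(counts.values())
        out.append(
            GeneVariabilityStats(
                family_id=aln.family_id,
                counts=counts,
                mean=float(np.mean(vals)) if vals else 0.0,
                sd=float(np.std(vals)) if vals else 0.0,
            )
        )
    return out


def _quartiles(means: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(means, [0.25, 0.75])  # linear interpolation
    return float(q1), float(q3)


def detect_hvgs(
    stats: list[GeneVariabilityStats],
) -> tuple[set[str], float]:
    """Upper-outlier families by the Tukey rule.

    Returns (HVG family IDs, cutoff value Q3 + 1.5*IQR); a family is an
    HVG iff its mean strictly exceeds the cutoff. Side effect: rate_class
    of flagged stats is set to "HVG".
    """
    if len(stats) < 4:
        raise ValueError("need >= 4 families for quartile-based detection")
    means = np.array([s.mean for s in stats])
    q1, q3 = _quartiles(means)
    cutoff = q3 + 1.5 * (q3 - q1)
    hvgs = set()
    for s in stats:
        if s.mean > cutoff:
            hvgs.add(s.family_id)
            s.rate_class = "HVG"
    return hvgs, cutoff


def conserved_genes(stats: list[GeneVariabilityStats]) -> set[str]:
    """Families whose mean SNP count falls below the 25th percentile."""
    if len(stats) < 4:
        raise ValueError("need >= 4 families for quartile-based selection")
    means = np.array([s.mean for s in stats])
    q1, _ = _quartiles(means)
    out = set()
    for s in stats:
        if s.mean < q1:
            out.add(s.family_id)
            if s.rate_class == "typical":
                s.rate_class = "conserved"
    return out


def p_distance_matrix(alignment: CoreAlignment) -> DistanceMatrix:
    """Pairwise proportion of differing ungapped, unambiguous columns."""
    if len(alignment.rows) < 3:
        raise ValueError("need >= 3 rows")
    mat = np.stack([seq_to_array(r) for r in alignment.rows])
    n = mat.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = (mat[i] < 4) & (mat[j] < 4)
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.genome_ids[i]} "
                    f"and {alignment.genome_ids[j]}"
                )
            d = np.sum(comparable & (mat[i] != mat[j])) / n_comp
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(ids=list(alignment.genome_ids), matrix=dist)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch lengths clamped to 0, deficit shifted to the sister
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Saitou-Nei Q-criterion).

    Deterministic: among tied Q values the pair with the lexicographically
    smallest (taxon-label, taxon-label) key is joined. Returns an unrooted
    tree rendered with a trifurcating root (bifurcating for < 4 taxa).
    """
    if len(dm.ids) < 3:
        raise ValueError("need >= 3 taxa")
    nodes = [TreeNode(name=g) for g in dm.ids]
    # sort key per working node: smallest descendant taxon label
    keys = list(dm.ids)
    D = dm.matrix.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                if best is None or (q, tie_key) < (best[0], best[1]):
                    best = (q, tie_key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(name="")
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_row[keep]
        D = D2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]
    root = TreeNode(name="")
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        limbs = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
        for node, limb in zip(nodes, limbs):
            node.branch_length = max(limb, 0.0)
        root.children = nodes
    else:  # exactly 2 working nodes cannot occur from >= 3 input taxa
        raise AssertionError("unreachable")
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of the tree, each canonicalised as the side not
    containing the lexicographically smallest taxon."""
    taxa = sorted(leaf.name for leaf in tree.leaves())
    anchor = taxa[0]
    all_taxa = set(taxa)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= walk(c)
        if node is not tree and 1 < len(below) < len(all_taxa) - 1:
            side = below if anchor not in below else all_taxa - below
            splits.add(frozenset(side))
        return below

    walk(tree)
    return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Symmetric-difference (RF) distance between two unrooted topologies."""
    return len(bipartitions(a) ^ bipartitions(b))


def _pair_diff_arrays(
    mat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    n = mat.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.empty((len(pairs), mat.shape[1]), dtype=np.float32)
    comp = np.empty_like(diff)
    for p, (i, j) in enumerate(pairs):
        comparable = (mat[i] < 4) & (mat[j] < 4)
        comp[p] = comparable
        diff[p] = comparable & (mat[i] != mat[j])
    return diff, comp, pairs


def bootstrap_support(
    alignments: list[CoreAlignment],
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree on the concatenated alignment with split support.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each split of the original
    tree. All splits are reported (display filtering, e.g. at 50, is the
    consumer's choice). Internal nodes of the returned tree carry their
    support as the node name.
    """
    concat = concatenate_alignments(alignments)
    if len(concat.genome_ids) < 4:
        raise ValueError("need >= 4 taxa for bootstrap support")
    base_tree = neighbor_joining(p_distance_matrix(concat))
    mat = np.stack([seq_to_array(r) for r in concat.rows])
    L = mat.shape[1]
    diff, comp, pairs = _pair_diff_arrays(mat)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(base_tree)}
    n = len(concat.genome_ids)
    for _ in range(n_replicates):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(
            np.float32
        )
        d_pairs = diff @ w
        c_pairs = comp @ w
        dist = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            if c_pairs[p] == 0:
                raise ValueError("bootstrap replicate with no comparable columns")
            dist[i, j] = dist[j, i] = d_pairs[p] / c_pairs[p]
        rep_tree = neighbor_joining(
            DistanceMatrix(ids=concat.genome_ids, matrix=dist)
        )
        for split in bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1
    support = {
        s: 100.0 * c / n_replicates for s, c in counts.items()
    }

    all_taxa = set(leaf.name for leaf in base_tree.leaves())
    anchor = min(all_taxa)

    def annotate(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= annotate(c)
        if node is not base_tree and 1 < len(below) < len(all_taxa) - 1:
            side = below if anchor not in below else all_taxa - below
            if frozenset(side) in support:
                node.name = f"{support[frozenset(side)]:.0f}"
        return below

    annotate(base_tree)
    return base_tree, support


def select_reference_strain(dm: DistanceMatrix) -> str:
    """The most divergent genome: maximal mean distance to all others
    (the strain at the deepest split); ties broken lexicographically."""
    if len(dm.ids) < 2:
        raise ValueError("need >= 2 taxa")
    means = dm.mean_distances()
    return sorted(means, key=lambda g: (-means[g], g))[0]


def hvg_tree(
    alignments: list[CoreAlignment], hvg_families: set[str]
) -> TreeNode:
    """NJ tree restricted to the highly variable gene families."""
    subset = [a for a in alignments if a.family_id in hvg_families]
    if not subset:
        raise ValueError("empty HVG set")
    return neighbor_joining(p_distance_matrix(concatenate_alignments(subset)))
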