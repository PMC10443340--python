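"""Synthetic pangenome and metagenome generator.

Emulates the variation structure the downstream analyses assume: a clonal
strain phylogeny (coalescent-style random binary tree rescaled to unit
root-to-tip depth), core genes evolving under Jukes-Cantor with per-gene
rate heterogeneity including an outlier "fast" class, accessory families
arising by gain/loss on internal branches, strain-unique genes, genes laid
onto contigs with intergenic spacers, and shotgun read mixtures drawn from
several strains at fixed proportions.

No indels are simulated by default, so orthologous core genes stay
positionally aligned; substitution events are Poisson per branch per site
with uniform choice among the three alternative bases (repeated hits at a
site are applied sequentially, i.e. the exact Jukes-Cantor event process).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as mio
from .records import Gene, GenomeRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised when a simulation parameter is out of its valid range."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``base_subst_rate`` is the expected number of substitutions per site
    accumulated along the total tree depth (root-to-tip = 1 after
    rescaling); a pair of strains is therefore separated by up to
    ``2 * base_subst_rate`` expected substitutions per site. Fast genes
    multiply this by ``fast_rate_multiplier``.
    """

    n_strains: int = 22
    tree_mode: str = "random_coalescent"
    user_newick: str | None = None
    n_core_genes: int = 500
    gene_length_range: tuple[int, int] = (600, 1400)
    base_subst_rate: float = 0.02
    fast_gene_fraction: float = 0.05
    fast_rate_multiplier: float = 10.0
    gain_loss_rate: float = 2.0
    n_unique_genes_per_strain: int = 12
    n_contigs: int = 2
    intergenic_spacer: int = 100
    read_length: int = 150
    error_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        def req(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigError(f"{name}: {why}")

        req(self.n_strains >= 1, "n_strains", "must be >= 1")
        req(
            self.tree_mode in ("random_coalescent", "user_newick"),
            "tree_mode",
            "must be random_coalescent or user_newick",
        )
        req(self.n_core_genes >= 1, "n_core_genes", "must be >= 1")
        lo, hi = self.gene_length_range
        req(3 <= lo <= hi, "gene_length_range", "needs 3 <= lo <= hi")
        req(self.base_subst_rate >= 0, "base_subst_rate", "must be >= 0")
        req(
            0 <= self.fast_gene_fraction <= 1,
            "fast_gene_fraction",
            "must lie in [0, 1]",
        )
        req(
            self.fast_rate_multiplier >= 1,
            "fast_rate_multiplier",
            "must be >= 1",
        )
        req(self.gain_loss_rate >= 0, "gain_loss_rate", "must be >= 0")
        req(
            self.n_unique_genes_per_strain >= 0,
            "n_unique_genes_per_strain",
            "must be >= 0",
        )
        req(self.n_contigs >= 1, "n_contigs", "must be >= 1")
        req(self.intergenic_spacer >= 0, "intergenic_spacer", "must be >= 0")
        req(self.read_length >= 1, "read_length", "must be >= 1")
        req(0 <= self.error_rate < 1, "error_rate", "must lie in [0, 1)")


@dataclass
class TreeNode:
    name: str
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.branch_length:.10f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name if not self.name.startswith("N") else ""
        return f"({inner}){label}:{self.branch_length:.10f}"


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic genomes."""

    true_tree: TreeNode
    gene_family_truth: dict[str, set[str]]
    per_gene_rate_class: dict[str, str]
    true_variant_sites: dict[str, list[int]]
    mixture_proportions: dict[str, dict[str, float]] = field(
        default_factory=dict
    )


def random_coalescent_tree(n: int, rng: np.random.Generator) -> TreeNode:
    """Kingman-style random binary tree, root-to-tip depth rescaled to 1."""
    nodes = [TreeNode(name=f"S{i + 1:02d}") for i in range(n)]
    heights = [0.0] * n
    t = 0.0
    counter = 0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode(name=f"N{counter}")
        counter += 1
        for idx in (i, j):
            nodes[idx].branch_length = t - heights[idx]
            parent.children.append(nodes[idx])
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        heights = [h for idx, h in enumerate(heights) if idx not in (i, j)]
        nodes.append(parent)
        heights.append(t)
    root = nodes[0]
    if n == 1:
        return root
    scale = 1.0 / t

    def rescale(node: TreeNode) -> None:
        node.branch_length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    root.branch_length = 0.0
    return root


def parse_newick(text: str) -> TreeNode:
    """Minimal Newick reader for rooted trees with branch lengths."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode(name="")
        if text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if text[pos] != ")":
                raise ValueError("unbalanced parentheses in newick")
            pos += 1
        # label and branch length
        label = ""
        while pos < len(text) and text[pos] not in ",():":
            label += text[pos]
            pos += 1
        node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            num = ""
            while pos < len(text) and text[pos] not in ",()":
                num += text[pos]
                pos += 1
            node.branch_length = float(num)
        return node

    return parse_node()


def _evolve_gene(
    root_seq: np.ndarray,
    tree: TreeNode,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Jukes-Cantor evolution of one gene; returns leaf name -> sequence."""
    L = len(root_seq)
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = seq.copy()
            d = rate * child.branch_length
            k = rng.poisson(L * d)
            if k:
                pos = rng.integers(0, L, size=k)
                uniq, counts = np.unique(pos, return_counts=True)
                single = uniq[counts == 1]
                child_seq[single] = (
                    child_seq[single] + rng.integers(1, 4, size=len(single))
                ) % 4
                for p in uniq[counts > 1]:
                    for _ in range(counts[np.searchsorted(uniq, p)]):
                        child_seq[p] = (child_seq[p] + rng.integers(1, 4)) % 4
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                descend(child, child_seq)
        if node.is_leaf:  # single-strain tree: root is the leaf
            out[node.name] = seq

    descend(tree, root_seq.copy())
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _internal_edges(root: TreeNode) -> list[TreeNode]:
    """Child nodes of internal edges (edges whose child is not a leaf)."""
    out = []

    def walk(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                out.append(c)
                walk(c)

    walk(root)
    return out


def _all_edges(root: TreeNode) -> list[TreeNode]:
    out = []

    def walk(node: TreeNode) -> None:
        for c in node.children:
            out.append(c)
            walk(c)

    walk(root)
    return out


def simulate_pangenome(
    config: SimulationConfig,
) -> tuple[list[GenomeRecord], TruthTables]:
    """Generate strain genomes plus ground-truth tables.

    Every strain carries a mutated copy of each core gene, a subset of
    accessory families gained/lost along the tree, and exactly
    ``n_unique_genes_per_strain`` genes carried by no other strain.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.tree_mode == "user_newick":
        if not config.user_newick:
            raise ConfigError("user_newick: required when tree_mode=user_newick")
        tree = parse_newick(config.user_newick)
        strains = sorted(leaf.name for leaf in tree.leaves())
        if len(strains) != config.n_strains:
            raise ConfigError("n_strains: does not match user_newick leaf count")
    else:
        tree = random_coalescent_tree(config.n_strains, rng)
        strains = sorted(leaf.name for leaf in tree.leaves())

    lo, hi = config.gene_length_range
    gene_seqs: dict[str, dict[str, np.ndarray]] = {}  # family -> strain -> seq
    rate_class: dict[str, str] = {}
    family_truth: dict[str, set[str]] = {}

    # --- core genes ---------------------------------------------------
    n_fast = int(round(config.fast_gene_fraction * config.n_core_genes))
    fast_idx = set(
        rng.choice(config.n_core_genes, size=n_fast, replace=False).tolist()
    )
    for i in range(config.n_core_genes):
        fam = f"CORE{i + 1:05d}"
        L = int(rng.integers(lo, hi + 1))
        fast = i in fast_idx
        rate = config.base_subst_rate * (
            config.fast_rate_multiplier if fast else 1.0
        )
        root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
        gene_seqs[fam] = _evolve_gene(root_seq, tree, rate, rng)
        rate_class[fam] = "fast" if fast else "normal"
        family_truth[fam] = set(strains)

    # --- accessory gain/loss ------------------------------------------
    acc_counter = 0
    internal = _internal_edges(tree)
    gains: dict[str, TreeNode] = {}
    for node in internal:
        for _ in range(rng.poisson(config.gain_loss_rate / 2.0)):
            acc_counter += 1
            gains[f"ACC{acc_counter:05d}"] = node
    for fam, origin in gains.items():
        L = int(rng.integers(lo, hi + 1))
        root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
        gene_seqs[fam] = _evolve_gene(
            root_seq, origin, config.base_subst_rate, rng
        )
        gene_seqs[fam][origin.name] = root_seq  # drop internal-root key
        carriers = {leaf.name for leaf in origin.leaves()}
        # loss events: each removes the family from a random sub-clade
        for edge in _all_edges(origin):
            if rng.poisson(config.gain_loss_rate / 2.0 / max(len(internal), 1)):
                lost = {leaf.name for leaf in edge.leaves()}
                if len(carriers - lost) >= 2:
                    carriers -= lost
        family_truth[fam] = carriers
        rate_class[fam] = "normal"
        gene_seqs[fam] = {
            s: seq for s, seq in gene_seqs[fam].items() if s in carriers
        }

    # --- strain-unique genes ------------------------------------------
    for strain in strains:
        for i in range(config.n_unique_genes_per_strain):
            fam = f"UNQ_{strain}_{i + 1:03d}"
            L = int(rng.integers(lo, hi + 1))
            gene_seqs[fam] = {
                strain: rng.integers(0, 4, size=L).astype(np.uint8)
            }
            family_truth[fam] = {strain}
            rate_class[fam] = "normal"

    # --- true variant sites over core families ------------------------
    variant_sites: dict[str, list[int]] = {}
    for fam in sorted(family_truth):
        if not fam.startswith("CORE"):
            continue
        mat = np.stack([gene_seqs[fam][s] for s in strains])
        varying = np.nonzero((mat != mat[0]).any(axis=0))[0]
        variant_sites[fam] = varying.tolist()

    # --- lay genes onto contigs ---------------------------------------
    genomes: list[GenomeRecord] = []
    for strain in strains:
        fams = sorted(f for f, c in family_truth.items() if strain in c)
        order = rng.permutation(len(fams))
        fams = [fams[i] for i in order]
        chunks = np.array_split(np.arange(len(fams)), config.n_contigs)
        contigs: dict[str, str] = {}
        genes: list[Gene] = []
        for ci, chunk in enumerate(chunks):
            contig_id = f"{strain}_c{ci + 1}"
            parts: list[str] = []
            pos = 0
            for gi in chunk:
                fam = fams[gi]
                spacer = _decode(
                    rng.integers(0, 4, size=config.intergenic_spacer).astype(
                        np.uint8
                    )
                )
                parts.append(spacer)
                pos += len(spacer)
                seq = _decode(gene_seqs[fam][strain])
                product = (
                    "strain-specific protein"
                    if fam.startswith("UNQ")
                    else "conserved hypothetical protein"
                )
                genes.append(
                    Gene(
                        gene_id=f"{strain}_{fam}",
                        contig_id=contig_id,
                        start=pos,
                        end=pos + len(seq),
                        strand="+",
                        product=product,
                    )
                )
                parts.append(seq)
                pos += len(seq)
            parts.append(
                _decode(
                    rng.integers(0, 4, size=config.intergenic_spacer).astype(
                        np.uint8
                    )
                )
            )
            contigs[contig_id] = "".join(parts)
        genomes.append(
            GenomeRecord(
                genome_id=strain, contigs=contigs, genes=genes, source="simulated"
            )
        )

    truth = TruthTables(
        true_tree=tree,
        gene_family_truth=family_truth,
        per_gene_rate_class=rate_class,
        true_variant_sites=variant_sites,
    )
    return genomes, truth


@dataclass
class SimulatedReads:
    """Reads plus per-read source-strain truth labels."""

    ids: list[str]
    seqs: list[str]
    labels: list[str]
    quality_char: str = "D"  # PHRED 35

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    def to_fastq(self, path: str | Path) -> None:
        qual = None
        mio.write_fastq(
            (
                (rid, seq, self.quality_char * len(seq))
                for rid, seq in zip(self.ids, self.seqs)
            ),
            path,
        )


def simulate_reads(
    genomes: list[GenomeRecord],
    proportions: dict[str, float] | list[float],
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedReads:
    """Draw shotgun reads from a strain mixture.

    Reads start uniformly over positions that fit within a contig of the
    strain chosen by the proportion weights; either strand with equal
    probability; per-base errors substitute a different base.
    """
    if isinstance(proportions, dict):
        weights = [proportions.get(g.genome_id, 0.0) for g in genomes]
    else:
        weights = list(proportions)
    if len(weights) != len(genomes):
        raise ConfigError("proportions: must give one weight per genome")
    if any(w < 0 for w in weights):
        raise ConfigError("proportions: weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError("proportions: must sum to 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights)
    ids: list[str] = []
    seqs: list[str] = []
    labels: list[str] = []
    for genome, c in zip(genomes, counts):
        if c == 0:
            continue
        contig_ids = list(genome.contigs)
        spans = np.array(
            [
                len(genome.contigs[cid]) - read_length + 1
                for cid in contig_ids
            ],
            dtype=float,
        )
        spans = np.clip(spans, 0, None)
        if spans.sum() == 0:
            raise ConfigError(
                f"read_length: longer than every contig of {genome.genome_id}"
            )
        contig_pick = rng.choice(len(contig_ids), size=c, p=spans / spans.sum())
        starts = np.empty(c, dtype=int)
        for idx in range(len(contig_ids)):
            mask = contig_pick == idx
            if mask.any():
                starts[mask] = rng.integers(
                    0, int(spans[idx]), size=int(mask.sum())
                )
        flip = rng.random(c) < 0.5
        for r in range(c):
            contig = genome.contigs[contig_ids[contig_pick[r]]]
            read = contig[starts[r] : starts[r] + read_length]
            if flip[r]:
                read = reverse_complement(read)
            seqs.append(read)
            labels.append(genome.genome_id)
    if error_rate > 0:
        lookup = {b: i for i, b in enumerate("ACGT")}
        for r in range(len(seqs)):
            k = rng.binomial(read_length, error_rate)
            if k:
                arr = bytearray(seqs[r], "ascii")
                pos = rng.choice(read_length, size=k, replace=False)
                for p in pos:
                    new = (lookup[chr(arr[p])] + int(rng.integers(1, 4))) % 4
                    arr[p] = ord("ACGT"[new])
                seqs[r] = arr.decode("ascii")
    # interleave strains deterministically
    order = rng.permutation(len(seqs))
    seqs = [seqs[i] for i in order]
    labels = [labels[i] for i in order]
    ids = [f"read{i + 1:07d}" for i in range(len(seqs))]
    return SimulatedReads(ids=ids, seqs=seqs, labels=labels)


def simulate_timeseries(
    genomes: list[GenomeRecord],
    truth: TruthTables,
    proportions_by_time: dict[str, dict[str, float]],
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, SimulatedReads]:
    """Read mixtures at several time points (e.g. 10/24/48 h samples)."""
    out: dict[str, SimulatedReads] = {}
    for i, (tp, props) in enumerate(sorted(proportions_by_time.items())):
        out[tp] = simulate_reads(
            genomes,
            props,
            n_reads,
            read_length=read_length,
            error_rate=error_rate,
            seed=seed + i + 1,
        )
        truth.mixture_proportions[tp] = dict(props)
    return out


def write_simulation(
    outdir: str | Path,
    genomes: list[GenomeRecord],
    truth: TruthTables,
    config: SimulationConfig,
) -> None:
    """Emit FASTA/GFF3 per strain, truth tables as TSV, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        mio.write_genome_fasta(genome, outdir / f"{genome.genome_id}.fasta")
        mio.write_genome_gff3(genome, outdir / f"{genome.genome_id}.gff3")
    (outdir / "true_tree.nwk").write_text(truth.true_tree.newick() + "\n")
    with open(outdir / "truth_families.tsv", "w") as fh:
        fh.write("family\trate_class\tcarriers\n")
        for fam in sorted(truth.gene_family_truth):
            carriers = ",".join(sorted(truth.gene_family_truth[fam]))
            fh.write(f"{fam}\t{truth.per_gene_rate_class[fam]}\t{carriers}\n")
    with open(outdir / "truth_variant_sites.tsv", "w") as fh:
        fh.write("family\tpositions\n")
        for fam in sorted(truth.true_variant_sites):
            pos = ",".join(map(str, truth.true_variant_sites[fam]))
            fh.write(f"{fam}\t{pos}\n")
    manifest = {"config": asdict(config), "seed": config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
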