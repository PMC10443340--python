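"""Marker-gene strain deconvolution of a mixed culture.

Each strain gets up to ten unique marker genes (no cross-genome
similarity, no mobile-element annotation, away from contig ends). Reads
from a four-strain mixture are counted against the markers under perfect
(full-length exact) matching, converted to RPKM, and normalised to
per-strain proportions at each sampling time.
"""
from microdiv import (
    SimulationConfig,
    profile_timeseries,
    select_marker_genes,
    simulate_pangenome,
    simulate_timeseries,
)
from microdiv.records import GeneFamilyTable

config = SimulationConfig(
    n_strains=4, n_core_genes=60, n_unique_genes_per_strain=12,
    error_rate=0.0, seed=5,
)
genomes, truth = simulate_pangenome(config)
members = {
    fam: {s: [f"{s}_{fam}"] for s in carriers}
    for fam, carriers in truth.gene_family_truth.items()
}
table = GeneFamilyTable(
    genome_ids=[g.genome_id for g in genomes], members=members
)

markers = select_marker_genes(table, genomes, max_markers=10)
print("markers per strain:",
      {s: len(m) for s, m in markers.markers.items()})

# community shifting over three sampling times (e.g. 10, 24, 48 h)
mixtures = {
    "10": {"S01": 0.25, "S02": 0.25, "S03": 0.25, "S04": 0.25},
    "24": {"S01": 0.45, "S02": 0.30, "S03": 0.15, "S04": 0.10},
    "48": {"S01": 0.60, "S02": 0.25, "S03": 0.10, "S04": 0.05},
}
reads = simulate_timeseries(
    genomes, truth, mixtures, n_reads=100_000, seed=6
)
profile = profile_timeseries(
    {tp: list(r) for tp, r in reads.items()}, markers
)
print("\nestimated vs true proportions:")
for row in profile.table.itertuples():
    true_p = mixtures[row.time][row.strain]
    print(f"  t={row.time}h {row.strain}: estimated {row.proportion:.3f} "
          f"(true {true_p:.2f}, mean RPKM {row.mean_rpkm:.1f})")
# With error-free reads and clean markers the estimates track the true
# mixture to within a few thousandths; one strain's rise over time mirrors
# the competitive dominance read out in a bioreactor co-culture.
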