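"""Alignment trimming, rogue-leaf filtering and supermatrix construction.

Simulates gene trees with five planted rogue leaves (20x terminal branches),
flags and prunes them, filters gene trees by completeness, trims a gappy
alignment to 90% occupancy, and concatenates genes into a codon-partitioned
supermatrix.
"""

from phyloconcord import (
    Alignment,
    RogueSpec,
    SimulationConfig,
    SpeciesTreeModel,
    concatenate_supermatrix,
    inject_rogues,
    iterative_occupancy_trim,
    min_taxa_filter,
    parse_newick,
    rogue_taxon_filter,
    simulate_msc_gene_trees,
)

SPECIES = "(((A:6,B:6):3,(C:6,D:6):3):3,(E:9,F:9):3);"
model = SpeciesTreeModel(parse_newick(SPECIES))
gene_trees = simulate_msc_gene_trees(
    model, SimulationConfig(n_genes=100, seed=21, p_miss=0.1)
)
rogued, truth = inject_rogues(gene_trees, [RogueSpec("D", 0.05, 20.0)], seed=22)
flags, filtered, _ = rogue_taxon_filter(rogued)
print(f"planted rogue (gene, taxon) pairs: {sorted(truth)}")
print(f"flagged:                           {flags}")
print(f"false positives: {len(set(flags) - set(truth))}, "
      f"misses: {len(set(truth) - set(flags))}")

complete = min_taxa_filter(filtered, min_taxa=5)
print(f"\ngene trees with >= 5 taxa after pruning: {len(complete)}/100")

gappy = Alignment(
    list("abcdefghij"),
    ["AACGTACGTA"] * 7 + ["-ACGTACGTA"] * 2 + ["-ACGT--GTA"],
)
trimmed, log = iterative_occupancy_trim(gappy)
for it in log:
    print(f"trim iteration {it.iteration}: -{it.columns_removed} sites, "
          f"-{it.sequences_removed} sequences")
print(f"trimmed alignment: {trimmed.n_taxa} taxa x {trimmed.width} sites")

g1 = Alignment(["sp1", "sp2", "sp3"], ["ATGAAA", "ATGAAG", "ATGAAT"])
g2 = Alignment(["sp1", "sp3"], ["ATGCCCGGG", "ATGCCCGGC"])
sm, scheme = concatenate_supermatrix([("g1", g1), ("g2", g2)],
                                     scheme_kind="codon_12_3")
print(f"\nsupermatrix: {sm.n_taxa} taxa x {sm.width} sites "
      f"(sp2 padded with '?' across gene g2)")
print(scheme.to_raxml().strip())
print("Positions 1+2 form one partition and position 3 the other, the "
      "standard codon-partitioned setup for a concatenated analysis.")
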