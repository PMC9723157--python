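"""Gene and site concordance factors on a simulated phylogenomic dataset.

Simulates 300 gene trees under the multispecies coalescent on a six-taxon
species tree with short internal branches (strong incomplete lineage
sorting), evolves a JC69 supermatrix along them, and prints the per-branch
concordance table.
"""

from phyloconcord import (
    SimulationConfig,
    SpeciesTreeModel,
    concatenate_supermatrix,
    concordance_table,
    parse_newick,
    simulate_jc_alignment,
    simulate_msc_gene_trees,
    summarize,
)

SPECIES = "(((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5):0.5,(E:1.5,F:1.5):0.5);"

ref = parse_newick(SPECIES)
model = SpeciesTreeModel(ref, mu=0.2)  # 0.2 substitutions per coalescent unit
gene_trees = simulate_msc_gene_trees(model, SimulationConfig(n_genes=300, seed=11))

named = [
    (f"gene{i:03d}", simulate_jc_alignment(t.scaled(model.mu), 300, seed=1000 + i))
    for i, t in enumerate(gene_trees)
]
supermatrix, _ = concatenate_supermatrix(named)

branches = concordance_table(ref, gene_trees, supermatrix, n_quartets=500, seed=7)

print(f"{'branch':<14}{'T':>5}{'gCF':>7}{'gDF1':>7}{'gDF2':>7}{'gDFP':>7}"
      f"{'sCF':>7}{'gEF p':>9}")
for b in branches:
    print(f"{b.branch_id:<14}{b.length:>5.2f}{b.gcf:>7.1f}{b.gdf1:>7.1f}"
          f"{b.gdf2:>7.1f}{b.gdfp:>7.1f}{b.scf:>7.1f}{b.gef_p:>9.3f}")

rep = summarize(branches)
print(f"\n{rep.frac_gcf_over * 100:.1f}% of branches have gCF > 50; "
      f"{rep.frac_scf_over * 100:.1f}% have sCF > 33.")
print("Every internal branch here is 0.5 coalescent units, so roughly "
      "1 - (2/3)e^-0.5 = 60% of quartets agree with the species tree; gCF "
      "sits lower because whole-split concordance is stricter, and the gEF "
      "p-values stay large because the two discordant resolutions are "
      "symmetric under pure incomplete lineage sorting.")
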