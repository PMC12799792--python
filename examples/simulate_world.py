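"""Generate a synthetic study and write its input tables to disk.

The world bundles everything the pipeline consumes — per-cohort GWAS summary
statistics, five QTL instrument panels, a drug catalog, PPI edge lists,
orthogonal-evidence catalogs, an association catalog, and the ground-truth
table of planted causal gene-trait effects.
"""

from targetmr import SimConfig, generate_world
from targetmr.io import write_world

cfg = SimConfig(n_traits=10, n_genes=100, seed=42, n_approved_pairs=40, n_dev_pairs=20)
world = generate_world(cfg)

print(f"genes: {len(world.genes)}, traits: {len(world.traits)}, cohorts: {len(world.gwas)}")
print(f"planted causal gene-trait pairs: {int(world.truth['causal'].sum())}")
for source, df in world.instruments.items():
    print(f"instruments[{source}]: {len(df)} variants")
n_gwas = sum(len(df) for df in world.gwas.values())
print(f"outcome GWAS records across cohorts: {n_gwas}")
print(f"drug catalog rows: {len(world.drug_catalog)} "
      f"(approved: {int((world.drug_catalog['max_phase'] == 4).sum())})")

write_world(world, "scratch/world_demo")
print("tables written under scratch/world_demo/ "
      "(gwas.<cohort>.<trait>.tsv, instruments.<source>.tsv, truth.tsv, ...)")
# The truth table is what downstream stages are benchmarked against: a pair
# is causal iff its true_effect is nonzero.
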