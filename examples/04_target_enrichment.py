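"""Diametric miRNA:mRNA target over-representation, both nulls.

Genes up in wild-type tumors are paired with miRNAs down in wild-type; the
count of predicted interactions linking the two sets is compared with a
permutation null (resampled gene sets) and the analytic hypergeometric
null.
"""

import mirgist as mg
from mirgist.target_integration import DiametricSets

cohort = mg.simulate_cohort(mg.SimConfig(seed=17))
sets = DiametricSets(
    "all_wt_vs_all_mutant",
    cohort.truth.enriched_mirnas,
    cohort.truth.enriched_genes,
)
print(f"diametric sets: {len(sets.mirnas_down)} miRNAs down in WT x "
      f"{len(sets.genes_up)} genes up in WT")
print(f"target table: {len(cohort.targets.pairs)} predicted pairs over "
      f"{len(cohort.targets.mirna_universe)} miRNAs x "
      f"{len(cohort.targets.gene_universe)} genes")

observed = mg.count_predicted_interactions(sets, cohort.targets)
for null in ("permutation", "hypergeometric"):
    r = mg.interaction_enrichment(sets, cohort.targets, null_kind=null,
                                  n_permutations=10_000, seed=17)
    print(f"{null:15s} null: observed {r.observed} vs expected {r.expected:.1f} "
          f"-> p = {r.p_value:.4g}")
print("(observed >> expected because the generator plants a 5x pair density "
      "inside the diametric sets; both nulls agree it is non-random)")
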