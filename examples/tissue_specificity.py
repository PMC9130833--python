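"""Screen a multi-tissue FPKM matrix for tissue-specific genes.

Simulates a 14-tissue expression panel with planted specific genes, then runs
the screening funnel: replicate averaging, the FPKM >= 1 filter, the tau
index, top-20% candidate selection, and the FPKM/rank caller.
"""

from adipospec import data_model as dm
from adipospec.specificity import (
    biotype_composition,
    call_tissue_specific,
    candidates_by_tau,
    evaluate_tsg_recovery,
    per_tissue_sets,
)
from adipospec.synthetic_data import SimConfig, simulate_expression

cfg = SimConfig(seed=0)
em, ann, truth = simulate_expression(cfg)
print(f"panel: {em.values.shape[0]} genes x {em.values.shape[1]} samples, "
      f"{len(em.tissues)} tissues")

tp = dm.tissue_means(em)
filtered = dm.filter_low_expression(tp, 1.0)
print(f"expression filter: {len(filtered.gene_ids)} genes with mean FPKM >= 1 somewhere")

candidates = candidates_by_tau(filtered, top_fraction=0.20)
calls = call_tissue_specific(candidates, filtered, fpkm_min=1.0, rank_k=3)
called = [c for c in calls if c.specific_tissues]
print(f"candidates (top 20% by tau): {len(candidates)}; "
      f"genes called tissue-specific: {len(called)}")

sets = per_tissue_sets(calls)
for tissue in cfg.adipose_tissues:
    print(f"  {tissue}: {len(sets.get(tissue, set()))} specific genes")

metrics = evaluate_tsg_recovery(calls, truth)
print(f"recovery vs planted truth: precision {metrics['precision']:.3f}, "
      f"recall {metrics['recall']:.3f} over {metrics['n_true_pairs']} planted assignments")
print(f"({metrics['background_genes_called']} non-planted candidates were also "
      "called; the top-20% rule always screens part of the background)")

mix = biotype_composition({c.gene_id for c in called}, ann)
print("biotype mix of called genes (lncRNA-enriched by design):",
      {k: round(v, 3) for k, v in mix.items()})
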