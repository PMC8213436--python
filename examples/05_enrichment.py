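"""Hypergeometric over-representation analysis of a hub-gene list."""

import herbnet as h

cfg = h.GeneratorConfig(seed=0)
hubs = [f"hub{i:03d}" for i in range(cfg.n_hub_tier)]
sets, universe, truth = h.gen_genesets(cfg, hub_genes=hubs)

collection = h.GeneSetCollection(dict(sets), universe=universe)
result = h.enrich(hubs, collection, top=10)

print(result.to_string(index=False,
                       formatters={"pvalue": "{:.2e}".format,
                                   "qvalue": "{:.2e}".format}))
print(f"\nplanted enriched set: {truth.enriched_set} "
      f"(rank 1: {result['set'].iloc[0] == truth.enriched_set})")

# p is the exact upper-tail hypergeometric probability of the observed
# overlap k given set size K, query size n and universe size N; q is the
# Benjamini-Hochberg adjusted value across all tested sets.
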