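"""Call DEGs on synthetic three-replicate counts and find the genes whose
disease-induced change is reversed by treatment (counter-regulated)."""

import herbnet as h

cfg = h.GeneratorConfig(seed=1)
counts, truth = h.gen_counts(cfg)

deg1 = h.call_degs(counts, "Con", "TNF")          # disease vs control
deg2 = h.call_degs(counts, "TNF", "TNF+WBT")      # treated vs disease
counter = h.counter_regulated(deg1, deg2)

print(f"contrast TNF vs Con:      {deg1.n_total} DEGs "
      f"({deg1.n_up} up, {deg1.n_down} down)")
print(f"contrast TNF+WBT vs TNF:  {deg2.n_total} DEGs "
      f"({deg2.n_up} up, {deg2.n_down} down)")
print(f"counter-regulated genes:  {len(counter)} "
      f"(planted: {len(truth.counter_regulated)})")

# A DEG needs |log2 fold change| >= 1 and p < 0.05 (Welch t on log2 CPM).
# Counter-regulated genes are significant in both contrasts with opposite
# directions — the candidate mediators of the treatment effect.
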