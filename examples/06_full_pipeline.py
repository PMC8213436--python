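"""Run the whole pipeline on a coherent synthetic study and print the report.

Equivalent shell command:  herbnet run --seed 5 --out scratch/demo
"""

import herbnet as h

cfg = h.PipelineConfig(generator=h.GeneratorConfig(seed=5))
report = h.run_pipeline(cfg)
print(report.to_text())

# The report chains every stage: feature annotation counts, DEGs per
# contrast (up + down = total), the counter-regulated gene count, both
# network stages with their densities, the hub count, the key-constituent
# count and the number of significantly enriched gene sets.
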