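# Static pathway -> functional-module label map, applied after enrichment.
# This grouping is curated domain knowledge, never computed by the pipeline.
inflammation-immune regulation:
  - NOD-like receptor signaling pathway
  - B cell receptor signaling pathway
  - T cell receptor signaling pathway
  - Fc epsilon RI signaling pathway
  - Toll-like receptor signaling pathway
  - Primary immunodeficiency
  - Leukocyte transendothelial migration
  - Chemokine signaling pathway
  - Complement and coagulation cascades
  - Natural killer cell mediated cytotoxicity
  - Regulation of actin cytoskeleton
  - Fc gamma R-mediated phagocytosis
  - Cytokine-cytokine receptor interaction
  - TNF signaling pathway
energy metabolism regulation:
  - Citrate cycle (TCA cycle)
  - Oxidative phosphorylation
  - Adipocytokine signaling pathway
  - Neurotrophin signaling pathway
  - Insulin signaling pathway
  - Valine, leucine and isoleucine biosynthesis
  - Glycolysis / Gluconeogenesis
  - Pyrimidine metabolism
cell function regulation:
  - Focal adhesion
  - mTOR signaling pathway
  - ECM-receptor interaction
  - Apoptosis
  - TGF-beta signaling pathway
  - MAPK signaling pathway
synovial pannus formation:
  - VEGF signaling pathway
  - Vascular smooth muscle contraction
bone destruction regulation:
  - Osteoclast differentiation
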