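"""Annotate two observed ions against a tiny compound library.

The two features are the worked reference spectra of the preparation:
a positive ion at m/z 823.3022 and a negative ion at m/z 927.4931.
"""

import herbnet as h

library = [
    h.CompoundRecord("baohuoside VI", "C39H50O19", herb="YYH"),
    h.CompoundRecord("akebiasaponin D", "C47H76O18", herb="XD"),
]
features = [
    h.MSFeature(rt=15.37, mz=823.3022, response=1.0, polarity="+"),
    h.MSFeature(rt=17.27, mz=927.4931, response=1.0, polarity="-"),
]

for m in h.match_features(features, library):
    print(f"m/z {m.feature.mz:9.4f} ({m.feature.polarity}) -> {m.compound} "
          f"{m.adduct}  theo {m.theoretical_mz:.4f}  "
          f"err {m.error_mda:+.2f} mDa / {m.error_ppm:+.2f} ppm")

# fragment ions of the protonated baohuoside VI explained by neutral losses
precursor = h.adduct_mz(h.formula_mass("C39H50O19"), "[M+H]+")
for frag in h.annotate_fragments(precursor, [677.2438, 531.1860, 369.1328]):
    print(f"fragment {frag.fragment_mz:8.4f}  assigned {frag.label or 'none'}")

# Each observed ion is assigned the library compound whose theoretical
# adduct m/z lies within 5 mDa or 10 ppm; fragments are the precursor minus
# rhamnose (rha) / glucose (Glc) residues.
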