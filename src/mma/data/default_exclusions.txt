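# Default currency-metabolite exclusion list (base names, all compartments).
# A curated reconstruction of the ubiquitous species whose shared production
# and consumption does not constitute a meaningful interaction between
# reactions: protons, water, phosphate, dissolved gases and similar
# inorganics.  Energy cofactors (ATP, ADP, NADH, NADPH, FADH2, CoA ...) are
# deliberately NOT listed: cofactor-mediated coupling between reactions is a
# signal the modularity analysis is designed to detect.
# Override with --exclusions / load_exclusion_list on a custom file.
h           # proton, H+
h2o         # water
pi          # inorganic phosphate
ppi         # pyrophosphate
co2         # carbon dioxide
o2          # molecular oxygen
h2o2        # hydrogen peroxide
nh4         # ammonium
so4         # sulfate
so3         # sulfite
cl          # chloride
na1         # sodium
k           # potassium
ca2         # calcium
mg2         # magnesium
fe2         # iron (II)
fe3         # iron (III)
zn2         # zinc
hco3        # bicarbonate
o2s         # superoxide
no          # nitric oxide
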