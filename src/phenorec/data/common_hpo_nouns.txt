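# Head nouns that commonly open phenotype term structures
# ("<noun> of the <body part>").  One phrase per line; singular and plural
# are listed separately because surface forms are inflection-sensitive.
abnormality
abnormalities
malformation
malformations
anomaly
anomalies
defect
defects
deformity
deformities
pit
pits
tumour
tumours
tumor
tumors
dysplasia
hypoplasia
aplasia
agenesis
atrophy
absence
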