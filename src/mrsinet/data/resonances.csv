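# Lorentzian-line approximation of proton MR resonances for brain metabolites.
# Columns: metabolite, ppm (chemical shift), relative_amplitude (proton-count weighted).
# Multiplets are collapsed to their centre positions; J-coupling is not modelled.
metabolite,ppm,relative_amplitude
Ala,1.47,3.0
Ala,3.77,1.0
Asp,2.65,1.0
Asp,2.80,1.0
Asp,3.89,1.0
Cho,3.19,9.0
Cho,3.50,2.0
Cho,4.05,2.0
Cr,3.03,3.0
Cr,3.91,2.0
GABA,1.89,2.0
GABA,2.28,2.0
GABA,3.01,2.0
Glc,3.43,1.0
Glc,3.70,2.0
Glc,3.88,1.0
Glc,5.22,0.4
Gln,2.13,2.0
Gln,2.45,2.0
Gln,3.75,1.0
Glu,2.04,2.0
Glu,2.35,2.0
Glu,3.74,1.0
GPC,3.21,9.0
GPC,3.68,2.0
GPC,4.31,2.0
GPE,3.22,2.0
GPE,3.98,2.0
GPE,4.12,1.0
GSH,2.15,2.0
GSH,2.55,2.0
GSH,2.95,2.0
GSH,3.77,2.0
GSH,4.56,1.0
Gly,3.55,2.0
Ins,3.27,1.0
Ins,3.52,2.0
Ins,3.61,2.0
Ins,4.05,1.0
Lac,1.31,3.0
Lac,4.10,1.0
NAA,2.01,3.0
NAA,2.49,1.0
NAA,2.67,1.0
NAA,4.38,1.0
NAAG,2.04,3.0
NAAG,2.18,2.0
NAAG,2.52,2.0
NAAG,4.61,1.0
PCh,3.21,9.0
PCh,3.58,2.0
PCh,4.16,2.0
PCr,3.03,3.0
PCr,3.93,2.0
PEtn,3.22,2.0
PEtn,3.98,2.0
Ser,3.83,1.0
Ser,3.94,2.0
ScyIns,3.34,6.0
Tau,3.25,2.0
Tau,3.42,2.0
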