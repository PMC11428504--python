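# Second H+/e- step of the double-HAT mechanism for Pt-3-O-glc, transcribed from the published
# reaction scheme. After the first H-atom transfer at 4'-OH, the phenoxyl 4'-O radical can lose a
# second H atom from the C5'-OCH3 group (closing a benzodioxole ring) or from the C3'-OH group
# (giving an o-quinone, singlet state). cost is the second-step energy (kcal/mol) on the same
# H-acceptor convention as the first-step O-H BDE.
compound,first_site,product,spin,phase,cost
Pt-3-O-glc,4'-OH,benzodioxole,singlet,gas,44.4
Pt-3-O-glc,4'-OH,benzodioxole,singlet,water,48.3
Pt-3-O-glc,4'-OH,benzodioxole,singlet,ethanol,47.4
Pt-3-O-glc,4'-OH,o-quinone,singlet,gas,80.8
Pt-3-O-glc,4'-OH,o-quinone,singlet,water,75.9
Pt-3-O-glc,4'-OH,o-quinone,singlet,ethanol,74.9
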