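# Gas-phase 4'-OH bond dissociation enthalpies as quoted in the published discussion's
# cross-compound ranking sentence. For Cy-3-O-glc the quoted value (89.8) differs from the
# printed descriptor table (4'-OH 94.0 / 5'-OH 89.8); both sources are shipped unedited.
compound,site,phase,bde
Pt-3-O-glc,4'-OH,gas,86.2
Dp-3-O-glc,4'-OH,gas,86.7
Mv-3-O-glc,4'-OH,gas,87.4
Cy-3-O-glc,4'-OH,gas,89.8
Pn-3-O-glc,4'-OH,gas,93.4
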