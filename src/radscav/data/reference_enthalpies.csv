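# Default reference enthalpies (kcal/mol) of the hydrogen atom, proton and electron per phase.
# Only the composite C = H(H+) + H(e-) - H(H.) is observable from a descriptor table
# (IP + PDE - BDE = PA + ETE - BDE = C); the per-species split below is a documented convention.
# gas: H(H+) = 5/2 RT = 1.481; H(e-) = 0.752 (electron-convention translational enthalpy);
#   H(H.) closes the gas composite C = 313.3 inferred from the bundled descriptor table.
# water/ethanol: H(H.) kept at the gas value (neutral-atom solvation neglected); H(e-) carries a
#   literature-style solvation enthalpy (-37.3 water, -34.0 ethanol); H(H+) absorbs the remaining
#   calibration so that C matches the solvent composites 53.9 and 47.0 inferred from the table.
# Override with any file of the same layout via the refs-path arguments / --refs CLI flag.
phase,h_hydrogen_atom,h_proton,h_electron,provenance
gas,-311.067,1.481,0.752,"H(H+)=5/2 RT; H(e-) electron convention; H(H.) calibrated to composite C=313.3"
water,-311.067,-220.619,-36.548,"H(H.) gas value; H(e-) incl. solvation -37.3; H(H+) calibrated to composite C=53.9"
ethanol,-311.067,-230.819,-33.248,"H(H.) gas value; H(e-) incl. solvation -34.0; H(H+) calibrated to composite C=47.0"
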