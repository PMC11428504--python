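# Gas-phase reaction thermodynamics and kinetics for H-atom abstraction from Pt-3-O-glc by the
# hydroxyl radical at 298.15 K, transcribed verbatim from the published kinetics table.
# delta_g and delta_g_activation (kcal/mol) are referenced to the pre-reaction complex (RC).
# k_ref (M^-1 s^-1) is the published rate constant, carried as a reference column only: the sigma,
# kappa and reference-state choices behind it are not published, so it is never a recompute target.
reaction_id,compound,site,phase,temperature,delta_g,delta_g_activation,k_ref
Pt-3'-OH+OH,Pt-3-O-glc,3'-OH,gas,298.15,-22.7,9.8,7.45e7
Pt-4'-OH+OH,Pt-3-O-glc,4'-OH,gas,298.15,-31.1,7.6,5.72e9
Pt-5-OH+OH,Pt-3-O-glc,5-OH,gas,298.15,-24.0,8.1,1.33e9
Pt-7-OH+OH,Pt-3-O-glc,7-OH,gas,298.15,-21.2,8.3,9.31e8
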