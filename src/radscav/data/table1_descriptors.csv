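# Thermodynamic antioxidant descriptors for the five grape-skin anthocyanin-3-O-glucosides,
# transcribed verbatim from the published descriptor table (kcal/mol, one decimal).
# IP is site-independent within a compound-phase and is repeated on every site row.
# Note: the Cy-3-O-glc block is transcribed exactly as printed (4'-OH 94.0, 5'-OH 89.8 in gas),
# although the accompanying discussion quotes Cy 4'-OH = 89.8; see section321_bde_ranking.csv.
compound,site,phase,bde,ip,pde,pa,ete
Cy-3-O-glc,4'-OH,gas,94.0,244.5,162.8,255.7,151.6
Cy-3-O-glc,5'-OH,gas,89.8,244.5,158.6,268.0,135.1
Cy-3-O-glc,5-OH,gas,94.2,244.5,163.0,247.0,160.5
Cy-3-O-glc,7-OH,gas,96.7,244.5,165.5,246.3,163.7
Cy-3-O-glc,4'-OH,water,88.9,139.7,3.1,25.8,117.0
Cy-3-O-glc,5'-OH,water,87.5,139.7,1.8,30.1,111.4
Cy-3-O-glc,5-OH,water,93.9,139.7,8.1,23.0,124.8
Cy-3-O-glc,7-OH,water,96.6,139.7,10.8,22.4,128.1
Cy-3-O-glc,4'-OH,ethanol,88.2,135.9,-0.7,25.0,110.3
Cy-3-O-glc,5'-OH,ethanol,86.8,135.9,-2.1,30.2,103.6
Cy-3-O-glc,5-OH,ethanol,93.1,135.9,4.2,21.7,118.4
Cy-3-O-glc,7-OH,ethanol,95.7,135.9,6.8,20.9,121.8
Dp-3-O-glc,3'-OH,gas,94.7,243.2,164.8,276.7,131.3
Dp-3-O-glc,4'-OH,gas,86.7,243.2,156.9,250.2,149.8
Dp-3-O-glc,5'-OH,gas,90.6,243.2,160.7,268.0,135.9
Dp-3-O-glc,5-OH,gas,94.1,243.2,164.2,246.9,160.5
Dp-3-O-glc,7-OH,gas,96.9,243.2,167.0,246.3,163.9
Dp-3-O-glc,3'-OH,water,89.6,139.4,4.2,31.6,112.0
Dp-3-O-glc,4'-OH,water,84.0,139.4,-1.4,23.1,114.9
Dp-3-O-glc,5'-OH,water,88.5,139.4,3.1,29.8,112.7
Dp-3-O-glc,5-OH,water,93.9,139.4,8.4,22.9,124.9
Dp-3-O-glc,7-OH,water,96.6,139.4,11.2,22.5,128.1
Dp-3-O-glc,3'-OH,ethanol,89.2,135.6,0.7,32.6,103.6
Dp-3-O-glc,4'-OH,ethanol,83.4,135.6,-5.2,22.0,108.4
Dp-3-O-glc,5'-OH,ethanol,87.6,135.6,-0.9,29.9,104.8
Dp-3-O-glc,5-OH,ethanol,93.2,135.6,4.7,21.6,118.7
Dp-3-O-glc,7-OH,ethanol,96.1,135.6,7.5,20.9,122.2
Pn-3-O-glc,4'-OH,gas,93.4,240.0,166.8,257.2,149.6
Pn-3-O-glc,5-OH,gas,93.9,240.0,167.3,247.7,159.6
Pn-3-O-glc,7-OH,gas,96.4,240.0,169.7,247.2,162.5
Pn-3-O-glc,4'-OH,water,88.6,138.5,4.1,26.5,116.0
Pn-3-O-glc,5-OH,water,93.7,138.5,9.2,23.0,124.6
Pn-3-O-glc,7-OH,water,96.9,138.5,12.4,22.6,128.2
Pn-3-O-glc,4'-OH,ethanol,88.0,134.5,0.5,25.6,109.4
Pn-3-O-glc,5-OH,ethanol,93.0,134.5,5.5,21.6,118.5
Pn-3-O-glc,7-OH,ethanol,95.8,134.5,8.3,21.0,121.8
Mv-3-O-glc,4'-OH,gas,87.4,234.8,165.9,255.5,145.3
Mv-3-O-glc,5-OH,gas,93.9,234.8,172.4,248.2,159.0
Mv-3-O-glc,7-OH,gas,96.4,234.8,174.9,247.8,162.0
Mv-3-O-glc,4'-OH,water,86.3,138.9,1.4,24.9,115.4
Mv-3-O-glc,5-OH,water,93.3,138.9,8.3,22.8,124.4
Mv-3-O-glc,7-OH,water,97.0,138.9,12.1,22.3,128.6
Mv-3-O-glc,4'-OH,ethanol,85.0,134.0,-2.0,23.7,108.3
Mv-3-O-glc,5-OH,ethanol,93.0,134.0,6.0,21.2,118.9
Mv-3-O-glc,7-OH,ethanol,95.5,134.0,8.5,20.6,122.0
Pt-3-O-glc,3'-OH,gas,94.6,239.6,168.4,278.0,130.0
Pt-3-O-glc,4'-OH,gas,86.2,239.6,160.0,251.7,147.8
Pt-3-O-glc,5-OH,gas,94.0,239.6,167.7,247.7,159.6
Pt-3-O-glc,7-OH,gas,96.7,239.6,170.4,247.3,162.7
Pt-3-O-glc,3'-OH,water,89.6,138.1,5.4,32.7,110.9
Pt-3-O-glc,4'-OH,water,83.7,138.1,-0.4,23.8,113.9
Pt-3-O-glc,5-OH,water,93.8,138.1,9.7,22.8,125.0
Pt-3-O-glc,7-OH,water,96.8,138.1,12.7,22.2,128.6
Pt-3-O-glc,3'-OH,ethanol,89.1,134.3,1.8,33.2,102.9
Pt-3-O-glc,4'-OH,ethanol,83.0,134.3,-4.3,22.5,107.5
Pt-3-O-glc,5-OH,ethanol,93.2,134.3,5.9,21.5,118.8
Pt-3-O-glc,7-OH,ethanol,96.0,134.3,8.7,20.8,122.3
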