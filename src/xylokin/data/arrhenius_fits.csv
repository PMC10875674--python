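# High-pressure-limit Arrhenius parameters for the two kinetic models,
# fitted over 300-1000 K.  A in 1/s (all forward steps are unimolecular),
# Ea in kJ/mol.  rss is the fit residual sum of squares as published
# (definition/units unstated there; retained for provenance only).
# reactants/products are ';'-separated species names from species_thermo.csv.
id,reactants,products,A,Ea,rss
R1,xylopyranose,xylose,2.53e12,181.8,7.30e-2
R2,xylopyranose,TH-C-OH2-c;H2O,7.08e13,305.1,1.80e-13
R3,xylopyranose,TH-C-OH2-t;H2O,6.42e13,280.8,7.90e-11
R4,xylopyranose,AXP_1;H2O,4.60e14,289.7,4.70e-9
R5,xylopyranose,AXP_2-1;H2O,2.76e14,349.9,9.90e-16
R6,xylopyranose,AXP_2-3;H2O,1.23e14,309.8,4.60e-12
R7,xylopyranose,AXP_3-2;H2O,4.58e13,295.4,2.60e-11
R8,xylopyranose,AXP_3-4;H2O,2.32e13,296.2,3.60e-12
R9,xylopyranose,AXP_4-3;H2O,1.26e13,296.5,1.10e-12
R10,xylopyranose,AXP_4-5;H2O,8.83e12,283.3,1.60e-11
R11,xylose,A1;H2O,1.17e15,273.4,7.30e-8
R12,xylose,B1,4.17e12,156.4,12.4
R13,xylose,C1;C2,1.76e14,166.5,421.5
R14,xylose,D1,4.38e13,182.7,6e-1
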