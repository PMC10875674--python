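# Forward/reverse barrier heights for the ten initial xylopyranose
# decomposition channels (coupled-cluster refined).  dh0 columns are
# 0 K enthalpy barriers (ZPE-inclusive), dh298/dg298/dg673 are the
# 298.15 K and 673.15 K activation enthalpies / free energies.
# All values kJ/mol.  reaction ids match arrhenius_fits.csv.
id,channel,dh0_f,dh0_r,dh298_f,dh298_r,dg298_f,dg298_r,dg673_f,dg673_r
R1,xylopyranose = xylose,183.8,165.7,181.9,163.7,185.5,170.0,191.2,179.1
R2,xylopyranose = TH-C-OH2-c + H2O,299.3,260.1,299.2,254.0,297.1,302.1,294.9,362.8
R3,xylopyranose = TH-C-OH2-t + H2O,274.7,233.0,275.4,227.6,273.1,275.9,270.0,336.2
R4,xylopyranose = AXP_1 + H2O,281.9,229.2,283.0,223.7,278.2,267.4,271.7,322.7
R5,xylopyranose = AXP_2-1 + H2O,345.6,333.0,346.1,326.8,342.8,373.3,338.1,432.0
R6,xylopyranose = AXP_2-3 + H2O,306.4,283.3,306.4,277.4,304.3,323.2,301.4,381.0
R7,xylopyranose = AXP_3-2 + H2O,293.0,267.2,292.8,261.0,292.1,308.2,290.8,367.7
R8,xylopyranose = AXP_3-4 + H2O,292.9,271.8,293.2,266.0,293.5,314.1,293.1,374.5
R9,xylopyranose = AXP_4-3 + H2O,294.5,270.3,294.2,263.8,295.8,313.2,297.0,375.4
R10,xylopyranose = AXP_4-5 + H2O,281.6,259.9,281.1,253.5,283.3,301.9,285.6,363.0
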