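# Gas-phase thermochemistry of the xylopyranose pyrolysis species set.
# dhf298 and dhf298_so in kJ/mol (so = spin-orbit corrected); atct_ref in kJ/mol
# (blank where no Active Thermochemical Tables value exists); s298 in J/mol/K;
# cp columns in J/mol/K at the temperature (K) in the header.
# formula is the printed stoichiometric formula; formula_corrected holds the
# element-balanced formula where the printed one is inconsistent (ADX only).
name,dhf298,dhf298_so,atct_ref,s298,cp300,cp400,cp500,cp600,cp800,cp1000,cp1500,formula,formula_corrected
xylopyranose,-881.85,-888.28,,400.15,168.60,212.33,250.57,281.98,328.47,360.92,410.09,C5H10O5,
xylose,-863.55,-869.99,,409.57,171.62,215.28,252.83,283.55,329.18,361.29,410.35,C5H10O5,
AXP_1,-579.18,-584.68,,374.16,145.63,183.44,215.83,242.12,280.73,307.53,348.08,C5H8O4,
AXP_2-1,-619.09,-624.60,,378.62,145.71,183.62,216.06,242.34,280.86,307.59,348.05,C5H8O4,
AXP_2-3,-609.46,-614.96,,372.30,142.96,181.49,214.35,240.96,279.99,307.05,347.90,C5H8O4,
AXP_3-2,-606.71,-612.21,,372.20,143.30,181.82,214.64,241.21,280.16,307.17,347.94,C5H8O4,
AXP_3-4,-611.31,-616.81,,371.74,144.00,182.39,215.10,241.58,280.41,307.34,348.00,C5H8O4,
AXP_4-3,-608.00,-613.50,,372.20,144.38,182.17,214.65,241.12,280.16,307.30,348.21,C5H8O4,
AXP_4-5,-610.90,-616.40,,366.35,141.94,181.27,214.60,241.40,280.37,307.26,347.86,C5H8O4,
TH-C-OH2-c,-593.26,-598.76,,379.99,141.11,178.95,212.07,239.24,279.45,307.41,349.06,C5H8O4,
TH-C-OH2-t,-590.67,-596.17,,381.12,142.38,180.11,213.09,240.09,279.98,307.70,349.10,C5H8O4,
H2O,-243.39,-244.33,-241.80,188.58,33.49,34.14,35.09,36.14,38.31,40.56,45.79,H2O,
A1,-561.33,-566.83,,407.14,156.54,191.10,220.99,245.64,282.60,308.75,348.74,C5H8O4,
A2,-613.36,-618.86,,398.08,150.92,185.97,216.65,242.12,280.54,307.77,348.99,C5H8O4,
A2-a1,-638.29,-643.79,,372.11,138.94,177.85,211.35,238.63,278.87,306.83,348.61,C5H8O4,
A2-a2,-353.77,-358.34,,324.63,102.53,137.73,168.03,192.47,227.99,252.14,286.96,C5H6O3,
A2-b1,-239.54,-242.46,,297.75,80.64,98.67,113.78,126.12,144.71,158.00,178.41,C3H4O2,
A2-c1,-640.37,-645.87,,374.94,141.34,179.95,213.12,240.11,279.93,307.62,349.07,C5H8O4,
A2-c2,-352.54,-357.11,,349.10,119.23,151.44,178.62,200.53,232.59,254.72,287.45,C5H6O3,
A2-c3,-321.83,-326.40,,356.25,119.05,149.98,176.78,198.72,231.19,253.69,286.94,C5H6O3,
B1,-870.30,-876.73,,404.95,167.49,212.32,251.14,282.70,328.99,361.15,410.02,C5H10O5,
C1,-273.58,-276.15,,285.09,71.62,86.89,99.80,110.21,125.62,136.66,154.38,C2H4O2,
C2,-468.24,-472.10,,344.19,107.31,129.65,149.81,166.81,192.78,211.45,240.27,C3H6O3,
D1,-858.35,-864.78,,432.34,179.13,220.24,256.24,286.00,330.57,362.10,410.53,C5H10O5,
D1-a1,-888.39,-894.82,,398.66,167.16,212.91,251.91,283.39,329.38,361.32,410.01,C5H10O5,
D1-a2,-551.37,-556.87,,379.80,146.00,183.41,215.63,241.90,280.61,307.54,348.22,C5H8O4,
D1-a3,-289.31,-293.87,,347.18,120.49,153.03,180.15,201.76,232.99,254.39,286.41,C5H6O3,
D1-b1,-393.44,-397.30,,335.53,96.73,114.71,130.71,144.24,165.02,179.84,202.08,C3H4O3,
D1-c1,-465.91,-469.77,,334.00,107.56,131.65,152.17,168.90,193.79,211.51,239.37,C3H6O3,
D1-d1,-587.81,-593.31,,401.20,155.69,190.43,220.44,245.17,282.25,308.48,348.61,C5H8O4,
D1-d2,-618.65,-624.15,,409.75,153.28,187.19,217.22,242.34,280.49,307.65,348.88,C5H8O4,
D1-d3,-646.38,-651.88,,378.07,142.23,180.31,213.11,239.87,279.48,307.12,348.63,C5H8O4,
D1-d4,-356.41,-360.98,,352.05,117.40,148.64,175.56,197.60,230.26,252.94,286.50,C5H6O3,
D1-d5,-356.18,-360.74,,351.27,114.60,145.85,173.19,195.78,229.59,253.16,287.56,C5H6O3,
D1-d6,-417.52,-421.73,,353.82,120.65,147.04,169.31,187.50,214.69,234.02,263.77,C4H6O3,
D1-d7,-454.25,-458.46,,365.85,120.52,144.80,166.40,184.66,212.84,233.17,264.16,C4H6O3,
DFO,-270.05,-273.34,,309.03,87.36,114.04,137.85,157.71,187.74,208.97,240.49,C4H6O2,
ETH,-119.77,-121.41,-123.72,256.18,56.08,69.14,80.44,89.76,103.98,114.48,131.47,C2H4O,
FF,-117.08,-120.72,,318.60,91.29,116.89,138.81,156.52,182.29,199.77,224.85,C5H4O2,
MGO,-253.47,-256.39,,312.78,82.58,98.26,112.38,124.53,143.70,157.73,179.02,C3H4O2,
DHA,-505.26,-509.12,,340.30,105.62,128.26,148.65,165.85,192.19,211.14,240.30,C3H6O3,
AD,-161.67,-163.31,-165.55,262.97,55.20,66.29,76.99,86.51,102.04,113.79,132.21,C2H4O,
CO,-97.79,-99.08,-110.52,197.40,29.12,29.25,29.60,30.15,31.48,32.71,34.75,CO,
ADX,-593.37,-598.87,,352.68,129.44,171.17,207.15,236.09,277.89,306.35,348.36,C5H4O4,C5H8O4
FD,-103.99,-105.27,-109.23,218.48,35.14,38.61,42.84,47.10,54.66,60.66,70.15,CH2O,
HAA,-306.78,-309.36,-317.50,284.71,67.95,82.06,95.00,106.08,123.33,135.90,155.27,C2H4O2,
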