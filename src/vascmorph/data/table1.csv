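# Per-specimen morphometry of postnatal Monodelphis domestica lungs.
# Units: age_dpn = days post natum (0 = neonate, first 24 h); body_mass_g = g;
# all volumes in mm^3. Lung and bronchial-tree volumes were measured in the
# same specimens in earlier reconstructions and are carried along as columns.
age_dpn,specimen,body_mass_g,lung_volume_mm3,bronchial_tree_volume_mm3,pulmonary_artery_volume_mm3,pulmonary_vein_volume_mm3
0,1965_1,0.12,2.70,0.21,0.06,0.06
0,2350_1,0.13,1.73,0.09,0.08,0.08
0,2350_7,0.13,2.74,0.24,0.08,0.03
4,1995_5,0.22,4.10,0.16,0.10,0.06
4,2257_6,0.21,4.19,0.23,0.09,0.11
4,2257_8,0.21,5.60,0.24,0.12,0.10
7,1987_5,0.34,6.08,0.42,0.11,0.07
7,2383_2,0.28,5.63,0.68,0.14,0.08
11,1993_2,0.69,20.58,1.00,0.30,0.18
14,1994_9,0.98,24.87,2.10,0.45,0.42
21,2040,2.43,71.14,4.00,1.86,1.54
28,2059,4.22,189.75,13.08,4.68,3.15
35,2065,7.25,388.59,28.71,8.97,9.03
49,2049,13.64,504.03,25.38,14.97,13.65
57,2179,31.58,1176.68,103.51,28.20,29.01
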