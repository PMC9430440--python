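# Partial-charge topology for water / DMSO mixtures.
# Water SOL: SPC/E 3-site charges. TIP4: 4-site water with a massless
# M-site on the HOH bisector (TIP4P-Ew-style charges, O-M 0.125 A),
# geometry rule in the vsite_distance column. DMSO: Luzar-Chandler P2
# united-atom model (methyl groups as single CM sites). GAS: neutral
# single-site ideal-gas particle. Charges in elementary charge units.
residue,site,charge,vsite_distance
SOL,OW,-0.8476,
SOL,HW1,0.4238,
SOL,HW2,0.4238,
TIP4,OW,0.0,
TIP4,HW1,0.52422,
TIP4,HW2,0.52422,
TIP4,M,-1.04844,0.125
DMS,S,0.139,
DMS,OS,-0.459,
DMS,CM1,0.160,
DMS,CM2,0.160,
GAS,X,0.0,
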