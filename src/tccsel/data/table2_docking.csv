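compound,receptor,delta_g_kcal_mol,binding_domain,binding_residue,bond_type
NNC 55-0395,α1C,-6.0,IV,3p49,hydrogen
NNC 55-0396,α1C,N/A,N/A,N/A,none
NNC 55-0397,α1C,-6.4,IV,N/A,none
Mibefradil,α1C,-6.4,IV,4i27,hydrogen
RO 40-5966,α1C,-5.7,IV,4p49,hydrogen
SKF-96365,α1C,N/A,IV,N/A,none
NNC 55-0395,α1G,-6.5,I,1p51,halogen
NNC 55-0396,α1G,-8.1,I,1i20,hydrogen
NNC 55-0397,α1G,-7.4,I,1p46,halogen
Mibefradil,α1G,-6.8,I,1o4,hydrogen
RO 40-5966,α1G,-7.3,I,1i27,hydrogen
SKF-96365,α1G,-5.6,I,1o4,hydrogen
NNC 55-0395,α1H,-6.6,I,1p46,hydrogen
NNC 55-0396,α1H,-7.7,I,1i8,halogen
NNC 55-0397,α1H,-7.0,IV,4p51,hydrogen
Mibefradil,α1H,-7.4,I,1o4,hydrogen
RO 40-5966,α1H,-7.4,IV,4i29,halogen
SKF-96365,α1H,-5.4,I,1o4,hydrogen
NNC 55-0395,α1I,-6.6,I,1i8,halogen
NNC 55-0396,α1I,-7.7,I,1o4,hydrogen
NNC 55-0397,α1I,-7.5,I,1p46,hydrogen
Mibefradil,α1I,-6.5,IV,4p53,halogen
RO 40-5966,α1I,-6.9,I,1o4,hydrogen
SKF-96365,α1I,N/A,N/A,N/A,none
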