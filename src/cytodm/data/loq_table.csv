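cytokine,uloq_pg_ml,lloq_pg_ml
MIP-1α,1880,1.84
IL-27,82000,20
IL-1β,8250,2.01
IL-2,26900,6.57
IL-5,30400,7.42
IP-10,7750,1.89
IL-6,37800,9.23
IL-8,9850,2.4
IL-17A,9550,2.33
IFN-γ,12675,12
GM-CSF,41000,10
TNF-α,29500,7.2
MCP-1,14800,3.61
IL-9,31000,7.57
IL-1α,3000,0.73
IL-18,49500,12
IL-21,39700,9.69
IL-22,82500,20
P-selectin,5051600,1233
sICAM1,870200,212
IL-4,36200,8.84
IL-10,9250,2.26
IL-12p70,28100,6.86
IL-13,13400,3.27
IL-23,68500,17
IFN-α,2250,0.55
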