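{
 "H2": 60,
 "H5": 205,
 "LE1": 228,
 "LE2": 234,
 "NPA_LB_0": 85,
 "NPA_LB_1": 86,
 "NPA_LB_2": 87,
 "NPA_LE_0": 220,
 "NPA_LE_1": 221,
 "NPA_LE_2": 222,
 "P1": 240,
 "P2": 250,
 "P3": 253,
 "P4": 256,
 "P5": 259,
 "SDP1": 35,
 "SDP2": 40,
 "SDP3": 45,
 "SDP4": 128,
 "SDP5": 133,
 "SDP6": 138,
 "SDP7": 143,
 "SDP8": 180,
 "SDP9": 185
}
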