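G0012
G0013
G0029
G0040
G0044
G0060
G0079
G0097
G0141
G0145
G0161
G0194
G0202
G0245
G0274
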