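,M-38.m1,M-38.m2,M-38.m3,M-38.m4
M-2,+,+,+,+
M-3,+,+,+,+
M-4,+,+,+,+
M-5,+,+,+,+
M-7,+,+,+,+
M-15,+,+,+,+
M-16,+,+,+,+
M-18,+,+,+,+
M-19,+,+,+,+
M-20,+,+,+,+
M-21,+,+,+,+
M-22,+,+,+,+
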