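,M-38.m1,M-38.m2,M-38.m3,M-38.m4
M-8.m1,+,+,+,+
M-8.m2,+,+,+,+
M-8.m3,+,+,+,+
M-8.m4,+,+,+,+
M-9.m1,+,+,+,+
M-9.m2,+,+,+,+
M-9.m3,+,+,+,+
M-9.m4,+,+,+,+
M-13.m1,+,+,+,+
M-13.m2,+,+,+,+
M-13.m3,+,+,+,+
M-13.m4,+,+,+,+
M-14.m1,+,+,+,+
M-14.m2,+,+,+,+
M-14.m3,+,+,+,+
M-14.m4,+,+,+,+
M-17.m1,+,+,+,+
M-17.m2,+,+,+,+
M-17.m3,+,+,+,+
M-17.m4,+,+,+,+
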