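pos_skew,neg_skew
9,9
10,26
12,36
14,43
17,48
20,52
24,55
29,58
36,60
46,62
63,63
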