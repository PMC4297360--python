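unimodal,bimodal,neg_skew,pos_skew
9,9,9,30
23,12,26,31
27,15,36,33
30,19,43,35
33,23,48,38
36,36,52,41
39,49,55,45
42,53,58,50
45,57,60,57
49,60,62,67
63,63,63,84
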