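threshold,sensitivity,specificity
0.3243723219,1,0.5
0.7051663456,1,1
0.71932833,0.5,1
0.9251393306,0,1
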