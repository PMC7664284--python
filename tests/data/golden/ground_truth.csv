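subject_id,group,model,alpha,beta,p_stay_win,p_shift_lose,seed
C001,control,qlearning,0.45,4,,,3314067545
C002,control,qlearning,0.2,1.2,,,1246660094
A001,ALS,qlearning,0.15,12,,,1099913641
A002,ALS,qlearning,0.2,9,,,3151871211
C003,control,wsls,,,0.92,0.9,2347398175
A003,ALS,random,,,,,1942466020
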