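subject_id,group,included,exclusion_reason
C001,control,True,none
C002,control,True,none
A001,ALS,True,none
A002,ALS,True,none
C003,control,False,non_q_strategy
A003,ALS,False,non_q_strategy
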