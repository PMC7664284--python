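subject_id,group,alpha,beta,p_alpha_beta,behavior
C001,control,0.19268611,7.58116314,0.7051663456,anomalous
C002,control,0.1858393625,0.9916937155,0.3243723219,typical
A001,ALS,0.1801048534,14.21954342,0.9251393306,anomalous
A002,ALS,0.1971085939,7.886042871,0.71932833,anomalous
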