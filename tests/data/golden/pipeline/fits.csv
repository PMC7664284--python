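subject_id,group,acquisition_score,reversal_score,total_score,model,alpha,beta,p_stay_win,p_shift_lose,loglik_q,loglik_wsls,loglik_random,aic_q,aic_wsls,aic_random,n_valid_trials,converged,at_bound
C001,control,46,42,88,qlearning,0.19268611,7.58116314,0.9540229885,0.3125,-23.85671804,-36.7929696,-83.17766167,51.71343608,77.5859392,166.3553233,120,True,False
C002,control,33,35,68,qlearning,0.1858393625,0.9916937155,0.5735294118,0.6078431373,-78.63858516,-81.24404632,-83.17766167,161.2771703,166.4880926,166.3553233,120,True,False
A001,ALS,45,43,88,qlearning,0.1801048534,14.21954342,0.9655172414,0.1875,-12.55507597,-29.18518762,-83.17766167,29.11015195,62.37037524,166.3553233,120,True,False
A002,ALS,43,42,85,qlearning,0.1971085939,7.886042871,0.9761904762,0.2571428571,-19.64643025,-30.09613661,-83.17766167,43.29286051,64.19227323,166.3553233,120,True,False
C003,control,37,39,76,wsls,1,2.716671087,0.9333333333,0.8409090909,-46.59418998,-38.34190927,-83.17766167,97.18837996,80.68381854,166.3553233,120,True,True
A003,ALS,32,31,63,random,0.02331059973,1.097040338,0.5322580645,0.5964912281,-82.90284666,-81.98044792,-83.17766167,169.8056933,167.9608958,166.3553233,120,True,False
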