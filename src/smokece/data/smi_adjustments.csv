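parameter,mean,sd,family
rr_mortality,2.22,0.02,lognormal
or_comorbidity,3.10,0.29,lognormal
smi_disutility,0.125,0.013,beta
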