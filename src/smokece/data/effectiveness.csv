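arm,quit_prob_12m,sd
bsci,0.173,0.024
usual_care,0.119,0.020
integrated_care,0.089,0.013
scc_referral,0.045,0.010
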