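arm,quit_prob_12m,sd
bsci,0.225,0.027
usual_care,0.160,0.025
integrated_care,0.180,0.022
scc_referral,0.090,0.014
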