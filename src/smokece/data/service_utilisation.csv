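arm,gbp
bsci,7903
usual_care,8667
integrated_care,18091
scc_referral,18941
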