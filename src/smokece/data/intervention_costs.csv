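arm,component,gbp
bsci,training,165
bsci,supervision,33
bsci,delivery,243
bsci,pharmacotherapy,94
bsci,standard_care,53
bsci,total_printed,581
usual_care,pharmacotherapy,30
usual_care,standard_care,67
usual_care,total_printed,96
integrated_care,pharmacotherapy,362
integrated_care,counsellor_visits,601
integrated_care,total_printed,963
scc_referral,pharmacotherapy,251
scc_referral,counsellor_visits,162
scc_referral,total_printed,412
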