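condition,annual_cost_mean,annual_cost_sd,utility_mean,utility_sd,smi_adjustable
asthma,1433,215,0.73,0.11,false
copd,636,95,0.73,0.11,true
chd,1178,177,0.76,0.03,true
lung_cancer,10772,1616,0.61,0.09,true
mi,1135,170,0.80,0.12,true
stroke,5618,842,0.48,0.07,true
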