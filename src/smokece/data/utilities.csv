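parameter,mean,sd
base_nonsmoker,0.88,0.13
decrement_current,0.04,0.01
decrement_former,0.02,0.01
smi_decrement,0.125,0.013
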