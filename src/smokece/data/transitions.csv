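parameter,mean,sd
net_cessation,0.02,0.003
relapse,0.0,0.0
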