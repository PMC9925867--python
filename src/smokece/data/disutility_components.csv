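condition,disutility,weight
mood_disorder,0.196,0.388
anxiety_disorder,0.043,0.516
substance_misuse_disorder,0.278,0.096
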