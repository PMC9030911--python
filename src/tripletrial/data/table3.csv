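row,control,fear,social
consistent_week6_consistent,40,35,45
consistent_week6_inconsistent,20,25,14
inconsistent_week6_consistent,18,28,29
inconsistent_week6_inconsistent,32,30,28
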