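row,control,fear,social
baseline_consistent,69,69,69
baseline_inconsistent,61,62,61
week3_consistent,62,62,70
week3_inconsistent,51,55,52
week6_consistent,58,63,74
week6_inconsistent,52,55,42
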